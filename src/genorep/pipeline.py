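"""End-to-end pipeline: simulate a replicate study, run QC, compute
concordance summaries, and optionally the odds-ratio surface, writing all
artifacts plus a run manifest (versions, seeds, parameters, checksums).

All randomness flows from one root seed; stage seeds are derived
deterministically from it, so a rerun with the same configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .concord import LEVELS, concordance_matrix, reproducibility_summary
from .core import table1_design
from .errorsim import SimConfig, percentile_surface
from .io import write_design_tsv, write_genotype_tsv
from .repqc import QCRules, exclusion_impact, flag_outlier_replicates, per_sample_stats
from .synthdata import ErrorModel, generate_truth, inject_low_quality, simulate_replicate_study


@dataclass(frozen=True)
class StudyConfig:
    """Synthetic-study stage parameters (defaults: the canonical six-subject,
    four-replicate, five-experiment design at a desk-scale SNP count)."""

    n_subjects: int = 6
    n_replicates: int = 4
    n_snps: int = 20_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    call_error_rate: Any = 0.003
    nocall_rate: Any = 0.005
    scheme: str = "uniform_other"
    experiments: dict | None = None  # experiment -> platform; None = E1..E5
    inject: tuple = ()  # records: {sample_id, het_inflation, callrate_drop}


@dataclass(frozen=True)
class RunConfig:
    """Umbrella configuration for one pipeline run."""

    out_dir: str = "genorep_run"
    seed: int = 0
    study: StudyConfig = field(default_factory=StudyConfig)
    qc: QCRules = field(default_factory=QCRules)
    mode: str = "co_called"
    levels: tuple = tuple(LEVELS)
    write_matrix: bool = True
    errorsim: SimConfig | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "study" in d:
            s = dict(d["study"])
            if "inject" in s:
                s["inject"] = tuple(dict(r) for r in s["inject"])
            d["study"] = StudyConfig(**s)
        if "qc" in d:
            d["qc"] = QCRules(**d["qc"])
        if "levels" in d:
            d["levels"] = tuple(d["levels"])
        if d.get("errorsim") is not None:
            e = dict(d["errorsim"])
            for key in ("maf_grid", "concordance_grid"):
                if key in e:
                    e[key] = tuple(e[key])
            d["errorsim"] = SimConfig(**e)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF for child in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages, write artifacts and manifest.json to
    ``config.out_dir`` and return the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 3 + len(config.study.inject))

    s = config.study
    panel, truth = generate_truth(s.n_subjects, s.n_snps, s.maf_low, s.maf_high, seeds[0])
    design = table1_design(
        n_replicates=s.n_replicates,
        subjects=truth.sample_ids,
        experiment_platforms=s.experiments,
    )
    model = ErrorModel(s.call_error_rate, s.nocall_rate, s.scheme)
    calls = simulate_replicate_study(truth, design, model, seeds[1])
    for k, rec in enumerate(s.inject):
        calls = inject_low_quality(
            calls,
            rec["sample_id"],
            rec.get("het_inflation", 0.0),
            rec.get("callrate_drop", 0.0),
            seeds[3 + k],
        )

    artifacts: dict[str, Path] = {}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        artifacts[name] = path

    emit("calls.tsv", lambda p: write_genotype_tsv(p, calls))
    emit("design.tsv", lambda p: write_design_tsv(p, design))

    stats = per_sample_stats(calls)
    report = flag_outlier_replicates(stats, design, config.qc)
    qc_table = stats.merge(
        report.flags.groupby("sample_id")["rule"].apply(lambda r: ";".join(sorted(r))).rename(
            "flags"
        ),
        on="sample_id",
        how="left",
    )
    qc_table["flags"] = qc_table["flags"].fillna("")
    qc_table["retained"] = ~qc_table["sample_id"].isin(set(report.flagged))
    emit("qc_report.tsv", lambda p: qc_table.to_csv(p, sep="\t", index=False))

    if config.write_matrix:
        cm = concordance_matrix(calls, mode=config.mode)
        emit("concordance_matrix.tsv", lambda p: cm.to_csv(p, sep="\t"))

    for level in config.levels:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, summary = reproducibility_summary(calls, design, level, config.mode)
        emit(f"summary_{level}.tsv",
             lambda p, df=summary: df.to_csv(p, sep="\t", index=False))

    impact = exclusion_impact(calls, design, report, config.mode)
    emit("exclusion_impact.tsv", lambda p: impact.to_csv(p, sep="\t", index=False))

    if config.errorsim is not None:
        surface = percentile_surface(config.errorsim)
        emit("surface.tsv",
             lambda p: surface.to_frame().to_csv(p, sep="\t", index=False))

    retained_per_exp = (
        design.table[design.table["sample_id"].isin(set(report.retained))]
        .groupby("experiment")["sample_id"]
        .count()
        .to_dict()
    )
    manifest = {
        "package": "genorep",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": _jsonable(asdict(config)),
        "qc": {
            "n_samples": int(len(stats)),
            "n_flagged": int(len(report.flagged)),
            "n_retained": int(len(report.retained)),
            "retained_per_experiment": {k: int(v) for k, v in retained_per_exp.items()},
        },
        "outputs": {name: _sha256(path) for name, path in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
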