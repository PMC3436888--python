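"""Synthetic replicate-study generator.

Emulates a six-subject, four-replicate, five-experiment genotyping study:
truth genotypes are drawn per subject under Hardy-Weinberg equilibrium with
per-SNP minor allele frequencies sampled uniformly from a configurable band,
and each designed technical replicate is a noisy copy of its subject's truth
with per-experiment no-call and call-error rates. Low-quality arrays
(inflated heterozygosity, depressed call rate) can be injected into single
samples to exercise the replicate-based QC stage.

Error model
-----------
Under the ``uniform_other`` scheme each call is independently turned into a
no-call with probability ``nocall_rate`` and otherwise reassigned, with
probability ``call_error_rate``, to one of the two other genotype classes
chosen uniformly. Two replicates of the same subject then agree at a called
SNP with probability ``1 - 2e + 1.5e**2`` (both unchanged, or both flipped
to the same class). Under ``direct_pairwise`` the same flip rule is applied
to a designated reference call set instead of the truth, so the expected
concordance against the reference is exactly ``1 - e`` (every flip changes
the class).

Errors are independent across replicates and SNPs; no batch or plate
effects are simulated, and subjects are unrelated. All randomness flows
from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    HET,
    HOM_MAJ,
    HOM_MIN,
    NO_CALL,
    NUCLEOTIDES,
    PANEL_COLUMNS,
    GenotypeMatrix,
    SnpPanel,
    StudyDesign,
)
from .exceptions import DesignError, InvalidParameterError

SCHEMES = ("uniform_other", "direct_pairwise")


@dataclass(frozen=True)
class ErrorModel:
    """Per-experiment call-error and no-call rates plus the flip scheme.

    Rates may be single floats (applied to every experiment) or mappings
    from experiment id to rate.
    """

    call_error_rate: float | Mapping[str, float] = 0.0
    nocall_rate: float | Mapping[str, float] = 0.0
    scheme: str = "uniform_other"

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise InvalidParameterError(f"unknown reassignment scheme: {self.scheme!r}")
        for name in ("call_error_rate", "nocall_rate"):
            value = getattr(self, name)
            rates = value.values() if isinstance(value, Mapping) else [value]
            for r in rates:
                if not np.isfinite(r) or not 0.0 <= float(r) <= 1.0:
                    raise InvalidParameterError(f"{name} must lie in [0, 1], got {r!r}")

    def rates_for(self, experiment: str) -> tuple[float, float]:
        def resolve(value):
            if isinstance(value, Mapping):
                if experiment not in value:
                    raise DesignError(f"no rate configured for experiment {experiment!r}")
                return float(value[experiment])
            return float(value)

        return resolve(self.call_error_rate), resolve(self.nocall_rate)


def _subject_codes(n_subjects: int) -> list[str]:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if n_subjects <= len(letters):
        return list(letters[:n_subjects])
    return [f"S{i + 1:03d}" for i in range(n_subjects)]


def generate_truth(
    n_subjects: int,
    n_snps: int,
    maf_low: float,
    maf_high: float,
    seed: int,
    subject_codes: Sequence[str] | None = None,
) -> tuple[SnpPanel, GenotypeMatrix]:
    """Sample a SNP panel and per-subject truth genotypes under HWE.

    Per SNP, the minor allele frequency p is drawn uniformly from
    ``[maf_low, maf_high]`` and each subject's genotype from the HWE
    probabilities ((1-p)^2, 2p(1-p), p^2). Truth contains no no-calls.
    """
    if n_subjects < 1 or n_snps < 1:
        raise InvalidParameterError("n_subjects and n_snps must be >= 1")
    for v in (maf_low, maf_high):
        if not np.isfinite(v):
            raise InvalidParameterError("maf bounds must be finite")
    if not 0.0 <= maf_low <= maf_high <= 0.5:
        raise InvalidParameterError(
            f"require 0 <= maf_low <= maf_high <= 0.5, got ({maf_low}, {maf_high})"
        )
    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_low, maf_high, size=n_snps)
    a_idx = rng.integers(0, 4, size=n_snps)
    b_idx = (a_idx + rng.integers(1, 4, size=n_snps)) % 4
    nts = np.array(NUCLEOTIDES)
    panel = SnpPanel(
        pd.DataFrame(
            {
                "snp_id": [f"rs{i + 1:07d}" for i in range(n_snps)],
                "chromosome": ((np.arange(n_snps) % 22) + 1).astype(str),
                "position": 10_000 + 997 * (np.arange(n_snps) // 22),
                "allele_major": nts[a_idx],
                "allele_minor": nts[b_idx],
                "maf": maf,
            },
            columns=list(PANEL_COLUMNS),
        )
    )
    hom_maj_p = (1.0 - maf) ** 2
    het_p = 2.0 * maf * (1.0 - maf)
    u = rng.random((n_subjects, n_snps))
    calls = (u >= hom_maj_p).astype(np.int8)
    calls += (u >= hom_maj_p + het_p).astype(np.int8)
    codes = list(subject_codes) if subject_codes is not None else _subject_codes(n_subjects)
    if len(codes) != n_subjects:
        raise InvalidParameterError("subject_codes length must equal n_subjects")
    return panel, GenotypeMatrix(panel, codes, calls)


def simulate_replicate_study(
    truth: GenotypeMatrix,
    design: StudyDesign,
    model: ErrorModel,
    seed: int,
    reference: GenotypeMatrix | None = None,
) -> GenotypeMatrix:
    """Produce one noisy call row per designed sample.

    Each replicate copies its subject's source row (the truth under
    ``uniform_other``; the designated ``reference`` under
    ``direct_pairwise``, defaulting to the truth) and then, independently
    per call: with probability ``nocall_rate`` the call becomes NO_CALL,
    otherwise with probability ``call_error_rate`` it is reassigned
    uniformly to one of the two other genotype classes.
    """
    source = truth if model.scheme == "uniform_other" or reference is None else reference
    known = set(source.sample_ids)
    missing = sorted(set(design.table["subject"]) - known)
    if missing:
        raise DesignError(f"design subjects missing from truth: {missing}")
    rng = np.random.default_rng(seed)
    n = source.n_snps
    rows = np.empty((len(design.table), n), dtype=np.int8)
    for k, rec in enumerate(design.table.itertuples(index=False)):
        e, nc = model.rates_for(rec.experiment)
        calls = source.row(rec.subject).copy()
        nc_mask = rng.random(n) < nc
        err_mask = (rng.random(n) < e) & ~nc_mask & (calls != NO_CALL)
        offsets = rng.integers(1, 3, size=n, dtype=np.int8)
        flipped = (calls + offsets) % 3
        calls = np.where(err_mask, flipped, calls)
        calls[nc_mask] = NO_CALL
        rows[k] = calls
    return GenotypeMatrix(source.panel, design.sample_ids, rows)


def inject_low_quality(
    matrix: GenotypeMatrix,
    sample_id: str,
    het_inflation: float,
    callrate_drop: float,
    seed: int,
) -> GenotypeMatrix:
    """Degrade exactly one sample: turn a ``het_inflation`` fraction of its
    homozygous calls into heterozygotes (chosen uniformly) and a
    ``callrate_drop`` fraction of all its calls into no-calls.

    Emulates the failure mode where a single array shows a disparately high
    heterozygosity rate relative to its technical-replicate peers. Every
    other sample row is returned bit-identical.
    """
    for name, v in (("het_inflation", het_inflation), ("callrate_drop", callrate_drop)):
        if not np.isfinite(v) or not 0.0 <= v <= 1.0:
            raise InvalidParameterError(f"{name} must lie in [0, 1], got {v!r}")
    out = matrix.copy()
    row = out.row(sample_id)  # raises DesignError if unknown
    rng = np.random.default_rng(seed)
    hom_idx = np.flatnonzero((row == HOM_MAJ) | (row == HOM_MIN))
    n_flip = int(round(het_inflation * hom_idx.size))
    if n_flip:
        row[rng.choice(hom_idx, size=n_flip, replace=False)] = HET
    n_drop = int(round(callrate_drop * row.size))
    if n_drop:
        row[rng.choice(row.size, size=n_drop, replace=False)] = NO_CALL
    return out


def expected_intra_concordance(call_error_rate: float) -> float:
    """Closed-form expected co-called concordance between two replicates
    generated independently from the same truth under ``uniform_other``:
    both calls unchanged ((1-e)^2) or both flipped to the same other class
    (e^2/2), i.e. ``1 - 2e + 1.5e**2``.
    """
    e = call_error_rate
    return 1.0 - 2.0 * e + 1.5 * e * e
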