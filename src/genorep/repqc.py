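"""Replicate-based array quality control.

Vendor QC metrics can pass arrays whose genotypes are nonetheless corrupted;
technical replicates expose such arrays because a failing array's
heterozygosity rate stands apart from its replicate peers. This module
computes per-array call and heterozygote rates, flags outliers within
replicate groups (same subject, same experiment), and quantifies the
concordance penalty of retaining flagged arrays.

Outlier rule
------------
Within each replicate group a sample is flagged ``het_outlier`` when its
heterozygote rate deviates from the group median by more than
``max(abs_floor, k_mad * MAD)`` where MAD is the median absolute deviation
of the group's het rates. The absolute floor (default 0.02) guards against
degenerate MADs in tight groups; ``k_mad`` defaults to 5. Samples with call
rate below ``call_rate_min`` (default 0.95) are flagged ``low_call_rate``.
Groups of one cannot be evaluated for het outliers (the median is the
sample itself) and are noted; in groups of two a het gap exceeding the
floor flags the replicate farther from the experiment-wide median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import HET, NO_CALL, GenotypeMatrix, StudyDesign
from .exceptions import DesignError, InvalidParameterError
from .concord import reproducibility_summary

STATS_COLUMNS = ("sample_id", "n_snps", "n_called", "call_rate", "n_het", "het_rate")
FLAG_COLUMNS = ("sample_id", "rule", "value", "reference", "threshold")


def per_sample_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Exact per-sample call-rate and heterozygote-rate tallies.

    ``het_rate`` is heterozygous calls over *called* SNPs; it is NaN for a
    sample with zero called SNPs.
    """
    if matrix.n_samples == 0 or matrix.n_snps == 0:
        raise InvalidParameterError("matrix must contain at least one sample and one SNP")
    called = (matrix.calls != NO_CALL).sum(axis=1)
    het = (matrix.calls == HET).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_rate = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    return pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "n_snps": matrix.n_snps,
            "n_called": called,
            "call_rate": called / matrix.n_snps,
            "n_het": het,
            "het_rate": het_rate,
        },
        columns=list(STATS_COLUMNS),
    )


@dataclass(frozen=True)
class QCRules:
    """Thresholds for replicate-group outlier flagging."""

    abs_floor: float = 0.02
    k_mad: float = 5.0
    call_rate_min: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.abs_floor <= 1.0 or not 0.0 <= self.call_rate_min <= 1.0:
            raise InvalidParameterError("abs_floor and call_rate_min must lie in [0, 1]")
        if self.k_mad < 0:
            raise InvalidParameterError("k_mad must be nonnegative")


@dataclass
class QCReport:
    """Per-sample stats, fired flags, retained samples, evaluation notes."""

    stats: pd.DataFrame
    flags: pd.DataFrame
    retained: list[str]
    notes: list[str] = field(default_factory=list)
    rules: QCRules = field(default_factory=QCRules)

    @property
    def flagged(self) -> list[str]:
        return sorted(self.flags["sample_id"].unique().tolist())


def flag_outlier_replicates(
    stats: pd.DataFrame,
    design: StudyDesign,
    rules: QCRules | None = None,
) -> QCReport:
    """Flag het-rate outliers within (subject, experiment) replicate groups
    and low-call-rate samples anywhere."""
    rules = rules or QCRules()
    meta = design.meta()
    missing = [s for s in stats["sample_id"] if s not in meta.index]
    if missing:
        raise DesignError(f"samples missing from design: {missing}")
    merged = stats.merge(design.table, on="sample_id", how="left")

    flags: list[dict] = []
    notes: list[str] = []

    low = merged[merged["call_rate"] < rules.call_rate_min]
    for rec in low.itertuples(index=False):
        flags.append(
            {"sample_id": rec.sample_id, "rule": "low_call_rate",
             "value": float(rec.call_rate), "reference": rules.call_rate_min,
             "threshold": rules.call_rate_min}
        )

    exp_median = merged.groupby("experiment")["het_rate"].median()
    for (subject, experiment), grp in merged.groupby(["subject", "experiment"], sort=True):
        het = grp["het_rate"].to_numpy(dtype=float)
        ids = grp["sample_id"].tolist()
        ok = ~np.isnan(het)
        if ok.sum() <= 1:
            notes.append(
                f"group ({subject}, {experiment}): <2 evaluable replicates; "
                "no het_outlier evaluation"
            )
            continue
        if ok.sum() == 2:
            (i1, i2) = np.flatnonzero(ok)
            gap = abs(het[i1] - het[i2])
            if gap > rules.abs_floor:
                ref = float(exp_median.loc[experiment])
                far = i1 if abs(het[i1] - ref) >= abs(het[i2] - ref) else i2
                flags.append(
                    {"sample_id": ids[far], "rule": "het_outlier",
                     "value": float(het[far]), "reference": ref,
                     "threshold": rules.abs_floor}
                )
            continue
        vals = het[ok]
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        thr = max(rules.abs_floor, rules.k_mad * mad)
        for i in np.flatnonzero(ok):
            if abs(het[i] - med) > thr:
                flags.append(
                    {"sample_id": ids[i], "rule": "het_outlier",
                     "value": float(het[i]), "reference": med, "threshold": thr}
                )

    flags_df = pd.DataFrame(flags, columns=list(FLAG_COLUMNS))
    flagged = set(flags_df["sample_id"])
    retained = [s for s in stats["sample_id"] if s not in flagged]
    return QCReport(stats=stats, flags=flags_df, retained=retained, notes=notes, rules=rules)


def exclusion_impact(
    matrix: GenotypeMatrix,
    design: StudyDesign,
    report: QCReport,
    mode: str = "co_called",
) -> pd.DataFrame:
    """Intra-group concordance computed twice — all samples vs retained only.

    One row per (subject, experiment) replicate group with the mean pair
    concordance including flagged arrays (``mean_all``), excluding them
    (``mean_retained``, NaN when fewer than two replicates remain), and the
    difference ``delta = mean_retained - mean_all`` (positive when exclusion
    helps).
    """
    _, all_summary = reproducibility_summary(matrix, design, "intra", mode)
    retained_set = set(report.retained)
    keep = design.table["sample_id"].isin(retained_set)
    sub_design_tbl = design.table[keep].reset_index(drop=True)
    if sub_design_tbl.empty:
        raise DesignError("no retained samples")
    sub_design = StudyDesign(sub_design_tbl)
    sub_matrix = matrix.subset_samples(sub_design_tbl["sample_id"].tolist())
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        _, kept_summary = reproducibility_summary(sub_matrix, sub_design, "intra", mode)

    a = all_summary[all_summary["subject"] != "ALL"][["subject", "group", "mean", "n_pairs"]]
    a = a.rename(columns={"group": "experiment", "mean": "mean_all", "n_pairs": "n_pairs_all"})
    if kept_summary.empty:
        k = pd.DataFrame(columns=["subject", "experiment", "mean_retained", "n_pairs_retained"])
    else:
        k = kept_summary[kept_summary["subject"] != "ALL"][
            ["subject", "group", "mean", "n_pairs"]
        ].rename(columns={"group": "experiment", "mean": "mean_retained",
                          "n_pairs": "n_pairs_retained"})
    out = a.merge(k, on=["subject", "experiment"], how="left")
    out["n_pairs_retained"] = out["n_pairs_retained"].fillna(0).astype(int)
    out["delta"] = out["mean_retained"] - out["mean_all"]
    return out
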