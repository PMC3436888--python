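"""Pairwise genotype concordance between technical replicates.

Concordance between two call vectors on a shared SNP panel is the fraction
of SNPs at which they report the same genotype. Two denominator conventions
are provided:

``co_called`` (default)
    only SNPs called in both samples enter the denominator — the standard
    practice when no-calls carry no information about agreement.
``strict``
    all N panel SNPs enter the denominator; a pair involving one no-call is
    discordant, two no-calls agree. This is the literal sum-of-equality-
    indicators definition.

Pairs are aggregated into the three reproducibility levels of a replicate
study: ``intra`` (same subject, same experiment), ``inter_lab`` (same
subject, same platform, different experiments) and ``inter_platform`` (same
subject, different platforms). Cross-platform comparisons first require
:func:`harmonize_panels` to intersect the two SNP universes and reconcile
allele orientation (major/minor swaps and strand flips).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import COMPLEMENT, HOM_MIN, NO_CALL, GenotypeMatrix, SnpPanel, StudyDesign
from .exceptions import (
    DesignError,
    InvalidParameterError,
    PanelError,
    UndefinedConcordanceError,
)

MODES = ("co_called", "strict")
LEVELS = ("intra", "inter_lab", "inter_platform")

SUMMARY_COLUMNS = ("level", "subject", "group", "mean", "sd", "n_pairs")


@dataclass(frozen=True)
class ConcordanceResult:
    """One pairwise comparison: counts compared/agreeing and the fraction."""

    sample_i: str
    sample_j: str
    n_total_snps: int
    n_compared: int
    n_agree: int
    mode: str
    concordance: float


def pairwise_concordance(
    a: np.ndarray,
    b: np.ndarray,
    mode: str = "co_called",
    sample_i: str = "a",
    sample_j: str = "b",
) -> ConcordanceResult:
    """Concordance between two call vectors bound to the same panel."""
    if mode not in MODES:
        raise InvalidParameterError(f"mode must be one of {MODES}, got {mode!r}")
    a = np.asarray(a)
    b = np.asarray(b)
    if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
        raise PanelError(f"call vectors must be 1-D and equal length, got {a.shape} vs {b.shape}")
    if a.size == 0:
        raise PanelError("call vectors must have length >= 1")
    n = int(a.size)
    if mode == "co_called":
        both = (a != NO_CALL) & (b != NO_CALL)
        n_compared = int(both.sum())
        if n_compared == 0:
            raise UndefinedConcordanceError(
                f"no co-called SNPs between {sample_i!r} and {sample_j!r}"
            )
        n_agree = int(((a == b) & both).sum())
    else:
        n_compared = n
        n_agree = int((a == b).sum())
    return ConcordanceResult(
        sample_i=sample_i,
        sample_j=sample_j,
        n_total_snps=n,
        n_compared=n_compared,
        n_agree=n_agree,
        mode=mode,
        concordance=n_agree / n_compared,
    )


def concordance_matrix(
    matrix: GenotypeMatrix,
    sample_ids: Sequence[str] | None = None,
    mode: str = "co_called",
) -> pd.DataFrame:
    """Symmetric sample x sample concordance table (diagonal 1.0)."""
    ids = list(sample_ids) if sample_ids is not None else list(matrix.sample_ids)
    if not ids:
        raise DesignError("empty sample selection for concordance matrix")
    out = np.eye(len(ids))
    for i, j in itertools.combinations(range(len(ids)), 2):
        r = pairwise_concordance(matrix.row(ids[i]), matrix.row(ids[j]), mode,
                                 sample_i=ids[i], sample_j=ids[j])
        out[i, j] = out[j, i] = r.concordance
    return pd.DataFrame(out, index=ids, columns=ids)


def _pair_group(meta_i, meta_j, level: str) -> str | None:
    """Comparison-group label for a sample pair at a level, or None."""
    if meta_i["subject"] != meta_j["subject"]:
        return None
    ei, ej = meta_i["experiment"], meta_j["experiment"]
    if level == "intra":
        return ei if ei == ej else None
    if level == "inter_lab":
        if ei != ej and meta_i["platform"] == meta_j["platform"]:
            return "|".join(sorted((ei, ej)))
        return None
    if level == "inter_platform":
        if meta_i["platform"] != meta_j["platform"]:
            return "|".join(sorted((ei, ej)))
        return None
    raise InvalidParameterError(f"level must be one of {LEVELS}, got {level!r}")


def level_pairs(design: StudyDesign, level: str) -> list[tuple[str, str, str, str]]:
    """All (sample_i, sample_j, subject, group) pairs at a comparison level."""
    if level not in LEVELS:
        raise InvalidParameterError(f"level must be one of {LEVELS}, got {level!r}")
    meta = design.meta()
    ids = list(meta.index)
    pairs = []
    for si, sj in itertools.combinations(ids, 2):
        mi, mj = meta.loc[si], meta.loc[sj]
        group = _pair_group(mi, mj, level)
        if group is not None:
            pairs.append((si, sj, mi["subject"], group))
    return pairs


def summarize_reproducibility(
    results: Iterable[ConcordanceResult],
    design: StudyDesign,
    level: str,
) -> pd.DataFrame:
    """Per-subject-per-group mean and sample SD of member pair concordances.

    Rows: one per (subject, group); one per group with subject="ALL"; one
    grand overall row (subject="ALL", group="ALL") over all member pairs.
    Pairs in ``results`` that do not belong to the requested level are
    ignored. SD uses the n-1 convention and is 0 when n_pairs == 1.
    """
    if level not in LEVELS:
        raise InvalidParameterError(f"level must be one of {LEVELS}, got {level!r}")
    meta = design.meta()
    records = []
    for r in results:
        if r.sample_i not in meta.index or r.sample_j not in meta.index:
            raise DesignError(f"pair ({r.sample_i}, {r.sample_j}) not in design")
        mi, mj = meta.loc[r.sample_i], meta.loc[r.sample_j]
        group = _pair_group(mi, mj, level)
        if group is not None:
            records.append((mi["subject"], group, r.concordance))
    if not records:
        warnings.warn(f"no pairs at level {level!r}; empty summary", stacklevel=2)
        return pd.DataFrame(columns=list(SUMMARY_COLUMNS))
    df = pd.DataFrame(records, columns=["subject", "group", "concordance"])

    def agg(sub: pd.DataFrame, subject: str, group: str) -> dict:
        vals = sub["concordance"].to_numpy()
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        return {"level": level, "subject": subject, "group": group,
                "mean": float(vals.mean()), "sd": sd, "n_pairs": int(vals.size)}

    rows = [agg(sub, subject, group)
            for (subject, group), sub in df.groupby(["subject", "group"], sort=True)]
    rows += [agg(sub, "ALL", group) for group, sub in df.groupby("group", sort=True)]
    rows.append(agg(df, "ALL", "ALL"))
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def reproducibility_summary(
    matrix: GenotypeMatrix,
    design: StudyDesign,
    level: str,
    mode: str = "co_called",
) -> tuple[list[ConcordanceResult], pd.DataFrame]:
    """Compute all pairwise results at a level and their summary table."""
    pairs = level_pairs(design, level)
    results = [
        pairwise_concordance(matrix.row(si), matrix.row(sj), mode, sample_i=si, sample_j=sj)
        for si, sj, _, _ in pairs
    ]
    return results, summarize_reproducibility(results, design, level)


# ---------------------------------------------------------------------------
# Cross-platform panel harmonization

MAPPINGS = ("identical", "swapped", "strand_flipped", "strand_flipped_swapped")
_SWAPPED_MAPPINGS = ("swapped", "strand_flipped_swapped")


@dataclass(frozen=True)
class PanelHarmonization:
    """Shared-SNP allele mapping between two panels plus dropped SNPs.

    ``shared`` has columns (snp_id, mapping); ``dropped`` has columns
    (snp_id, reason) with reasons ``strand_ambiguous`` (palindromic A/T or
    C/G SNP whose strand cannot be resolved) or ``allele_mismatch``.
    """

    shared: pd.DataFrame
    dropped: pd.DataFrame


def harmonize_panels(panel_a: SnpPanel, panel_b: SnpPanel) -> PanelHarmonization:
    """Match SNPs by id and reconcile allele orientation between panels."""
    a = panel_a.table[["snp_id", "allele_major", "allele_minor"]]
    b = panel_b.table[["snp_id", "allele_major", "allele_minor"]]
    merged = a.merge(b, on="snp_id", suffixes=("_a", "_b"))
    if merged.empty:
        warnings.warn("panels share no snp_ids; downstream concordance undefined",
                      stacklevel=2)
        empty_shared = pd.DataFrame(columns=["snp_id", "mapping"])
        empty_dropped = pd.DataFrame(columns=["snp_id", "reason"])
        return PanelHarmonization(empty_shared, empty_dropped)

    amaj = merged["allele_major_a"].to_numpy()
    amin = merged["allele_minor_a"].to_numpy()
    bmaj = merged["allele_major_b"].to_numpy()
    bmin = merged["allele_minor_b"].to_numpy()
    comp = np.vectorize(lambda x: COMPLEMENT.get(x, "N"))

    def palindromic(x, y):
        return comp(x) == y

    ambiguous = palindromic(amaj, amin) | palindromic(bmaj, bmin)
    mapping = np.full(len(merged), "", dtype=object)
    mapping[(bmaj == amaj) & (bmin == amin)] = "identical"
    mapping[(bmaj == amin) & (bmin == amaj)] = "swapped"
    mapping[(bmaj == comp(amaj)) & (bmin == comp(amin))] = "strand_flipped"
    mapping[(bmaj == comp(amin)) & (bmin == comp(amaj))] = "strand_flipped_swapped"

    reason = np.full(len(merged), "", dtype=object)
    reason[mapping == ""] = "allele_mismatch"
    reason[ambiguous] = "strand_ambiguous"
    keep = reason == ""

    shared = pd.DataFrame({"snp_id": merged.loc[keep, "snp_id"].to_numpy(),
                           "mapping": mapping[keep]})
    dropped = pd.DataFrame({"snp_id": merged.loc[~keep, "snp_id"].to_numpy(),
                            "reason": reason[~keep]})
    if shared.empty:
        warnings.warn("no SNPs survived harmonization", stacklevel=2)
    return PanelHarmonization(shared.reset_index(drop=True), dropped.reset_index(drop=True))


def harmonize_matrices(
    matrix_a: GenotypeMatrix, matrix_b: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix, PanelHarmonization]:
    """Restrict both matrices to harmonized shared SNPs, remapping the calls
    of ``matrix_b`` onto ``matrix_a``'s major/minor orientation (for swapped
    mappings HOM_MAJ and HOM_MIN exchange; heterozygotes and no-calls are
    orientation-invariant). Returned matrices share ``matrix_a``'s panel
    rows in ``matrix_a`` order.
    """
    harm = harmonize_panels(matrix_a.panel, matrix_b.panel)
    shared_ids = harm.shared["snp_id"].to_numpy()
    pos_a = pd.Index(matrix_a.panel.snp_ids)
    order = np.argsort(pos_a.get_indexer(shared_ids))
    shared_ids = shared_ids[order]
    mapping = harm.shared["mapping"].to_numpy()[order]

    idx_a = pd.Index(matrix_a.panel.snp_ids).get_indexer(shared_ids)
    idx_b = pd.Index(matrix_b.panel.snp_ids).get_indexer(shared_ids)
    sub_a = matrix_a.subset_snps(idx_a)

    calls_b = matrix_b.calls[:, idx_b].copy()
    swap = np.isin(mapping, _SWAPPED_MAPPINGS)
    if swap.any():
        cols = calls_b[:, swap]
        called = cols != NO_CALL
        cols[called] = (HOM_MIN - cols[called]).astype(calls_b.dtype)
        calls_b[:, swap] = cols
    sub_b = GenotypeMatrix(sub_a.panel, list(matrix_b.sample_ids), calls_b)
    ordered = PanelHarmonization(
        pd.DataFrame({"snp_id": shared_ids, "mapping": mapping}), harm.dropped
    )
    return sub_a, sub_b, ordered
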