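"""Readers and writers for the package's text formats.

Canonical genotype format is a TSV with one row per SNP: ``snp_id``,
``chromosome``, ``position``, ``allele_major``, ``allele_minor``, then one
column per sample holding a two-letter genotype ("AG") or "NN" for a
no-call. Heterozygous genotypes are accepted in either letter order and
normalized on read. PLINK-style .ped/.map text is supported as an
interchange convenience; minor/major orientation is inferred from observed
allele frequencies unless a panel is supplied.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DESIGN_COLUMNS,
    HET,
    HOM_MAJ,
    HOM_MIN,
    NO_CALL,
    PANEL_COLUMNS,
    GenotypeMatrix,
    SnpPanel,
    StudyDesign,
)
from .exceptions import FormatError

_FIXED_COLUMNS = ("snp_id", "chromosome", "position", "allele_major", "allele_minor")


def write_genotype_tsv(path: str | Path, matrix: GenotypeMatrix) -> None:
    """Write a genotype matrix (with its panel columns) as TSV."""
    panel = matrix.panel.table
    maj = panel["allele_major"].to_numpy()
    mnr = panel["allele_minor"].to_numpy()
    if (mnr == "N").any():
        needs = (matrix.calls[:, mnr == "N"] == HET).any() or (
            matrix.calls[:, mnr == "N"] == HOM_MIN
        ).any()
        if needs:
            raise FormatError("cannot encode HET/HOM_MIN calls for SNPs with unknown minor allele")
    # genotype strings per SNP indexed by call code (column 3 = no-call)
    strings = np.stack(
        [
            np.char.add(maj, maj),
            np.char.add(maj, mnr),
            np.char.add(mnr, mnr),
            np.full(len(panel), "NN"),
        ],
        axis=1,
    )
    code_idx = np.where(matrix.calls < 0, 3, matrix.calls)
    rows = np.arange(len(panel))
    sample_cols = pd.DataFrame(
        {sample: strings[rows, code_idx[s]] for s, sample in enumerate(matrix.sample_ids)}
    )
    out = pd.concat([panel[list(_FIXED_COLUMNS)].reset_index(drop=True), sample_cols], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str | Path) -> tuple[SnpPanel, GenotypeMatrix]:
    """Read a genotype TSV back into a panel and call matrix.

    Round-trips bit-identically with :func:`write_genotype_tsv`; the MAF
    column is not part of the format and is NaN on the returned panel.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in _FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: header missing columns {missing}")
    sample_ids = [c for c in df.columns if c not in _FIXED_COLUMNS]
    if not sample_ids:
        raise FormatError(f"{path}: no sample columns in header")
    dup = df["snp_id"].duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2  # header is line 1
        raise FormatError(f"{path}: duplicate snp_id at line {line}")
    if df[list(_FIXED_COLUMNS) + sample_ids].isna().any().any():
        row = int(np.flatnonzero(df.isna().any(axis=1))[0]) + 2
        raise FormatError(f"{path}: ragged or empty fields at line {row}")
    try:
        positions = df["position"].astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer position: {exc}") from exc
    panel = SnpPanel(
        pd.DataFrame(
            {
                "snp_id": df["snp_id"],
                "chromosome": df["chromosome"],
                "position": positions,
                "allele_major": df["allele_major"],
                "allele_minor": df["allele_minor"],
                "maf": np.nan,
            },
            columns=list(PANEL_COLUMNS),
        )
    )
    maj = df["allele_major"].to_numpy()
    mnr = df["allele_minor"].to_numpy()
    calls = np.empty((len(sample_ids), len(df)), dtype=np.int8)
    for s, sample in enumerate(sample_ids):
        g = df[sample].to_numpy()
        col = np.full(len(df), np.int8(127))
        col[g == np.char.add(maj, maj)] = HOM_MAJ
        col[(g == np.char.add(maj, mnr)) | (g == np.char.add(mnr, maj))] = HET
        col[g == np.char.add(mnr, mnr)] = HOM_MIN
        col[g == "NN"] = NO_CALL
        bad = col == 127
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2
            raise FormatError(
                f"{path}: line {line}: genotype {g[np.flatnonzero(bad)[0]]!r} for sample "
                f"{sample!r} does not match alleles "
                f"{maj[np.flatnonzero(bad)[0]]}/{mnr[np.flatnonzero(bad)[0]]}"
            )
        calls[s] = col
    return panel, GenotypeMatrix(panel, sample_ids, calls)


def write_design_tsv(path: str | Path, design: StudyDesign) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_design_tsv(path: str | Path) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in DESIGN_COLUMNS} | {"replicate": int})
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: design header missing columns {missing}")
    return StudyDesign(df)


# ---------------------------------------------------------------------------
# PLINK-style text interchange


def write_ped_map(ped_path: str | Path, map_path: str | Path, matrix: GenotypeMatrix) -> None:
    """Write PLINK-style .map (chrom, snp_id, 0, position) and .ped text
    (six metadata columns then allele pairs, "0 0" for missing)."""
    panel = matrix.panel.table
    with open(map_path, "w") as fh:
        for rec in panel.itertuples(index=False):
            fh.write(f"{rec.chromosome}\t{rec.snp_id}\t0\t{rec.position}\n")
    maj = panel["allele_major"].to_numpy()
    mnr = panel["allele_minor"].to_numpy()
    if (mnr == "N").any() and ((matrix.calls == HET) | (matrix.calls == HOM_MIN))[
        :, mnr == "N"
    ].any():
        raise FormatError("cannot encode HET/HOM_MIN calls for SNPs with unknown minor allele")
    pairs = np.stack(
        [
            np.char.add(np.char.add(maj, " "), maj),
            np.char.add(np.char.add(maj, " "), mnr),
            np.char.add(np.char.add(mnr, " "), mnr),
            np.full(len(panel), "0 0"),
        ],
        axis=1,
    )
    rows = np.arange(len(panel))
    code_idx = np.where(matrix.calls < 0, 3, matrix.calls)
    with open(ped_path, "w") as fh:
        for s, sample in enumerate(matrix.sample_ids):
            geno = pairs[rows, code_idx[s]]
            fh.write("\t".join([sample, sample, "0", "0", "0", "-9", *geno]) + "\n")


def read_ped_map(
    ped_path: str | Path, map_path: str | Path, panel: SnpPanel | None = None
) -> tuple[SnpPanel, GenotypeMatrix]:
    """Read PLINK-style text. Without a supplied panel, major/minor alleles
    are inferred from observed frequencies (ties broken alphabetically); a
    monomorphic SNP's minor allele is recorded as "N" with a warning."""
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(f"{map_path}: line {ln}: expected 4 fields, got {len(parts)}")
            map_rows.append((parts[0], parts[1], int(parts[3])))
    n_snps = len(map_rows)
    if n_snps == 0:
        raise FormatError(f"{map_path}: no SNPs")

    sample_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            n_alleles = len(parts) - 6
            if n_alleles < 0 or n_alleles % 2 == 1:
                raise FormatError(f"{ped_path}: line {ln}: odd allele count ({n_alleles})")
            if n_alleles // 2 != n_snps:
                raise FormatError(
                    f"{ped_path}: line {ln}: {n_alleles // 2} genotype pairs but "
                    f"{n_snps} SNPs in {map_path}"
                )
            sample_ids.append(parts[1])
            allele_rows.append(np.array(parts[6:], dtype="U1").reshape(n_snps, 2))
    if not allele_rows:
        raise FormatError(f"{ped_path}: no samples")
    alleles = np.stack(allele_rows)  # samples x snps x 2

    if panel is not None:
        if len(panel) != n_snps:
            raise FormatError("supplied panel size does not match .map")
        maj = panel.table["allele_major"].to_numpy()
        mnr = panel.table["allele_minor"].to_numpy()
        maf = panel.maf
    else:
        maj = np.empty(n_snps, dtype="U1")
        mnr = np.empty(n_snps, dtype="U1")
        maf = np.empty(n_snps)
        mono: list[str] = []
        for k in range(n_snps):
            obs = alleles[:, k, :].ravel()
            obs = obs[obs != "0"]
            uniq, counts = np.unique(obs, return_counts=True)
            if uniq.size == 0 or uniq.size > 2:
                raise FormatError(
                    f"{ped_path}: SNP {map_rows[k][1]}: expected 1-2 observed alleles, "
                    f"got {uniq.tolist()}"
                )
            if uniq.size == 1:
                maj[k], mnr[k], maf[k] = uniq[0], "N", 0.0
                mono.append(map_rows[k][1])
            else:
                order = np.lexsort((uniq, -counts))  # most frequent first, ties alphabetical
                maj[k], mnr[k] = uniq[order[0]], uniq[order[1]]
                maf[k] = counts[order[1]] / counts.sum()
        if mono:
            warnings.warn(
                f"monomorphic SNPs with unknown minor allele: {mono[:5]}"
                + ("..." if len(mono) > 5 else ""),
                stacklevel=2,
            )
    out_panel = panel or SnpPanel(
        pd.DataFrame(
            {
                "snp_id": [r[1] for r in map_rows],
                "chromosome": [r[0] for r in map_rows],
                "position": [r[2] for r in map_rows],
                "allele_major": maj,
                "allele_minor": mnr,
                "maf": maf,
            },
            columns=list(PANEL_COLUMNS),
        )
    )
    a1, a2 = alleles[:, :, 0], alleles[:, :, 1]
    calls = np.full((len(sample_ids), n_snps), np.int8(127))
    calls[(a1 == "0") & (a2 == "0")] = NO_CALL
    calls[(a1 == maj) & (a2 == maj)] = HOM_MAJ
    calls[((a1 == maj) & (a2 == mnr)) | ((a1 == mnr) & (a2 == maj))] = HET
    calls[(a1 == mnr) & (a2 == mnr)] = HOM_MIN
    if (calls == 127).any():
        s, k = np.argwhere(calls == 127)[0]
        raise FormatError(
            f"{ped_path}: sample {sample_ids[s]!r}, SNP {map_rows[k][1]}: alleles "
            f"{a1[s, k]}/{a2[s, k]} do not match {maj[k]}/{mnr[k]}"
        )
    return out_panel, GenotypeMatrix(out_panel, sample_ids, calls)
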