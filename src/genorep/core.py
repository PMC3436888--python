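"""Core containers for replicate genotyping studies.

Genotype calls are stored as small integer codes in a sample x SNP array:
``0`` homozygous for the major allele, ``1`` heterozygous, ``2`` homozygous
for the minor allele, ``-1`` no-call. All downstream statistics (pairwise
concordance, call/heterozygosity rates, QC flags) are computed from a
:class:`GenotypeMatrix` bound to a :class:`SnpPanel`, with comparison groups
defined by a :class:`StudyDesign` (subject, technical replicate, genotyping
experiment, platform, plate well).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DesignError, PanelError

HOM_MAJ: int = 0
HET: int = 1
HOM_MIN: int = 2
NO_CALL: int = -1

CALL_CODES = (HOM_MAJ, HET, HOM_MIN, NO_CALL)
CALL_NAMES = {HOM_MAJ: "HOM_MAJ", HET: "HET", HOM_MIN: "HOM_MIN", NO_CALL: "NO_CALL"}

NUCLEOTIDES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PANEL_COLUMNS = ("snp_id", "chromosome", "position", "allele_major", "allele_minor", "maf")
DESIGN_COLUMNS = ("sample_id", "subject", "replicate", "experiment", "platform", "well")

#: The six-subject, four-replicate, five-experiment replicate study layout.
TABLE1_SUBJECTS = ("A", "B", "C", "D", "E", "F")
TABLE1_PLATFORMS = {"E1": "Affy6", "E2": "Affy6", "E3": "Affy6",
                    "E4": "Illu1M", "E5": "Illu1M"}

_WELL_ROWS = "ABCDEFGH"


@dataclass(frozen=True)
class SnpPanel:
    """The SNP universe: id, locus, major/minor alleles and optionally MAF.

    ``maf`` may be NaN for panels read back from call files, where allele
    frequency is not part of the format; it is required only when sampling
    truth genotypes.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in PANEL_COLUMNS if c not in t.columns]
        if missing:
            raise PanelError(f"panel table missing columns: {missing}")
        if t["snp_id"].duplicated().any():
            dup = t.loc[t["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise PanelError(f"duplicate snp_id in panel: {dup!r}")
        pos = t["position"].to_numpy()
        if not np.issubdtype(pos.dtype, np.integer) or (pos <= 0).any():
            raise PanelError("positions must be positive integers")
        maj = t["allele_major"].to_numpy()
        mnr = t["allele_minor"].to_numpy()
        if not np.isin(maj, NUCLEOTIDES).all():
            raise PanelError("allele_major must be one of A, C, G, T")
        # "N" marks an unknown minor allele (monomorphic SNP on import)
        if not np.isin(mnr, NUCLEOTIDES + ("N",)).all():
            raise PanelError("allele_minor must be one of A, C, G, T (or N if unknown)")
        if (maj == mnr).any():
            raise PanelError("allele_major and allele_minor must differ")
        maf = t["maf"].to_numpy(dtype=float)
        bad = ~np.isnan(maf) & ((maf < 0.0) | (maf > 0.5))
        if bad.any():
            raise PanelError("maf must lie in [0, 0.5] (or be NaN if unknown)")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def maf(self) -> np.ndarray:
        return self.table["maf"].to_numpy(dtype=float)

    def subset(self, index: np.ndarray) -> "SnpPanel":
        """Panel restricted to rows selected by positional ``index``."""
        return SnpPanel(self.table.iloc[index].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Calls for a set of samples on one SNP panel (samples x SNPs, int8)."""

    panel: SnpPanel
    sample_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise PanelError("calls must be a 2-D samples x SNPs array")
        if self.calls.shape != (len(self.sample_ids), len(self.panel)):
            raise PanelError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.panel)} SNPs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DesignError("sample_ids must be unique")
        valid = np.isin(self.calls, np.array(CALL_CODES, dtype=np.int8))
        if not valid.all():
            raise PanelError("calls contain values outside {HOM_MAJ, HET, HOM_MIN, NO_CALL}")
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.panel)

    def row(self, sample_id: str) -> np.ndarray:
        try:
            return self.calls[self._index[sample_id]]
        except KeyError:
            raise DesignError(f"unknown sample_id: {sample_id!r}") from None

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.panel, list(self.sample_ids), self.calls.copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._index[s] for s in sample_ids if s in self._index]
        if len(idx) != len(sample_ids):
            unknown = [s for s in sample_ids if s not in self._index]
            raise DesignError(f"unknown sample_ids: {unknown}")
        return GenotypeMatrix(self.panel, [self.sample_ids[i] for i in idx], self.calls[idx])

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.panel.subset(index), list(self.sample_ids),
                              self.calls[:, index])

    def to_frame(self) -> pd.DataFrame:
        """Calls as a samples x SNPs DataFrame of integer codes."""
        return pd.DataFrame(self.calls, index=self.sample_ids, columns=self.panel.snp_ids)


@dataclass(frozen=True)
class StudyDesign:
    """Per-sample replicate-study metadata defining all comparison groups."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise DesignError(f"design table missing columns: {missing}")
        if t["sample_id"].duplicated().any():
            raise DesignError("sample_id values must be unique")
        if t.duplicated(subset=["subject", "replicate", "experiment"]).any():
            raise DesignError("(subject, replicate, experiment) must be unique")
        plat = t.groupby("experiment")["platform"].nunique()
        if (plat > 1).any():
            bad = plat[plat > 1].index.tolist()
            raise DesignError(f"experiments mapped to more than one platform: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def experiments(self) -> list[str]:
        return sorted(self.table["experiment"].unique())

    @property
    def subjects(self) -> list[str]:
        return sorted(self.table["subject"].unique())

    def platform_of(self, experiment: str) -> str:
        rows = self.table.loc[self.table["experiment"] == experiment, "platform"]
        if rows.empty:
            raise DesignError(f"unknown experiment: {experiment!r}")
        return rows.iloc[0]

    def meta(self) -> pd.DataFrame:
        """Design table indexed by sample_id."""
        return self.table.set_index("sample_id")


def table1_design(
    n_replicates: int = 4,
    subjects: Sequence[str] = TABLE1_SUBJECTS,
    experiment_platforms: Mapping[str, str] | None = None,
) -> StudyDesign:
    """Build the canonical replicate-study design: every subject assayed
    ``n_replicates`` times in every experiment, experiments E1-E3 on the
    Affy6 platform and E4-E5 on Illu1M by default.

    Plate wells are assigned deterministically (24 samples fill rows A-H of
    columns 1-3, the same layout on every experiment's plate); wells are
    carried as metadata only.
    """
    if experiment_platforms is None:
        experiment_platforms = TABLE1_PLATFORMS
    records = []
    for exp, platform in experiment_platforms.items():
        for si, subj in enumerate(subjects):
            for rep in range(1, n_replicates + 1):
                idx = si * n_replicates + (rep - 1)
                well = f"{_WELL_ROWS[idx % 8]}{idx // 8 + 1}"
                records.append(
                    {
                        "sample_id": f"{subj}{rep}_{exp}",
                        "subject": subj,
                        "replicate": rep,
                        "experiment": exp,
                        "platform": platform,
                        "well": well,
                    }
                )
    return StudyDesign(pd.DataFrame.from_records(records, columns=list(DESIGN_COLUMNS)))
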