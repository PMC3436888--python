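"""Monte-Carlo simulation of odds-ratio inflation from genotyping error.

A case population (default 2,000) and a control population (default 3,000)
are built with deterministic Hardy-Weinberg genotype counts carrying exactly
the same minor allele frequency, so the allelic odds ratio of the clean data
is exactly one. Genotype noise at a fixed concordance rate c is then applied
independently to both populations — each individual retains its genotype
with probability c and is otherwise reassigned uniformly to one of the two
other genotype classes — and the allelic odds ratio of the noisy table is
recorded. Repeating this (default 50,000 times) per cell of a (minor allele
frequency x concordance) grid and taking a top percentile (default the 95th,
nearest-rank) yields the surface of spurious odds ratios attributable to
genotyping discordance alone.

Noise is drawn at the genotype-count level via multinomial transition draws,
which is distributionally equivalent to perturbing individuals one at a
time and conserves the population size exactly. Each grid cell has its own
RNG stream derived from (seed, maf, concordance), so cell values do not
depend on grid layout or evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import GridAlignmentError, InvalidParameterError, UndefinedRatioError

NOISE_TARGETS = ("both", "cases_only")


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype composition of one population."""

    n_hom_major: int
    n_het: int
    n_hom_minor: int

    def __post_init__(self) -> None:
        if min(self.n_hom_major, self.n_het, self.n_hom_minor) < 0:
            raise InvalidParameterError("genotype counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.n_hom_major + self.n_het + self.n_hom_minor

    @property
    def minor_allele_count(self) -> int:
        return self.n_het + 2 * self.n_hom_minor

    @property
    def major_allele_count(self) -> int:
        return 2 * self.n - self.minor_allele_count


def default_maf_grid() -> tuple[float, ...]:
    """Minor allele frequencies 0.01 to 0.40 in steps of 0.01."""
    return tuple(round(0.01 * k, 2) for k in range(1, 41))


def default_concordance_grid() -> tuple[float, ...]:
    """Concordance rates 0.940 to 1.000 in steps of 0.001."""
    return tuple(round(0.940 + 0.001 * k, 3) for k in range(61))


@dataclass(frozen=True)
class SimConfig:
    """Simulation configuration; defaults reproduce the reference study
    conditions (2,000 cases, 3,000 controls, 50,000 repetitions, 95th
    percentile, full default grids)."""

    n_case: int = 2000
    n_control: int = 3000
    reps: int = 50_000
    maf_grid: tuple[float, ...] = field(default_factory=default_maf_grid)
    concordance_grid: tuple[float, ...] = field(default_factory=default_concordance_grid)
    percentile: float = 0.95
    seed: int = 0
    scheme: str = "uniform_other"
    zero_cell_correction: bool = True
    noise_target: str = "both"

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1 or self.reps < 1:
            raise InvalidParameterError("n_case, n_control and reps must be >= 1")
        if not 0.0 < self.percentile < 1.0:
            raise InvalidParameterError("percentile must lie in (0, 1)")
        if self.scheme != "uniform_other":
            raise InvalidParameterError(f"unsupported reassignment scheme {self.scheme!r}")
        if self.noise_target not in NOISE_TARGETS:
            raise InvalidParameterError(f"noise_target must be one of {NOISE_TARGETS}")
        if self.seed < 0:
            raise InvalidParameterError("seed must be a nonnegative integer")
        maf = np.asarray(self.maf_grid, dtype=float)
        conc = np.asarray(self.concordance_grid, dtype=float)
        if maf.size == 0 or conc.size == 0:
            raise InvalidParameterError("grids must be non-empty")
        if (np.diff(maf) <= 0).any() or (np.diff(conc) <= 0).any():
            raise InvalidParameterError("grids must be strictly increasing")
        if (maf <= 0).any() or (maf > 0.5).any():
            raise InvalidParameterError("maf grid values must lie in (0, 0.5]")
        if (conc < 0).any() or (conc > 1).any():
            raise InvalidParameterError("concordance grid values must lie in [0, 1]")


def build_baseline(maf: float, n: int) -> GenotypeCounts:
    """Deterministic HWE-rounded genotype counts with an exact minor-allele
    total ``m = 2 n maf``.

    The heterozygote count is the rounded HWE expectation ``2 n maf (1-maf)``
    decremented by one when needed so that ``m - n_het`` is even; the
    remainder is split into minor homozygotes. The resulting allele
    frequency equals ``maf`` exactly, so case and control populations built
    at the same maf give an allelic odds ratio of exactly one.
    """
    if n < 1:
        raise InvalidParameterError("population size must be >= 1")
    if not 0.0 < maf <= 0.5:
        raise InvalidParameterError(f"maf must lie in (0, 0.5], got {maf!r}")
    m_float = 2.0 * n * maf
    m = int(round(m_float))
    if abs(m_float - m) > 1e-9:
        raise GridAlignmentError(
            f"2*n*maf = {m_float} is not an integer for maf={maf}, n={n}; "
            "align the maf grid so allele totals are whole numbers"
        )
    h = int(round(m_float * (1.0 - maf)))
    if (m - h) % 2 == 1:
        h -= 1
    hom_minor = (m - h) // 2
    hom_major = n - h - hom_minor
    return GenotypeCounts(hom_major, h, hom_minor)


def _transition_probs(concordance: float) -> np.ndarray:
    """Row-stochastic genotype transition matrix for uniform reassignment."""
    c = concordance
    off = (1.0 - c) / 2.0
    return np.array(
        [[c, off, off],
         [off, c, off],
         [off, off, c]]
    )


def _noisy_counts_batch(
    counts: GenotypeCounts, concordance: float, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """(reps, 3) noisy genotype counts via multinomial transition draws."""
    probs = _transition_probs(concordance)
    out = np.zeros((reps, 3), dtype=np.int64)
    for g, n_g in enumerate((counts.n_hom_major, counts.n_het, counts.n_hom_minor)):
        if n_g:
            out += rng.multinomial(n_g, probs[g], size=reps)
    return out


def apply_genotype_noise(
    counts: GenotypeCounts,
    concordance: float,
    rng: np.random.Generator,
    scheme: str = "uniform_other",
) -> GenotypeCounts:
    """One noisy realization of a population's genotype counts."""
    if scheme != "uniform_other":
        raise InvalidParameterError(f"unsupported reassignment scheme {scheme!r}")
    if not 0.0 <= concordance <= 1.0:
        raise InvalidParameterError("concordance must lie in [0, 1]")
    draw = _noisy_counts_batch(counts, concordance, 1, rng)[0]
    return GenotypeCounts(int(draw[0]), int(draw[1]), int(draw[2]))


def allelic_odds_ratio(
    case: GenotypeCounts, control: GenotypeCounts, correction: bool = True
) -> float:
    """Allelic odds ratio (a*d)/(b*c) on the 2x2 allele-count table.

    a = case minor alleles, b = case major, c = control minor, d = control
    major, with minor counts = n_het + 2 n_hom_minor. A zero cell triggers
    the Haldane-Anscombe correction (0.5 added to all four cells) when
    ``correction`` is on, otherwise an :class:`UndefinedRatioError`.
    """
    if case.n == 0 or control.n == 0:
        raise InvalidParameterError("populations must be non-empty")
    a, b = case.minor_allele_count, case.major_allele_count
    c, d = control.minor_allele_count, control.major_allele_count
    if min(a, b, c, d) == 0:
        if not correction:
            raise UndefinedRatioError("zero cell in allele table with correction disabled")
        return (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    return (a * d) / (b * c)


def _nearest_rank(sorted_values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: ascending order statistic at ceil(q*n)."""
    n = sorted_values.size
    idx = max(math.ceil(q * n), 1) - 1
    return float(sorted_values[idx])


def _cell_rng(seed: int, maf: float, concordance: float) -> np.random.Generator:
    return np.random.default_rng(
        (seed, int(round(maf * 10_000)), int(round(concordance * 100_000)))
    )


@dataclass(frozen=True)
class ORSurface:
    """Top-percentile odds ratios over the (maf x concordance) grid."""

    maf_grid: tuple[float, ...]
    concordance_grid: tuple[float, ...]
    values: np.ndarray  # |maf_grid| x |concordance_grid|
    reps: int
    seed: int
    percentile: float
    n_case: int
    n_control: int
    samples: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"maf": m, "concordance": c,
             "percentile_or": self.values[i, j],
             "reps": self.reps, "seed": self.seed}
            for i, m in enumerate(self.maf_grid)
            for j, c in enumerate(self.concordance_grid)
        ]
        return pd.DataFrame(rows)


def simulate_cell(
    maf: float,
    concordance: float,
    config: SimConfig,
) -> np.ndarray:
    """All ``reps`` simulated odds ratios for one grid cell."""
    case0 = build_baseline(maf, config.n_case)
    control0 = build_baseline(maf, config.n_control)
    rng = _cell_rng(config.seed, maf, concordance)
    case = _noisy_counts_batch(case0, concordance, config.reps, rng)
    if config.noise_target == "both":
        control = _noisy_counts_batch(control0, concordance, config.reps, rng)
    else:
        control = np.tile(
            [control0.n_hom_major, control0.n_het, control0.n_hom_minor], (config.reps, 1)
        )
    a = case[:, 1] + 2 * case[:, 2]
    b = 2 * config.n_case - a
    c = control[:, 1] + 2 * control[:, 2]
    d = 2 * config.n_control - c
    cells = np.stack([a, b, c, d]).astype(np.float64)
    zero = (cells == 0).any(axis=0)
    if zero.any():
        if not config.zero_cell_correction:
            raise UndefinedRatioError(
                "zero allele-table cell encountered with correction disabled"
            )
        cells[:, zero] += 0.5
    return (cells[0] * cells[3]) / (cells[1] * cells[2])


def percentile_surface(
    config: SimConfig,
    keep_samples: bool = False,
    sample_cap: int = 20_000,
) -> ORSurface:
    """Top-percentile OR per (maf, concordance) grid cell.

    When ``keep_samples`` is true and ``reps <= sample_cap``, the full OR
    samples of every cell are retained under ``surface.samples`` keyed by
    (maf, concordance).
    """
    values = np.empty((len(config.maf_grid), len(config.concordance_grid)))
    samples: dict | None = {} if keep_samples and config.reps <= sample_cap else None
    for i, maf in enumerate(config.maf_grid):
        for j, conc in enumerate(config.concordance_grid):
            ors = simulate_cell(maf, conc, config)
            ors.sort()
            values[i, j] = _nearest_rank(ors, config.percentile)
            if samples is not None:
                samples[(maf, conc)] = ors
    return ORSurface(
        maf_grid=tuple(config.maf_grid),
        concordance_grid=tuple(config.concordance_grid),
        values=values,
        reps=config.reps,
        seed=config.seed,
        percentile=config.percentile,
        n_case=config.n_case,
        n_control=config.n_control,
        samples=samples,
    )
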