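"""Niche-overlap statistics and the age-range correlation test.

Suitability surfaces are first normalized to probability surfaces over
their common non-nodata mask.  Overlap between two taxa is then measured
by Schoener's D = 1 - 1/2 * sum |p_x - p_y| and the Hellinger-based
I = 1 - 1/2 * sum (sqrt(p_x) - sqrt(p_y))^2; both lie in [0, 1], equal 1
only for identical surfaces and 0 for disjoint supports.

The age-range correlation (ARC) regresses pairwise overlap on the age of
the pair's most recent common ancestor.  Because pairs sharing a taxon
are not independent, significance comes from a permutation null that
jointly relabels the rows and columns of the overlap matrix; the
parametric regression p-value is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .bioclim import SuitabilitySurface
from .phylo import DatedTree

__all__ = [
    "OverlapMatrix",
    "ARCResult",
    "normalize_surface",
    "overlap_D",
    "overlap_I",
    "overlap_matrix",
    "age_range_correlation",
]


@dataclass
class OverlapMatrix:
    taxa: list[str]
    D: np.ndarray
    I: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        for M in (self.D, self.I):
            if M.shape != (n, n):
                raise ValueError("overlap matrix shape mismatch")
            if not np.allclose(M, M.T, atol=1e-9):
                raise ValueError("overlap matrix must be symmetric")

    def matrix(self, statistic: Literal["D", "I"]) -> np.ndarray:
        return self.D if statistic == "D" else self.I

    def pair_value(self, statistic: Literal["D", "I"], a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.matrix(statistic)[i, j])

    def mean_offdiagonal(self, statistic: Literal["D", "I"]) -> float:
        M = self.matrix(statistic)
        iu = np.triu_indices(len(self.taxa), k=1)
        return float(M[iu].mean())

    def mean_over_pairs(
        self, statistic: Literal["D", "I"], pairs: list[tuple[str, str]]
    ) -> float:
        return float(np.mean([self.pair_value(statistic, a, b) for a, b in pairs]))

    def mean_within_clade(
        self, statistic: Literal["D", "I"], members: list[str]
    ) -> float:
        pairs = list(combinations(members, 2))
        return self.mean_over_pairs(statistic, pairs)

    def to_dataframe(self, statistic: Literal["D", "I"]) -> pd.DataFrame:
        return pd.DataFrame(self.matrix(statistic), index=self.taxa, columns=self.taxa)


@dataclass
class ARCResult:
    slope: float
    intercept: float
    adjusted_r2: float
    p_value: float       # permutation p on |slope|
    p_parametric: float  # OLS t-test p, reported alongside
    n_pairs: int
    n_permutations: int
    seed: int
    statistic: str = "D"

    def summary(self) -> str:
        return (
            f"Age-range correlation ({self.statistic}): slope={self.slope:.4g}, "
            f"intercept={self.intercept:.4g}, adjusted r^2={self.adjusted_r2:.3f}, "
            f"permutation p={self.p_value:.3f} ({self.n_permutations} permutations), "
            f"parametric p={self.p_parametric:.3f}, n_pairs={self.n_pairs}"
        )


def normalize_surface(surface: SuitabilitySurface) -> np.ndarray:
    """Suitability grid rescaled to sum to 1 over non-nodata cells.

    Returns a dense array with masked cells set to 0.
    """
    grid = surface.grid.astype(float).copy()
    grid[surface.nodata_mask] = 0.0
    total = grid.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero surface")
    return grid / total


def _common_probability(
    x: SuitabilitySurface, y: SuitabilitySurface
) -> tuple[np.ndarray, np.ndarray]:
    if x.grid.shape != y.grid.shape:
        raise ValueError("surfaces must share a grid")
    mask = x.nodata_mask | y.nodata_mask
    gx = x.grid.astype(float).copy()
    gy = y.grid.astype(float).copy()
    gx[mask] = 0.0
    gy[mask] = 0.0
    sx, sy = gx.sum(), gy.sum()
    if sx <= 0 or sy <= 0:
        raise ValueError("cannot normalize an all-zero surface on the common mask")
    return gx / sx, gy / sy


def overlap_D(x: SuitabilitySurface, y: SuitabilitySurface) -> float:
    """Schoener's D on the common non-nodata mask."""
    px, py = _common_probability(x, y)
    return float(1.0 - 0.5 * np.abs(px - py).sum())


def overlap_I(x: SuitabilitySurface, y: SuitabilitySurface) -> float:
    """Hellinger-based I on the common non-nodata mask."""
    px, py = _common_probability(x, y)
    return float(1.0 - 0.5 * ((np.sqrt(px) - np.sqrt(py)) ** 2).sum())


def overlap_matrix(surfaces: Mapping[str, SuitabilitySurface]) -> OverlapMatrix:
    """All pairwise D and I values, computed once and mirrored."""
    taxa = list(surfaces)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    n = len(taxa)
    D = np.eye(n)
    I = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = overlap_D(surfaces[taxa[i]], surfaces[taxa[j]])
            w = overlap_I(surfaces[taxa[i]], surfaces[taxa[j]])
            D[i, j] = D[j, i] = d
            I[i, j] = I[j, i] = w
    return OverlapMatrix(taxa=taxa, D=D, I=I)


def _pairwise_regression(
    overlap: np.ndarray, ages: np.ndarray
) -> tuple[float, float, float, float]:
    """OLS of upper-triangle overlap on MRCA age.

    Returns (slope, intercept, adjusted r^2, parametric p).
    """
    iu = np.triu_indices(overlap.shape[0], k=1)
    y = overlap[iu]
    x = ages[iu]
    if np.ptp(x) == 0:
        raise ValueError("all MRCA ages equal; ARC slope undefined")
    res = stats.linregress(x, y)
    n = y.size
    r2 = res.rvalue ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return res.slope, res.intercept, adj, res.pvalue


def age_range_correlation(
    overlap: OverlapMatrix,
    tree: DatedTree,
    statistic: Literal["D", "I"] = "D",
    n_permutations: int = 1000,
    seed: int = 0,
) -> ARCResult:
    """Regression of pairwise niche overlap on MRCA age, permutation-tested.

    The null jointly permutes the rows and columns of the overlap matrix
    (taxon relabeling), which preserves the dependence structure among
    pairs sharing a taxon.  p = (1 + #{|slope*| >= |slope|}) /
    (1 + n_permutations).
    """
    taxa = overlap.taxa
    tips = set(tree.tip_labels)
    missing = [t for t in taxa if t not in tips]
    if missing:
        raise ValueError(f"taxa not in tree: {missing}")
    n = len(taxa)
    n_pairs = n * (n - 1) // 2
    if n_pairs < 3:
        raise ValueError("need at least 3 taxon pairs")
    ages = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ages[i, j] = ages[j, i] = tree.mrca_age(taxa[i], taxa[j])
    M = overlap.matrix(statistic)
    slope, intercept, adj, p_param = _pairwise_regression(M, ages)

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    x = ages[iu]
    xc = x - x.mean()
    sxx = float(xc @ xc)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        y = M[np.ix_(perm, perm)][iu]
        s = float(xc @ (y - y.mean())) / sxx
        if abs(s) >= abs(slope) - 1e-15:
            hits += 1
    p_perm = (hits + 1) / (n_permutations + 1)
    return ARCResult(
        slope=float(slope),
        intercept=float(intercept),
        adjusted_r2=float(adj),
        p_value=float(p_perm),
        p_parametric=float(p_param),
        n_pairs=n_pairs,
        n_permutations=n_permutations,
        seed=seed,
        statistic=statistic,
    )
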