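"""Correlation-aware climate-variable selection.

Highly correlated climate variables over-weight one climate component
(temperature or precipitation) in envelope models, so from every pair of
variables whose Pearson correlation exceeds a threshold (default 0.8),
the one with the lower single-variable mean AUC is excluded.  The greedy
order is deterministic: the remaining pair with the largest |r| above the
threshold is resolved first, until no pair exceeds the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .evaluation import MeanAucTable

__all__ = [
    "CorrelationMatrix",
    "SelectionConfig",
    "ExclusionRecord",
    "correlation_matrix",
    "select_variables",
]


@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: np.ndarray  # symmetric, unit diagonal

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.variables)
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-9):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-9:
            raise ValueError("|r| must not exceed 1")

    def value(self, a: str, b: str) -> float:
        i, j = self.variables.index(a), self.variables.index(b)
        return float(self.r[i, j])

    @classmethod
    def from_lower_triangle(
        cls, variables: Sequence[str], rows: Sequence[Sequence[float]]
    ) -> "CorrelationMatrix":
        """Build from a strictly-lower-triangular listing (row i has i entries)."""
        n = len(variables)
        r = np.eye(n)
        for i, row in enumerate(rows):
            if len(row) != i:
                raise ValueError(f"row {i} must have {i} entries, got {len(row)}")
            for j, val in enumerate(row):
                r[i, j] = r[j, i] = val
        return cls(list(variables), r)


@dataclass
class SelectionConfig:
    threshold: float = 0.8
    use_absolute: bool = True
    order: Literal["highest_r_first", "single_pass"] = "highest_r_first"
    tie_break: Literal["keep_first_listed", "error"] = "keep_first_listed"

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")


@dataclass
class ExclusionRecord:
    pair: tuple[str, str]
    r: float
    dropped: str
    reason: str


@dataclass
class SelectionResult:
    retained: list[str]
    log: list[ExclusionRecord] = field(default_factory=list)

    def write_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.log:
                fh.write(
                    f"dropped {rec.dropped}: pair ({rec.pair[0]}, {rec.pair[1]}) "
                    f"r={rec.r:+.3f} — {rec.reason}\n"
                )
            fh.write("retained: " + ", ".join(self.retained) + "\n")


def correlation_matrix(values_table: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson correlation over valid pooled occurrence values.

    Metadata columns from ``sample_values`` are ignored; rows flagged
    invalid are excluded.  Constant columns have undefined correlation;
    these are flagged with a warning and their coefficients set to 0.
    """
    meta = {"lon", "lat", "row", "col", "valid"}
    variables = [c for c in values_table.columns if c not in meta]
    data = values_table[values_table["valid"]] if "valid" in values_table else values_table
    data = data[variables]
    if len(data) < 3:
        raise ValueError("need at least 3 valid points for correlation")
    constant = [v for v in variables if data[v].nunique() <= 1]
    if constant:
        warnings.warn(f"constant columns, correlation undefined, set to 0: {constant}")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data.to_numpy(dtype=float), rowvar=False)
    r = np.atleast_2d(r)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(variables, r)


def select_variables(
    corr: CorrelationMatrix,
    mean_auc: MeanAucTable,
    cfg: SelectionConfig | None = None,
) -> SelectionResult:
    """Greedy exclusion of correlated variables by lower mean AUC.

    While any retained pair has correlation above ``cfg.threshold``
    (absolute value by default), the pair with the largest magnitude is
    found and its lower-mean-AUC member dropped.  Equal AUCs are resolved
    by ``cfg.tie_break``: keep the variable listed first in the input
    ordering, or raise.  Returns the retained set plus a log with one
    record per exclusion.
    """
    cfg = cfg or SelectionConfig()
    variables = list(corr.variables)
    missing = [v for v in variables if v not in mean_auc.variables]
    if missing:
        raise ValueError(f"mean AUC missing for variables {missing}")
    auc_of = {v: mean_auc.mean_auc(v) for v in variables}
    alive = list(variables)
    log: list[ExclusionRecord] = []

    def magnitude(val: float) -> float:
        return abs(val) if cfg.use_absolute else val

    def offending_pairs() -> list[tuple[float, str, str]]:
        out = []
        for i, a in enumerate(alive):
            for b in alive[i + 1:]:
                val = corr.value(a, b)
                if magnitude(val) > cfg.threshold:
                    out.append((magnitude(val), a, b))
        return out

    def sort_pairs(pairs: list[tuple[float, str, str]]) -> None:
        # deterministic: |r| descending, then input order of the pair
        pairs.sort(key=lambda t: (-t[0], variables.index(t[1]), variables.index(t[2])))

    def resolve(a: str, b: str) -> None:
        r_val = corr.value(a, b)
        if auc_of[a] < auc_of[b]:
            drop, reason = a, f"mean AUC {auc_of[a]:.3g} < {auc_of[b]:.3g}"
        elif auc_of[b] < auc_of[a]:
            drop, reason = b, f"mean AUC {auc_of[b]:.3g} < {auc_of[a]:.3g}"
        else:
            if cfg.tie_break == "error":
                raise ValueError(f"AUC tie between {a} and {b} ({auc_of[a]})")
            # keep the variable listed first in the input ordering
            drop = b if variables.index(a) < variables.index(b) else a
            reason = f"AUC tie at {auc_of[a]:.3g}; kept first-listed variable"
        alive.remove(drop)
        log.append(ExclusionRecord(pair=(a, b), r=r_val, dropped=drop, reason=reason))

    if cfg.order == "single_pass":
        pairs = offending_pairs()
        sort_pairs(pairs)
        for _, a, b in pairs:
            if a in alive and b in alive:
                resolve(a, b)
    else:
        while True:
            pairs = offending_pairs()
            if not pairs:
                break
            sort_pairs(pairs)
            _, a, b = pairs[0]
            resolve(a, b)
    return SelectionResult(retained=alive, log=log)
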