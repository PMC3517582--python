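"""AUC evaluation of envelope models against presence and background sites.

Presence-only models are scored with the area under the ROC curve: the
probability that a randomly chosen presence cell receives a higher
suitability than a randomly chosen background cell, with ties counted
half.  1 is perfect discrimination, 0.5 is random.  Background
(pseudo-absence) cells are drawn uniformly without replacement from the
non-nodata, non-presence cells of the scenario; the draw is seeded and
fully reproducible.

The per-variable mean-AUC table averages single-variable model AUCs over
species, restricted to species contributing at least ``min_unique``
environmentally unique occurrence points for that model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .bioclim import count_env_unique, fit_envelope, project_envelope, EnvelopeModel
from .geodata import ClimateScenario, OccurrenceSet, sample_values

__all__ = [
    "EvaluationResult",
    "MeanAucTable",
    "sample_background",
    "auc",
    "evaluate_model",
    "mean_auc_per_variable",
]

DEFAULT_MIN_UNIQUE = 10
MAX_BACKGROUND = 10_000


@dataclass
class EvaluationResult:
    taxon: str
    variable_set: tuple[str, ...]
    auc: float
    n_presence: int
    n_background: int
    n_env_unique: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC {self.auc} outside [0, 1]")


@dataclass
class MeanAucTable:
    """Per-variable mean AUC over qualifying species."""

    table: pd.DataFrame  # columns: variable, mean_auc, n_species_used

    @property
    def variables(self) -> list[str]:
        return list(self.table["variable"])

    def mean_auc(self, variable: str) -> float:
        row = self.table[self.table["variable"] == variable]
        if row.empty:
            raise KeyError(variable)
        return float(row["mean_auc"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeanAucTable":
        return cls(pd.read_csv(path))

    @classmethod
    def from_mapping(cls, mean_auc: Mapping[str, float],
                     n_species: Mapping[str, int] | None = None) -> "MeanAucTable":
        rows = [
            {
                "variable": var,
                "mean_auc": val,
                "n_species_used": (n_species or {}).get(var, 0),
            }
            for var, val in mean_auc.items()
        ]
        return cls(pd.DataFrame(rows, columns=["variable", "mean_auc", "n_species_used"]))


def sample_background(
    scenario: ClimateScenario,
    exclude_cells: set[tuple[int, int]],
    n: int,
    seed: int,
) -> list[tuple[int, int]]:
    """Uniform random sample of eligible cells, without replacement.

    Eligible cells are non-nodata (in every layer) and not in
    ``exclude_cells``.  If fewer than ``n`` are eligible, all of them are
    returned with a warning.
    """
    mask = scenario.nodata_mask()
    eligible = [
        (r, c)
        for r in range(mask.shape[0])
        for c in range(mask.shape[1])
        if not mask[r, c] and (r, c) not in exclude_cells
    ]
    rng = np.random.default_rng(seed)
    if n >= len(eligible):
        if n > len(eligible):
            warnings.warn(
                f"requested {n} background cells but only {len(eligible)} eligible"
            )
        return eligible
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in idx]


def auc(presence_scores: Sequence[float], background_scores: Sequence[float]) -> float:
    """Rank-statistic AUC with half credit for ties.

    AUC = [#(p > b) + 0.5 * #(p = b)] / (n_p * n_b), identical to the
    trapezoidal area under the ROC curve and to the normalized
    Mann-Whitney U statistic.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("presence and background score lists must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


def evaluate_model(
    model: EnvelopeModel,
    occ: OccurrenceSet,
    scenario: ClimateScenario,
    n_background: int | None = None,
    seed: int = 0,
) -> EvaluationResult:
    """AUC of an envelope model on a scenario.

    Presences are the distinct valid occurrence cells (duplicate cells
    collapse to one, consistent with the environmentally-unique logic);
    background cells are sampled uniformly from the rest of the grid.
    Default background size is min(10 * n_presence, 10000).
    """
    table = sample_values(scenario, occ.points, variables=model.variables)
    valid = table[table["valid"]]
    if valid.empty:
        raise ValueError(f"{occ.species}: no valid presence cells")
    cells = sorted({(int(r), int(c)) for r, c in zip(valid["row"], valid["col"])})
    if n_background is None:
        n_background = min(10 * len(cells), MAX_BACKGROUND)
    surface = project_envelope(model, scenario)
    presence_scores = [surface.grid[rc] for rc in cells]
    bg_cells = sample_background(scenario, set(cells), n_background, seed)
    background_scores = [surface.grid[rc] for rc in bg_cells]
    return EvaluationResult(
        taxon=occ.species,
        variable_set=tuple(model.variables),
        auc=auc(presence_scores, background_scores),
        n_presence=len(cells),
        n_background=len(bg_cells),
        n_env_unique=count_env_unique(table),
        seed=seed,
    )


def mean_auc_per_variable(
    all_species: Mapping[str, OccurrenceSet],
    scenario: ClimateScenario,
    min_unique: int = DEFAULT_MIN_UNIQUE,
    seed: int = 0,
    n_background: int | None = None,
) -> MeanAucTable:
    """Single-variable mean AUC per climate variable.

    For each variable, fits a one-variable envelope per species, records
    its AUC, and averages over species whose occurrence data contain at
    least ``min_unique`` environmentally unique points for that variable.
    Variables with no qualifying species get NaN with a warning.
    """
    rows = []
    for j, var in enumerate(scenario.variable_names):
        aucs = []
        for k, (name, occ) in enumerate(all_species.items()):
            table = sample_values(scenario, occ.points, variables=[var])
            if not table["valid"].any():
                continue
            n_unique = count_env_unique(table)
            if n_unique < min_unique:
                continue
            model = fit_envelope(table, taxon=name)
            res = evaluate_model(
                model, occ, scenario,
                n_background=n_background,
                # decorrelate draws across (variable, species) pairs
                seed=seed * 1_000_003 + j * 1_009 + k,
            )
            aucs.append(res.auc)
        if not aucs:
            warnings.warn(f"no species with >= {min_unique} unique points for {var!r}")
        rows.append(
            {
                "variable": var,
                "mean_auc": float(np.mean(aucs)) if aucs else np.nan,
                "n_species_used": len(aucs),
            }
        )
    return MeanAucTable(pd.DataFrame(rows, columns=["variable", "mean_auc", "n_species_used"]))
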