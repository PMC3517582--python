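"""Envelope Score bioclimatic models.

The envelope of a taxon is, per climate variable, the closed interval
[min, max] of values observed at its occurrence localities.  Projected
into a climate scenario, the suitability of a cell is the fraction of
variables whose value at that cell falls inside the taxon's interval:
with L variables the surface takes values in {0, 1/L, ..., 1}.  This
deliberately simple algorithm treats variables independently, which is
what makes per-variable ancestral reconstruction of the bounds possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geodata import ClimateScenario

__all__ = [
    "EnvelopeModel",
    "SuitabilitySurface",
    "fit_envelope",
    "project_envelope",
    "classify_surface",
    "count_env_unique",
    "read_envelope_table",
    "write_envelope_table",
    "CLASS_BELOW",
    "CLASS_YELLOW",
    "CLASS_RED",
]

logger = logging.getLogger(__name__)

MIN_RECOMMENDED_POINTS = 10

# classified-map codes
CLASS_BELOW = 0   # fewer than L-1 variables suitable
CLASS_YELLOW = 1  # exactly L-1 variables suitable
CLASS_RED = 2     # all L variables suitable


class EnvelopeFitError(ValueError):
    """No valid occurrence points to fit an envelope from."""


@dataclass
class EnvelopeModel:
    """Per-variable (min, max) climate bounds for a taxon or tree node."""

    taxon_or_node: str
    bounds: dict[str, tuple[float, float]]
    n_points: int = 0

    def __post_init__(self) -> None:
        for var, (lo, hi) in self.bounds.items():
            if hi < lo:
                raise ValueError(f"{self.taxon_or_node}/{var}: max {hi} < min {lo}")

    @property
    def variables(self) -> list[str]:
        return list(self.bounds)

    def contains(self, variable: str, value: float) -> bool:
        lo, hi = self.bounds[variable]
        return lo <= value <= hi


@dataclass
class SuitabilitySurface:
    """Grid of envelope-projection probabilities over a scenario's grid.

    Values are k/L where k is the number of variables whose cell value lies
    inside the envelope; cells nodata in any scored layer are masked.
    """

    grid: np.ndarray
    n_layers: int
    nodata_mask: np.ndarray
    scenario_name: str = ""
    taxon_or_node: str = ""

    @property
    def values(self) -> np.ndarray:
        """Grid with masked cells as NaN."""
        out = self.grid.astype(float).copy()
        out[self.nodata_mask] = np.nan
        return out

    def area_at_least(self, min_value: float) -> int:
        """Number of unmasked cells with suitability >= min_value."""
        ok = ~self.nodata_mask
        return int(np.sum(self.grid[ok] >= min_value - 1e-12))


def fit_envelope(values_table: pd.DataFrame, taxon: str) -> EnvelopeModel:
    """Fit min-max bounds from a ``sample_values`` table.

    Only rows flagged valid contribute.  The envelope is the observed
    per-variable minimum and maximum; a single occurrence cell yields a
    degenerate (min == max) envelope, which is legitimate for narrow
    endemics known from one climate cell.
    """
    meta = {"lon", "lat", "row", "col", "valid"}
    variables = [c for c in values_table.columns if c not in meta]
    valid = values_table[values_table["valid"]] if "valid" in values_table else values_table
    if len(valid) == 0:
        raise EnvelopeFitError(f"{taxon}: no valid points to fit an envelope")
    if len(valid) < MIN_RECOMMENDED_POINTS:
        logger.warning(
            "%s: envelope fitted from only %d points (< %d); model may be minimal",
            taxon, len(valid), MIN_RECOMMENDED_POINTS,
        )
    bounds = {
        var: (float(valid[var].min()), float(valid[var].max())) for var in variables
    }
    return EnvelopeModel(taxon_or_node=taxon, bounds=bounds, n_points=len(valid))


def project_envelope(
    model: EnvelopeModel, scenario: ClimateScenario
) -> SuitabilitySurface:
    """Project an envelope into a scenario.

    Each cell scores (number of variables with min <= value <= max) / L,
    L being the number of variables in the model.  Bounds are closed, so a
    degenerate envelope still matches its own training cells exactly.
    """
    missing = [v for v in model.variables if v not in scenario.variable_names]
    if missing:
        raise KeyError(f"scenario {scenario.name!r} lacks variables {missing}")
    L = len(model.variables)
    stack = scenario.values_stack(model.variables)
    mask = scenario.nodata_mask(model.variables)
    inside = np.zeros(scenario.shape, dtype=int)
    for i, var in enumerate(model.variables):
        lo, hi = model.bounds[var]
        inside += ((stack[i] >= lo) & (stack[i] <= hi)).astype(int)
    grid = inside / L
    grid[mask] = 0.0
    return SuitabilitySurface(
        grid=grid,
        n_layers=L,
        nodata_mask=mask,
        scenario_name=scenario.name,
        taxon_or_node=model.taxon_or_node,
    )


def classify_surface(surface: SuitabilitySurface) -> np.ndarray:
    """Map a suitability surface to {0 below, 1 yellow, 2 red} codes.

    Red: all L variables suitable (value 1); yellow: exactly L-1 of L;
    everything else (and masked cells) below.
    """
    L = surface.n_layers
    if L < 1:
        raise ValueError("surface must score at least one layer")
    counts = np.rint(surface.grid * L).astype(int)
    out = np.full(surface.grid.shape, CLASS_BELOW, dtype=int)
    out[counts == L] = CLASS_RED
    if L >= 2:
        out[counts == L - 1] = CLASS_YELLOW
    out[surface.nodata_mask] = CLASS_BELOW
    return out


def count_env_unique(values_table: pd.DataFrame) -> int:
    """Count environmentally unique occurrence points.

    An occurrence is environmentally unique if the joint vector of climate
    values at its cell (over all variables in the table) has not been
    contributed by an earlier point.  Equivalently: the number of distinct
    climate-value vectors among valid points, compared at cell resolution.
    """
    meta = {"lon", "lat", "row", "col", "valid"}
    variables = [c for c in values_table.columns if c not in meta]
    valid = values_table[values_table["valid"]] if "valid" in values_table else values_table
    if len(valid) == 0:
        return 0
    return int(valid[variables].drop_duplicates().shape[0])


# ---------------------------------------------------------------------------
# Envelope table I/O (taxon,variable,min,max,n_points)

def write_envelope_table(
    models: Mapping[str, EnvelopeModel] | Sequence[EnvelopeModel], path: str | Path
) -> None:
    items = models.values() if isinstance(models, Mapping) else models
    rows = [
        {
            "taxon": m.taxon_or_node,
            "variable": var,
            "min": lo,
            "max": hi,
            "n_points": m.n_points,
        }
        for m in items
        for var, (lo, hi) in m.bounds.items()
    ]
    pd.DataFrame(rows, columns=["taxon", "variable", "min", "max", "n_points"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_envelope_table(path: str | Path) -> dict[str, EnvelopeModel]:
    df = pd.read_csv(path, float_precision="round_trip")
    out: dict[str, EnvelopeModel] = {}
    for taxon, sub in df.groupby("taxon", sort=False):
        bounds = {
            str(r.variable): (float(r.min), float(r.max)) for r in sub.itertuples()
        }
        n_points = int(sub["n_points"].iloc[0]) if "n_points" in sub else 0
        out[str(taxon)] = EnvelopeModel(str(taxon), bounds, n_points)
    return out
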