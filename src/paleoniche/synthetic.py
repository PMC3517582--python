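"""Synthetic phyloclimatic studies with known ground truth.

The generator emulates the three inputs the analysis pipeline consumes —
a dated ultrametric phylogeny, climate scenario grids, and per-species
occurrence records — from a single seed, keeping the true envelopes of
every node so each pipeline stage can be checked against truth.

Trees come from a pure-birth (Yule) process.  Envelopes evolve along the
tree as Brownian motion on (center, log-width) per variable rather than
on (min, max) directly, so simulated truth always satisfies max >= min;
the inference stage still reconstructs min and max independently, and
that deliberate mismatch is itself a test of the independence assumption.
Climate layers are spatially autocorrelated Gaussian noise plus a
latitudinal gradient, rescaled per variable to span the simulated
envelopes; paleo scenarios are smooth perturbations of the present-day
fields.  Occurrences are drawn uniformly from the cells where the tip's
true envelope scores 1.0, jittered within the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage

from .bioclim import EnvelopeModel, project_envelope
from .geodata import (
    ClimateLayer,
    ClimateScenario,
    OccurrenceSet,
    write_occurrences,
    write_scenario,
)
from .phylo import DatedTree

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_tree",
    "simulate_envelopes",
    "simulate_scenarios",
    "sample_occurrences",
    "generate_study",
    "write_study",
    "default_root_envelope",
]

DEFAULT_VARIABLES = (
    "mean_temperature_coolest_month",
    "sd_mean_temperature",
    "precipitation_warmest_month",
    "precipitation_coolest_month",
)


def default_root_envelope() -> EnvelopeModel:
    """Root climate envelope loosely shaped like a temperate montane taxon.

    Temperatures in degC, precipitation in mm/day.
    """
    return EnvelopeModel(
        taxon_or_node="root",
        bounds={
            "mean_temperature_coolest_month": (-5.0, 3.0),
            "sd_mean_temperature": (6.0, 10.0),
            "precipitation_warmest_month": (0.1, 1.5),
            "precipitation_coolest_month": (1.0, 5.0),
        },
    )


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a mid-sized clade analysis: a few dozen tips, four
    climate variables, about a hundred occurrence records per species,
    and present plus three paleo time slices.
    """

    n_tips: int = 32
    birth_rate: float = 0.25            # speciations / lineage / Ma
    root_envelope: EnvelopeModel = field(default_factory=default_root_envelope)
    sigma2_center: float = 0.05         # units^2 / Ma, envelope midpoint drift
    sigma2_logwidth: float = 0.005      # (log units)^2 / Ma, envelope width drift
    grid_shape: tuple[int, int] = (60, 60)
    smoothing_scale: float = 3.0        # cells, Gaussian kernel sd
    n_occurrences_per_tip: int = 100
    paleo_ages: tuple[float, ...] = (3.0, 8.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        for rate in (self.birth_rate, self.sigma2_center, self.sigma2_logwidth):
            if rate < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class GroundTruth:
    """A complete simulated study with the truth retained."""

    config: SimulationConfig
    tree: DatedTree
    true_envelopes: dict[int, EnvelopeModel]   # node_id -> envelope, all nodes
    scenarios: list[ClimateScenario]           # present first, then paleo
    occurrences: dict[str, OccurrenceSet]      # tip label -> points

    @property
    def present(self) -> ClimateScenario:
        return self.scenarios[0]

    @property
    def true_root_envelope(self) -> EnvelopeModel:
        return self.true_envelopes[self.tree.root.node_id]


# ---------------------------------------------------------------------------
# Tree simulation

def simulate_tree(n_tips: int, birth_rate: float, seed: int) -> DatedTree:
    """Ultrametric pure-birth tree with ``n_tips`` tips.

    The process starts from the root split (two lineages at time 0); each
    lineage then splits at rate ``birth_rate``.  Growth stops when the
    target tip count is reached and every tip is extended by the waiting
    time to the next (unrealized) event, keeping tip ages exchangeable.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)

    # each active lineage: (parent_node, birth_time)
    tree = dendropy.Tree()
    root = tree.seed_node
    root.sim_time = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        active.append((root, 0.0))
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = rng.integers(len(active))
        parent, birth = active.pop(i)
        node = dendropy.Node()
        node.sim_time = t
        parent.add_child(node)
        node.edge.length = t - birth
        active.append((node, t))
        active.append((node, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    ns = dendropy.TaxonNamespace()
    tree.taxon_namespace = ns
    for k, (parent, birth) in enumerate(active):
        tip = dendropy.Node()
        tip.taxon = ns.new_taxon(f"t{k + 1}")
        parent.add_child(tip)
        tip.edge.length = t_end - birth
    # clade-support labels, emulating posterior probabilities on an MCC tree
    for node in tree.postorder_internal_node_iter():
        pp = 1.0 if node is tree.seed_node else float(rng.uniform(0.5, 1.0))
        node.label = f"{pp:.3f}"
    return DatedTree.from_dendropy(tree)


# ---------------------------------------------------------------------------
# Envelope evolution

def simulate_envelopes(
    tree: DatedTree,
    root_envelope: EnvelopeModel,
    sigma2_center: float | Mapping[str, float],
    sigma2_logwidth: float | Mapping[str, float],
    seed: int,
) -> dict[int, EnvelopeModel]:
    """Evolve envelopes by BM on (center, log-width) along the tree.

    Per variable, the interval midpoint and the log of the interval width
    follow independent Brownian motions with the given rates (variance =
    rate x branch length).  min/max are derived as center -/+ width/2, so
    every simulated envelope is valid by construction.
    """
    rng = np.random.default_rng(seed)
    variables = root_envelope.variables

    def rate_of(rates: float | Mapping[str, float], var: str) -> float:
        return float(rates[var]) if isinstance(rates, Mapping) else float(rates)

    # state per node: {var: (center, logwidth)}
    states: dict[int, dict[str, tuple[float, float]]] = {}
    root_state = {}
    for var in variables:
        lo, hi = root_envelope.bounds[var]
        if hi <= lo:
            raise ValueError(f"root envelope for {var!r} must have max > min")
        root_state[var] = (0.5 * (lo + hi), float(np.log(hi - lo)))
    states[tree.root.node_id] = root_state

    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = node.edge.length
        parent_state = states[node.parent_node.node_id]
        st = {}
        for var in variables:
            c, lw = parent_state[var]
            c += rng.normal(0.0, np.sqrt(rate_of(sigma2_center, var) * bl))
            lw += rng.normal(0.0, np.sqrt(rate_of(sigma2_logwidth, var) * bl))
            st[var] = (c, lw)
        states[node.node_id] = st

    out: dict[int, EnvelopeModel] = {}
    for node in tree.nodes():
        bounds = {}
        for var in variables:
            c, lw = states[node.node_id][var]
            half = 0.5 * np.exp(lw)
            bounds[var] = (c - half, c + half)
        name = node.taxon.label if node.is_leaf() else f"node_{node.node_id}"
        out[node.node_id] = EnvelopeModel(name, bounds)
    return out


# ---------------------------------------------------------------------------
# Climate fields

def _tiles(grid_shape: tuple[int, int], n: int) -> list[tuple[slice, slice]]:
    """Partition a grid into n contiguous, roughly square tiles."""
    nrows, ncols = grid_shape
    k = int(np.ceil(np.sqrt(n)))
    m = int(np.ceil(n / k))
    row_edges = np.linspace(0, nrows, m + 1).astype(int)
    col_edges = np.linspace(0, ncols, k + 1).astype(int)
    tiles = [
        (slice(row_edges[i], row_edges[i + 1]), slice(col_edges[j], col_edges[j + 1]))
        for i in range(m)
        for j in range(k)
    ]
    tiles = [t for t in tiles if (t[0].stop > t[0].start and t[1].stop > t[1].start)]
    if len(tiles) < n:
        raise ValueError(f"grid {grid_shape} too small for {n} territories")
    return tiles[:n]


def _smooth_field(
    shape: tuple[int, int], smoothing_scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance spatially autocorrelated Gaussian field."""
    noise = rng.standard_normal(shape)
    if smoothing_scale > 0:
        noise = ndimage.gaussian_filter(noise, smoothing_scale, mode="reflect")
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def simulate_scenarios(
    config: SimulationConfig,
    envelopes: Mapping[int, EnvelopeModel] | None = None,
    seed: int | None = None,
    tip_ids: Sequence[int] | None = None,
) -> list[ClimateScenario]:
    """Present-day plus paleo scenario stacks.

    Each variable's present-day layer is smoothed noise plus a
    north-south gradient, affinely rescaled so the layer's value range
    spans the union of simulated envelope bounds with a margin.  When
    ``tip_ids`` is given, the grid is additionally partitioned into one
    contiguous territory tile per tip, and cell values inside a tile are
    drawn uniformly within that tip's envelope — every species then has
    a coherent region of fully suitable climate, as real species do.
    Paleo layers add an age-scaled smooth anomaly to the present-day
    field.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    variables = config.root_envelope.variables
    if envelopes:
        span: dict[str, tuple[float, float]] = {}
        for var in variables:
            los = [env.bounds[var][0] for env in envelopes.values()]
            his = [env.bounds[var][1] for env in envelopes.values()]
            lo, hi = min(los), max(his)
            margin = 0.5 * (hi - lo) + 1e-6
            span[var] = (lo - margin, hi + margin)
    else:
        span = {
            var: (lo - 0.5 * (hi - lo) - 1e-6, hi + 0.5 * (hi - lo) + 1e-6)
            for var, (lo, hi) in config.root_envelope.bounds.items()
        }

    nrows, ncols = config.grid_shape
    lat_gradient = np.linspace(1.0, -1.0, nrows)[:, None] * np.ones((1, ncols))
    origin = (-125.0, 49.0)  # western North America-like window
    cell = 0.25

    present_fields: dict[str, np.ndarray] = {}
    for var in variables:
        raw = 0.7 * _smooth_field(config.grid_shape, config.smoothing_scale, rng)
        raw = raw + 0.5 * lat_gradient
        lo, hi = span[var]
        rmin, rmax = raw.min(), raw.max()
        present_fields[var] = lo + (raw - rmin) / (rmax - rmin) * (hi - lo)

    if envelopes and tip_ids:
        for tile, tid in zip(_tiles(config.grid_shape, len(tip_ids)), tip_ids):
            env = envelopes[tid]
            rsl, csl = tile
            shape = (rsl.stop - rsl.start, csl.stop - csl.start)
            for var in variables:
                lo, hi = env.bounds[var]
                present_fields[var][rsl, csl] = rng.uniform(lo, hi, size=shape)

    def make_scenario(name: str, age: float, fields: Mapping[str, np.ndarray]):
        layers = [
            ClimateLayer(var, fields[var], origin=origin, cell_size=cell)
            for var in variables
        ]
        return ClimateScenario(name=name, age_ma=age, layers=layers)

    scenarios = [make_scenario("present", 0.0, present_fields)]
    max_age = max(config.paleo_ages) if config.paleo_ages else 1.0
    for age in config.paleo_ages:
        fields = {}
        for var in variables:
            lo, hi = span[var]
            anomaly = _smooth_field(config.grid_shape, config.smoothing_scale, rng)
            # anomaly grows with age but stays a fraction of the variable span
            fields[var] = present_fields[var] + 0.15 * (age / max_age) * (hi - lo) * anomaly
        scenarios.append(make_scenario(f"{age:g}Ma", age, fields))
    return scenarios


def sample_occurrences(
    tip_envelope: EnvelopeModel,
    scenario: ClimateScenario,
    n: int,
    seed: int,
) -> OccurrenceSet:
    """Presence points drawn from fully suitable cells of the scenario.

    Cells where the envelope scores 1.0 are sampled uniformly with
    replacement; each point is placed uniformly within its cell so
    coordinates are distinct while cell membership is exact.
    """
    rng = np.random.default_rng(seed)
    surface = project_envelope(tip_envelope, scenario)
    rows, cols = np.where((surface.grid >= 1.0 - 1e-12) & (~surface.nodata_mask))
    if rows.size == 0:
        raise ValueError(
            f"{tip_envelope.taxon_or_node}: no cell of scenario "
            f"{scenario.name!r} is suitable under all variables"
        )
    idx = rng.integers(rows.size, size=n)
    west, north = scenario.origin
    cs = scenario.cell_size
    points = []
    for r, c in zip(rows[idx], cols[idx]):
        lon = west + (c + rng.uniform(0.05, 0.95)) * cs
        lat = north - (r + rng.uniform(0.05, 0.95)) * cs
        points.append((float(lon), float(lat)))
    return OccurrenceSet(
        species=tip_envelope.taxon_or_node, points=points, source="synthetic"
    )


# ---------------------------------------------------------------------------
# Full study

def generate_study(config: SimulationConfig) -> GroundTruth:
    """Simulate tree, envelopes, scenarios and occurrences from one seed."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    tree = simulate_tree(config.n_tips, config.birth_rate, seeds[0])
    envelopes = simulate_envelopes(
        tree, config.root_envelope, config.sigma2_center,
        config.sigma2_logwidth, seeds[1],
    )
    tip_ids = tree.tip_ids()
    scenarios = simulate_scenarios(
        config, envelopes, seeds[2],
        tip_ids=[tip_ids[t] for t in tree.tip_labels],
    )
    occ_rng = np.random.SeedSequence(seeds[3]).spawn(config.n_tips)
    occurrences = {}
    for k, label in enumerate(tree.tip_labels):
        occurrences[label] = sample_occurrences(
            envelopes[tip_ids[label]],
            scenarios[0],
            config.n_occurrences_per_tip,
            int(occ_rng[k].generate_state(1)[0] % (2**31)),
        )
    return GroundTruth(
        config=config,
        tree=tree,
        true_envelopes=envelopes,
        scenarios=scenarios,
        occurrences=occurrences,
    )


def write_study(truth: GroundTruth, directory: str | Path) -> dict[str, Path]:
    """Write a complete study bundle (scenarios, occurrences, tree, truth)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for scen in truth.scenarios:
        paths[f"scenario_{scen.name}"] = write_scenario(
            scen, directory / "scenarios" / scen.name
        )
    occ_path = directory / "occurrences.csv"
    write_occurrences(truth.occurrences.values(), occ_path)
    paths["occurrences"] = occ_path
    tree_path = directory / "tree.nwk"
    truth.tree.write(tree_path)
    paths["tree"] = tree_path
    rows = [
        {
            "node_id": node_id,
            "taxon_or_node": env.taxon_or_node,
            "variable": var,
            "min": lo,
            "max": hi,
        }
        for node_id, env in sorted(truth.true_envelopes.items())
        for var, (lo, hi) in env.bounds.items()
    ]
    truth_path = directory / "true_envelopes.csv"
    pd.DataFrame(rows).to_csv(truth_path, index=False)
    paths["true_envelopes"] = truth_path
    return paths
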