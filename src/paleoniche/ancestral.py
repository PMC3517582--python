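"""Maximum-likelihood Brownian-motion ancestral state reconstruction.

Under Brownian motion a continuous character changes along each branch by
a Gaussian increment with variance sigma^2 * (branch length).  The joint
maximum-likelihood states at the internal nodes are the solution of the
sparse linear system in which every internal state is the
branch-length-inverse-weighted mean of its neighbours' states (tips held
at their observed values).  These coincide with the generalized
least-squares estimates built from the phylogenetic covariance matrix
C_ij = shared root-to-tip path length, and obey the maximum principle:
every reconstructed state lies between the smallest and largest tip
value.

The ML rate is sigma^2 = Q / n with n = number of tips and
Q = (x - a 1)' C^{-1} (x - a 1) evaluated at the GLS root state a;
Q equals the minimized sum over edges of (Ds)^2 / branch length.  The
REML variant (divisor n - 1) is reported alongside for transparency.

Climate envelopes are reconstructed by running this machinery
independently for every (variable, bound) character — 8 characters for a
4-variable envelope — mirroring the independence assumption of the
envelope algorithm itself.  Because the bounds are reconstructed
independently nothing forces max >= min at an ancestor; when an inversion
occurs both bounds are collapsed to their midpoint and the event logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .bioclim import EnvelopeModel
from .phylo import DatedTree

__all__ = [
    "AncestralReconstruction",
    "EnvelopeReconstruction",
    "reconstruct_bm",
    "reconstruct_envelopes",
    "phylogenetic_covariance",
]

logger = logging.getLogger(__name__)


@dataclass
class AncestralReconstruction:
    """ML states of one continuous character at every node of a tree.

    Attributes
    ----------
    character
        Name of the character, e.g. ``("Mean_temperature", "max")``.
    node_states
        Map node id -> ML state (tips carry their observed value).
    sigma2
        ML Brownian rate, units^2 / Ma (divisor n).
    sigma2_reml
        REML rate (divisor n - 1), reported for transparency.
    loglik
        Log-likelihood of the tip data at the ML rate.
    """

    character: tuple[str, str] | str
    node_states: dict[int, float]
    sigma2: float
    sigma2_reml: float
    loglik: float
    root_state: float

    def summary(self) -> str:
        lines = [
            f"Brownian-motion ML reconstruction: {self.character}",
            f"  nodes: {len(self.node_states)}",
            f"  root state: {self.root_state:.6g}",
            f"  sigma^2 (ML, divisor n): {self.sigma2:.6g}",
            f"  sigma^2 (REML, divisor n-1): {self.sigma2_reml:.6g}",
            f"  log-likelihood: {self.loglik:.6g}",
        ]
        return "\n".join(lines)


def _merge_zero_branches(tree: DatedTree) -> dict[int, int]:
    """Union-find map collapsing nodes joined by zero-length branches."""
    parent: dict[int, int] = {n.node_id: n.node_id for n in tree.nodes()}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    merged = False
    for node in tree.nodes():
        if node.parent_node is not None and node.edge.length == 0:
            merged = True
            parent[find(node.node_id)] = find(node.parent_node.node_id)
    if merged:
        warnings.warn("zero-length branches collapsed; merged nodes share a state")
    return {i: find(i) for i in parent}


def reconstruct_bm(
    tree: DatedTree, tip_values: Mapping[str, float],
    character: tuple[str, str] | str = "trait",
) -> AncestralReconstruction:
    """Joint-ML Brownian-motion states at the internal nodes.

    Parameters
    ----------
    tree
        Dated phylogeny (>= 2 tips).
    tip_values
        Finite value per tip label; every tip must be present.

    Notes
    -----
    States come from solving the harmonic linear system; the rate and
    log-likelihood from the GLS quadratic form, using the identity that
    the minimized edge sum of squared scaled increments equals
    (x - a1)' C^{-1} (x - a1).
    """
    tips = tree.tip_labels
    if len(tips) < 2:
        raise ValueError("need at least 2 tips")
    missing = [t for t in tips if t not in tip_values]
    if missing:
        raise ValueError(f"missing tip values for {missing}")
    vals = {t: float(tip_values[t]) for t in tips}
    if not all(np.isfinite(v) for v in vals.values()):
        raise ValueError("tip values must be finite")

    rep = _merge_zero_branches(tree)
    nodes = tree.nodes()
    # representative ids that actually need solving (internal, not pinned to a tip)
    tip_of_rep: dict[int, float] = {}
    for node in nodes:
        if node.is_leaf():
            r = rep[node.node_id]
            if r in tip_of_rep and tip_of_rep[r] != vals[node.taxon.label]:
                raise ValueError("zero-length branches merge tips with unequal values")
            tip_of_rep[r] = vals[node.taxon.label]
    free = sorted(
        {rep[n.node_id] for n in nodes} - set(tip_of_rep)
    )
    index = {r: k for k, r in enumerate(free)}

    m = len(free)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for node in nodes:
        if node.parent_node is None or node.edge.length == 0:
            continue
        u, v = rep[node.node_id], rep[node.parent_node.node_id]
        w = 1.0 / node.edge.length
        for x, y in ((u, v), (v, u)):
            if x in index:
                A[index[x], index[x]] += w
                if y in index:
                    A[index[x], index[y]] -= w
                else:
                    b[index[x]] += w * tip_of_rep[y]
    if m:
        sol = np.linalg.solve(A, b)
    else:
        sol = np.empty(0)

    state_of_rep = dict(tip_of_rep)
    state_of_rep.update({r: float(sol[index[r]]) for r in free})
    node_states = {n.node_id: state_of_rep[rep[n.node_id]] for n in nodes}

    # minimized sum of squared scaled increments = GLS quadratic form Q
    Q = 0.0
    for node in nodes:
        if node.parent_node is None or node.edge.length == 0:
            continue
        ds = node_states[node.node_id] - node_states[node.parent_node.node_id]
        Q += ds * ds / node.edge.length
    n = len(tips)
    sigma2 = Q / n
    sigma2_reml = Q / (n - 1) if n > 1 else np.nan

    C, order = phylogenetic_covariance(tree)
    sign, logdet = np.linalg.slogdet(C)
    if sigma2 > 0:
        loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    else:
        loglik = np.inf  # degenerate: all tips identical, point mass
    root_state = node_states[tree.root.node_id]
    return AncestralReconstruction(
        character=character,
        node_states=node_states,
        sigma2=float(sigma2),
        sigma2_reml=float(sigma2_reml),
        loglik=float(loglik),
        root_state=float(root_state),
    )


def phylogenetic_covariance(tree: DatedTree) -> tuple[np.ndarray, list[str]]:
    """Dense BM covariance among tips: shared root-to-tip path length.

    Returns (C, tip_order); C[i, j] is the depth of the MRCA of tips i and
    j below the root (branch-length distance from root to MRCA).
    """
    tips = [n for n in tree.nodes() if n.is_leaf()]
    order = [t.taxon.label for t in tips]
    n = len(tips)
    # path of ancestors for each tip
    anc: list[dict[int, float]] = []
    for t in tips:
        path = {}
        node = t
        while node is not None:
            path[node.node_id] = node.depth
            node = node.parent_node
        anc.append(path)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            shared = set(anc[i]) & set(anc[j])
            C[i, j] = C[j, i] = max(anc[i][k] for k in shared)
    return C, order


@dataclass
class EnvelopeReconstruction:
    """Ancestral envelopes plus per-character rates and diagnostics."""

    node_envelopes: dict[int, EnvelopeModel]
    characters: dict[tuple[str, str], AncestralReconstruction]
    repairs: list[tuple[int, str, float, float]] = field(default_factory=list)

    def rates_table(self) -> pd.DataFrame:
        rows = [
            {
                "variable": var,
                "bound": bound,
                "sigma2": rec.sigma2,
                "sigma2_reml": rec.sigma2_reml,
                "loglik": rec.loglik,
            }
            for (var, bound), rec in self.characters.items()
        ]
        return pd.DataFrame(rows)

    def bounds_table(self, tree: DatedTree | None = None) -> pd.DataFrame:
        """Wide table: node_id then Max/Min columns per variable."""
        variables: list[str] = []
        for var, _ in self.characters:
            if var not in variables:
                variables.append(var)
        rows = []
        for node_id, env in sorted(self.node_envelopes.items()):
            row: dict[str, object] = {"node_id": node_id}
            if tree is not None:
                row["age_ma"] = tree.node_by_id(node_id).age_ma
            for var in variables:
                lo, hi = env.bounds[var]
                row[f"{var}_max"] = hi
                row[f"{var}_min"] = lo
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Ancestral envelope reconstruction: {len(self.node_envelopes)} nodes"]
        for (var, bound), rec in self.characters.items():
            lines.append(
                f"  {var} [{bound}]: sigma^2={rec.sigma2:.4g}, "
                f"root={rec.root_state:.4g}, loglik={rec.loglik:.4g}"
            )
        if self.repairs:
            lines.append(f"  {len(self.repairs)} node/variable inversions repaired "
                         "(bounds collapsed to midpoint)")
        return "\n".join(lines)


def reconstruct_envelopes(
    tree: DatedTree, tip_envelopes: Mapping[str, EnvelopeModel]
) -> EnvelopeReconstruction:
    """Reconstruct ancestral envelopes, one BM fit per (variable, bound).

    All tips must share the same variable set.  If a node's reconstructed
    max falls below its min for a variable (possible because bounds are
    reconstructed independently), both are replaced by their midpoint and
    the repair recorded.
    """
    tips = tree.tip_labels
    missing = [t for t in tips if t not in tip_envelopes]
    if missing:
        raise ValueError(f"missing envelopes for tips {missing}")
    variables = tip_envelopes[tips[0]].variables
    for t in tips:
        if tip_envelopes[t].variables != variables:
            raise ValueError(f"tip {t!r} has a different variable set")

    characters: dict[tuple[str, str], AncestralReconstruction] = {}
    for var in variables:
        for bound, pick in (("min", 0), ("max", 1)):
            tip_vals = {t: tip_envelopes[t].bounds[var][pick] for t in tips}
            characters[(var, bound)] = reconstruct_bm(
                tree, tip_vals, character=(var, bound)
            )

    node_envelopes: dict[int, EnvelopeModel] = {}
    repairs: list[tuple[int, str, float, float]] = []
    for node in tree.nodes():
        if node.is_leaf():
            continue
        bounds: dict[str, tuple[float, float]] = {}
        for var in variables:
            lo = characters[(var, "min")].node_states[node.node_id]
            hi = characters[(var, "max")].node_states[node.node_id]
            if hi < lo:
                mid = 0.5 * (lo + hi)
                repairs.append((node.node_id, var, lo, hi))
                logger.warning(
                    "node %d / %s: reconstructed max %.4g < min %.4g; "
                    "collapsed to midpoint", node.node_id, var, hi, lo,
                )
                lo = hi = mid
            bounds[var] = (lo, hi)
        node_envelopes[node.node_id] = EnvelopeModel(
            taxon_or_node=f"node_{node.node_id}", bounds=bounds, n_points=0
        )
    return EnvelopeReconstruction(
        node_envelopes=node_envelopes, characters=characters, repairs=repairs
    )
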