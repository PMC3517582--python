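"""Dated phylogenies: Newick ingestion, node ages, support filtering.

Trees are rooted, fully resolved (binary), with branch lengths in Ma.
Internal Newick node labels, when numeric and in [0, 1], are read as
posterior probabilities (the convention of BEAST maximum-clade-credibility
exports); bracketed metadata comments ``[&...]`` are tolerated and
ignored.  Node ids are assigned deterministically: tips first in the
order they appear in postorder, then internal nodes in postorder, so the
root always has the largest id.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .geodata import ClimateScenario

__all__ = ["DatedTree", "read_tree", "supported_nodes", "assign_scenario"]

ULTRAMETRIC_RTOL = 1e-6


@dataclass
class DatedTree:
    """A dated, fully resolved phylogeny with derived node ages.

    Wraps a :class:`dendropy.Tree`; every node carries ``node_id`` (int),
    ``age_ma`` (float, Ma above present) and internal nodes optionally
    ``posterior`` (float in [0, 1]).
    """

    tree: dendropy.Tree

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "DatedTree":
        tree.is_rooted = True
        self = cls(tree)
        self._validate()
        self._index_nodes()
        self._compute_ages()
        return self

    @classmethod
    def from_newick(cls, newick: str) -> "DatedTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as err:
            raise ValueError(f"duplicate tip label: {err}") from err
        return cls.from_dendropy(tree)

    def _validate(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate tip labels")
        if len(labels) < 2:
            raise ValueError("tree must have at least 2 tips")
        for node in self.tree.preorder_node_iter():
            nch = len(node.child_nodes())
            if nch not in (0, 2):
                raise ValueError(
                    f"tree must be fully resolved (binary); node has {nch} children"
                )
            if node.parent_node is not None:
                if node.edge.length is None:
                    raise ValueError("every non-root branch needs a length")
                if node.edge.length < 0:
                    raise ValueError(f"negative branch length {node.edge.length}")
            # internal labels are posterior probabilities
            if nch > 0:
                pp = _parse_posterior(node.label)
                node.posterior = pp

    def _index_nodes(self) -> None:
        tips = [n for n in self.tree.postorder_node_iter() if n.is_leaf()]
        internals = [n for n in self.tree.postorder_node_iter() if not n.is_leaf()]
        for i, node in enumerate(tips + internals):
            node.node_id = i

    def _compute_ages(self) -> None:
        # depth = distance from root
        root = self.tree.seed_node
        root.depth = 0.0
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                node.depth = node.parent_node.depth + node.edge.length
        tip_depths = [n.depth for n in self.tree.leaf_node_iter()]
        height = max(tip_depths)
        if height > 0 and (max(tip_depths) - min(tip_depths)) > ULTRAMETRIC_RTOL * height:
            warnings.warn(
                "tree is not ultrametric; node ages measured as tree height "
                "minus node depth"
            )
        for node in self.tree.preorder_node_iter():
            node.age_ma = max(height - node.depth, 0.0)

    # -- accessors -----------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def tip_labels(self) -> list[str]:
        return [n.taxon.label for n in self.tree.postorder_node_iter() if n.is_leaf()]

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    @property
    def root_age(self) -> float:
        return float(self.root.age_ma)

    def nodes(self) -> list[dendropy.Node]:
        """All nodes sorted by node_id (tips first, then internals postorder)."""
        return sorted(self.tree.preorder_node_iter(), key=lambda n: n.node_id)

    def node_by_id(self, node_id: int) -> dendropy.Node:
        for node in self.tree.preorder_node_iter():
            if node.node_id == node_id:
                return node
        raise KeyError(f"no node with id {node_id}")

    def tip_ids(self) -> dict[str, int]:
        return {
            n.taxon.label: n.node_id
            for n in self.tree.preorder_node_iter()
            if n.is_leaf()
        }

    def mrca_age(self, taxon_a: str, taxon_b: str) -> float:
        mrca = self.tree.mrca(taxon_labels=[taxon_a, taxon_b])
        return float(mrca.age_ma)

    def sister_pairs(self) -> list[tuple[str, str]]:
        """Cherries: internal nodes whose two children are both tips."""
        out = []
        for node in self.tree.postorder_node_iter():
            ch = node.child_nodes()
            if len(ch) == 2 and all(c.is_leaf() for c in ch):
                out.append((ch[0].taxon.label, ch[1].taxon.label))
        return out

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def node_table(self) -> pd.DataFrame:
        """``node_id, label, age_ma, pp, child_ids`` for every node."""
        rows = []
        for node in self.nodes():
            rows.append(
                {
                    "node_id": node.node_id,
                    "label": node.taxon.label if node.is_leaf() else (node.label or ""),
                    "age_ma": node.age_ma,
                    "pp": getattr(node, "posterior", None),
                    "child_ids": ";".join(
                        str(c.node_id) for c in node.child_nodes()
                    ),
                }
            )
        return pd.DataFrame(rows)


def _parse_posterior(label: str | None) -> float | None:
    if label is None:
        return None
    label = re.sub(r"\[&[^\]]*\]", "", str(label)).strip()
    if not label:
        return None
    try:
        pp = float(label)
    except ValueError:
        return None
    if not 0.0 <= pp <= 1.0:
        raise ValueError(f"internal node label {label!r} is not a posterior in [0,1]")
    return pp


def read_tree(newick_path: str | Path) -> DatedTree:
    """Read a dated tree from a Newick file.

    Internal node labels parse as posterior probabilities; polytomies,
    negative branch lengths and duplicate tip labels are rejected.
    """
    text = Path(newick_path).read_text()
    return DatedTree.from_newick(text)


def supported_nodes(tree: DatedTree, min_pp: float = 0.95) -> list[int]:
    """Ids of internal nodes with posterior probability above ``min_pp``.

    The root is included even when it carries no posterior label (the MCC
    root is by construction present in every sampled tree).
    """
    out = []
    for node in tree.nodes():
        if node.is_leaf():
            continue
        pp = getattr(node, "posterior", None)
        if pp is None:
            if node is tree.root:
                out.append(node.node_id)
            continue
        if pp > min_pp:
            out.append(node.node_id)
    return out


def assign_scenario(
    node_age: float, scenarios: list[ClimateScenario]
) -> ClimateScenario:
    """The scenario whose age is closest to the node's age; ties go younger."""
    if not scenarios:
        raise ValueError("no scenarios supplied")
    return min(scenarios, key=lambda s: (abs(s.age_ma - node_age), s.age_ma))
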