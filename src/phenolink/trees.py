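"""Newick trees and the phylogenetic correlation kernel.

Under a Brownian-motion model of trait evolution on an ultrametric tree, the
correlation between two species' random effects equals the fraction of the
root-to-tip path they share.  ``correlation_matrix`` builds that matrix
(unit diagonal, entries in [0, 1], positive semi-definite) for use as the
covariance kernel of the phylogenetic species component in the
meta-analysis.  Parsing and serialization go through :mod:`dendropy`.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import LabellingError, NotUltrametricError

__all__ = [
    "PhyloCorrelation",
    "parse_newick",
    "read_newick",
    "write_newick",
    "tip_depths",
    "is_ultrametric",
    "correlation_matrix",
    "align_to_studies",
]


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; every non-root edge must carry a branch length."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parser error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(
                f"missing branch length above node "
                f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
            )
    return tree


def read_newick(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length per tip label."""
    depths: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths


def is_ultrametric(tree: dendropy.Tree, rtol: float = 1e-6) -> bool:
    d = np.array(list(tip_depths(tree).values()))
    depth = float(np.max(d))
    if depth == 0:
        return True
    return bool(np.max(np.abs(d - depth)) <= rtol * depth)


@dataclass
class PhyloCorrelation:
    """Species-level phylogenetic correlation matrix."""

    species: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.species)
        if self.matrix.shape != (k, k):
            raise ValueError("matrix shape must match species list")

    def loc(self, a: str, b: str) -> float:
        i, j = self.species.index(a), self.species.index(b)
        return float(self.matrix[i, j])


def correlation_matrix(tree: dendropy.Tree, rtol: float = 1e-6) -> PhyloCorrelation:
    """Shared-path-length correlation: A_ij = depth(MRCA(i, j)) / tree depth.

    Requires an ultrametric tree (all tips equidistant from the root within
    ``rtol``); non-ultrametric inputs are rejected with instructions to
    rescale rather than silently normalized.
    """
    if not is_ultrametric(tree, rtol=rtol):
        raise NotUltrametricError(
            "tree is not ultrametric; rescale branch lengths (e.g. with a "
            "dating method) before building a phylogenetic correlation"
        )
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    depth = max(tip_depths(tree).values())
    k = len(leaves)
    A = np.eye(k)
    if depth == 0:
        return PhyloCorrelation(species=labels, matrix=A)

    # node depth via preorder accumulation
    node_depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node_depth[id(node)] = node_depth[id(node.parent_node)] + (
                node.edge.length or 0.0
            )

    # MRCA depth of a tip pair = depth of the deepest node having both tips
    # below it; fill by postorder merge of leaf sets
    leafsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = [index[id(node)]]
            continue
        children = [leafsets[id(c)] for c in node.child_nodes()]
        d = node_depth[id(node)] / depth
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    for j in children[b]:
                        A[i, j] = A[j, i] = d
        merged: list[int] = []
        for c in children:
            merged.extend(c)
        leafsets[id(node)] = merged
    return PhyloCorrelation(species=labels, matrix=A)


def align_to_studies(
    A: PhyloCorrelation, species_of_each_effect: list[str]
) -> np.ndarray:
    """Expand the species kernel to one row/column per effect record."""
    unknown = sorted(set(species_of_each_effect) - set(A.species))
    if unknown:
        raise LabellingError(f"species not in tree: {unknown}")
    pos = [A.species.index(s) for s in species_of_each_effect]
    return A.matrix[np.ix_(pos, pos)]
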