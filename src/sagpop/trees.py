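"""Helpers around rooted dendropy trees used as clonal genealogies.

A clonal genealogy is a rooted (binary, except where a caller builds a
multifurcation on purpose) dendropy ``Tree`` whose edge lengths are in
expected clonal substitutions per site (or in abstract units the caller
multiplies by a rate).  ``index_tree`` flattens it into arrays so that the
simulators, the parsimony machinery and the HMM can all traverse it the same
way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

__all__ = ["IndexedTree", "index_tree", "read_newick", "write_newick",
           "label_nodes", "three_cluster_tree"]


@dataclass
class IndexedTree:
    """Flat arrays for a rooted tree: node 0 is the root, order is preorder."""

    tree: dendropy.Tree
    nodes: list  # dendropy nodes, preorder
    labels: list[str]  # node labels (leaf taxon labels; internal node labels)
    parent: np.ndarray  # parent index per node, -1 for root
    length: np.ndarray  # edge length above each node, 0.0 for root
    is_leaf: np.ndarray  # bool
    postorder: np.ndarray = field(init=False)  # node indices, children first

    def __post_init__(self) -> None:
        order = np.arange(len(self.nodes))[::-1]  # reverse preorder = postorder-compatible
        self.postorder = order

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def leaf_labels(self) -> list[str]:
        return [l for l, leaf in zip(self.labels, self.is_leaf) if leaf]

    def children(self, i: int) -> np.ndarray:
        return np.nonzero(self.parent == i)[0]

    def branch_label(self, i: int) -> str:
        """Label of the branch above node i (named after its child node)."""
        return self.labels[i]


def label_nodes(tree: dendropy.Tree) -> dendropy.Tree:
    """Ensure every node carries a label (leaves: taxon; internals: n<k>)."""
    used = {n.label for n in tree.preorder_node_iter() if not n.is_leaf() and n.label}
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            if node.taxon is None:
                raise ValueError("leaf without taxon label")
        elif not node.label:
            while f"n{k}" in used:
                k += 1
            node.label = f"n{k}"
            used.add(f"n{k}")
    return tree


def index_tree(tree: dendropy.Tree) -> IndexedTree:
    label_nodes(tree)
    nodes = list(tree.preorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    labels = [n.taxon.label if n.is_leaf() else n.label for n in nodes]
    parent = np.array(
        [idx[id(n.parent_node)] if n.parent_node is not None else -1 for n in nodes],
        dtype=np.int64,
    )
    length = np.array(
        [n.edge.length if (n.parent_node is not None and n.edge.length is not None) else 0.0
         for n in nodes],
        dtype=float,
    )
    if (length < 0).any():
        raise ValueError("negative branch length in genealogy")
    is_leaf = np.array([n.is_leaf() for n in nodes], dtype=bool)
    return IndexedTree(tree=tree, nodes=nodes, labels=labels, parent=parent,
                       length=length, is_leaf=is_leaf)


def read_newick(path: str | Path, require_rooted: bool = True) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    if require_rooted and len(tree.seed_node.child_nodes()) > 2:
        raise ValueError("tree is unrooted (root has >2 children); a rooted tree is required")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def three_cluster_tree(n_per_cluster: int = 3, within: float = 0.02,
                       between: float = 0.5) -> dendropy.Tree:
    """A fixed genealogy with three tight microclusters (A, B, C).

    ``within`` is the expected pairwise path length between members of one
    cluster, ``between`` the expected cross-cluster pairwise path length —
    both in the tree's branch-length units (use mu=1 downstream so they read
    as substitutions per site).  Mirrors the observed structure of a
    population split into microclusters with within-group divergence far
    below between-group divergence.
    """
    if between <= within:
        raise ValueError("between-cluster divergence must exceed within-cluster")
    stem = (between - within) / 2.0

    def clade(prefix: str) -> str:
        tip = within / 2.0
        labels = [f"{prefix}{i+1}" for i in range(n_per_cluster)]
        if n_per_cluster == 1:
            return f"{labels[0]}:0"
        # ladder with all tips at depth `tip` below the cluster MRCA
        inner = f"({labels[0]}:{tip},{labels[1]}:{tip})"
        depth = tip
        for lab in labels[2:]:
            # keep tip depths equal; internal branches of length 0
            inner = f"({inner}:0,{lab}:{depth})"
        return inner

    nwk = (f"(({clade('A')}:{stem},{clade('B')}:{stem}):0,"
           f"{clade('C')}:{stem});")
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    tree.is_rooted = True
    return label_nodes(tree)
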