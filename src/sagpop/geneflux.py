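"""Gene-content flux on a fixed rooted genealogy by weighted parsimony.

The substrate is an occurrence matrix: taxa x ortholog clusters, binary
presence (copy number is deliberately discarded).  Ancestral presence is
reconstructed per cluster with a two-state Sankoff dynamic program — cost 0
to stay, ``gain_cost`` for 0->1, ``loss_cost`` for 1->0; the field-standard
asymmetry (gain 2, loss 1) is the default — with ACCTRAN tie resolution in
the traceback: whenever two child states are cost-equivalent, the one that
implies a change on the current (rootward) branch is chosen, placing changes
as close to the root as possible.  No prior is put on the root state; ties
there resolve toward absence (override with ``root_state``).

A penalty sweep over the gain cost quantifies how confidently clusters are
called as gained on a focal branch: true gains survive high penalties, while
patterns equally explained by repeated losses drop out.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trees import IndexedTree, index_tree

__all__ = [
    "FluxReconstruction",
    "build_occurrence_matrix",
    "read_membership_tsv",
    "build_composite_taxon",
    "sankoff_reconstruct",
    "penalty_sweep",
    "find_branch",
    "cluster_genes_single_linkage",
]

_BIG = 1e18


class MissingTaxonError(KeyError):
    pass


# ---------------------------------------------------------------------------
# occurrence matrix

def build_occurrence_matrix(membership: pd.DataFrame) -> pd.DataFrame:
    """Binary taxa x cluster presence from (taxon, gene, cluster) rows.

    A cell is 1 iff the taxon has at least one gene in the cluster —
    presence/absence disregarding copy number.
    """
    if membership.empty:
        raise ValueError("empty membership table")
    cols = list(membership.columns[:3])
    df = membership.rename(columns=dict(zip(cols, ["taxon", "gene", "cluster"])))
    mat = (pd.crosstab(df["taxon"], df["cluster"]) > 0).astype(int)
    mat.index.name = None
    mat.columns.name = None
    return mat.sort_index(axis=0).sort_index(axis=1)


def read_membership_tsv(path: str | Path) -> pd.DataFrame:
    """Read a 3-column (taxon, gene, cluster) TSV, reporting bad lines."""
    df = pd.read_csv(path, sep="\t", header=None, names=["taxon", "gene", "cluster"],
                     dtype=str, comment="#")
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"malformed membership row at line {int(bad[0]) + 1}")
    return df


def build_composite_taxon(
    matrix: pd.DataFrame, external_hits: Iterable[str] = ()
) -> tuple[pd.Series, list[str]]:
    """Collapse partial taxa into one composite gene-content row.

    A cluster is part of the composite iff it occurs in >= 2 of the partial
    taxa, or in exactly one of them but with a hit in at least one external
    genome.  Clusters found in a single partial taxon and nowhere else are
    excluded (likely amplification artifacts or ORF calls without support)
    and returned for audit.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 partial taxa to build a composite")
    ext = set(external_hits)
    counts = matrix.sum(axis=0)
    keep = (counts >= 2) | ((counts == 1) & matrix.columns.isin(ext))
    composite = ((counts > 0) & keep).astype(int)
    composite.name = "composite"
    excluded = sorted(counts.index[(counts == 1) & ~keep])
    return composite, excluded


# ---------------------------------------------------------------------------
# Sankoff reconstruction

@dataclass
class FluxReconstruction:
    """Ancestral presence states and per-branch event counts."""

    node_states: pd.DataFrame  # nodes x clusters, 0/1 (root first, preorder)
    gains: pd.Series  # per-branch (labelled by child node) gained clusters
    losses: pd.Series
    presence: pd.Series  # per-node number of clusters present
    total_cost: float
    gain_cost: float
    loss_cost: float

    def events_table(self) -> pd.DataFrame:
        return pd.DataFrame({"gains": self.gains, "losses": self.losses})


def _sankoff_states(
    itree: IndexedTree,
    leaf_states: np.ndarray,  # (n_nodes, n_clusters) with -1 for internals
    gain_cost: float,
    loss_cost: float,
    root_state: int | None,
) -> tuple[np.ndarray, float]:
    n_nodes, n_clusters = leaf_states.shape
    # cost[node, state, cluster]
    cost = np.zeros((n_nodes, 2, n_clusters))
    trans = np.array([[0.0, gain_cost], [loss_cost, 0.0]])  # trans[parent, child]

    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for i in range(1, n_nodes):
        children[itree.parent[i]].append(i)

    for i in itree.postorder:
        if itree.is_leaf[i]:
            s = leaf_states[i]
            cost[i, 0] = np.where(s == 0, 0.0, _BIG)
            cost[i, 1] = np.where(s == 1, 0.0, _BIG)
        else:
            acc0 = np.zeros(n_clusters)
            acc1 = np.zeros(n_clusters)
            for c in children[i]:
                acc0 += np.minimum(cost[c, 0] + trans[0, 0], cost[c, 1] + trans[0, 1])
                acc1 += np.minimum(cost[c, 0] + trans[1, 0], cost[c, 1] + trans[1, 1])
            cost[i, 0] = acc0
            cost[i, 1] = acc1

    states = np.zeros((n_nodes, n_clusters), dtype=np.int8)
    if root_state is None:
        # no prior; ties resolve toward absence (presence then explained by
        # gains on the rootmost branches, the ACCTRAN-flavored choice)
        states[0] = (cost[0, 1] < cost[0, 0]).astype(np.int8)
    else:
        states[0] = int(root_state)
    total = float(cost[0, states[0], np.arange(n_clusters)].sum())

    for i in range(1, n_nodes):  # preorder; parent states already fixed
        ps = states[itree.parent[i]]
        v0 = cost[i, 0] + trans[ps, 0]
        v1 = cost[i, 1] + trans[ps, 1]
        # ACCTRAN: on cost ties prefer the child state != parent state,
        # putting the change on the current (rootward) branch
        v_keep = np.where(ps == 0, v0, v1)
        v_change = np.where(ps == 0, v1, v0)
        states[i] = np.where(v_change <= v_keep, 1 - ps, ps).astype(np.int8)
    return states, total


def sankoff_reconstruct(
    tree,
    matrix: pd.DataFrame,
    gain_cost: float = 2.0,
    loss_cost: float = 1.0,
    resolution: str = "acctran",
    root_state: int | None = None,
) -> FluxReconstruction:
    """Weighted-parsimony ancestral presence with ACCTRAN tie resolution."""
    if gain_cost <= 0 or loss_cost <= 0:
        raise ValueError("costs must be positive")
    if resolution != "acctran":
        raise ValueError("only 'acctran' resolution is implemented")
    itree = tree if isinstance(tree, IndexedTree) else index_tree(tree)
    missing = [t for t in itree.leaf_labels if t not in matrix.index]
    if missing:
        raise MissingTaxonError(f"tree leaves absent from matrix: {missing}")

    n_nodes = itree.n_nodes
    clusters = list(matrix.columns)
    leaf_states = np.full((n_nodes, len(clusters)), -1, dtype=np.int8)
    for i in range(n_nodes):
        if itree.is_leaf[i]:
            leaf_states[i] = matrix.loc[itree.labels[i]].to_numpy(dtype=np.int8)

    states, total = _sankoff_states(itree, leaf_states, gain_cost, loss_cost, root_state)

    labels = itree.labels
    gains = pd.Series(0, index=labels[1:], dtype=int)
    losses = pd.Series(0, index=labels[1:], dtype=int)
    for i in range(1, n_nodes):
        ps = states[itree.parent[i]]
        gains.loc[labels[i]] = int(((ps == 0) & (states[i] == 1)).sum())
        losses.loc[labels[i]] = int(((ps == 1) & (states[i] == 0)).sum())
    presence = pd.Series(states.sum(axis=1), index=labels, dtype=int)
    node_states = pd.DataFrame(states, index=labels, columns=clusters)
    cost_realized = float(gains.sum() * gain_cost + losses.sum() * loss_cost)
    return FluxReconstruction(
        node_states=node_states, gains=gains, losses=losses, presence=presence,
        total_cost=cost_realized, gain_cost=gain_cost, loss_cost=loss_cost,
    )


def find_branch(tree, clade_leaves: Iterable[str]) -> str:
    """Label of the branch subtending exactly the given leaf set (its MRCA)."""
    itree = tree if isinstance(tree, IndexedTree) else index_tree(tree)
    target = set(clade_leaves)
    below: list[set[str]] = [set() for _ in range(itree.n_nodes)]
    for i in itree.postorder:
        if itree.is_leaf[i]:
            below[i] = {itree.labels[i]}
        else:
            for c in np.nonzero(itree.parent == i)[0]:
                below[i] |= below[c]
    for i in range(1, itree.n_nodes):
        if below[i] == target:
            return itree.labels[i]
    raise ValueError(f"no branch subtends exactly {sorted(target)}")


def penalty_sweep(
    tree,
    matrix: pd.DataFrame,
    focal_branch: str | Iterable[str],
    gain_costs: Sequence[float] = (2, 3, 4, 5),
    loss_cost: float = 1.0,
    root_state: int | None = None,
) -> pd.DataFrame:
    """Clusters gained on a focal branch as the gain penalty increases.

    ``focal_branch`` is either a branch label (child-node label) or a leaf
    set whose MRCA branch is the focus.  Returns one row per gain cost.
    """
    itree = tree if isinstance(tree, IndexedTree) else index_tree(tree)
    if isinstance(focal_branch, str):
        label = focal_branch
    else:
        label = find_branch(itree, focal_branch)
    if label not in itree.labels[1:]:
        raise ValueError(f"no branch labelled {label!r}")
    rows = []
    for g in gain_costs:
        rec = sankoff_reconstruct(itree, matrix, gain_cost=g, loss_cost=loss_cost,
                                  root_state=root_state)
        rows.append((float(g), int(rec.gains.loc[label]), int(rec.losses.loc[label])))
    return pd.DataFrame(rows, columns=["gain_cost", "gained", "lost"])


# ---------------------------------------------------------------------------
# fallback clusterer

def cluster_genes_single_linkage(
    seqs: dict[str, dict[str, str]], min_identity: float = 0.7
) -> pd.DataFrame:
    """Single-linkage ortholog clustering on pairwise global identity.

    ``seqs`` maps taxon -> gene id -> sequence.  Edges join gene pairs whose
    global alignment identity is >= ``min_identity``; connected components
    become clusters.  Output matches the (taxon, gene, cluster) membership
    table format, so it can stand in when an external clustering is absent.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                    mismatch_score=-1, open_gap_score=-2,
                                    extend_gap_score=-0.5)
    items = [(t, g, s) for t, genes in seqs.items() for g, s in genes.items()]
    n = len(items)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(items[i][2], items[j][2])[0]
            c = aln.counts()
            cols = c.identities + c.mismatches + c.gaps
            if cols and c.identities / cols >= min_identity:
                parent[find(i)] = find(j)

    roots: dict[int, int] = {}
    rows = []
    for i, (t, g, _) in enumerate(items):
        r = find(i)
        cid = roots.setdefault(r, len(roots))
        rows.append((t, g, f"cl{cid:04d}"))
    return pd.DataFrame(rows, columns=["taxon", "gene", "cluster"])
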