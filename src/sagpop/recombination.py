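"""Recombination-to-mutation ratio (r/m) from a multi-taxon alignment.

The estimator mirrors the role a Bayesian clonal-frame analysis plays in
comparative studies, as a deterministic EM point-estimator of the same
generative quantities: along each branch of a fixed clonal genealogy,
substitutions arise either from clonal point mutation (rate l_b per site) or
inside horizontally imported tracts (initiation rate R per site per unit
branch length, mean tract length delta, donor divergence nu).  Substitutions
are first placed on branches by column-wise Fitch parsimony; a per-branch
two-state hidden Markov model over alignment columns then separates clonal
from imported substitutions, with R, delta and nu shared across branches.

r/m is reported as the ratio of posterior-expected substitution counts in
the import versus clonal states (robust under model misfit); the plug-in
R * delta * nu is reported alongside.  This is deliberately not a
re-implementation of any particular Bayesian tool — multiple jittered EM
restarts stand in for multiple MCMC chains.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._hmm import forward_backward
from ._rng import stream
from .alignment import Alignment
from .simulate import SimTruth
from .trees import IndexedTree, index_tree

__all__ = [
    "RecombinationModel",
    "ImportAnnotation",
    "SaturationError",
    "infer_clonal_tree",
    "assign_substitutions",
    "fit_import_hmm",
    "estimate_r_over_m",
    "realized_rm_oracle",
]


class SaturationError(ValueError):
    pass


@dataclass
class RecombinationModel:
    """Fitted import-model parameters and the derived r/m."""

    branch_lengths: pd.Series  # expected clonal substitutions/site per branch
    R: float  # import initiations / site / unit clonal branch length
    delta: float  # mean tract length (columns)
    nu: float  # substitution probability inside an import
    r_over_m: float  # posterior-expected imported / clonal substitutions
    r_over_m_plugin: float  # R * delta * nu
    loglik: float
    n_restarts: int
    converged: bool
    n_iter: int
    loglik_history: list[float] = field(default_factory=list)


@dataclass
class ImportAnnotation:
    """Per-branch import-state posteriors and called tracts."""

    branches: list[str]
    posterior: np.ndarray  # (n_branches, n_columns)
    tracts: pd.DataFrame  # branch, start, end, mean_posterior (posterior >= 0.5)


# ---------------------------------------------------------------------------
# clonal tree from distances

def _jc_distance_matrix(aln: Alignment) -> np.ndarray:
    mat = aln.matrix
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (mat[i] <= 3) & (mat[j] <= 3)
            nb = int(both.sum())
            if nb == 0:
                raise SaturationError(f"no comparable sites between {aln.taxa[i]} and {aln.taxa[j]}")
            p = float((mat[i, both] != mat[j, both]).sum()) / nb
            if p >= 0.75:
                raise SaturationError(
                    f"saturated distance (p={p:.3f}) between {aln.taxa[i]} and {aln.taxa[j]}"
                )
            d[i, j] = d[j, i] = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    return d


def infer_clonal_tree(aln: Alignment) -> dendropy.Tree:
    """Neighbor-joining on JC-corrected distances, midpoint-rooted.

    Negative NJ branch lengths are clamped to zero.  Raises
    :class:`SaturationError` when a pairwise p-distance reaches 3/4.
    """
    if aln.n_taxa < 3:
        raise ValueError("need >= 3 taxa to infer a tree")
    d = _jc_distance_matrix(aln)
    buf = io.StringIO()
    buf.write("," + ",".join(aln.taxa) + "\n")
    for i, t in enumerate(aln.taxa):
        buf.write(t + "," + ",".join(f"{x:.10f}" for x in d[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    if max(leaf.distance_from_root() for leaf in tree.leaf_node_iter()) > 0:
        tree.reroot_at_midpoint(update_bipartitions=True)
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# observation layer: parsimony substitution tracks

def assign_substitutions(
    aln: Alignment, tree: dendropy.Tree | IndexedTree, multi_hit: str = "mask"
) -> tuple[np.ndarray, list[str]]:
    """Column-wise Fitch parsimony, each state change assigned to a branch.

    Returns an int8 array (branches x columns): 1 = substitution assigned to
    that branch, 0 = none, -1 = column has a gap/N in some taxon (missing
    for every branch).  Ambiguous placements resolve rootward: the top-down
    pass keeps the parent state whenever it is in the child's Fitch set and
    otherwise changes immediately on that branch.

    Columns that require more than one change (infinite-sites violations)
    are masked as missing on every branch by default (``multi_hit="mask"``):
    their per-branch placement is unreliable, and keeping them scatters
    events of dense import tracts onto the wrong branches, which inflates
    the clonal background.  Pass ``multi_hit="keep"`` to retain them.
    """
    if multi_hit not in ("mask", "keep"):
        raise ValueError("multi_hit must be 'mask' or 'keep'")
    itree = tree if isinstance(tree, IndexedTree) else index_tree(tree)
    leaf_set = set(itree.leaf_labels)
    if leaf_set != set(aln.taxa):
        raise ValueError("tree leaves and alignment taxa differ")
    L = len(aln)
    n_nodes = itree.n_nodes

    missing = (aln.matrix > 3).any(axis=0)

    sets = np.zeros((n_nodes, L), dtype=np.uint8)
    for i in range(n_nodes):
        if itree.is_leaf[i]:
            codes = aln.row(itree.labels[i]).astype(np.int16)
            codes = np.clip(codes, 0, 3)
            sets[i] = (1 << codes).astype(np.uint8)
    for i in itree.postorder:
        if not itree.is_leaf[i]:
            kids = np.nonzero(itree.parent == i)[0]
            inter = np.full(L, 0xFF, dtype=np.uint8)
            union = np.zeros(L, dtype=np.uint8)
            for c in kids:
                inter &= sets[c]
                union |= sets[c]
            sets[i] = np.where(inter != 0, inter, union)

    def low_bit(x: np.ndarray) -> np.ndarray:
        xi = x.astype(np.int16)
        return (xi & (-xi)).astype(np.uint8)

    states = np.zeros((n_nodes, L), dtype=np.uint8)
    states[0] = low_bit(sets[0])
    tracks = np.zeros((n_nodes - 1, L), dtype=np.int8)
    for i in range(1, n_nodes):
        ps = states[itree.parent[i]]
        keep = (sets[i] & ps) != 0
        states[i] = np.where(keep, ps, low_bit(sets[i]))
        tracks[i - 1] = (~keep).astype(np.int8)
    if multi_hit == "mask":
        missing = missing | ((tracks == 1).sum(axis=0) >= 2)
    tracks[:, missing] = -1
    labels = itree.labels[1:]
    return tracks, labels


# ---------------------------------------------------------------------------
# EM fit

def _clamp(x: float, lo: float, hi: float) -> float:
    return min(max(x, lo), hi)


def fit_import_hmm(
    tracks: np.ndarray,
    branch_labels: list[str] | None = None,
    init: dict | None = None,
    n_restarts: int = 3,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> tuple[RecombinationModel, ImportAnnotation]:
    """Baum–Welch fit of the per-branch import HMM with shared R, delta, nu.

    ``tracks`` is the (branches x columns) output of
    :func:`assign_substitutions`.  Each restart jitters the initialization
    by +/-50%; the best log-likelihood wins.  Non-convergence within
    ``max_iter`` returns the best fit so far with ``converged=False``.
    """
    tracks = np.asarray(tracks, dtype=np.int8)
    B, L = tracks.shape
    if branch_labels is None:
        branch_labels = [f"b{i}" for i in range(B)]
    observed = tracks >= 0
    n_events = int((tracks == 1).sum())
    n_obs = int(observed.sum())
    if n_obs == 0:
        raise ValueError("no observed columns on any branch")
    if n_events == 0:
        warnings.warn("all-zero substitution tracks; degenerate clonal fit", stacklevel=2)
        zero = pd.Series(np.zeros(B), index=branch_labels)
        model = RecombinationModel(
            branch_lengths=zero, R=0.0, delta=500.0, nu=0.0, r_over_m=0.0,
            r_over_m_plugin=0.0, loglik=0.0, n_restarts=n_restarts,
            converged=True, n_iter=0,
        )
        ann = ImportAnnotation(branches=list(branch_labels),
                               posterior=np.zeros((B, L)),
                               tracts=pd.DataFrame(columns=["branch", "start", "end", "mean_posterior"]))
        return model, ann

    mean_rate = n_events / n_obs
    base = dict(nu0=min(10.0 * mean_rate, 0.5), delta0=500.0, R0=1e-4)
    if init:
        base.update(init)
    rng = stream(seed, "hmm-restarts")

    best = None
    for r in range(max_restarts := max(1, n_restarts)):
        if r == 0:
            nu, delta, R = base["nu0"], base["delta0"], base["R0"]
        else:
            jit = lambda v: v * (0.5 + rng.random())  # noqa: E731
            nu, delta, R = jit(base["nu0"]), jit(base["delta0"]), jit(base["R0"])
        p = np.array([
            _clamp((tracks[b] == 1).sum() / max(observed[b].sum(), 1), 1e-8, 0.5)
            for b in range(B)
        ])
        nu = _clamp(nu, 1e-6, 0.95)
        delta = _clamp(delta, 2.0, 1e7)

        history: list[float] = []
        converged = False
        post = np.zeros((B, L))
        n_iter = 0
        for it in range(max_iter):
            n_iter = it + 1
            lb = -np.log1p(-p)
            a = np.clip(1.0 - np.exp(-R * lb), 1e-12, 0.5)
            bb = 1.0 / delta
            ll = 0.0
            agg = np.zeros(8)
            per_branch_ev0 = np.zeros(B)
            per_branch_occ0 = np.zeros(B)
            lb_occ = 0.0
            xi01 = 0.0
            for bidx in range(B):
                llb, post_b, st = forward_backward(tracks[bidx], p[bidx], nu,
                                                   float(a[bidx]), bb)
                ll += llb
                post[bidx] = post_b
                agg += st
                per_branch_ev0[bidx] = st[4]
                per_branch_occ0[bidx] = st[6]
                lb_occ += lb[bidx] * st[2]
                xi01 += st[0]
            history.append(ll)
            if len(history) > 1 and abs(history[-1] - history[-2]) < tol:
                converged = True
                break
            # M-step
            p = np.array([
                _clamp(per_branch_ev0[b] / max(per_branch_occ0[b], 1e-12), 1e-8, 0.5)
                for b in range(B)
            ])
            nu = _clamp(agg[5] / max(agg[7], 1e-12), 1e-6, 0.95)
            delta = _clamp(max(agg[3], 1e-12) / max(agg[1], 1e-12), 2.0, 1e7)
            R = max(xi01 / max(lb_occ, 1e-12), 0.0)

        ev_import = float((post * (tracks == 1)).sum())
        ev_clonal = float(((1.0 - post) * (tracks == 1)).sum())
        rm = ev_import / ev_clonal if ev_clonal > 0 else float("inf")
        fit = dict(p=p, nu=nu, delta=delta, R=R, ll=history[-1], history=history,
                   converged=converged, n_iter=n_iter, post=post.copy(), rm=rm)
        if best is None or fit["ll"] > best["ll"]:
            best = fit

    lb = -np.log1p(-best["p"])
    model = RecombinationModel(
        branch_lengths=pd.Series(lb, index=branch_labels),
        R=float(best["R"]), delta=float(best["delta"]), nu=float(best["nu"]),
        r_over_m=float(best["rm"]),
        r_over_m_plugin=float(best["R"] * best["delta"] * best["nu"]),
        loglik=float(best["ll"]), n_restarts=max_restarts,
        converged=bool(best["converged"]), n_iter=int(best["n_iter"]),
        loglik_history=[float(x) for x in best["history"]],
    )
    ann = _annotate(best["post"], list(branch_labels))
    return model, ann


def _annotate(post: np.ndarray, branches: list[str]) -> ImportAnnotation:
    rows = []
    for b, label in enumerate(branches):
        called = post[b] >= 0.5
        if not called.any():
            continue
        idx = np.nonzero(called)[0]
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        for run in np.split(idx, breaks + 1):
            rows.append((label, int(run[0]), int(run[-1]) + 1,
                         float(post[b, run].mean())))
    tracts = pd.DataFrame(rows, columns=["branch", "start", "end", "mean_posterior"])
    return ImportAnnotation(branches=branches, posterior=post, tracts=tracts)


def estimate_r_over_m(
    aln: Alignment, tree: dendropy.Tree | None = None, **fit_kwargs
) -> tuple[RecombinationModel, ImportAnnotation, dendropy.Tree]:
    """Alignment -> (clonal tree if absent) -> tracks -> fitted import model."""
    if tree is None:
        tree = infer_clonal_tree(aln)
    tracks, labels = assign_substitutions(aln, tree)
    model, ann = fit_import_hmm(tracks, branch_labels=labels, **fit_kwargs)
    return model, ann, tree


# ---------------------------------------------------------------------------
# ground truth accounting

def realized_rm_oracle(truth: SimTruth) -> float:
    """True imported / clonal substitution counts from simulator truth."""
    m = truth.n_clonal_substitutions
    if m == 0:
        raise ZeroDivisionError("no clonal substitutions; realized r/m undefined")
    return truth.n_import_substitutions / m
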