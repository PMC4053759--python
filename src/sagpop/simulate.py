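"""Synthetic single-amplified-genome (SAG) population data with full truth.

The generator emulates the inputs of a comparative population-genomics study
of partial single-cell genomes: a clonal genealogy relates the sampled cells;
point substitutions accumulate along branches (Jukes–Cantor); homologous
recombination overlays divergent import tracts; gene content drifts by gains
and losses; multiple-displacement amplification drops most of each genome in
contiguous blocks; and a lake metagenome is a read cloud over the community.

Every stochastic event is recorded in :class:`SimTruth`, so each downstream
estimator (gene-flux parsimony, dS, the import HMM, recruitment) can be
scored against ground truth.

Conventions: coordinates are 0-based half-open; one integer seed drives all
stages through named substreams (see :mod:`sagpop._rng`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import msprime
import numpy as np
import pandas as pd

from ._rng import stream, substream_seed
from .alignment import Alignment, encode
from .trees import IndexedTree, index_tree, label_nodes

__all__ = [
    "SimConfig",
    "SimTruth",
    "SagTruth",
    "simulate_genealogy",
    "simulate_clonal_sequences",
    "overlay_imports",
    "simulate_gene_flux",
    "degrade_to_sag",
    "simulate_metagenome",
]


@dataclass
class SimConfig:
    """Generator parameters.

    Defaults describe the freshwater-like study conditions: nine partial
    genomes, a 25 kb core alignment, clonal divergence that puts
    within-microcluster SNP rates in the low-percent range, and a
    recombination-to-mutation ratio well below one (r/m = R*delta*nu/mu).
    """

    n_taxa: int = 9
    genome_len: int = 25_000
    n_genes: int = 25
    gene_len: int = 900  # multiple of 3
    mu: float = 0.008  # expected clonal substitutions / site / unit branch length
    R: float = 2.8e-5  # import initiations / site / unit branch length
    delta: float = 1000.0  # mean import tract length (bp)
    nu: float = 0.04  # per-site substitution probability inside a tract
    gain_rate: float = 0.3  # gene gains / unit branch length
    loss_rate: float = 0.3
    recovery_mean: float = 0.6  # fraction of genome retained per SAG
    recovery_sd: float = 0.15
    err_rate: float = 5e-6  # per-base sequencing/assembly error probability
    read_len: int = 400
    n_reads: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu", "R", "gain_rate", "loss_rate", "err_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.nu <= 1.0:
            raise ValueError("nu must be in [0, 1]")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if not 0.0 < self.recovery_mean <= 1.0:
            raise ValueError("recovery_mean must be in (0, 1]")
        if self.recovery_sd < 0:
            raise ValueError("recovery_sd must be >= 0")
        if self.gene_len % 3 != 0:
            raise ValueError("gene_len must be a multiple of 3")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.genome_len < 1 or self.n_genes < 0 or self.read_len < 1 or self.n_reads < 0:
            raise ValueError("sizes must be positive")

    @property
    def expected_r_over_m(self) -> float:
        """The generative r/m: imported vs clonal substitutions per site."""
        if self.mu == 0:
            return float("nan")
        return self.R * self.delta * self.nu / self.mu

    @classmethod
    def rm_regime(cls, r_over_m: float, seed: int = 0, **overrides) -> "SimConfig":
        """Study-conditions preset for the r/m contrast experiments.

        Tracts are 1 kb at 10% donor divergence; the clonal rate scales
        down with the target ratio (mu ~ 0.009/(1+r/m), clipped to
        [0.001, 0.008]) so that total substitution density stays moderate.
        This mirrors the empirical contrast: in the high-recombination
        (marine-like) regime imports, not clonal mutation, supply nearly
        all substitutions, and clonal diversity is lower than in the
        clonal (freshwater-like) regime.
        """
        params = dict(n_taxa=9, genome_len=25_000, delta=1000.0, nu=0.10,
                      seed=seed)
        params.setdefault("mu", min(0.008, max(0.001, 0.009 / (1.0 + r_over_m))))
        params.update(overrides)
        params["R"] = r_over_m * params["mu"] / (params["delta"] * params["nu"])
        return cls(**params)


@dataclass
class SagTruth:
    """Ground truth of one degraded assembly."""

    retained: list[tuple[int, int]]  # genome-coordinate half-open intervals
    errors: list[tuple[int, int]]  # (genome position, new base code)
    recovery: float  # realized retained fraction


@dataclass
class SimTruth:
    """Ground truth accumulated across generator stages."""

    tree: IndexedTree | None = None
    root_seq: np.ndarray | None = None
    # branch label -> (positions, new base codes), in application order
    clonal_events: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    # branch label -> list of (start, end, substituted positions)
    import_tracts: dict[str, list[tuple[int, int, np.ndarray]]] = field(default_factory=dict)
    node_gene_sets: dict[str, set[str]] = field(default_factory=dict)
    sags: dict[str, SagTruth] = field(default_factory=dict)
    reads: pd.DataFrame | None = None  # read id, taxon, start, end, strand

    @property
    def n_clonal_substitutions(self) -> int:
        return sum(len(p) for p, _ in self.clonal_events.values())

    @property
    def n_import_substitutions(self) -> int:
        return sum(len(s) for tr in self.import_tracts.values() for _, _, s in tr)

    @property
    def realized_r_over_m(self) -> float:
        """Imported / clonal substitution events; NaN if no clonal events."""
        m = self.n_clonal_substitutions
        if m == 0:
            return float("nan")
        return self.n_import_substitutions / m


# ---------------------------------------------------------------------------
# genealogy

def simulate_genealogy(n_taxa: int, seed: int = 0) -> dendropy.Tree:
    """A Kingman-coalescent genealogy, rescaled to mean root-to-tip length 1.

    Delegates the coalescent itself to msprime (haploid samples, population
    size 1, so k lineages coalesce at rate k(k-1)/2).  The true genealogy of
    the study organisms is unknown; the coalescent is a neutral stand-in.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    ts = msprime.sim_ancestry(
        samples=n_taxa, ploidy=1, population_size=1.0,
        random_seed=substream_seed(seed, "genealogy"),
    )
    nwk = ts.first().as_newick()
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    tree.is_rooted = True
    # msprime labels samples n0..n{k-1}; relabel to t1..tk
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = "t" + str(int(leaf.taxon.label[1:]) + 1)
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    scale = float(np.mean(depths))
    if scale > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length / scale
    # pre-rescaling TMRCA in coalescent units (the tree is ultrametric)
    tree.tmrca = scale
    return label_nodes(tree)


# ---------------------------------------------------------------------------
# sequences

def _apply_substitutions(seq: np.ndarray, pos: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Substitute seq[pos] to one of the 3 alternatives chosen by shift (1..3)."""
    new = (seq[pos] + shift) % 4
    seq[pos] = new
    return new


def simulate_clonal_sequences(
    tree: dendropy.Tree | IndexedTree, cfg: SimConfig, seed: int | None = None
) -> tuple[Alignment, SimTruth]:
    """Evolve a uniform-random root sequence along the genealogy.

    On a branch of length ``l`` the substitution count is
    Poisson(mu * l * genome_len); positions are uniform (multiple hits
    allowed, each a separate recorded event); the new base is uniform over
    the three alternatives (Jukes–Cantor).
    """
    itree = tree if isinstance(tree, IndexedTree) else index_tree(tree)
    rng = stream(cfg.seed if seed is None else seed, "clonal")
    L = cfg.genome_len
    truth = SimTruth(tree=itree)
    truth.root_seq = rng.integers(0, 4, size=L, dtype=np.uint8)

    node_seq: dict[int, np.ndarray] = {0: truth.root_seq.copy()}
    leaves: dict[str, np.ndarray] = {}
    for i in range(itree.n_nodes):  # preorder
        if i == 0:
            seq = node_seq[0]
        else:
            seq = node_seq[itree.parent[i]].copy()
            n_sub = rng.poisson(cfg.mu * itree.length[i] * L)
            pos = rng.integers(0, L, size=n_sub)
            shift = rng.integers(1, 4, size=n_sub).astype(np.uint8)
            new = _apply_substitutions(seq, pos, shift)
            truth.clonal_events[itree.labels[i]] = (pos, new)
            node_seq[i] = seq
        if itree.is_leaf[i]:
            leaves[itree.labels[i]] = seq
    order = itree.leaf_labels
    aln = Alignment(order, np.vstack([leaves[t] for t in order]))
    return aln, truth


def overlay_imports(
    alignment: Alignment,
    tree: dendropy.Tree | IndexedTree,
    cfg: SimConfig,
    truth: SimTruth,
    seed: int | None = None,
) -> tuple[Alignment, SimTruth]:
    """Overlay recombination import tracts on an existing clonal realization.

    Replays the recorded clonal events from the root, then, per branch, draws
    Poisson(R * l * genome_len) tract initiations with uniform starts and
    geometric lengths of mean ``delta`` (truncated at the sequence end, no
    wraparound).  Each tract site is substituted with probability ``nu`` to a
    uniform alternative base, mimicking a divergent donor.  Clonal events are
    applied before imports on each branch (documented convention).
    """
    itree = tree if isinstance(tree, IndexedTree) else index_tree(tree)
    if truth.root_seq is None:
        raise ValueError("truth lacks a clonal realization; run simulate_clonal_sequences first")
    rng = stream(cfg.seed if seed is None else seed, "imports")
    L = cfg.genome_len
    truth.import_tracts = {}

    node_seq: dict[int, np.ndarray] = {0: truth.root_seq.copy()}
    leaves: dict[str, np.ndarray] = {}
    for i in range(itree.n_nodes):
        if i == 0:
            seq = node_seq[0]
        else:
            seq = node_seq[itree.parent[i]].copy()
            label = itree.labels[i]
            pos, new = truth.clonal_events.get(label, (np.empty(0, int), np.empty(0, np.uint8)))
            seq[pos] = new
            tracts: list[tuple[int, int, np.ndarray]] = []
            n_tracts = rng.poisson(cfg.R * itree.length[i] * L)
            for _ in range(n_tracts):
                start = int(rng.integers(0, L))
                tlen = int(rng.geometric(1.0 / cfg.delta))
                end = min(start + tlen, L)
                hit = np.nonzero(rng.random(end - start) < cfg.nu)[0] + start
                shift = rng.integers(1, 4, size=hit.size).astype(np.uint8)
                _apply_substitutions(seq, hit, shift)
                tracts.append((start, end, hit))
            truth.import_tracts[label] = tracts
            node_seq[i] = seq
        if itree.is_leaf[i]:
            leaves[itree.labels[i]] = seq
    order = itree.leaf_labels
    aln = Alignment(order, np.vstack([leaves[t] for t in order]))
    return aln, truth


# ---------------------------------------------------------------------------
# gene content

def simulate_gene_flux(
    tree: dendropy.Tree | IndexedTree, cfg: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Evolve binary gene presence along the genealogy.

    Root presence is Bernoulli(0.8) per cluster; along a branch of length
    ``l`` an absent cluster is gained with probability 1-exp(-gain_rate*l)
    and a present one lost with probability 1-exp(-loss_rate*l).  Returns the
    leaf occurrence matrix (taxa x clusters, 0/1) and per-node presence sets.
    """
    itree = tree if isinstance(tree, IndexedTree) else index_tree(tree)
    rng = stream(cfg.seed if seed is None else seed, "geneflux")
    clusters = [f"c{j:04d}" for j in range(cfg.n_genes)]
    state = np.zeros((itree.n_nodes, cfg.n_genes), dtype=np.int8)
    state[0] = (rng.random(cfg.n_genes) < 0.8).astype(np.int8)
    for i in range(1, itree.n_nodes):
        p_gain = 1.0 - np.exp(-cfg.gain_rate * itree.length[i])
        p_loss = 1.0 - np.exp(-cfg.loss_rate * itree.length[i])
        parent = state[itree.parent[i]]
        u = rng.random(cfg.n_genes)
        gained = (parent == 0) & (u < p_gain)
        lost = (parent == 1) & (u < p_loss)
        state[i] = parent.copy()
        state[i, gained] = 1
        state[i, lost] = 0
    node_sets = {
        itree.labels[i]: {clusters[j] for j in np.nonzero(state[i])[0]}
        for i in range(itree.n_nodes)
    }
    leaf_idx = np.nonzero(itree.is_leaf)[0]
    matrix = pd.DataFrame(
        state[leaf_idx], index=[itree.labels[i] for i in leaf_idx], columns=clusters
    ).astype(int)
    return matrix, node_sets


# ---------------------------------------------------------------------------
# amplification dropout

def degrade_to_sag(
    genome: str | np.ndarray, cfg: SimConfig, seed: int | None = None,
    name: str = "sag",
) -> tuple[dict[str, str], SagTruth]:
    """Reduce a genome to a partial assembly the way MDA dropout does.

    Keeps k ~ Uniform[5, 100] contiguous blocks whose total length is a
    Normal(recovery_mean, recovery_sd) fraction of the genome (clipped to
    (0, 1]; non-positive draws are resampled with bounded retries), then
    injects per-base errors at ``err_rate``.  Returns scaffold sequences and
    the retained-interval / error truth.
    """
    from .alignment import decode

    arr = encode(genome) if isinstance(genome, str) else np.asarray(genome, dtype=np.uint8)
    L = arr.size
    rng = stream(cfg.seed if seed is None else seed, f"sag:{name}")

    frac = 0.0
    for _ in range(100):
        frac = rng.normal(cfg.recovery_mean, cfg.recovery_sd)
        if 0.0 < frac:
            break
    else:
        raise ValueError("recovery fraction never positive; check recovery_mean/sd")
    frac = min(frac, 1.0)
    retained_len = max(1, int(round(frac * L)))

    if retained_len >= L:
        blocks = [(0, L)]
    else:
        k = int(rng.integers(5, 101))
        k = max(1, min(k, retained_len))
        # split retained length into k blocks (each >= 1) and the rest into k+1 gaps
        lens = 1 + rng.multinomial(retained_len - k, np.ones(k) / k)
        free = L - int(lens.sum())
        gaps = rng.multinomial(free, np.ones(k + 1) / (k + 1))
        blocks = []
        cursor = 0
        for bi in range(k):
            cursor += int(gaps[bi])
            blocks.append((cursor, cursor + int(lens[bi])))
            cursor += int(lens[bi])

    scaffolds: dict[str, str] = {}
    errors: list[tuple[int, int]] = []
    for si, (s, e) in enumerate(blocks):
        piece = arr[s:e].copy()
        n_err = rng.binomial(e - s, cfg.err_rate)
        if n_err:
            pos = rng.choice(e - s, size=n_err, replace=False)
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            new = _apply_substitutions(piece, pos, shift)
            errors.extend((int(s + p), int(b)) for p, b in zip(pos, new))
        scaffolds[f"{name}_scaffold_{si:03d}"] = decode(piece)
    total = sum(e - s for s, e in blocks)
    return scaffolds, SagTruth(retained=blocks, errors=sorted(errors), recovery=total / L)


# ---------------------------------------------------------------------------
# metagenome

def simulate_metagenome(
    genomes: Mapping[str, str],
    abundances: Sequence[float],
    cfg: SimConfig,
    seed: int | None = None,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Draw a read cloud from a weighted community.

    Each read picks a source taxon from ``abundances``, a uniform start, and
    a uniform strand; bases are flipped to a uniform alternative with
    probability ``err_rate``.  Quality strings are constant (Sanger 'I').
    Returns (id, sequence, quality) triples and a truth table.
    """
    from .alignment import decode

    taxa = list(genomes)
    if not taxa:
        raise ValueError("empty genome set")
    ab = np.asarray(abundances, dtype=float)
    if ab.size != len(taxa) or abs(ab.sum() - 1.0) > 1e-8 or (ab < 0).any():
        raise ValueError("abundances must be a simplex over the genomes")
    arrs = {t: encode(genomes[t]) for t in taxa}
    for t, a in arrs.items():
        if cfg.read_len > a.size:
            raise ValueError(f"read_len exceeds genome length of {t}")

    rng = stream(cfg.seed if seed is None else seed, "metagenome")
    comp = np.array([3, 2, 1, 0], dtype=np.uint8)
    which = rng.choice(len(taxa), size=cfg.n_reads, p=ab)
    reads: list[tuple[str, str, str]] = []
    rows = []
    qual = "I" * cfg.read_len
    for ri in range(cfg.n_reads):
        t = taxa[which[ri]]
        g = arrs[t]
        start = int(rng.integers(0, g.size - cfg.read_len + 1))
        piece = g[start:start + cfg.read_len].copy()
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            piece = comp[piece][::-1]
        n_err = rng.binomial(cfg.read_len, cfg.err_rate)
        if n_err:
            pos = rng.choice(cfg.read_len, size=n_err, replace=False)
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            _apply_substitutions(piece, pos, shift)
        rid = f"read_{ri:06d}"
        reads.append((rid, decode(piece), qual))
        rows.append((rid, t, start, start + cfg.read_len, strand))
    truth = pd.DataFrame(rows, columns=["read", "taxon", "start", "end", "strand"])
    return reads, truth
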