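"""End-to-end experiment drivers shared by the pipeline, tests and scripts.

Each function builds its own synthetic inputs under the study conditions,
runs the relevant estimators, and returns plain dicts / DataFrames.  Problem
sizes default to desk scale (a 25 kb core alignment, nine taxa, a handful of
genes) — the regimes, not the data volumes, are what carry over.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import stream, substream_seed
from .alignment import Alignment, decode
from .divergence import (consensus_sequence, count_global_snps,
                         pairwise_ds_table, snp_rate_vs_consensus)
from .geneflux import sankoff_reconstruct
from .recombination import assign_substitutions, fit_import_hmm
from .recruitment import (assign_microcluster, build_patchwork, recruit_reads,
                          summarize_recruitment)
from .simulate import (SimConfig, degrade_to_sag, overlay_imports,
                       simulate_clonal_sequences, simulate_gene_flux,
                       simulate_genealogy, simulate_metagenome)
from .trees import index_tree, three_cluster_tree

__all__ = [
    "rm_regime_experiment",
    "snp_consensus_experiment",
    "error_rate_experiment",
    "microcluster_community",
    "microcluster_assignment_experiment",
    "ds_contrast_experiment",
    "patchwork_experiment",
    "recruitment_coverage_experiment",
    "flux_recovery_experiment",
]


# ---------------------------------------------------------------------------
# r/m regimes

def rm_regime_experiment(
    rm_targets: list[float],
    n_seeds: int = 50,
    base_seed: int = 0,
    n_taxa: int = 9,
    genome_len: int = 25_000,
    n_restarts: int = 3,
) -> pd.DataFrame:
    """Simulate and re-estimate r/m across regimes on the true genealogy.

    One row per (target, replicate): the generative target, the realized
    (truth-accounted) ratio, and the EM estimate with its plug-in variant.
    """
    rows = []
    for rm in rm_targets:
        for i in range(n_seeds):
            seed = substream_seed(base_seed, f"rm:{rm}:{i}")
            cfg = SimConfig.rm_regime(rm, seed=seed, n_taxa=n_taxa,
                                      genome_len=genome_len)
            tree = simulate_genealogy(cfg.n_taxa, seed=seed)
            itree = index_tree(tree)
            aln, truth = simulate_clonal_sequences(itree, cfg)
            aln, truth = overlay_imports(aln, itree, cfg, truth)
            tracks, labels = assign_substitutions(aln, itree)
            model, _ = fit_import_hmm(tracks, branch_labels=labels,
                                      n_restarts=n_restarts, seed=seed)
            rows.append((rm, i, truth.realized_r_over_m, model.r_over_m,
                         model.r_over_m_plugin, model.converged))
    return pd.DataFrame(rows, columns=["rm_true", "replicate", "rm_realized",
                                       "rm_est", "rm_plugin", "converged"])


# ---------------------------------------------------------------------------
# SNPs vs microcluster consensus

def snp_consensus_experiment(
    seed: int = 0,
    genome_len: int = 25_000,
    tip_divergence: float = 0.0145,
    stem_fraction: float = 0.1,
) -> dict:
    """Median SNPs/kb of microcluster members against their consensus.

    A three-member microcluster with per-tip divergence ``tip_divergence``
    (expected substitutions/site between a member and the cluster ancestor)
    mirrors the within-microcluster regime, where member-vs-consensus SNP
    rates sit in the low-teens per kb.
    """
    import dendropy

    a = tip_divergence
    s = stem_fraction * a
    nwk = f"((A:{a},B:{a}):{s},C:{a + s});"
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    tree.is_rooted = True
    cfg = SimConfig(n_taxa=3, genome_len=genome_len, mu=1.0, R=0.0, seed=seed)
    aln, _ = simulate_clonal_sequences(tree, cfg)
    cons = consensus_sequence(aln)
    rates = {t: snp_rate_vs_consensus(aln.sequence(t), cons) for t in aln.taxa}
    return {"rates": rates, "median_snps_per_kb": float(np.median(list(rates.values())))}


# ---------------------------------------------------------------------------
# benchmark error rate

def error_rate_experiment(
    seed: int = 0,
    genome_len: int = 2_500_000,
    recovery_mean: float = 0.8,
    err_rate: float = 5e-6,
    n_sags: int = 1,
) -> dict:
    """Inject assembly errors and recover the rate via global-SNP counting.

    Emulates benchmarking partial assemblies against a conventionally
    sequenced reference: scaffolds are compared to their true source
    intervals, and mismatches with clean 20 bp flanks count as global SNPs.
    ``n_sags`` independent assemblies are pooled, as in a benchmark set of
    several cells from one reference strain.
    """
    rng = stream(seed, "error-genome")
    genome = decode(rng.integers(0, 4, size=genome_len).astype(np.uint8))
    cfg = SimConfig(n_taxa=2, genome_len=genome_len, err_rate=err_rate,
                    recovery_mean=recovery_mean, recovery_sd=0.02, seed=seed)
    tot_global = tot_total = tot_bp = n_injected = 0
    for k in range(n_sags):
        scaffolds, truth = degrade_to_sag(genome, cfg, seed=seed,
                                          name=f"bench{k}")
        n_injected += len(truth.errors)
        for (s, e), (_, piece) in zip(truth.retained, scaffolds.items()):
            stats = count_global_snps(piece, genome[s:e])
            tot_global += stats.global_snps
            tot_total += stats.total_snps
            tot_bp += stats.assembled_bp
    return {
        "n_injected": n_injected,
        "global_snps": tot_global,
        "total_snps": tot_total,
        "assembled_bp": tot_bp,
        "rate_per_bp": tot_global / tot_bp,
        "rate_per_mb": tot_global / (tot_bp / 1e6),
        "true_rate_per_bp": err_rate,
    }


# ---------------------------------------------------------------------------
# microcluster community: divergence, assignment, abundance

def microcluster_community(
    seed: int = 0,
    n_per_cluster: int = 3,
    within: float = 0.03,
    between: float = 0.5,
    n_genes: int = 10,
    gene_len: int = 900,
):
    """Simulate a three-microcluster population (A, B, C) gene by gene."""
    genome_len = n_genes * gene_len
    tree = three_cluster_tree(n_per_cluster, within=within, between=between)
    cfg = SimConfig(n_taxa=3 * n_per_cluster, genome_len=genome_len, mu=1.0,
                    R=0.0, n_genes=n_genes, gene_len=gene_len, seed=seed)
    aln, truth = simulate_clonal_sequences(tree, cfg)
    genes = pd.DataFrame({
        "gene": [f"g{j:03d}" for j in range(n_genes)],
        "start": [j * gene_len for j in range(n_genes)],
        "end": [(j + 1) * gene_len for j in range(n_genes)],
        "strand": "+",
    })
    return tree, cfg, aln, genes, truth


def _cluster_consensuses(aln: Alignment, genes: pd.DataFrame) -> dict[str, dict[str, str]]:
    """Per-gene consensus per microcluster (taxa grouped by name prefix)."""
    groups: dict[str, list[str]] = {}
    for t in aln.taxa:
        groups.setdefault(t[0], []).append(t)
    out: dict[str, dict[str, str]] = {}
    for _, g in genes.iterrows():
        per_gene = {}
        for label, members in sorted(groups.items()):
            seqs = [aln.sequence(m)[g["start"]:g["end"]] for m in members]
            per_gene[label] = consensus_sequence(seqs)
        out[g["gene"]] = per_gene
    return out


def microcluster_assignment_experiment(
    seed: int = 0,
    n_reads: int = 400,
    read_len: int = 300,
    abundances_by_cluster: tuple[float, float, float] = (0.2, 0.1, 0.7),
    margin: float = 0.02,
    min_overlap: int = 150,
) -> dict:
    """Assignment accuracy of read slices to microclusters by consensus identity.

    Reads are drawn from a three-cluster community, cut to gene boundaries
    (truth coordinates; the slices are what recruitment would deliver), and
    labelled by nearest per-gene cluster consensus with an identity margin.
    """
    tree, cfg, aln, genes, _ = microcluster_community(seed=seed)
    members = aln.taxa
    per_member = []
    for t in members:
        per_member.append(abundances_by_cluster["ABC".index(t[0])])
    ab = np.array(per_member)
    ab = ab / ab.sum()
    rcfg = SimConfig(n_taxa=cfg.n_taxa, genome_len=cfg.genome_len,
                     read_len=read_len, n_reads=n_reads, err_rate=0.002,
                     seed=seed)
    genomes = aln.to_dict()
    reads, rtruth = simulate_metagenome(genomes, ab, rcfg, seed=seed)
    consensuses = _cluster_consensuses(aln, genes)

    read_seqs = dict((rid, s) for rid, s, _ in reads)
    rows = []
    from .recruitment import revcomp

    for _, rt in rtruth.iterrows():
        seq = read_seqs[rt["read"]]
        oriented = revcomp(seq) if rt["strand"] == "-" else seq
        for _, g in genes.iterrows():
            lo = max(rt["start"], g["start"])
            hi = min(rt["end"], g["end"])
            if hi - lo < min_overlap:
                continue
            s = oriented[lo - rt["start"]: hi - rt["start"]]
            label, _ids = assign_microcluster(s, consensuses[g["gene"]], margin=margin)
            rows.append((rt["read"], rt["taxon"][0], g["gene"], label))
    df = pd.DataFrame(rows, columns=["read", "true_cluster", "gene", "label"])
    assigned = df[df["label"] != "unassigned"]
    accuracy = float((assigned["label"] == assigned["true_cluster"]).mean()) \
        if len(assigned) else float("nan")
    unassigned = float((df["label"] == "unassigned").mean())
    frac = (assigned.groupby("label").size() / max(len(assigned), 1)).to_dict()
    truth_frac = (df.groupby("true_cluster").size() / len(df)).to_dict()
    return {
        "assignments": df,
        "accuracy": accuracy,
        "unassigned_fraction": unassigned,
        "recovered_fractions": frac,
        "true_fractions": truth_frac,
        "n_slices": len(df),
    }


def ds_contrast_experiment(seed: int = 0) -> dict:
    """Per-pair median dS inside vs between microclusters."""
    tree, cfg, aln, genes, _ = microcluster_community(seed=seed)
    gene_alns = {
        g["gene"]: Alignment(aln.taxa, aln.matrix[:, g["start"]:g["end"]])
        for _, g in genes.iterrows()
    }
    table, medians = pairwise_ds_table(gene_alns)
    within, between = [], []
    for (a, b), v in medians.items():
        (within if a[0] == b[0] else between).append(v)
    return {
        "table": table,
        "medians": medians,
        "within_median": float(np.median(within)),
        "between_median": float(np.median(between)),
        "max_within": float(np.max(within)),
        "min_between": float(np.min(between)),
    }


# ---------------------------------------------------------------------------
# patchwork and recruitment

def patchwork_experiment(seed: int = 0, genome_len: int = 120_000) -> dict:
    """Cut a genome into overlapping scaffolds across taxa and rebuild it."""
    rng = stream(seed, "patchwork-genome")
    template = rng.integers(0, 4, size=genome_len).astype(np.uint8)

    def variant() -> np.ndarray:
        g = template.copy()
        n = rng.poisson(0.005 * genome_len)  # 0.5% divergence between cells
        pos = rng.integers(0, genome_len, size=n)
        g[pos] = (g[pos] + rng.integers(1, 4, size=n)) % 4
        return g

    taxa = {"t1": variant(), "t2": variant(), "t3": variant()}
    cuts = {
        "t1": [(0, 40_000), (90_000, genome_len)],
        "t2": [(28_000, 70_000)],
        "t3": [(58_000, 102_000)],
    }
    scaffolds = {
        t: {f"{t}_s{i}": decode(taxa[t][s:e]) for i, (s, e) in enumerate(iv)}
        for t, iv in cuts.items()
    }
    true_start = {f"{t}_s{i}": s for t, iv in cuts.items() for i, (s, e) in enumerate(iv)}
    ref = build_patchwork(scaffolds, ["t1", "t2", "t3"], min_overlap=10_000)
    prov = ref.provenance_table().sort_values("ref_start")
    starts = [true_start[s] + ss for s, ss in zip(prov["scaffold"], prov["src_start"])]
    order_ok = bool(all(np.diff(starts) > 0))
    return {
        "reference": ref,
        "provenance": prov,
        "length_ok": ref.length == genome_len,
        "order_recovered": order_ok and ref.length == genome_len,
        "length": ref.length,
    }


def recruitment_coverage_experiment(
    seed: int = 0,
    genome_len: int = 50_000,
    n_reads: int = 1500,
    read_len: int = 300,
    err_rate: float = 0.005,
) -> dict:
    """One-taxon community: recruited fold coverage should match the truth.

    True fold coverage is n_reads * read_len / genome_len; the recruitment
    summary recomputes it from recruited counts and dataset size.
    """
    rng = stream(seed, "recruit-genome")
    genome = decode(rng.integers(0, 4, size=genome_len).astype(np.uint8))
    cfg = SimConfig(n_taxa=2, genome_len=genome_len, n_reads=n_reads,
                    read_len=read_len, err_rate=err_rate, seed=seed)
    reads, _ = simulate_metagenome({"g": genome}, [1.0], cfg, seed=seed)
    recruited = recruit_reads(((rid, s) for rid, s, _ in reads), genome)
    total_mb = n_reads * read_len / 1e6
    summary = summarize_recruitment(len(recruited), n_reads, total_mb,
                                    genome_len / 1e6)
    summary["true_fold_coverage"] = n_reads * read_len / genome_len
    summary["recruited_fraction"] = len(recruited) / n_reads
    return summary


# ---------------------------------------------------------------------------
# gene flux recovery

def flux_recovery_experiment(
    n_seeds: int = 50,
    base_seed: int = 0,
    n_taxa: int = 8,
    n_genes: int = 100,
    gain_rate: float = 0.02,
    loss_rate: float = 0.005,
    outgroup_stem: float = 0.4,
    n_outgroups: int = 3,
) -> dict:
    """Fraction of true gain events recovered by Sankoff/ACCTRAN (cost 2/1).

    Several outgroup lineages are grafted above the coalescent ingroup so
    the root state is data-informed, as on an outgroup-rich reference tree.
    With a single outgroup (or none), an ingroup-wide gain is
    indistinguishable from one loss on the complement branch under the
    2-versus-1 cost asymmetry.  Event rates are low enough that most
    clusters see at most one event; losses are rarer than gains so that
    loss-then-regain and convergent-gain histories — which parsimony
    rightly explains with fewer events — stay negligible.  Recovery is
    scored over ingroup branches (the ingroup MRCA's stem and below).
    """
    import dendropy

    found = missed = spurious = 0
    for i in range(n_seeds):
        seed = substream_seed(base_seed, f"flux:{i}")
        tree = simulate_genealogy(n_taxa, seed=seed)
        for j in range(n_outgroups):
            old_root = tree.seed_node
            new_root = dendropy.Node()
            new_root.add_child(old_root)
            old_root.edge.length = (old_root.edge.length or 0.0) + outgroup_stem / 3.0
            og = dendropy.Node(edge_length=outgroup_stem)
            new_root.add_child(og)
            taxon = dendropy.Taxon(f"OG{j + 1}")
            tree.taxon_namespace.add_taxon(taxon)
            og.taxon = taxon
            tree.seed_node = new_root
        itree = index_tree(tree)
        cfg = SimConfig(n_taxa=n_taxa, n_genes=n_genes, gain_rate=gain_rate,
                        loss_rate=loss_rate, seed=seed)
        matrix, node_sets = simulate_gene_flux(itree, cfg)
        rec = sankoff_reconstruct(itree, matrix)
        states = rec.node_states
        # ingroup = subtree whose leaves are exactly the coalescent samples
        ingroup_leaves = {t for t in itree.leaf_labels if not t.startswith("OG")}
        below: list[set] = [set() for _ in range(itree.n_nodes)]
        for bi in itree.postorder:
            if itree.is_leaf[bi]:
                below[bi] = {itree.labels[bi]}
            else:
                for ci in np.nonzero(itree.parent == bi)[0]:
                    below[bi] |= below[ci]
        for bi in range(1, itree.n_nodes):
            if not below[bi] <= ingroup_leaves:
                continue
            child = itree.labels[bi]
            par = itree.labels[itree.parent[bi]]
            for c in matrix.columns:
                true_gain = (c not in node_sets[par]) and (c in node_sets[child])
                est_gain = (states.loc[par, c] == 0) and (states.loc[child, c] == 1)
                if true_gain and est_gain:
                    found += 1
                elif true_gain:
                    missed += 1
                elif est_gain:
                    spurious += 1
    total = found + missed
    return {
        "true_gains": total,
        "recovered": found,
        "recovery_rate": found / total if total else float("nan"),
        "spurious": spurious,
    }
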