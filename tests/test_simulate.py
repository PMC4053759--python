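"""Generator correctness: tree shapes, event-rate calibration, truth bookkeeping."""

from __future__ import annotations

import numpy as np
import pytest

from sagpop.simulate import (SimConfig, degrade_to_sag, overlay_imports,
                             simulate_clonal_sequences, simulate_gene_flux,
                             simulate_genealogy, simulate_metagenome)
from sagpop.trees import index_tree

from conftest import tree_from_newick


class TestGenealogy:
    def test_two_taxa_is_equal_cherry(self):
        tree = simulate_genealogy(2, seed=5)
        it = index_tree(tree)
        tips = it.length[it.is_leaf]
        assert it.n_nodes == 3
        assert tips[0] == pytest.approx(tips[1])

    def test_nine_taxa_binary_counts(self):
        it = index_tree(simulate_genealogy(9, seed=7))
        assert sum(it.is_leaf) == 9
        assert it.n_nodes == 17  # 8 internal + 9 leaves; 16 branches
        assert (np.bincount(it.parent[1:]) <= 2).all()

    def test_rejects_single_taxon(self):
        with pytest.raises(ValueError):
            simulate_genealogy(1, seed=0)

    def test_mean_depth_rescaled_to_one(self):
        tree = simulate_genealogy(12, seed=3)
        depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
        assert np.mean(depths) == pytest.approx(1.0)

    def test_tmrca_matches_coalescent_closed_form(self):
        """Monte-Carlo TMRCA vs the Kingman expectation 2(1 - 1/n)."""
        n = 50
        vals = np.array([simulate_genealogy(n, seed=s).tmrca for s in range(1000)])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 2 * (1 - 1 / n)) < 3 * se


class TestClonalSequences:
    def test_zero_rate_keeps_root_everywhere(self):
        it = tree_from_newick("((A:1,B:1):1,C:2);")
        cfg = SimConfig(n_taxa=3, genome_len=2000, mu=0.0, seed=1)
        aln, truth = simulate_clonal_sequences(it, cfg)
        for t in aln.taxa:
            assert np.array_equal(aln.row(t), truth.root_seq)
        assert truth.n_clonal_substitutions == 0

    def test_pairwise_divergence_matches_jc_expectation(self):
        """Two tips at total path 0.02: mean p-distance matches the
        Jukes-Cantor closed form 3/4 (1 - exp(-4d/3))."""
        it = tree_from_newick("(A:1,B:1);")
        expected = 0.75 * (1 - np.exp(-4 * 0.02 / 3))
        obs = []
        for s in range(200):
            cfg = SimConfig(n_taxa=2, genome_len=100_000, mu=0.01, seed=s)
            aln, _ = simulate_clonal_sequences(it, cfg)
            obs.append((aln.row("A") != aln.row("B")).mean())
        obs = np.array(obs)
        se = obs.std(ddof=1) / np.sqrt(len(obs))
        assert abs(obs.mean() - expected) < 3 * se

    def test_same_seed_bit_identical_different_seed_differs(self):
        it = index_tree(simulate_genealogy(5, seed=2))
        cfg = SimConfig(n_taxa=5, genome_len=5000, seed=9)
        a1, _ = simulate_clonal_sequences(it, cfg)
        a2, _ = simulate_clonal_sequences(it, cfg)
        a3, _ = simulate_clonal_sequences(it, cfg, seed=10)
        assert np.array_equal(a1.matrix, a2.matrix)
        assert not np.array_equal(a1.matrix, a3.matrix)


class TestImports:
    def test_zero_rate_leaves_alignment_unchanged(self):
        it = index_tree(simulate_genealogy(4, seed=1))
        cfg = SimConfig(n_taxa=4, genome_len=5000, R=0.0, seed=4)
        aln, truth = simulate_clonal_sequences(it, cfg)
        before = aln.matrix.copy()
        aln2, truth = overlay_imports(aln, it, cfg, truth)
        assert np.array_equal(aln2.matrix, before)
        assert truth.realized_r_over_m == 0.0

    def test_truth_tracts_within_bounds(self):
        cfg = SimConfig.rm_regime(10, seed=6)
        it = index_tree(simulate_genealogy(cfg.n_taxa, seed=6))
        aln, truth = simulate_clonal_sequences(it, cfg)
        _, truth = overlay_imports(aln, it, cfg, truth)
        for tracts in truth.import_tracts.values():
            for s, e, hit in tracts:
                assert 0 <= s < e <= cfg.genome_len
                assert ((hit >= s) & (hit < e)).all()

    def test_realized_ratio_within_factor_15_of_target(self):
        """9 taxa x 25 kb at target r/m 60: realized within x1.5 in >=90%."""
        ok = 0
        n = 100
        for s in range(n):
            cfg = SimConfig.rm_regime(60, seed=s)
            it = index_tree(simulate_genealogy(cfg.n_taxa, seed=s))
            aln, truth = simulate_clonal_sequences(it, cfg)
            _, truth = overlay_imports(aln, it, cfg, truth)
            r = truth.realized_r_over_m
            if np.isfinite(r) and 60 / 1.5 <= r <= 60 * 1.5:
                ok += 1
        assert ok >= 0.9 * n

    def test_low_regime_realized_below_one(self):
        """Target r/m 0.14 stays below 1 in every replicate."""
        for s in range(100):
            cfg = SimConfig.rm_regime(0.14, seed=s)
            it = index_tree(simulate_genealogy(cfg.n_taxa, seed=s))
            aln, truth = simulate_clonal_sequences(it, cfg)
            _, truth = overlay_imports(aln, it, cfg, truth)
            r = truth.realized_r_over_m
            assert (not np.isfinite(r)) or r < 1.0

    def test_realized_ratio_consistent_at_large_length(self):
        """Mean realized r/m converges to R*delta*nu/mu (10% at L=1e6)."""
        vals = []
        for s in range(20):
            cfg = SimConfig.rm_regime(1.0, seed=s, n_taxa=2, genome_len=1_000_000)
            it = tree_from_newick("(A:1,B:1);")
            aln, truth = simulate_clonal_sequences(it, cfg)
            _, truth = overlay_imports(aln, it, cfg, truth)
            vals.append(truth.realized_r_over_m)
        assert abs(np.mean(vals) - 1.0) <= 0.10


class TestGeneFlux:
    def test_zero_rates_copy_root_set(self):
        it = index_tree(simulate_genealogy(5, seed=8))
        cfg = SimConfig(n_taxa=5, n_genes=40, gain_rate=0.0, loss_rate=0.0, seed=8)
        matrix, node_sets = simulate_gene_flux(it, cfg)
        root = node_sets[it.labels[0]]
        for t in matrix.index:
            assert node_sets[t] == root

    def test_loss_dominated_regime_shrinks_leaf_sets(self):
        it = tree_from_newick("((A:2,B:2):2,C:4);")
        smaller = 0
        for s in range(50):
            cfg = SimConfig(n_taxa=3, n_genes=50, gain_rate=0.01,
                            loss_rate=0.5, seed=s)
            matrix, node_sets = simulate_gene_flux(it, cfg)
            root = len(node_sets[it.labels[0]])
            if matrix.sum(axis=1).mean() < root:
                smaller += 1
        assert smaller >= 45

    def test_branch_transition_probability_calibrated(self):
        """Gain frequency on a unit branch matches 1 - exp(-gain_rate)."""
        it = tree_from_newick("(A:1,B:1);")
        gain_rate = 0.3
        gains = opportunities = 0
        for s in range(100):
            cfg = SimConfig(n_taxa=2, n_genes=50, gain_rate=gain_rate,
                            loss_rate=0.0, seed=s)
            matrix, node_sets = simulate_gene_flux(it, cfg)
            root = node_sets[it.labels[0]]
            absent = [c for c in matrix.columns if c not in root]
            opportunities += 2 * len(absent)
            for t in matrix.index:
                gains += sum(1 for c in absent if c in node_sets[t])
        p = 1 - np.exp(-gain_rate)
        se = np.sqrt(p * (1 - p) * opportunities)
        assert abs(gains - p * opportunities) < 3 * se


class TestDegradeToSag:
    def test_full_recovery_is_identity(self):
        genome = "ACGT" * 500
        cfg = SimConfig(n_taxa=2, genome_len=2000, recovery_mean=1.0,
                        recovery_sd=0.0, err_rate=0.0, seed=1)
        scaffolds, truth = degrade_to_sag(genome, cfg)
        assert list(scaffolds.values()) == [genome]
        assert truth.retained == [(0, 2000)]
        assert truth.recovery == 1.0

    def test_retained_union_equals_reported_recovery(self):
        genome_len = 100_000
        rng = np.random.default_rng(0)
        genome = "".join(rng.choice(list("ACGT"), size=genome_len))
        cfg = SimConfig(n_taxa=2, genome_len=genome_len, recovery_mean=0.6,
                        recovery_sd=0.1, seed=3)
        scaffolds, truth = degrade_to_sag(genome, cfg)
        total = sum(e - s for s, e in truth.retained)
        assert truth.recovery == pytest.approx(total / genome_len)
        assert sum(len(s) for s in scaffolds.values()) == total
        last_end = 0
        for s, e in truth.retained:
            assert 0 <= s < e <= genome_len
            assert s >= last_end
            last_end = e

    def test_error_injection_count_and_truth_positions(self):
        genome_len = 200_000
        rng = np.random.default_rng(1)
        genome = "".join(rng.choice(list("ACGT"), size=genome_len))
        counts = []
        for s in range(50):
            cfg = SimConfig(n_taxa=2, genome_len=genome_len, err_rate=1e-4,
                            recovery_mean=0.9, recovery_sd=0.02, seed=s)
            scaffolds, truth = degrade_to_sag(genome, cfg)
            # every truth error is a real mismatch at the stated position
            flat = "".join(scaffolds.values())
            offset = {}
            pos0 = 0
            for (a, b), sid in zip(truth.retained, scaffolds):
                offset[(a, b)] = pos0
                pos0 += b - a
            for gpos, newbase in truth.errors:
                for (a, b) in truth.retained:
                    if a <= gpos < b:
                        assert flat[offset[(a, b)] + gpos - a] == "ACGT"[newbase]
                        assert genome[gpos] != "ACGT"[newbase]
                        break
            counts.append(len(truth.errors))
        lam = np.mean([c for c in counts])
        expected = 1e-4 * 0.9 * genome_len
        se = np.sqrt(expected / len(counts))
        assert abs(lam - expected) < 4 * se

    def test_half_recovery_gives_half_presence(self):
        """At 50% recovery over 10 assemblies a locus lands in ~5 of them."""
        genome_len = 50_000
        rng = np.random.default_rng(2)
        genome = "".join(rng.choice(list("ACGT"), size=genome_len))
        probe = np.arange(0, genome_len, 500)
        hits = np.zeros_like(probe, dtype=float)
        n_sags = 10
        for s in range(n_sags):
            cfg = SimConfig(n_taxa=2, genome_len=genome_len, recovery_mean=0.5,
                            recovery_sd=0.05, seed=s)
            _, truth = degrade_to_sag(genome, cfg, name=f"s{s}")
            for i, p in enumerate(probe):
                hits[i] += any(a <= p < b for a, b in truth.retained)
        assert abs(hits.mean() - 0.5 * n_sags) < 1.0


class TestMetagenome:
    def test_degenerate_simplex_labels_one_taxon(self):
        genomes = {"a": "ACGT" * 300, "b": "TTTT" * 300}
        cfg = SimConfig(n_taxa=2, genome_len=1200, read_len=100, n_reads=50,
                        err_rate=0.0, seed=0)
        _, truth = simulate_metagenome(genomes, [1.0, 0.0], cfg)
        assert (truth["taxon"] == "a").all()

    def test_minor_taxon_count_is_binomial(self):
        rngseq = np.random.default_rng(4)
        genomes = {k: "".join(rngseq.choice(list("ACGT"), size=2000))
                   for k in ("a", "b")}
        cfg = SimConfig(n_taxa=2, genome_len=2000, read_len=150,
                        n_reads=20_000, err_rate=0.0, seed=7)
        _, truth = simulate_metagenome(genomes, [0.05, 0.95], cfg)
        n_a = (truth["taxon"] == "a").sum()
        sd = np.sqrt(20_000 * 0.05 * 0.95)
        assert abs(n_a - 1000) < 3 * sd

    def test_read_matches_genome_at_truth_interval(self):
        rngseq = np.random.default_rng(5)
        genome = "".join(rngseq.choice(list("ACGT"), size=3000))
        cfg = SimConfig(n_taxa=2, genome_len=3000, read_len=120, n_reads=20,
                        err_rate=0.0, seed=2)
        reads, truth = simulate_metagenome({"g": genome}, [1.0], cfg)
        from sagpop.recruitment import revcomp
        for (rid, seq, qual), (_, row) in zip(reads, truth.iterrows()):
            src = genome[row["start"]:row["end"]]
            assert seq == (src if row["strand"] == "+" else revcomp(src))
            assert set(qual) == {"I"}

    def test_empty_community_rejected(self):
        cfg = SimConfig(n_taxa=2, genome_len=1000, seed=0)
        with pytest.raises(ValueError):
            simulate_metagenome({}, [], cfg)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"mu": -1}, {"nu": 1.5}, {"delta": 0.0}, {"recovery_mean": 0.0},
        {"gene_len": 901}, {"n_taxa": 1},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)
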