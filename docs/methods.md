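# Methods

`sagpop` analyses closely related partial genomes — single-amplified
genomes (SAGs) of uncultivated bacteria — on a shared clonal genealogy, and
ships a generator that produces every input the analysis consumes together
with complete ground truth. This note records the models, the defaults and
why they were chosen, the numerical conventions, and the limits of what the
synthetic experiments demonstrate.

Coordinates are 0-based half-open everywhere inside the package; GFF3 I/O
converts at the boundary. All randomness flows from one integer seed
through named substreams (`sagpop._rng`), so any stage can be re-run in
isolation and reproduce its in-pipeline realization exactly.

## Synthetic populations (`sagpop.simulate`)

**Genealogy.** `simulate_genealogy` draws a Kingman coalescent (haploid
samples, pairwise coalescence rate k(k−1)/2, delegated to msprime) and
rescales branch lengths so the mean root-to-tip length is 1. The true
genealogy of the organisms this emulates is unknown; the coalescent is a
neutral convenience, not an inference, and every downstream method takes an
arbitrary rooted tree.

**Sequences.** The root sequence is uniform over {A,C,G,T}. On a branch of
length *l* the substitution count is Poisson(μ·l·L) with uniform positions
(multiple hits allowed; each is a recorded event) and a uniform alternative
target base — Jukes–Cantor, matching the JC-corrected estimators
downstream. No indels are simulated.

**Imports.** Recombination initiations are Poisson(R·l·L) per branch, with
uniform starts and geometric tract lengths of mean δ (truncated at the
sequence end, no wraparound — the memoryless-tract model standard in
clonal-frame-style inference). Each tract site is substituted with
probability ν toward a uniform alternative, mimicking a divergent donor
without simulating a donor population. The generative
recombination-to-mutation ratio is r/m = R·δ·ν⁄μ; `SimTruth` also records
the *realized* ratio (imported / clonal substitution events).

**Gene content.** Root presence is Bernoulli(0.8) per ortholog cluster;
per branch, absent→present with probability 1−exp(−gain_rate·l) and
present→absent with 1−exp(−loss_rate·l). Leaf output is a binary
occurrence matrix — presence/absence disregarding copy number.

**Amplification dropout.** `degrade_to_sag` keeps k ~ Uniform[5,100]
contiguous blocks (multiple displacement amplification amplifies contiguous
regions) whose total length is a Normal(recovery_mean, recovery_sd)
fraction of the genome, clipped to (0,1] with bounded resampling, then
injects per-base errors at `err_rate` (default 5×10⁻⁶, the error-rate
regime of benchmark single-cell assemblies). Default recovery is 0.6±0.15,
the "each gene seen in roughly 6 of 10 cells" regime of partial SAG sets.

**Metagenome.** Reads draw a source taxon from a supplied abundance
simplex, a uniform position and strand, and per-base errors; qualities are
constant Sanger 'I'. Truth records taxon and interval per read.

**The r/m regime preset.** `SimConfig.rm_regime(r)` fixes 9 taxa × 25 kb,
δ = 1 kb, ν = 0.10, and scales the clonal rate with the target:
μ = 0.009⁄(1+r) clipped to [0.001, 0.008], with R derived as r·μ⁄(δ·ν).
Two generative facts force this shape. In a clonal regime the realized
ratio is dominated by tract quantization — one 1 kb tract carries ~100
substitutions — so staying reliably below r/m = 1 requires several hundred
clonal events (hence μ ≈ 0.008 at r = 0.14). In a recombinogenic regime
imports supply ~r times the clonal substitutions, so a large clonal rate
would saturate the alignment with overlapping imports and homoplasy; the
high regime therefore runs at μ = 0.001, i.e. nearly all substitutions are
imported. This mirrors the empirical contrast between clonal freshwater
and recombinogenic marine populations, where the recombinogenic dataset is
*less*, not more, clonally diverged.

## Gene flux (`sagpop.geneflux`)

Ancestral presence per cluster is reconstructed by a two-state Sankoff
dynamic program with transition costs 0 (stay), `gain_cost` (0→1, default
2) and `loss_cost` (1→0, default 1) — the field-standard asymmetry that
makes a gain twice as expensive as a loss. No prior is placed on the root
state; on a root tie the reconstruction prefers absence, so tied presence
is explained by gains on the rootmost branches, and a `root_state` override
exists for degenerate toy cases. In the traceback, cost-equivalent child
states resolve toward a change on the current (rootward) branch — an
ACCTRAN-style convention; the exact tie-breaking of legacy parsimony
software is unpublished, so this is documented as ours. Multi-copy counts
are binarized before reconstruction.

`build_composite_taxon` collapses partial assemblies into one composite
gene-content row: a cluster enters the composite if seen in ≥2 partial
taxa, or in exactly one but with a hit in an external genome; singletons
with no external support are excluded (amplification artifacts and
unsupported ORF calls) and returned for audit.

`penalty_sweep` repeats the reconstruction for gain costs 2–5 and reports
the clusters gained on a focal branch; counts are non-increasing in the
penalty (verified exhaustively in the tests), so the high-penalty survivors
are conservative gain calls.

The simulation-recovery experiment grafts three outgroup lineages above
the coalescent ingroup before scoring. This is not cosmetic: with costs
2/1 and one (or no) outgroup, a clade-wide gain is exactly as cheap as a
single loss on the complement branch and therefore unrecoverable in
principle; with three outgroup lineages the root is data-informed, as on
the outgroup-rich reference trees such analyses actually use. Event rates
(gain 0.02, loss 0.005 per unit branch) keep expected events per cluster
near 0.4, so loss-then-regain and convergent-gain histories — which
parsimony rightly explains with fewer events — stay rare; under these
conditions ≥90% of true ingroup gains are recovered. A fallback
single-linkage clusterer (global identity ≥ cutoff, connected components)
stands in when no external ortholog clustering is available.

## Synonymous divergence (`sagpop.divergence`)

`map_to_codon_alignment` expands an aligned protein into an in-frame codon
alignment (each residue column → one codon triple, protein gaps → `---`),
verifying that every CDS translates to its protein row under the standard
code. `mask_blocks` is a two-rule well-aligned-block filter: drop columns
with gap fraction above 0.5 (Ns count as gaps), then drop surviving runs
shorter than 10 columns. It approximates, but does not reproduce, the
conservation-class logic of the classical block-filtering tool.

**dS/dN.** `ng86_ds` is classical NG86 counting with Jukes–Cantor
correction: synonymous site counts per codon are the fraction of the three
changes per position that are synonymous (changes to stop codons count as
nonsynonymous); differences in multi-substitution codons are averaged with
equal weights over all minimal mutational pathways, excluding pathways
through stop codons unless all pass through one; codon pairs containing
gaps, Ns, or stop codons are skipped; dS = −¾·ln(1−4pS/3), flagged
saturated when the argument is non-positive (pS ≥ ¾). This is *not* the
ML/yn00 estimator the field also uses: no transition/transversion ratio
and no codon-usage weighting. The simplification is deliberate — every
filtering decision around the estimator is preserved, the
within/between-microcluster contrast does not depend on the κ correction,
and externally computed dS values can be slotted into the same table
format. Per-codon-pair counts are precomputed into 64×64 tables at import;
the test suite checks them exactly against an independent pathway
enumerator.

**Filters.** In `pairwise_ds_table`, a sequence is removed from a gene
when its ungapped span covers <70% of the alignment length, and a gene is
excluded for a pair when <70% of columns are ungapped in both sequences;
medians per taxon pair are taken over retained, unsaturated genes.

**Consensus and SNP statistics.** Consensus is the per-column majority
base over ungapped members (ties → alphabetically smallest; all-gap → gap).
SNP rates per kb count mismatches over columns where both sequences have
an unambiguous base — the caller chooses whether to pass whole scaffolds
or gene regions, which is how both published variants of the statistic are
expressed. `count_global_snps` implements the conservative error-rate
statistic: a mismatch is a *global* SNP only when the 20 alignment columns
on each side exist and are perfect matches; totals are normalized per
assembled (ungapped query) Mb.

## Recombination (`sagpop.recombination`)

This module is deliberately **not** a re-implementation of the Bayesian
clonal-frame machinery. It is a deterministic EM point-estimator of the
same generative quantities (R, δ, ν, per-branch clonal lengths) producing
the same headline statistic, r/m; multiple jittered restarts play the role
of multiple MCMC chains.

**Observation layer.** `infer_clonal_tree` (used when no tree is given)
is neighbor joining on JC-corrected distances, midpoint-rooted, negative
branches clamped to zero; saturated pairs (p ≥ ¾) raise an error naming
the pair. `assign_substitutions` reconstructs each column by Fitch
parsimony and assigns every state change to a branch; ambiguity resolves
rootward (the top-down pass keeps the parent state whenever possible).
Columns with a gap or N in any taxon are missing for all branches.
Columns requiring more than one change are additionally masked by default:
their per-branch placement is unreliable, and keeping them scatters
substitutions of dense import tracts onto the wrong branches, which
inflates the clonal background and biases r/m low by about 2× in
import-dominated regimes (`multi_hit="keep"` restores the permissive
behavior).

**Model.** Per branch, a two-state HMM over alignment columns: the clonal
state emits an event with probability 1−exp(−l_b), the import state with
probability ν; transitions are clonal→import 1−exp(−R·l_b) and
import→clonal 1/δ; the initial distribution is the chain's stationary
distribution; missing columns are marginalized. Baum–Welch updates share
R, δ, ν across branches while l_b stays branch-specific. Initialization:
ν₀ = 10× the mean observed event rate, δ₀ = 500, R₀ = 10⁻⁴, jittered ±50%
per restart from a fixed restart stream; the best log-likelihood wins.
Convergence is |Δ log L| < 10⁻⁶ (default) within 500 iterations;
non-convergence returns the best fit flagged `converged=False`; all-zero
tracks return r/m = 0 with a degenerate-fit warning. The forward–backward
kernel is numba-compiled; log-likelihood is asserted non-decreasing in the
tests.

**The statistic.** r/m is the ratio of posterior-expected substitution
counts in the import versus clonal states — meaningful even under model
misfit — with the plug-in R·δ·ν (branch-length-free under this
parameterization) reported alongside. Two biases are worth knowing: clonal
events that fall inside true import tracts are credited to the import
state (inflating r/m when tract coverage is high), while residual
homoplasy deflates it; in the 60-regime experiments the net effect is an
underestimate, with medians within a factor two of the truth, and the
clonal/recombinogenic contrast exceeds two orders of magnitude.

## Recruitment (`sagpop.recruitment`)

**Patchwork.** `build_patchwork` seeds with the largest scaffold of the
first taxon and repeatedly extends either end with the scaffold having the
longest end overlap ≥ 10 kb (ties: earlier taxon in the supplied
phylogenetic order, then input order); everything never joined is appended
at the end, taxon by taxon, largest first, and per-segment provenance
(source taxon, scaffold, interval) is recorded. Overlap detection is
gap-free — exact 31-mer anchors sampled from scaffold ends, verified by
Hamming identity ≥ 0.95 over the overlap — which is adequate for scaffolds
cut from near-identical genomes; the ≥95% identity requirement is our
convention, as is forward-strand-only joining (no inversions).

**Aligner.** Reads are recruited by seed-and-extend: exact 15-mer seeds
vote for a diagonal, the best diagonal defines a reference window (±64 bp
band), and a gap-affine local alignment (match +1, mismatch −2, gap open
4, extend 1; Biopython's PairwiseAligner) runs inside the window. The
best-scoring location per read wins, ties to the leftmost coordinate, both
strands tried. A read is recruited iff identity > 0.75 AND aligned columns
> 150 AND aligned read fraction > 0.5 — all strict inequalities. The test
suite proves the seeded aligner equivalent to a naive full Smith–Waterman
(same scoring, same filters) on mixed synthetic reads. An adapter for
externally computed coordinate tables can be layered on the same
`RecruitedRead` container.

**Gene slices and assignment.** Recruited reads are cut to gene
boundaries; slices overlapping a gene by <150 bp are removed; slices are
reported in gene orientation. Microcluster assignment is
nearest-consensus: each slice is aligned to every per-gene cluster
consensus, identity is scored **over the whole slice** (matched slice
bases / slice length, so a short spuriously perfect local hit to a distant
consensus cannot win), and the best label is accepted only when it beats
the runner-up by ≥ 0.02 identity — otherwise "unassigned". This is a
distance-based substitute for per-gene phylogenetic placement of reads; it
is validated against simulation truth (≥95% accuracy at the
within < 0.05 / between ≈ 0.5 divergence regime for ≥150 bp slices) and
is expected to degrade when clusters are much closer than that.

`summarize_recruitment` computes percent recruited and fold coverage as
(recruited/total)·dataset_Mb/reference_Mb, the arithmetic behind published
recruitment tables.

## Pipeline (`sagpop.pipeline`, `sagpop.cli`)

`PipelineConfig` is a flat typed config whose defaults are the thresholds
above (0.75 / 150 / 0.5; 0.7 / 0.7; 10 kb; flank 20; gain 2 / loss 1);
unknown keys are rejected by name. `run_pipeline` executes the synthetic
demo stages in dependency order and writes a manifest with per-file sha256
digests; the same config and seed reproduce every output bit for bit.
`make_report` condenses a run directory (including partial ones — missing
stages are listed, not fatal) into `report.json`/`report.txt`. The
`sagpop` command is a thin click layer: `simulate`, `flux`, `ds`,
`recomb`, `recruit`, `run`, `report`.

## What the synthetic experiments do and do not show

The generator reproduces the *statistical regimes* of the study system —
microcluster structure (within-dS < 0.05, between ≈ 0.5), 13–16 SNPs/kb
against cluster consensus, 5×10⁻⁶ assembly errors per bp, partial recovery
with contiguous dropout, clonal vs recombinogenic r/m — but not real-data
messiness: no indels, no chimeras or contamination, no assembly errors
beyond substitutions, no rate heterogeneity across sites, no codon-usage
or selection structure (dS ≈ total divergence here), and gene content
evolves independently per cluster. Passing tests therefore demonstrate
estimator correctness and calibration under the stated models, not
robustness to artifacts outside them. Problem sizes in tests and the
acceptance script (25 kb alignments, ≤2.5 Mb genomes, hundreds of reads,
tens of replicates) were chosen as the smallest at which the targeted
regime statistics stabilize.

## Known limitations

- dS is NG86+JC, not ML; absolute values at high divergence differ from
  κ-aware estimators (the within/between ordering does not).
- r/m is a point estimate; no credible intervals, no co-estimation of the
  genealogy, and a known downward bias in import-dominated regimes.
- The patchwork joiner assumes gap-free overlaps and forward strands.
- Microcluster assignment is distance-based, not phylogenetic placement.
- Parsimony gene flux cannot recover histories whose true event count
  exceeds the minimal one (loss-then-regain, convergent gains), and gains
  adjacent to an uninformed root are intrinsically confounded with losses.
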