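"""Codon-aware divergence statistics for partial-genome comparisons.

Covers the alignment-handling steps around pairwise synonymous divergence:
protein-guided codon mapping, gap-block masking, NG86 dS/dN with
Jukes–Cantor correction, the coverage filters used to build per-gene dS
tables, microcluster consensus sequences with SNP rates, and the
flank-filtered "global SNP" statistic used to benchmark assembly error
rates.

The dS estimator is classical NG86 counting (equal-weight minimal mutational
pathways, JC multiple-hit correction).  It is not yn00: no transition /
transversion or codon-usage weighting is applied.  Ambiguous bases (N) are
treated as gaps throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .alignment import Alignment, GAP, decode, encode
from .codon import ND, SD, SYN_SITES, IS_STOP

__all__ = [
    "DsEstimate",
    "GlobalSnpStats",
    "map_to_codon_alignment",
    "mask_blocks",
    "ng86_ds",
    "pairwise_ds_table",
    "consensus_sequence",
    "snp_rate_vs_consensus",
    "count_global_snps",
]


class FrameError(ValueError):
    pass


@dataclass
class DsEstimate:
    """NG86 synonymous / nonsynonymous divergence for one sequence pair."""

    dS: float
    dN: float
    pS: float
    pN: float
    S: float  # synonymous sites (averaged over the two sequences)
    N: float
    Sd: float  # synonymous differences (pathway-averaged)
    Nd: float
    n_codons: int  # codon pairs actually compared
    saturated: bool  # pS >= 3/4: dS undefined


@dataclass
class GlobalSnpStats:
    global_snps: int
    total_snps: int
    global_per_mb: float
    total_per_mb: float
    assembled_bp: int


# ---------------------------------------------------------------------------
# codon alignment construction

def map_to_codon_alignment(
    protein_alignment: Mapping[str, str], cds: Mapping[str, str]
) -> Alignment:
    """Expand an aligned protein into an in-frame codon alignment.

    Each amino-acid column becomes one codon column triple; protein gaps
    become ``---``.  Every CDS must translate exactly to its (ungapped)
    protein row under the standard code.
    """
    rows: list[tuple[str, str]] = []
    for taxon, prot in protein_alignment.items():
        if taxon not in cds:
            raise FrameError(f"no CDS for taxon {taxon!r}")
        nt = cds[taxon].upper().replace("U", "T")
        residues = prot.replace("-", "")
        if len(nt) != 3 * len(residues):
            raise FrameError(
                f"taxon {taxon!r}: CDS length {len(nt)} != 3 x {len(residues)} residues"
            )
        trans = str(Seq(nt).translate())
        for k, (a, b) in enumerate(zip(trans, residues)):
            if a != b and b != "X":
                raise FrameError(
                    f"taxon {taxon!r}: translation mismatch at residue {k} ({a!r} vs {b!r})"
                )
        out = []
        j = 0
        for ch in prot:
            if ch == "-":
                out.append("---")
            else:
                out.append(nt[3 * j:3 * j + 3])
                j += 1
        rows.append((taxon, "".join(out)))
    return Alignment.from_strings(rows)


# ---------------------------------------------------------------------------
# block masking

def mask_blocks(
    alignment: Alignment, max_gap_fraction: float = 0.5, min_block: int = 10
) -> tuple[Alignment, np.ndarray]:
    """Two-rule well-aligned-block filter.

    Drops columns whose gap fraction (gaps and Ns) exceeds
    ``max_gap_fraction``, then drops surviving runs shorter than
    ``min_block`` columns.  Returns the masked alignment and the kept-column
    indices (a subset of input columns, in order).
    """
    gapish = alignment.matrix >= GAP
    frac = gapish.mean(axis=0)
    keep = frac <= max_gap_fraction
    # run-length filter on kept columns
    kept_idx = np.nonzero(keep)[0]
    if kept_idx.size:
        breaks = np.nonzero(np.diff(kept_idx) > 1)[0]
        runs = np.split(kept_idx, breaks + 1)
        kept_idx = np.concatenate([r for r in runs if r.size >= min_block]) \
            if any(r.size >= min_block for r in runs) else np.empty(0, dtype=int)
    if kept_idx.size == 0:
        warnings.warn("mask_blocks: all columns removed", stacklevel=2)
    return alignment.take_columns(kept_idx), kept_idx


# ---------------------------------------------------------------------------
# NG86

def _codon_indices(codes: np.ndarray) -> np.ndarray:
    """Codon index per triple; -1 where the codon contains a gap/N."""
    cod = codes.reshape(-1, 3)
    bad = (cod > 3).any(axis=1)
    idx = cod[:, 0].astype(int) * 16 + cod[:, 1].astype(int) * 4 + cod[:, 2].astype(int)
    idx[bad] = -1
    return idx


def ng86_ds(seq1: str | np.ndarray, seq2: str | np.ndarray) -> DsEstimate:
    """Pairwise dS/dN by NG86 counting with Jukes–Cantor correction.

    Codon pairs containing gaps or Ns, or where either codon is a stop, are
    skipped.  Synonymous and nonsynonymous sites are averaged over the two
    sequences; multi-substitution codons average their differences over all
    minimal mutational pathways with equal weights.
    """
    a = encode(seq1) if isinstance(seq1, str) else np.asarray(seq1, dtype=np.uint8)
    b = encode(seq2) if isinstance(seq2, str) else np.asarray(seq2, dtype=np.uint8)
    if a.size != b.size:
        raise ValueError("sequences differ in length")
    if a.size % 3 != 0:
        raise ValueError("sequence length is not a multiple of 3 (frame violation)")
    ia = _codon_indices(a)
    ib = _codon_indices(b)
    ok = (ia >= 0) & (ib >= 0)
    ok &= ~(IS_STOP[np.clip(ia, 0, 63)] | IS_STOP[np.clip(ib, 0, 63)])
    ia, ib = ia[ok], ib[ok]

    S = float((SYN_SITES[ia] + SYN_SITES[ib]).sum() / 2.0)
    N = 3.0 * ia.size - S
    Sd = float(SD[ia, ib].sum())
    Nd = float(ND[ia, ib].sum())
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0

    def jc(p: float) -> tuple[float, bool]:
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0.0:
            return float("nan"), True
        return -0.75 * float(np.log(arg)), False

    dS, sat_s = jc(pS)
    dN, _ = jc(pN)
    return DsEstimate(dS=dS, dN=dN, pS=pS, pN=pN, S=S, N=N, Sd=Sd, Nd=Nd,
                      n_codons=int(ia.size), saturated=sat_s)


# ---------------------------------------------------------------------------
# per-gene dS tables

def pairwise_ds_table(
    gene_alignments: Mapping[str, Alignment],
    min_seq_coverage: float = 0.7,
    min_aln_used: float = 0.7,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene, per-pair dS with the coverage filters, plus per-pair medians.

    A sequence is dropped from a gene when its non-gap span covers less than
    ``min_seq_coverage`` of the gene alignment length; a gene is dropped for
    a pair when fewer than ``min_aln_used`` of the alignment columns are
    ungapped in both sequences.  Returns a long-format table (one row per
    retained gene x pair) and the median dS per taxon pair over retained,
    unsaturated genes.
    """
    rows = []
    for gene, aln in gene_alignments.items():
        L = len(aln)
        if L == 0:
            continue
        good = (aln.matrix <= 3).sum(axis=1) >= min_seq_coverage * L
        taxa = [t for t, g in zip(aln.taxa, good) if g]
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                r1 = aln.row(taxa[i])
                r2 = aln.row(taxa[j])
                usable = int(((r1 <= 3) & (r2 <= 3)).sum())
                if usable < min_aln_used * L:
                    continue
                est = ng86_ds(r1, r2)
                rows.append((gene, taxa[i], taxa[j], est.dS, est.dN, est.pS,
                             est.pN, est.n_codons, est.saturated))
    table = pd.DataFrame(
        rows, columns=["gene", "taxon_a", "taxon_b", "dS", "dN", "pS", "pN",
                       "n_codons", "saturated"],
    )
    if table.empty:
        return table, pd.Series(dtype=float)
    medians = (
        table[~table["saturated"]]
        .groupby(["taxon_a", "taxon_b"])["dS"].median()
    )
    return table, medians


# ---------------------------------------------------------------------------
# consensus and SNP statistics

def consensus_sequence(seqs: Sequence[str] | Alignment) -> str:
    """Per-column majority base over non-gap members.

    Ties pick the alphabetically smallest base; all-gap columns give '-'.
    """
    aln = seqs if isinstance(seqs, Alignment) else Alignment.from_strings(
        [(f"s{i}", s) for i, s in enumerate(seqs)]
    )
    if aln.n_taxa < 2:
        raise ValueError("need >= 2 member sequences for a consensus")
    mat = aln.matrix
    counts = np.stack([(mat == b).sum(axis=0) for b in range(4)])  # (4, L)
    best = counts.argmax(axis=0).astype(np.uint8)  # argmax takes first max: A<C<G<T
    empty = counts.sum(axis=0) == 0
    out = best.copy()
    out[empty] = GAP
    return decode(out)


def snp_rate_vs_consensus(seq: str, consensus: str) -> float:
    """Mismatches per kb over columns where both have an unambiguous base."""
    a = encode(seq)
    b = encode(consensus)
    if a.size != b.size:
        raise ValueError("sequence and consensus differ in length")
    both = (a <= 3) & (b <= 3)
    n = int(both.sum())
    if n == 0:
        raise ValueError("no comparable columns; SNP rate undefined")
    snps = int((a[both] != b[both]).sum())
    return snps / (n / 1000.0)


def count_global_snps(
    query_aln: str, ref_aln: str, flank: int = 20
) -> GlobalSnpStats:
    """Flank-filtered SNP counts from a pairwise query/reference alignment.

    A mismatch column is a *global* SNP iff the ``flank`` columns on each
    side all exist and are perfect matches (no gaps, no mismatches) — the
    conservative definition used for benchmarking assembly error rates.
    Rates are normalized per assembled (non-gap query) Mb.
    """
    q = encode(query_aln)
    r = encode(ref_aln)
    if q.size != r.size:
        raise ValueError("query and reference alignments differ in length")
    both = (q <= 3) & (r <= 3)
    match = both & (q == r)
    mismatch = both & (q != r)
    total = int(mismatch.sum())
    assembled = int((q <= 3).sum())
    mb = assembled / 1e6

    if q.size < 2 * flank + 1:
        warnings.warn("alignment shorter than 2*flank+1; no global SNPs callable",
                      stacklevel=2)
        n_global = 0
    else:
        # run of perfect matches to the left/right of each column (vectorized)
        n = q.size
        idx = np.arange(n)
        lastbad = np.maximum.accumulate(np.where(~match, idx, -1))
        left = np.zeros(n, dtype=np.int64)
        left[1:] = (idx[1:] - 1) - lastbad[:-1]
        rev = (~match)[::-1]
        nextbad_rev = np.maximum.accumulate(np.where(rev, idx, -1))
        right_rev = np.zeros(n, dtype=np.int64)
        right_rev[1:] = (idx[1:] - 1) - nextbad_rev[:-1]
        right = right_rev[::-1]
        is_global = mismatch & (left >= flank) & (right >= flank)
        # flanks must exist within the alignment
        idx = np.arange(q.size)
        is_global &= (idx >= flank) & (idx < q.size - flank)
        n_global = int(is_global.sum())

    return GlobalSnpStats(
        global_snps=n_global,
        total_snps=total,
        global_per_mb=n_global / mb if mb > 0 else float("nan"),
        total_per_mb=total / mb if mb > 0 else float("nan"),
        assembled_bp=assembled,
    )
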