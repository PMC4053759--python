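"""Patchwork reference construction and metagenome fragment recruitment.

A *patchwork reference* is one composite genome pieced together from the
scaffolds of several partial assemblies: starting from the largest scaffold
of the first taxon, scaffolds are repeatedly joined at substantial
(>= ``min_overlap``, default 10 kb) end overlaps, and everything that never
overlaps is appended at the end, taxon by taxon, with per-segment
provenance.

Reads are recruited with a seed-and-extend aligner (exact 15-mer seeds,
best-diagonal window, gap-affine local extension) and kept only when they
pass all three strict filters: identity > 75%, aligned length > 150 bp, and
aligned fraction of the read > 50%.  Recruited reads can then be trimmed to
gene boundaries and assigned to microclusters by nearest-consensus identity
with a margin — a distance-based stand-in for per-gene phylogenetic
placement, validated against simulation truth.

Coordinates are 0-based half-open internally; GFF3 I/O converts at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

__all__ = [
    "PatchworkReference",
    "PatchworkSegment",
    "RecruitedRead",
    "build_patchwork",
    "recruit_reads",
    "summarize_recruitment",
    "trim_reads_to_genes",
    "assign_microcluster",
    "abundance_profile",
    "read_gff3_genes",
    "write_gff3_genes",
]

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# patchwork

@dataclass
class PatchworkSegment:
    taxon: str
    scaffold: str
    src_start: int
    src_end: int
    ref_start: int
    ref_end: int


@dataclass
class PatchworkReference:
    sequence: str
    segments: list[PatchworkSegment]

    @property
    def length(self) -> int:
        return len(self.sequence)

    def provenance_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.taxon, s.scaffold, s.src_start, s.src_end, s.ref_start, s.ref_end)
             for s in self.segments],
            columns=["taxon", "scaffold", "src_start", "src_end", "ref_start", "ref_end"],
        )


def _end_overlap(ref: str, scaf: str, min_overlap: int, min_identity: float,
                 k: int = 31) -> tuple[int, int]:
    """Best (suffix_overlap, prefix_overlap) between ref and scaf.

    suffix_overlap: ref suffix == scaf prefix (scaf extends the right end);
    prefix_overlap: scaf suffix == ref prefix (scaf extends the left end).
    Overlaps are gap-free (scaffolds cut from near-identical genomes);
    anchored by exact k-mers sampled from the scaffold end, verified by
    Hamming identity >= ``min_identity``.
    """
    def hamming_id(a: str, b: str) -> float:
        n = min(len(a), len(b))
        if n == 0:
            return 0.0
        mism = sum(1 for x, y in zip(a[:n], b[:n]) if x != y)
        return 1.0 - mism / n

    best_suffix = 0
    tail = ref[-(len(scaf) + k):]
    offset0 = len(ref) - len(tail)
    for off in range(0, min(min_overlap, len(scaf) - k + 1), 500):
        anchor = scaf[off:off + k]
        start = 0
        while True:
            pos = tail.find(anchor, start)
            if pos < 0:
                break
            ov = len(ref) - (offset0 + pos) + off
            if min_overlap <= ov <= len(scaf) and ov <= len(ref):
                if hamming_id(ref[-ov:], scaf[:ov]) >= min_identity:
                    best_suffix = max(best_suffix, ov)
            start = pos + 1

    best_prefix = 0
    head = ref[: len(scaf) + k]
    for off in range(0, min(min_overlap, len(scaf) - k + 1), 500):
        anchor = scaf[len(scaf) - k - off: len(scaf) - off]
        start = 0
        while True:
            pos = head.find(anchor, start)
            if pos < 0:
                break
            ov = pos + k + off
            if min_overlap <= ov <= len(scaf) and ov <= len(ref):
                if hamming_id(scaf[-ov:], ref[:ov]) >= min_identity:
                    best_prefix = max(best_prefix, ov)
            start = pos + 1
    return best_suffix, best_prefix


def build_patchwork(
    scaffolds: Mapping[str, Mapping[str, str]],
    taxon_order: Sequence[str],
    min_overlap: int = 10_000,
    min_identity: float = 0.95,
) -> PatchworkReference:
    """Join overlapping scaffolds into one composite reference.

    ``scaffolds`` maps taxon -> scaffold id -> sequence; ``taxon_order`` is
    the (phylogenetic) priority order.  Seeds with the largest scaffold of
    the first taxon, then repeatedly extends either end with the candidate
    having the longest end overlap >= ``min_overlap`` (ties: earlier taxon,
    then input order).  Non-overlapping scaffolds are appended at the end,
    taxon by taxon, largest first.  Every scaffold contributes at most once.
    """
    if not taxon_order:
        raise ValueError("need at least one taxon")
    pool: list[tuple[str, str, str]] = []  # (taxon, scaffold id, seq)
    for t in taxon_order:
        for sid, seq in scaffolds.get(t, {}).items():
            pool.append((t, sid, seq.upper()))
    if not pool:
        raise ValueError("no scaffolds provided")

    first = [p for p in pool if p[0] == taxon_order[0]] or pool
    seed = max(first, key=lambda p: len(p[2]))
    pool.remove(seed)
    ref = seed[2]
    segments = [PatchworkSegment(seed[0], seed[1], 0, len(seed[2]), 0, len(seed[2]))]

    while True:
        best = None  # (overlap, pool index, side)
        for pi, (t, sid, seq) in enumerate(pool):
            if len(seq) < min_overlap:
                continue
            suf, pre = _end_overlap(ref, seq, min_overlap, min_identity)
            for ov, side in ((suf, "right"), (pre, "left")):
                if ov >= min_overlap and (best is None or ov > best[0]):
                    best = (ov, pi, side)
        if best is None:
            break
        ov, pi, side = best
        t, sid, seq = pool.pop(pi)
        if side == "right":
            start = len(ref)
            ref = ref + seq[ov:]
            segments.append(PatchworkSegment(t, sid, ov, len(seq), start, len(ref)))
        else:
            added = len(seq) - ov
            for s in segments:
                s.ref_start += added
                s.ref_end += added
            ref = seq[:added] + ref
            segments.insert(0, PatchworkSegment(t, sid, 0, added, 0, added))

    for t in taxon_order:
        rest = sorted((p for p in pool if p[0] == t), key=lambda p: -len(p[2]))
        for taxon, sid, seq in rest:
            start = len(ref)
            ref = ref + seq
            segments.append(PatchworkSegment(taxon, sid, 0, len(seq), start, len(ref)))

    return PatchworkReference(sequence=ref, segments=segments)


# ---------------------------------------------------------------------------
# read recruitment

@dataclass
class RecruitedRead:
    read_id: str
    ref_start: int
    ref_end: int
    strand: str
    identity: float
    aligned_length: int  # alignment columns
    aligned_fraction: float  # aligned read bases / read length
    read_seq: str  # read in reference orientation
    blocks: list[tuple[int, int, int, int]] = field(default_factory=list)
    # gapless blocks: (ref_start, ref_end, read_start, read_end), read coords
    # in reference orientation
    score: float = 0.0


def _make_aligner() -> Align.PairwiseAligner:
    # match 1 / mismatch -2 / gap open 4 + extend 1 (affine)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def _index_reference(reference: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(reference) - k + 1):
        index.setdefault(reference[i:i + k], []).append(i)
    return index


def _best_window(read: str, index: Mapping[str, list[int]], k: int,
                 n_ref: int, band: int = 64) -> tuple[int, int] | None:
    stride = max(1, (len(read) - k) // 24)
    diag_votes: dict[int, int] = {}
    for off in range(0, len(read) - k + 1, stride):
        for pos in index.get(read[off:off + k], ()):
            d = (pos - off) // 32
            diag_votes[d] = diag_votes.get(d, 0) + 1
    if not diag_votes:
        return None
    best_bin = max(diag_votes, key=lambda d: (diag_votes[d], -d))
    diag = best_bin * 32
    lo = max(0, diag - band)
    hi = min(n_ref, diag + 32 + len(read) + band)
    return lo, hi


def _align_in_window(aligner, read: str, reference: str, lo: int, hi: int):
    window = reference[lo:hi]
    if not window:
        return None
    alns = aligner.align(read, window)
    if len(alns) == 0:
        return None
    aln = alns[0]
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    if cols == 0:
        return None
    read_blocks, ref_blocks = aln.aligned  # query=read, target=window
    blocks = [
        (int(rs + lo), int(re + lo), int(qs), int(qe))
        for (qs, qe), (rs, re) in zip(read_blocks, ref_blocks)
    ]
    read_span = int(read_blocks[-1][1] - read_blocks[0][0])
    return dict(
        score=float(aln.score),
        identity=counts.identities / cols,
        aligned_length=int(cols),
        read_span=read_span,
        ref_start=blocks[0][0],
        ref_end=blocks[-1][1],
        blocks=blocks,
    )


def recruit_reads(
    reads: Mapping[str, str] | Iterable[tuple[str, str]],
    reference: str,
    min_id: float = 0.75,
    min_alnlen: int = 150,
    min_fraction: float = 0.5,
    k: int = 15,
) -> list[RecruitedRead]:
    """Recruit reads passing identity/length/fraction filters (all strict).

    Both strands are tried; the best-scoring location wins (ties: leftmost
    reference coordinate).  Reads without seeds or failing any filter are
    simply absent from the result.
    """
    items = list(reads.items()) if isinstance(reads, Mapping) else list(reads)
    reference = reference.upper()
    index = _index_reference(reference, k)
    aligner = _make_aligner()
    out: list[RecruitedRead] = []
    for rid, seq in items:
        seq = seq.upper()
        best = None
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            win = _best_window(oriented, index, k, len(reference))
            if win is None:
                continue
            res = _align_in_window(aligner, oriented, reference, *win)
            if res is None:
                continue
            key = (res["score"], -res["ref_start"])
            if best is None or key > best[0]:
                best = (key, strand, oriented, res)
        if best is None:
            continue
        _, strand, oriented, res = best
        frac = res["read_span"] / len(seq)
        if (res["identity"] > min_id and res["aligned_length"] > min_alnlen
                and frac > min_fraction):
            out.append(RecruitedRead(
                read_id=rid, ref_start=res["ref_start"], ref_end=res["ref_end"],
                strand=strand, identity=float(res["identity"]),
                aligned_length=res["aligned_length"], aligned_fraction=float(frac),
                read_seq=oriented, blocks=res["blocks"], score=res["score"],
            ))
    return out


def summarize_recruitment(
    n_recruited: int, total_reads: int, total_mb: float, reference_mb: float
) -> dict:
    """Recruited count, percent of reads, and fold coverage of the reference.

    Fold coverage treats recruited reads as an unbiased sample of the
    dataset: (recruited/total) * total_Mb / reference_Mb.
    """
    if total_reads <= 0 or total_mb <= 0 or reference_mb <= 0:
        raise ValueError("totals must be positive")
    frac = n_recruited / total_reads
    cov = frac * total_mb / reference_mb
    return {
        "recruited": int(n_recruited),
        "percent_reads": round(100.0 * frac, 1),
        "fold_coverage": round(cov, 1),
    }


# ---------------------------------------------------------------------------
# gene trimming and microcluster assignment

def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Gene coordinates from GFF3 (1-based closed) to 0-based half-open."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["seqid", "source", "type", "start", "end", "score",
                            "strand", "phase", "attributes"])
    df = df[df["type"].isin(["gene", "CDS"])].copy()
    ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
    fallback = pd.Series([f"gene{i}" for i in range(len(df))], index=ids.index)
    out = pd.DataFrame({
        "gene": ids.fillna(fallback),
        "start": df["start"].astype(int) - 1,
        "end": df["end"].astype(int),
        "strand": df["strand"].fillna("+"),
    })
    return out.reset_index(drop=True)


def write_gff3_genes(genes: pd.DataFrame, seqid: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in genes.iterrows():
            fh.write(
                f"{seqid}\tsagpop\tgene\t{row['start'] + 1}\t{row['end']}\t.\t"
                f"{row.get('strand', '+')}\t.\tID={row['gene']}\n"
            )


def _project_to_read(rr: RecruitedRead, ref_lo: int, ref_hi: int) -> str:
    """Read bases aligned within [ref_lo, ref_hi), reference orientation."""
    pieces = []
    for rs, re, qs, qe in rr.blocks:
        lo = max(rs, ref_lo)
        hi = min(re, ref_hi)
        if lo < hi:
            pieces.append(rr.read_seq[qs + (lo - rs): qs + (hi - rs)])
    return "".join(pieces)


def trim_reads_to_genes(
    recruited: Sequence[RecruitedRead],
    genes: pd.DataFrame,
    reference_length: int,
    min_overlap: int = 150,
) -> pd.DataFrame:
    """Cut recruited reads to gene boundaries, dropping short overlaps.

    ``genes`` needs columns gene/start/end (0-based half-open) and
    optionally strand.  A read spanning several genes yields one slice per
    gene with >= ``min_overlap`` bp of overlap; slices are reported in gene
    orientation.
    """
    for _, g in genes.iterrows():
        if g["start"] < 0 or g["end"] > reference_length:
            raise ValueError(f"gene {g['gene']} outside reference bounds")
    rows = []
    for rr in recruited:
        for _, g in genes.iterrows():
            lo = max(rr.ref_start, int(g["start"]))
            hi = min(rr.ref_end, int(g["end"]))
            if hi - lo < min_overlap:
                continue
            s = _project_to_read(rr, lo, hi)
            if len(s) < min_overlap:
                continue
            if str(g.get("strand", "+")) == "-":
                s = revcomp(s)
            rows.append((g["gene"], rr.read_id, lo, hi, len(s), s))
    return pd.DataFrame(rows, columns=["gene", "read", "ref_start", "ref_end",
                                       "length", "sequence"])


def assign_microcluster(
    slice_seq: str,
    consensuses: Mapping[str, str],
    margin: float = 0.02,
) -> tuple[str, dict[str, float]]:
    """Nearest-consensus label with an identity margin.

    Identity is scored over the whole slice (matched slice bases divided by
    slice length), so a short spuriously perfect local alignment to a
    distant consensus cannot outrank a full-length, slightly imperfect
    match.  Returns (label, identities); label is "unassigned" when no
    consensus exists, nothing aligns, or best-minus-second identity <
    ``margin``.
    """
    if not consensuses:
        return "unassigned", {}
    aligner = _make_aligner()
    ids: dict[str, float] = {}
    n = max(len(slice_seq), 1)
    for label, cons in consensuses.items():
        res = _align_in_window(aligner, slice_seq.upper(), cons.upper(), 0, len(cons))
        ids[label] = (res["identity"] * res["aligned_length"] / n) if res else 0.0
    ranked = sorted(ids.items(), key=lambda kv: -kv[1])
    if not ranked or ranked[0][1] == 0.0:
        return "unassigned", ids
    if len(ranked) > 1 and ranked[0][1] - ranked[1][1] < margin:
        return "unassigned", ids
    return ranked[0][0], ids


def abundance_profile(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-sample microcluster fractions over assigned slices.

    ``assignments`` needs columns sample/label.  Fractions are over assigned
    slices; the unassigned fraction (of all slices) is reported separately.
    """
    if assignments.empty:
        raise ValueError("no assignments")
    rows = []
    for sample, grp in assignments.groupby("sample"):
        assigned = grp[grp["label"] != "unassigned"]
        n_all = len(grp)
        for label, cnt in assigned["label"].value_counts().items():
            rows.append((sample, label, cnt / max(len(assigned), 1)))
        rows.append((sample, "unassigned", (n_all - len(assigned)) / n_all))
    return pd.DataFrame(rows, columns=["sample", "label", "fraction"])
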