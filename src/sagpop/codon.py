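"""Standard genetic code tables and NG86 codon-pair counts.

Codons are indexed 0..63 as 16*b1 + 4*b2 + b3 with A,C,G,T = 0..3.
``SYN_SITES[c]`` is the number of synonymous sites of codon c (the classic
fraction-of-synonymous-changes count; changes creating a stop codon count as
nonsynonymous, stop codons themselves have no defined sites).  ``SD``/``ND``
hold synonymous / nonsynonymous difference counts for every codon pair,
averaged with equal weight over all minimal mutational pathways; pathways
passing through a stop codon are excluded unless every pathway does.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

__all__ = ["CODONS", "AA", "SYN_SITES", "SD", "ND", "codon_index", "IS_STOP"]

_BASES = "ACGT"
CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_TABLE = CodonTable.unambiguous_dna_by_id[1]

AA = np.array(
    ["*" if c in _TABLE.stop_codons else _TABLE.forward_table[c] for c in CODONS]
)
IS_STOP = AA == "*"


def codon_index(codon_codes) -> int:
    """Index of a codon given three base codes (0..3)."""
    b1, b2, b3 = codon_codes
    return int(b1) * 16 + int(b2) * 4 + int(b3)


def _neighbors(ci: int, pos: int):
    base = (ci // (4 ** (2 - pos))) % 4
    for nb in range(4):
        if nb != base:
            yield ci + (nb - base) * (4 ** (2 - pos))


def _syn_sites() -> np.ndarray:
    s = np.zeros(64)
    for ci in range(64):
        if IS_STOP[ci]:
            s[ci] = np.nan
            continue
        frac = 0.0
        for pos in range(3):
            syn = sum(
                1 for nj in _neighbors(ci, pos) if not IS_STOP[nj] and AA[nj] == AA[ci]
            )
            frac += syn / 3.0
        s[ci] = frac
    return s


SYN_SITES = _syn_sites()


def _diff_positions(c1: int, c2: int) -> list[int]:
    out = []
    for pos in range(3):
        if (c1 // (4 ** (2 - pos))) % 4 != (c2 // (4 ** (2 - pos))) % 4:
            out.append(pos)
    return out


def _step(ci: int, cj: int, pos: int) -> int:
    """Codon ci with position pos replaced by cj's base at that position."""
    bi = (ci // (4 ** (2 - pos))) % 4
    bj = (cj // (4 ** (2 - pos))) % 4
    return ci + (bj - bi) * (4 ** (2 - pos))


def _pair_counts(c1: int, c2: int) -> tuple[float, float]:
    diffs = _diff_positions(c1, c2)
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur = c1
        steps = []
        through_stop = False
        for pos in order:
            nxt = _step(cur, c2, pos)
            steps.append((cur, nxt))
            if IS_STOP[nxt] and nxt != c2:
                through_stop = True
            cur = nxt
        paths.append((through_stop, steps))
    usable = [st for ts, st in paths if not ts] or [st for _, st in paths]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if AA[a] == AA[b] and AA[a] != "*":
                sd += 1
            else:
                nd += 1
    return sd / len(usable), nd / len(usable)


def _pair_tables() -> tuple[np.ndarray, np.ndarray]:
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for i in range(64):
        for j in range(64):
            sd[i, j], nd[i, j] = _pair_counts(i, j)
    return sd, nd


SD, ND = _pair_tables()
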