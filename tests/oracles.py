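"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by a route deliberately different from the
package implementation: exhaustive enumeration for parsimony, recursive
pathway enumeration for NG86 counting, and a full (unseeded) Smith–Waterman
with traceback for read recruitment.
"""

from __future__ import annotations

from itertools import permutations, product

import numpy as np

# ---------------------------------------------------------------------------
# weighted parsimony by exhaustive enumeration


def exhaustive_parsimony_cost(itree, leaf_pattern: dict[str, int],
                              gain_cost: float, loss_cost: float,
                              root_state: int | None = None) -> float:
    """Minimum weighted cost over all internal labelings (trees <= ~8 leaves)."""
    internal = [i for i in range(itree.n_nodes) if not itree.is_leaf[i]]
    best = np.inf
    for combo in product((0, 1), repeat=len(internal)):
        assign = dict(zip(internal, combo))
        if root_state is not None and assign[0] != root_state:
            continue
        cost = 0.0
        for i in range(1, itree.n_nodes):
            s_child = (leaf_pattern[itree.labels[i]] if itree.is_leaf[i]
                       else assign[i])
            s_par = assign[itree.parent[i]]
            if s_par == 0 and s_child == 1:
                cost += gain_cost
            elif s_par == 1 and s_child == 0:
                cost += loss_cost
        best = min(best, cost)
    return best


def fitch_length(itree, leaf_pattern: dict[str, int]) -> int:
    """Classic Fitch parsimony length for a binary character."""
    sets: dict[int, frozenset] = {}
    length = 0
    for i in itree.postorder:
        if itree.is_leaf[i]:
            sets[i] = frozenset([leaf_pattern[itree.labels[i]]])
        else:
            kids = np.nonzero(itree.parent == i)[0]
            inter = frozenset([0, 1])
            union: frozenset = frozenset()
            for c in kids:
                inter = inter & sets[c]
                union = union | sets[c]
            # Fitch for multifurcations generalizes; trees here are binary
            k0, k1 = kids[0], kids[1]
            if sets[k0] & sets[k1]:
                sets[i] = sets[k0] & sets[k1]
            else:
                sets[i] = sets[k0] | sets[k1]
                length += 1
    return length


# ---------------------------------------------------------------------------
# NG86 by direct recursive pathway enumeration

_BASES = "TCAG"
_CODE = {}
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_b1, _b2, _b3) in enumerate(product(_BASES, repeat=3)):
    _CODE[_b1 + _b2 + _b3] = _AAS[_i]


def ng86_pair_oracle(c1: str, c2: str) -> tuple[float, float, float, float]:
    """(S1, S2, Sd, Nd) for one codon pair, by independent enumeration."""
    def syn_sites(codon: str) -> float:
        s = 0.0
        for pos in range(3):
            for nb in "ACGT":
                if nb == codon[pos]:
                    continue
                mut = codon[:pos] + nb + codon[pos + 1:]
                if _CODE[mut] != "*" and _CODE[mut] == _CODE[codon]:
                    s += 1.0 / 3.0
        return s

    diffs = [p for p in range(3) if c1[p] != c2[p]]
    paths = []
    for order in permutations(diffs):
        cur = c1
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            steps.append((cur, nxt))
            if _CODE[nxt] == "*" and nxt != c2:
                ok = False
            cur = nxt
        paths.append((ok, steps))
    usable = [st for ok, st in paths if ok] or [st for _, st in paths]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if _CODE[a] == _CODE[b] and _CODE[a] != "*":
                sd += 1
            else:
                nd += 1
    n = len(usable)
    return syn_sites(c1), syn_sites(c2), sd / n, nd / n


# ---------------------------------------------------------------------------
# full Smith–Waterman with affine gaps and traceback

from numba import njit  # noqa: E402


@njit(cache=True)
def _sw_fill(read, ref, match, mismatch, gap_open, gap_extend):
    n, m = read.shape[0], ref.shape[0]
    NEG = -10**9
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap consumes a read base
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap consumes a ref base
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i - 1, j] + gap_extend, H[i - 1, j] + gap_open)
            F[i, j] = max(F[i, j - 1] + gap_extend, H[i, j - 1] + gap_open)
            sub = match if read[i - 1] == ref[j - 1] else mismatch
            h = H[i - 1, j - 1] + sub
            if h < E[i, j]:
                h = E[i, j]
            if h < F[i, j]:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


def smith_waterman(read: str, ref: str, match: int = 1, mismatch: int = -2,
                   gap_open: int = -5, gap_extend: int = -1):
    """Best local alignment; returns dict with identity / lengths / span.

    Row-vectorized DP over the reference; traceback reconstructed from
    stored matrices.  Scoring matches the recruitment aligner exactly.
    """
    H, E, F = _sw_fill(np.frombuffer(read.encode(), dtype=np.uint8),
                       np.frombuffer(ref.encode(), dtype=np.uint8),
                       match, mismatch, gap_open, gap_extend)
    i, j = np.unravel_index(np.argmax(H), H.shape)
    score = int(H[i, j])
    if score == 0:
        return None
    # traceback
    ident = mism = gaps = 0
    read_end, ref_end = i, j
    state = "H"
    while True:
        if state == "H":
            if i == 0 or j == 0 or H[i, j] == 0:
                break
            sub = match if read[i - 1] == ref[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + sub:
                ident += read[i - 1] == ref[j - 1]
                mism += read[i - 1] != ref[j - 1]
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover
                raise AssertionError("traceback failure")
        elif state == "E":  # consumes a read base against a gap
            assert i > 0
            gaps += 1
            opened = E[i, j] == H[i - 1, j] + gap_open
            i -= 1
            if opened:
                state = "H"
        else:  # F: consumes a reference base against a gap
            assert j > 0
            gaps += 1
            opened = F[i, j] == H[i, j - 1] + gap_open
            j -= 1
            if opened:
                state = "H"
    read_start, ref_start = i, j
    cols = ident + mism + gaps
    return dict(
        score=score,
        identity=ident / cols,
        aligned_length=cols,
        read_span=read_end - read_start,
        ref_start=ref_start,
        ref_end=ref_end,
    )
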