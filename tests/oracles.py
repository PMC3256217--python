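"""Independent alignment oracles used by the test suite.

Two formulations of the affine-gap local alignment optimum, both written
independently of the package's aligner:

* :func:`enumerate_local` -- literal enumeration of every local alignment
  (all start pairs, all monotone move sequences), tractable for strings of
  length <= ~5;
* :func:`dp_local` -- a three-state recursive formulation with
  memoization, tractable to length ~8 and beyond.

Gap convention matches BLAST: a gap of length k costs open + k * extend.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def pair_score(a: str, b: str) -> float:
    return float(_B62[a, b])


def enumerate_local(x: str, y: str, open_: float = 11.0, ext: float = 1.0) -> float:
    """Max score over every local alignment, by explicit path enumeration.

    An optimal local alignment starts and ends on an aligned residue pair,
    so paths start at every (i, j), begin with a match move, and the score
    is recorded after every match move.
    """
    best = 0.0

    def walk(i: int, j: int, score: float, in_gap: bool) -> None:
        nonlocal best
        if i < len(x) and j < len(y):
            s = score + pair_score(x[i], y[j])
            if s > best:
                best = s
            walk(i + 1, j + 1, s, False)
        # gap moves (never record a score ending in a gap)
        if i < len(x):
            walk(i + 1, j, score - (ext if in_gap else open_ + ext), True)
        if j < len(y):
            walk(i, j + 1, score - (ext if in_gap else open_ + ext), True)

    for i in range(len(x)):
        for j in range(len(y)):
            walk(i, j, 0.0, False)
    return best


def dp_local(x: str, y: str, open_: float = 11.0, ext: float = 1.0) -> float:
    """Affine-gap Smith-Waterman optimum via memoized three-state recursion."""
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def state(i: int, j: int) -> tuple[float, float, float]:
        # (best ending in match at (i-1,j-1), in x-gap, in y-gap) for prefix i,j
        if i == 0 or j == 0:
            return (NEG, NEG, NEG)
        m_prev, gx_prev, gy_prev = state(i - 1, j - 1)
        m = pair_score(x[i - 1], y[j - 1]) + max(0.0, m_prev, gx_prev, gy_prev)
        m_up, gx_up, _ = state(i - 1, j)
        gx = max(
            m_up - (open_ + ext) if m_up > NEG else NEG,
            gx_up - ext if gx_up > NEG else NEG,
        )
        m_left, _, gy_left = state(i, j - 1)
        gy = max(
            m_left - (open_ + ext) if m_left > NEG else NEG,
            gy_left - ext if gy_left > NEG else NEG,
        )
        return (m, gx, gy)

    best = 0.0
    for i in range(1, len(x) + 1):
        for j in range(1, len(y) + 1):
            m, _, _ = state(i, j)
            if m > best:
                best = m
    state.cache_clear()
    return best
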