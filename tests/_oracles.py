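"""Independent oracles used to validate the scanner and the aligner.

These deliberately share no code with the package: the motif oracle is a
naive enumeration over every (start, x, y1, y2, y3) assignment with direct
string-slice checks, and the alignment oracle is a memoized recursion over
suffixes with explicit gap-state bookkeeping (validated itself, on tiny
inputs, against full enumeration of every alignment path).
"""

from __future__ import annotations

import functools
from math import inf


def enumerate_qgrs_bruteforce(
    seq: str,
    min_tetrads: int = 2,
    max_tetrads: int | None = None,
    max_motif_length: int = 45,
    min_loop_length: int = 0,
    max_loop_length: int = 36,
    max_zero_loops: int = 1,
) -> set[tuple[int, int, int, int, int]]:
    """All (start, x, y1, y2, y3) assignments forming G(x)N(y1)G(x)N(y2)G(x)N(y3)G(x)."""
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    out = set()
    max_x = (max_motif_length - 3 * min_loop_length) // 4
    if max_tetrads is not None:
        max_x = min(max_x, max_tetrads)
    for x in range(min_tetrads, max_x + 1):
        tract = "G" * x
        for s in range(n - 4 * x - 3 * min_loop_length + 1):
            if seq[s : s + x] != tract:
                continue
            for y1 in range(min_loop_length, max_loop_length + 1):
                t2 = s + x + y1
                if 4 * x + y1 + 2 * min_loop_length > max_motif_length or t2 + x > n:
                    break
                if seq[t2 : t2 + x] != tract:
                    continue
                for y2 in range(min_loop_length, max_loop_length + 1):
                    t3 = t2 + x + y2
                    if (
                        4 * x + y1 + y2 + min_loop_length > max_motif_length
                        or t3 + x > n
                    ):
                        break
                    if seq[t3 : t3 + x] != tract:
                        continue
                    for y3 in range(min_loop_length, max_loop_length + 1):
                        t4 = t3 + x + y3
                        if 4 * x + y1 + y2 + y3 > max_motif_length or t4 + x > n:
                            break
                        if seq[t4 : t4 + x] != tract:
                            continue
                        if (y1, y2, y3).count(0) > max_zero_loops:
                            continue
                        out.add((s, x, y1, y2, y3))
    return out


def oracle_semiglobal_score(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    end_gaps_penalized: bool = False,
) -> float:
    """Optimal end-gap-free affine-gap score by memoized suffix recursion.

    A gap of length L costs ``gap_open + L*gap_extend``; gap runs touching
    either end of the *other* sequence are free unless penalized.
    """
    n, m = len(a), len(b)
    open_cost = gap_open + gap_extend
    free = not end_gaps_penalized

    @functools.lru_cache(maxsize=None)
    def f(i: int, j: int, prev: str) -> float:
        if i == n and j == m:
            return 0.0
        best = -inf
        if i < n and j < m:
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + f(i + 1, j + 1, "M"))
        if i < n:  # a[i] against a gap in b
            if free and (j == 0 or j == m):
                cost = 0.0
            else:
                cost = gap_extend if prev == "X" else open_cost
            best = max(best, -cost + f(i + 1, j, "X"))
        if j < m:  # gap in a against b[j]
            if free and (i == 0 or i == n):
                cost = 0.0
            else:
                cost = gap_extend if prev == "Y" else open_cost
            best = max(best, -cost + f(i, j + 1, "Y"))
        return best

    return f(0, 0, "S")


def enumerate_all_alignments_score(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Best end-gap-free score by exhaustively generating every alignment path.

    Exponential; only usable for sequences of length <= ~5.  Exists to
    validate :func:`oracle_semiglobal_score` itself.
    """
    n, m = len(a), len(b)
    best = [-inf]

    def walk(i: int, j: int, score: float, prev: str) -> None:
        if i == n and j == m:
            best[0] = max(best[0], score)
            return
        if i < n and j < m:
            s = match if a[i] == b[j] else mismatch
            walk(i + 1, j + 1, score + s, "M")
        if i < n:
            if j == 0 or j == m:
                cost = 0.0
            elif prev == "X":
                cost = gap_extend
            else:
                cost = gap_open + gap_extend
            walk(i + 1, j, score - cost, "X")
        if j < m:
            if i == 0 or i == n:
                cost = 0.0
            elif prev == "Y":
                cost = gap_extend
            else:
                cost = gap_open + gap_extend
            walk(i, j + 1, score - cost, "Y")

    walk(0, 0, 0.0, "S")
    return best[0]
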