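"""Semi-global (end-gap-free) pairwise alignment with affine gap costs.

Homologous mRNAs differ most in the lengths of their untranslated regions,
so a *semi-global* alignment — a global Needleman–Wunsch/Gotoh optimum in
which leading and trailing gaps are free — is used to put the principal and
comparison sequences into a common coordinate frame.  Default parameters
mirror EMBOSS needle's DNA defaults (match +5, mismatch −4, gap open 10,
gap extend 0.5); a gap of length L costs ``gap_open + L*gap_extend``.

The alignment object keeps bidirectional coordinate maps so that motif
positions found on the ungapped sequences can be translated into gapped
columns (where overlap is measured) and back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Tuple

import numpy as np

from .errors import CoordinateError, InputError, ResourceLimitError
from .motifs import normalize_sequence

_NEG = -np.inf
_EPS = 1e-9

Which = Literal["principal", "comparison"]


@dataclass(frozen=True)
class AlignParams:
    match_score: float = 5.0
    mismatch_score: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    end_gaps_penalized: bool = False
    max_length: int = 1_000_000

    def __post_init__(self) -> None:
        if self.match_score <= self.mismatch_score:
            raise InputError("match_score must exceed mismatch_score")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise InputError("gap penalties must be non-negative")
        if self.gap_open < self.gap_extend:
            raise InputError("gap_open must be >= gap_extend")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped homolog pair plus ungapped<->gapped coordinate maps."""

    principal_gapped: str
    comparison_gapped: str
    score: float
    percent_identity: float
    # _to_gapped[i] = gapped column of ungapped position i
    _p_to_gapped: np.ndarray = field(repr=False, compare=False, default=None)
    _c_to_gapped: np.ndarray = field(repr=False, compare=False, default=None)
    # _from_gapped[col] = ungapped position at that column, -1 on a gap
    _p_from_gapped: np.ndarray = field(repr=False, compare=False, default=None)
    _c_from_gapped: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def n_columns(self) -> int:
        return len(self.principal_gapped)

    @property
    def principal(self) -> str:
        """Ungapped principal sequence."""
        return self.principal_gapped.replace("-", "")

    @property
    def comparison(self) -> str:
        return self.comparison_gapped.replace("-", "")

    def to_gapped(self, which: Which, ungapped_pos: int) -> int:
        return map_position(self, which, ungapped_pos)

    def from_gapped(self, which: Which, column: int) -> int:
        """Ungapped position at ``column`` (−1 if the column is a gap)."""
        if not 0 <= column < self.n_columns:
            raise CoordinateError(
                f"column {column} outside alignment of {self.n_columns} columns"
            )
        arr = self._p_from_gapped if which == "principal" else self._c_from_gapped
        return int(arr[column])

    def gapped_interval(self, which: Which, start: int, end: int) -> Tuple[int, int]:
        """Translate an ungapped half-open interval into gapped columns.

        The returned half-open column interval spans from the column of the
        first nucleotide through the column of the last nucleotide plus one,
        so internal gaps widen the interval (as they should: overlap is
        measured in the shared frame).
        """
        if end <= start:
            raise CoordinateError(f"degenerate interval [{start}, {end})")
        gs = self.to_gapped(which, start)
        ge = self.to_gapped(which, end - 1) + 1
        return gs, ge


def _build_maps(gapped: str) -> Tuple[np.ndarray, np.ndarray]:
    cols = np.arange(len(gapped))
    is_base = np.frombuffer(gapped.encode(), dtype=np.uint8) != ord("-")
    to_gapped = cols[is_base]
    from_gapped = np.full(len(gapped), -1, dtype=np.int64)
    from_gapped[is_base] = np.arange(is_base.sum())
    return to_gapped, from_gapped


def map_position(alignment: PairwiseAlignment, which: Which, ungapped_pos: int) -> int:
    """Gapped column holding the nucleotide at ``ungapped_pos``."""
    if which not in ("principal", "comparison"):
        raise InputError(f"which must be 'principal' or 'comparison', got {which!r}")
    arr = (
        alignment._p_to_gapped if which == "principal" else alignment._c_to_gapped
    )
    if not 0 <= ungapped_pos < len(arr):
        raise CoordinateError(
            f"position {ungapped_pos} outside {which} sequence of length {len(arr)}"
        )
    return int(arr[ungapped_pos])


def semiglobal_align(
    principal: str, comparison: str, params: AlignParams | None = None
) -> PairwiseAlignment:
    """Optimal end-gap-free global alignment (Gotoh affine-gap DP).

    Traceback ties are broken deterministically: diagonal first, then gap
    in the comparison sequence, then gap in the principal.
    """
    if params is None:
        params = AlignParams()
    a = normalize_sequence(principal)
    b = normalize_sequence(comparison)
    if len(a) > params.max_length or len(b) > params.max_length:
        raise ResourceLimitError(
            f"sequence length exceeds safety limit of {params.max_length} nt"
        )

    n, m = len(a), len(b)
    open_cost = params.gap_open + params.gap_extend  # first gap residue
    ext = params.gap_extend
    free_ends = not params.end_gaps_penalized

    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)

    # State matrices: M diagonal, X gap-in-comparison (consumes principal,
    # vertical), Y gap-in-principal (consumes comparison, horizontal).
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    i_idx = np.arange(1, n + 1, dtype=float)
    j_idx = np.arange(1, m + 1, dtype=float)
    X[1:, 0] = 0.0 if free_ends else -(open_cost + (i_idx - 1) * ext)
    Y[0, 1:] = 0.0 if free_ends else -(open_cost + (j_idx - 1) * ext)

    jj = np.arange(m, dtype=float)  # column index helper for the Y prefix-max
    for i in range(1, n + 1):
        sub = np.where(a_arr[i - 1] == b_arr, params.match_score, params.mismatch_score)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + sub
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - open_cost,
            X[i - 1, 1:] - ext,
        )
        # Y along the row is a running max over gap-opening points k < j:
        #   Y[i, j] = max_k ( max(M,X)[i, k] - open - (j-1-k)*ext )
        opener = np.maximum(M[i, :-1], X[i, :-1]) + jj * ext
        Y[i, 1:] = np.maximum.accumulate(opener) - open_cost - (jj) * ext

    V = np.maximum(np.maximum(M, X), Y)

    # Choose the end cell: (n, m) preferred, then deeper cells in the last
    # column (more comparison consumed), then in the last row.
    if free_ends:
        # j == 0 / i == 0 end cells cover degenerate "slide-past" alignments
        bi, bj = n, m
        best = V[n, m]
        for i in range(n - 1, -1, -1):
            if V[i, m] > best + _EPS:
                best, bi, bj = V[i, m], i, m
        for j in range(m - 1, -1, -1):
            if V[n, j] > best + _EPS:
                best, bi, bj = V[n, j], n, j
    else:
        bi, bj = n, m
        best = V[n, m]

    ap, bp = _traceback(a, b, M, X, Y, bi, bj, open_cost, ext, free_ends)
    # free trailing gaps
    if bi < n:
        ap.append(a[bi:])
        bp.append("-" * (n - bi))
    if bj < m:
        ap.append("-" * (m - bj))
        bp.append(b[bj:])

    pg = "".join(ap)
    cg = "".join(bp)
    ncol = len(pg)
    ident = sum(1 for x, y in zip(pg, cg) if x == y and x != "-")
    p2g, pfg = _build_maps(pg)
    c2g, cfg = _build_maps(cg)
    return PairwiseAlignment(
        principal_gapped=pg,
        comparison_gapped=cg,
        score=float(best),
        percent_identity=100.0 * ident / ncol,
        _p_to_gapped=p2g,
        _c_to_gapped=c2g,
        _p_from_gapped=pfg,
        _c_from_gapped=cfg,
    )


def _pick_state(cands: tuple[float, float, float]) -> int:
    """Index of the best candidate; ties prefer M (0), then X (1), then Y (2)."""
    best = max(cands)
    for k in range(3):
        if cands[k] >= best - _EPS:
            return k
    return 0  # unreachable


def _traceback(a, b, M, X, Y, bi, bj, open_cost, ext, free_ends):
    """Reconstruct the optimal path as aligned string fragments."""
    state = _pick_state((M[bi, bj], X[bi, bj], Y[bi, bj]))
    ap: list[str] = []
    bp: list[str] = []
    i, j = bi, bj
    while i > 0 or j > 0:
        if state == 0:  # M: a[i-1] aligned to b[j-1]
            ap.append(a[i - 1])
            bp.append(b[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = _pick_state((M[i, j], X[i, j], Y[i, j]))
        elif state == 1:  # X: a[i-1] over a gap in the comparison
            ap.append(a[i - 1])
            bp.append("-")
            if j == 0:  # leading gap region; stay in X until i == 0
                i -= 1
                continue
            state = _pick_state(
                (
                    M[i - 1, j] - open_cost,
                    X[i - 1, j] - ext,
                    Y[i - 1, j] - open_cost,
                )
            )
            i -= 1
        else:  # Y: gap in the principal over b[j-1]
            ap.append("-")
            bp.append(b[j - 1])
            if i == 0:
                j -= 1
                continue
            state = _pick_state(
                (
                    M[i, j - 1] - open_cost,
                    X[i, j - 1] - open_cost,
                    Y[i, j - 1] - ext,
                )
            )
            j -= 1
    ap.reverse()
    bp.reverse()
    return ap, bp


def alignment_to_fasta(
    alignment: PairwiseAlignment, principal_id: str, comparison_id: str
) -> str:
    """Two-record aligned-FASTA text for the gapped pair."""
    return (
        f">{principal_id}\n{alignment.principal_gapped}\n"
        f">{comparison_id}\n{alignment.comparison_gapped}\n"
    )
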