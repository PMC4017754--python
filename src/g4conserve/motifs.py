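"""QGRS motif scanning.

A putative quadruplex-forming G-rich sequence (QGRS) is a motif

    G(x) N(y1) G(x) N(y2) G(x) N(y3) G(x)

of four guanine tracts of equal length ``x`` (the number of stacked
G-tetrads the folded quadruplex would contain) separated by three loops of
lengths ``y1``–``y3``.  The scanner enumerates *every* distinct assignment
``(start, x, y1, y2, y3)`` satisfying the scan parameters — overlapping
motifs are all reported, because downstream conservation scoring must be
able to choose among them.

Each motif carries a heuristic stability G-score (more tetrads, shorter
loops, more even loops score higher) and a *fractional tetrad count*: the
tetrad count augmented by one quarter per tract that has an adjacent extra
guanine in the underlying sequence, used only when comparing tetrad counts
across homologs.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional, Sequence, Tuple

from .errors import CoordinateError, InputError

_VALID_CHARS = frozenset("ACGTN")


def normalize_sequence(sequence: str) -> str:
    """Uppercase, fold U to T and validate the alphabet.

    Raises
    ------
    InputError
        If the sequence is empty or contains a character outside
        ``{A, C, G, T, U, N}`` (the offending symbol is named).
    """
    if not isinstance(sequence, str):
        raise InputError(f"sequence must be a string, got {type(sequence).__name__}")
    if not sequence:
        raise InputError("sequence must be non-empty")
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise InputError(
            f"illegal character {sorted(bad)[0]!r} in sequence "
            f"(allowed: A, C, G, T, U, N)"
        )
    return seq


def default_g_score(
    tetrads: int, loops: Tuple[int, int, int], params: "ScanParams"
) -> float:
    """Heuristic stability score.

    Implements the three published ranking principles — more tetrads,
    shorter loops, more even loops::

        G = c1*(x - 2) + c2*(1 - mean(y)/Ymax) + c3*(1 - (max(y)-min(y))/Ymax)

    with ``c1=20, c2=10, c3=10`` and ``Ymax = params.max_loop_length``.
    Only the *ordering* of scores matters downstream (family-representative
    selection and optional filtering); the formula is pluggable via
    ``ScanParams.g_score_fn``.
    """
    ymax = max(params.max_loop_length, 1)
    mean_loop = sum(loops) / 3.0
    spread = max(loops) - min(loops)
    return (
        20.0 * (tetrads - 2)
        + 10.0 * (1.0 - mean_loop / ymax)
        + 10.0 * (1.0 - spread / ymax)
    )


@dataclass(frozen=True)
class ScanParams:
    """Bounds on the QGRS motif search.

    Defaults follow the common QGRS-scanner lineage: tetrad count >= 2,
    motif length <= 45 nt (so e.g. the 42-nt KISS1 quadruplex is findable),
    loop lengths 0–36 with at most one zero-length loop.
    """

    min_tetrads: int = 2
    max_tetrads: Optional[int] = None
    max_motif_length: int = 45
    min_loop_length: int = 0
    max_loop_length: int = 36
    max_zero_loops: int = 1
    g_score_fn: Callable[[int, Tuple[int, int, int], "ScanParams"], float] = field(
        default=default_g_score, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.min_tetrads < 2:
            raise InputError("min_tetrads must be >= 2")
        if self.max_tetrads is not None and self.max_tetrads < self.min_tetrads:
            raise InputError("max_tetrads must be >= min_tetrads")
        if self.min_loop_length < 0 or self.max_loop_length < self.min_loop_length:
            raise InputError("loop bounds must satisfy 0 <= min <= max")
        if self.max_motif_length < 4 * self.min_tetrads + 3 * self.min_loop_length:
            raise InputError(
                "max_motif_length too small to hold any motif under these bounds"
            )


@dataclass(frozen=True)
class QGRSMotif:
    """One putative quadruplex: position, structure and scores.

    ``start`` is a 0-based offset; the motif occupies the half-open
    interval ``[start, start + length)``.  Human-readable exports convert
    to 1-based inclusive coordinates.
    """

    sequence_id: str
    start: int
    tetrads: int
    loops: Tuple[int, int, int]
    motif_string: str
    g_score: float
    fractional_tetrads: float

    @property
    def length(self) -> int:
        return 4 * self.tetrads + sum(self.loops)

    @property
    def end(self) -> int:
        """Exclusive end offset."""
        return self.start + self.length

    @property
    def tract_starts(self) -> Tuple[int, int, int, int]:
        """0-based start of each of the four G-tracts."""
        x = self.tetrads
        y1, y2, y3 = self.loops
        t1 = self.start
        t2 = t1 + x + y1
        t3 = t2 + x + y2
        t4 = t3 + x + y3
        return (t1, t2, t3, t4)

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        """Inclusive 1-based end coordinate."""
        return self.start + self.length


def _g_windows(seq: str, x: int) -> list[int]:
    """Start offsets of every length-``x`` all-G window."""
    out = []
    run_start = None
    for i, ch in enumerate(seq + "$"):  # sentinel terminates final run
        if ch == "G":
            if run_start is None:
                run_start = i
        elif run_start is not None:
            run_len = i - run_start
            out.extend(range(run_start, run_start + run_len - x + 1))
            run_start = None
    return out


def g_score(motif: QGRSMotif, params: ScanParams) -> float:
    """G-score of a motif under ``params`` (delegates to the pluggable formula)."""
    return params.g_score_fn(motif.tetrads, motif.loops, params)


def fractional_tetrads(
    start: int, tetrads: int, loops: Tuple[int, int, int], sequence: str
) -> float:
    """Tetrad count plus 1/4 per tract with an adjacent extra guanine.

    A tract "extends" if the base immediately 5' of its first G or
    immediately 3' of its last G (outside the assigned x-window but
    contiguous with it) is a guanine; extra guanines beyond the first add
    nothing.  The fraction is capped at 0.75: if all four tracts extend,
    the (x+1)-tetrad motif exists in its own right and is enumerated
    separately.  Used only for tetrad-similarity scoring.
    """
    x = tetrads
    length = 4 * x + sum(loops)
    if start < 0 or start + length > len(sequence):
        raise CoordinateError(
            f"motif [{start}, {start + length}) outside sequence of length "
            f"{len(sequence)}"
        )
    t1 = start
    t2 = t1 + x + loops[0]
    t3 = t2 + x + loops[1]
    t4 = t3 + x + loops[2]
    k = 0
    for t in (t1, t2, t3, t4):
        left = t - 1 >= 0 and sequence[t - 1] == "G"
        right = t + x < len(sequence) and sequence[t + x] == "G"
        if left or right:
            k += 1
    return x + min(k, 3) / 4.0


def motif_fractional_tetrads(motif: QGRSMotif, sequence: str) -> float:
    """:func:`fractional_tetrads` for an already-constructed motif."""
    seq = normalize_sequence(sequence)
    value = fractional_tetrads(motif.start, motif.tetrads, motif.loops, seq)
    expect = "G" * motif.tetrads
    for t in motif.tract_starts:
        if seq[t : t + motif.tetrads] != expect:
            raise CoordinateError(
                f"motif at {motif.start} does not decompose into G-tracts in "
                f"the given sequence"
            )
    return value


def find_qgrs(
    sequence: str,
    params: ScanParams | None = None,
    sequence_id: str = "",
) -> list[QGRSMotif]:
    """Enumerate every QGRS in ``sequence`` satisfying ``params``.

    All distinct ``(start, x, y1, y2, y3)`` assignments are returned —
    including mutually overlapping motifs and alternative tract placements
    inside G-runs longer than ``x``.  The result is sorted by start
    position, then by descending G-score (further ties: shorter motif,
    lexicographically smaller loop triple).
    """
    if params is None:
        params = ScanParams()
    seq = normalize_sequence(sequence)
    n = len(seq)
    max_x = (params.max_motif_length - 3 * params.min_loop_length) // 4
    if params.max_tetrads is not None:
        max_x = min(max_x, params.max_tetrads)

    out: list[QGRSMotif] = []
    for x in range(params.min_tetrads, max_x + 1):
        windows = _g_windows(seq, x)
        if len(windows) < 4:
            continue
        out.extend(_enumerate_for_x(seq, x, windows, params, sequence_id))

    out.sort(key=lambda m: (m.start, -m.g_score, m.length, m.loops))
    return out


def _enumerate_for_x(
    seq: str,
    x: int,
    windows: Sequence[int],
    params: ScanParams,
    sequence_id: str,
) -> Iterator[QGRSMotif]:
    """Yield all 4-tract placements for a fixed tract length ``x``."""
    minl, maxl = params.min_loop_length, params.max_loop_length
    max_len = params.max_motif_length
    wset = windows  # sorted ascending by construction
    for i1, t1 in enumerate(wset):
        # total length = t4 + x - t1 <= max_len bounds every later tract
        limit = t1 + max_len - x
        lo2, hi2 = t1 + x + minl, t1 + x + maxl
        for i2 in range(bisect.bisect_left(wset, lo2, i1), len(wset)):
            t2 = wset[i2]
            if t2 > hi2 or t2 > limit:
                break
            y1 = t2 - (t1 + x)
            lo3, hi3 = t2 + x + minl, t2 + x + maxl
            for i3 in range(bisect.bisect_left(wset, lo3, i2), len(wset)):
                t3 = wset[i3]
                if t3 > hi3 or t3 > limit:
                    break
                y2 = t3 - (t2 + x)
                lo4, hi4 = t3 + x + minl, t3 + x + maxl
                for i4 in range(bisect.bisect_left(wset, lo4, i3), len(wset)):
                    t4 = wset[i4]
                    if t4 > hi4 or t4 > limit:
                        break
                    y3 = t4 - (t3 + x)
                    loops = (y1, y2, y3)
                    if sum(1 for y in loops if y == 0) > params.max_zero_loops:
                        continue
                    length = 4 * x + y1 + y2 + y3
                    yield QGRSMotif(
                        sequence_id=sequence_id,
                        start=t1,
                        tetrads=x,
                        loops=loops,
                        motif_string=seq[t1 : t1 + length],
                        g_score=params.g_score_fn(x, loops, params),
                        fractional_tetrads=fractional_tetrads(t1, x, loops, seq),
                    )
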