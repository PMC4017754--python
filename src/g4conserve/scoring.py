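"""Conservation scoring for a pair of QGRS across aligned homologs.

The conservation score of a motif pair is a weighted composite in [0, 1]:

    score = 0.65*overlap + 0.20*tetrad + 0.10*loop + 0.05*length

* ``overlap`` — positional agreement of the two motifs in the shared
  (gapped) alignment frame.  Each motif interval is padded on both ends by
  50% of the smaller motif's ungapped length (so proximate but imperfectly
  aligned motifs are not eliminated outright), the Jaccard fraction
  |intersection|/|union| of the padded intervals is taken, and a step
  function saturates it: >= 0.85 scores 1.0, 0 scores 0, values between
  are scaled linearly by 1/0.85.
* ``tetrad`` — min/max ratio of the two *fractional* tetrad counts; a
  ratio at or below 0.5 scores 0, larger ratios pass through unchanged.
* ``loop`` — mean over the three positionally-paired loops of the min/max
  length ratio, with any per-loop ratio below 0.5 zeroed (0/0 counts as a
  perfect 1.0).
* ``length`` — min/max ratio of the ungapped total lengths; 0 at or below
  0.6, linearly interpolated up to 1.0 at equality.

Loop and total lengths are always ungapped nucleotide counts; only
*positions* pass through the gapped frame.  A pair whose overlap component
is 0 is flagged disposable — the two motifs occupy unrelated regions and
the pair is never persisted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

from .align import PairwiseAlignment
from .errors import CoordinateError, InputError
from .motifs import QGRSMotif

Interval = Tuple[int, int]


@dataclass(frozen=True)
class ScoringParams:
    """All constants of the conservation score."""

    w_overlap: float = 0.65
    w_tetrad: float = 0.20
    w_loop: float = 0.10
    w_length: float = 0.05
    overlap_saturation: float = 0.85
    tetrad_floor: float = 0.50
    loop_floor: float = 0.50
    length_floor: float = 0.60
    padding_fraction: float = 0.50
    overlap_denominator: str = "union"  # or "smaller"

    def __post_init__(self) -> None:
        total = self.w_overlap + self.w_tetrad + self.w_loop + self.w_length
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"component weights must sum to 1.0, got {total}")
        for name in ("overlap_saturation", "tetrad_floor", "loop_floor", "length_floor"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InputError(f"{name} must lie in (0, 1), got {v}")
        if self.overlap_denominator not in ("union", "smaller"):
            raise InputError("overlap_denominator must be 'union' or 'smaller'")


@dataclass(frozen=True)
class ConservationComponents:
    overlap: float
    tetrad: float
    loop: float
    length: float
    composite: float

    @property
    def disposable(self) -> bool:
        """True when the pair occupies unrelated regions (zero overlap)."""
        return self.overlap == 0.0


def overlap_score(
    principal_interval: Interval,
    comparison_interval: Interval,
    smaller_len: int,
    params: ScoringParams | None = None,
) -> float:
    """Padded-interval overlap component on gapped-column intervals."""
    if params is None:
        params = ScoringParams()
    (s1, e1), (s2, e2) = principal_interval, comparison_interval
    if e1 <= s1 or e2 <= s2:
        raise CoordinateError(
            f"degenerate interval: [{s1}, {e1}) vs [{s2}, {e2})"
        )
    pad = math.floor(params.padding_fraction * smaller_len)
    s1, e1 = s1 - pad, e1 + pad
    s2, e2 = s2 - pad, e2 + pad
    inter = min(e1, e2) - max(s1, s2)
    if inter <= 0:
        return 0.0
    if params.overlap_denominator == "union":
        denom = (e1 - s1) + (e2 - s2) - inter
    else:
        denom = min(e1 - s1, e2 - s2)
    raw = inter / denom
    if raw >= params.overlap_saturation:
        return 1.0
    return raw / params.overlap_saturation


def tetrad_similarity(
    t_a: float, t_b: float, params: ScoringParams | None = None
) -> float:
    """min/max ratio of fractional tetrad counts with a 0.5 cut-off.

    A ratio at or below the floor scores 0; above it the ratio itself is
    the score (so 3 vs 4 tetrads gives 0.75, 2 vs 4 gives 0).
    """
    if params is None:
        params = ScoringParams()
    r = min(t_a, t_b) / max(t_a, t_b)
    return 0.0 if r <= params.tetrad_floor else r


def loop_similarity(
    loops_a: Tuple[int, int, int],
    loops_b: Tuple[int, int, int],
    params: ScoringParams | None = None,
) -> float:
    """Mean per-loop min/max ratio; ratios below the floor are zeroed.

    Loops are paired positionally (first with first, and so on); two
    zero-length loops are identical (ratio 1.0), a zero against a non-zero
    loop scores 0 for that loop.  A ratio exactly at the floor is kept
    (only ratios strictly below 0.5 are zeroed).
    """
    if params is None:
        params = ScoringParams()
    total = 0.0
    for ya, yb in zip(loops_a, loops_b):
        if ya == yb == 0:
            r = 1.0
        else:
            r = min(ya, yb) / max(ya, yb)
        total += r if r >= params.loop_floor else 0.0
    return total / 3.0


def length_similarity(
    len_a: int, len_b: int, params: ScoringParams | None = None
) -> float:
    """Total-length component: 0 at or below the 0.6 floor, then linear."""
    if params is None:
        params = ScoringParams()
    r = min(len_a, len_b) / max(len_a, len_b)
    if r <= params.length_floor:
        return 0.0
    return (r - params.length_floor) / (1.0 - params.length_floor)


def conservation_score(
    motif_a: QGRSMotif,
    motif_b: QGRSMotif,
    alignment: PairwiseAlignment,
    params: ScoringParams | None = None,
) -> ConservationComponents:
    """All four components plus the weighted composite for one motif pair.

    ``motif_a`` must come from the principal sequence of ``alignment`` and
    ``motif_b`` from the comparison sequence.
    """
    if params is None:
        params = ScoringParams()
    iv_a = alignment.gapped_interval("principal", motif_a.start, motif_a.end)
    iv_b = alignment.gapped_interval("comparison", motif_b.start, motif_b.end)
    smaller = min(motif_a.length, motif_b.length)
    ov = overlap_score(iv_a, iv_b, smaller, params)
    te = tetrad_similarity(
        motif_a.fractional_tetrads, motif_b.fractional_tetrads, params
    )
    lo = loop_similarity(motif_a.loops, motif_b.loops, params)
    le = length_similarity(motif_a.length, motif_b.length, params)
    composite = (
        params.w_overlap * ov
        + params.w_tetrad * te
        + params.w_loop * lo
        + params.w_length * le
    )
    return ConservationComponents(
        overlap=ov, tetrad=te, loop=lo, length=le, composite=composite
    )
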