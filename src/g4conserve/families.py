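"""Overlapping-motif families and family-pair conservation.

Exhaustive QGRS scanning reports every overlapping variant of a
quadruplex-forming region, which is unusable at scale: overlapping motifs
inflate counts and a pair list over all motifs grows quadratically.  The
compromise implemented here groups mutually proximate motifs into
*families* (all start positions within a family differ by fewer than
``family_distance`` bases, default 5), stores one representative per
family — the member with the highest G-score — but scores conservation of
a family *pair* as the maximum composite over the full member
cross-product.  Scoring only the two representatives can underestimate
conservation: the most stable motif in one homolog need not be the one
best mirrored in the other.

The representative depends only on the family itself, never on which
homolog it is compared against, so one sequence's family records can be
cross-referenced against many species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

from .align import PairwiseAlignment
from .errors import InputError
from .motifs import QGRSMotif
from .scoring import ConservationComponents, ScoringParams, conservation_score

DEFAULT_FAMILY_DISTANCE = 5


@dataclass(frozen=True)
class QGRSFamily:
    """A 5'→3'-ordered group of overlapping QGRS with one stored representative."""

    family_id: int
    members: Tuple[QGRSMotif, ...]
    representative: QGRSMotif

    @property
    def start(self) -> int:
        return self.members[0].start


@dataclass(frozen=True)
class ConservationRecord:
    """Best-scoring pairing between a principal and a comparison family."""

    principal_family_id: int
    comparison_family_id: int
    principal_representative: QGRSMotif
    comparison_representative: QGRSMotif
    best_components: ConservationComponents
    best_member_pair: Tuple[int, int]  # indices into the two member tuples
    principal_best: QGRSMotif
    comparison_best: QGRSMotif


def select_representative(members: Sequence[QGRSMotif]) -> QGRSMotif:
    """Member with the highest G-score; ties go to the 5'-most, then shortest."""
    if not members:
        raise InputError("cannot select a representative from an empty family")
    return min(members, key=lambda m: (-m.g_score, m.start, m.length))


def group_families(
    motifs: Sequence[QGRSMotif],
    family_distance: int = DEFAULT_FAMILY_DISTANCE,
) -> list[QGRSFamily]:
    """Greedy 5'→3' partition of motifs into proximity families.

    A new family opens whenever the next motif's start differs from the
    current family's *first* member's start by ``family_distance`` or more;
    seeding from the 5'-most member guarantees every pairwise start
    difference within a family is below the threshold.  Families are
    numbered 1, 2, ... in 5'→3' order.
    """
    if family_distance < 1:
        raise InputError("family_distance must be >= 1")
    ordered = sorted(motifs, key=lambda m: (m.start, -m.g_score, m.length, m.loops))
    families: list[QGRSFamily] = []
    current: list[QGRSMotif] = []
    for motif in ordered:
        if current and motif.start - current[0].start >= family_distance:
            families.append(_close_family(len(families) + 1, current))
            current = []
        current.append(motif)
    if current:
        families.append(_close_family(len(families) + 1, current))
    return families


def _close_family(family_id: int, members: list[QGRSMotif]) -> QGRSFamily:
    return QGRSFamily(
        family_id=family_id,
        members=tuple(members),
        representative=select_representative(members),
    )


def score_family_pair(
    family_p: QGRSFamily,
    family_c: QGRSFamily,
    alignment: PairwiseAlignment,
    params: ScoringParams | None = None,
) -> Optional[ConservationRecord]:
    """Maximum conservation over the member cross-product of two families.

    Pairs whose overlap component is 0 are disposed of immediately (the
    motifs occupy unrelated alignment regions); if every pairing is
    disposed the family pair yields no record.  Ties on the composite are
    broken by the larger overlap component, then by the 5'-most principal
    member.
    """
    if params is None:
        params = ScoringParams()
    best: Optional[ConservationComponents] = None
    best_pair = (-1, -1)
    for i, mp in enumerate(family_p.members):
        for j, mc in enumerate(family_c.members):
            comp = conservation_score(mp, mc, alignment, params)
            if comp.disposable:
                continue
            better = best is None or comp.composite > best.composite + 1e-12
            tied = (
                best is not None
                and abs(comp.composite - best.composite) <= 1e-12
                and comp.overlap > best.overlap + 1e-12
            )
            # members iterate in 5'->3' order, so keeping the first winner
            # on full ties selects the 5'-most principal member
            if better or tied:
                best = comp
                best_pair = (i, j)
    if best is None:
        return None
    return ConservationRecord(
        principal_family_id=family_p.family_id,
        comparison_family_id=family_c.family_id,
        principal_representative=family_p.representative,
        comparison_representative=family_c.representative,
        best_components=best,
        best_member_pair=best_pair,
        principal_best=family_p.members[best_pair[0]],
        comparison_best=family_c.members[best_pair[1]],
    )
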