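"""End-to-end orchestration: scan both homologs, align, group, score, filter.

The run proceeds in three stages: (1) exhaustive QGRS scanning of each
sequence independently, (2) a semi-global alignment of the pair, and
(3) conservation scoring of every principal-family x comparison-family
pairing, keeping the best member pairing per family pair.  Records whose
best overlap is zero are disposed; survivors are filtered by a minimum
composite (default 0.95, the conventional "highly conserved" cut-off) and
optionally by a minimum representative G-score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

from .align import AlignParams, PairwiseAlignment, semiglobal_align
from .errors import InputError
from .families import (
    DEFAULT_FAMILY_DISTANCE,
    ConservationRecord,
    QGRSFamily,
    group_families,
    score_family_pair,
)
from .motifs import QGRSMotif, ScanParams, find_qgrs
from .scoring import ScoringParams

REGION_5UTR = "5'-UTR"
REGION_CDS = "CDS"
REGION_3UTR = "3'-UTR"


@dataclass(frozen=True)
class RegionAnnotation:
    """CDS span (1-based inclusive) on an mRNA, splitting it into three regions."""

    sequence_id: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.cds_start <= self.cds_end:
            raise InputError(
                f"require 1 <= cds_start <= cds_end, got "
                f"[{self.cds_start}, {self.cds_end}]"
            )


@dataclass(frozen=True)
class RunConfig:
    """Everything an end-to-end run needs."""

    scan: ScanParams = field(default_factory=ScanParams)
    align: AlignParams = field(default_factory=AlignParams)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    family_distance: int = DEFAULT_FAMILY_DISTANCE
    min_conservation: float = 0.95
    min_g_score: Optional[float] = None
    region_rule: str = "start"  # or "majority"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_conservation <= 1.0:
            raise InputError("min_conservation must lie in [0, 1]")
        if self.region_rule not in ("start", "majority"):
            raise InputError("region_rule must be 'start' or 'majority'")


def classify_region(
    motif: QGRSMotif, annot: RegionAnnotation, rule: str = "start"
) -> str:
    """Assign a motif to the 5'-UTR, CDS or 3'-UTR of its mRNA.

    Under the default ``start`` rule a boundary-spanning motif takes the
    region containing its 5' end; under ``majority`` it takes the region
    holding most of its nucleotides (ties fall back to the start rule).
    """
    start1 = motif.start + 1  # 1-based
    if rule == "start":
        if start1 < annot.cds_start:
            return REGION_5UTR
        if start1 <= annot.cds_end:
            return REGION_CDS
        return REGION_3UTR
    if rule == "majority":
        s, e = motif.start + 1, motif.end  # 1-based inclusive span
        in5 = max(0, min(e, annot.cds_start - 1) - s + 1)
        incds = max(0, min(e, annot.cds_end) - max(s, annot.cds_start) + 1)
        in3 = max(0, e - max(s, annot.cds_end + 1) + 1)
        best = max(in5, incds, in3)
        counts = ((in5, REGION_5UTR), (incds, REGION_CDS), (in3, REGION_3UTR))
        winners = [r for c, r in counts if c == best]
        if len(winners) == 1:
            return winners[0]
        return classify_region(motif, annot, rule="start")
    raise InputError(f"unknown region rule {rule!r}")


def filter_records(
    records: Sequence[ConservationRecord], config: RunConfig
) -> list[ConservationRecord]:
    """Keep records meeting the composite and G-score thresholds (stable order)."""
    out = []
    for rec in records:
        if rec.best_components.composite < config.min_conservation:
            continue
        if (
            config.min_g_score is not None
            and rec.principal_representative.g_score < config.min_g_score
        ):
            continue
        out.append(rec)
    return out


def run_pair(
    principal: Tuple[str, str],
    comparison: Tuple[str, str],
    config: RunConfig | None = None,
) -> Tuple[list[QGRSFamily], list[QGRSFamily], list[ConservationRecord], PairwiseAlignment]:
    """Full pipeline on one ``(id, sequence)`` homolog pair.

    Returns the principal families, comparison families, the filtered
    conservation records (ordered by principal then comparison family id)
    and the alignment itself.
    """
    if config is None:
        config = RunConfig()
    p_id, p_seq = principal
    c_id, c_seq = comparison
    if not p_id or not c_id:
        raise InputError("both records need a non-empty sequence id")

    motifs_p = find_qgrs(p_seq, config.scan, sequence_id=p_id)
    motifs_c = find_qgrs(c_seq, config.scan, sequence_id=c_id)
    families_p = group_families(motifs_p, config.family_distance)
    families_c = group_families(motifs_c, config.family_distance)
    alignment = semiglobal_align(p_seq, c_seq, config.align)

    records: list[ConservationRecord] = []
    for fp in families_p:
        for fc in families_c:
            rec = score_family_pair(fp, fc, alignment, config.scoring)
            if rec is not None:
                records.append(rec)
    records.sort(key=lambda r: (r.principal_family_id, r.comparison_family_id))
    return families_p, families_c, filter_records(records, config), alignment
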