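"""Synthetic homolog pairs with planted QGRS.

The generator builds a principal sequence from a G-free random backbone
(alphabet {A, C, T}) into which QGRS motifs are planted at chosen
positions, then derives a comparison "homolog" by applying per-site point
substitutions and single-nucleotide indels.  Because the backbone and the
mutation alphabet exclude guanine outside planted G-tracts, the set of
QGRS in each sequence is exactly the planted set — no accidental motifs —
and the truth table of planted coordinates in both sequences is exact.

G-tracts are exempt from substitution, and whole motifs from indels,
unless ``mutate_g_tracts`` is set; this lets tests degrade loop identity
while keeping motif structure, or destroy motifs deliberately.

Defaults emulate a moderately diverged homolog pair: a 400-nt backbone,
2% substitutions and 0.5% single-base indels outside the motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .errors import FixtureSpecError
from .motifs import ScanParams, find_qgrs

_BACKBONE = np.array(list("ACT"))


@dataclass(frozen=True)
class PlantedMotif:
    """One motif to plant: position in the principal, structure, loop sequences."""

    position: int
    tetrads: int = 3
    loops: Tuple[int, int, int] = (2, 2, 2)
    loop_seqs: Optional[Tuple[str, str, str]] = None

    @property
    def length(self) -> int:
        return 4 * self.tetrads + sum(self.loops)

    def render(self, rng: np.random.Generator) -> str:
        if self.loop_seqs is not None:
            seqs = self.loop_seqs
            if tuple(len(s) for s in seqs) != self.loops:
                raise FixtureSpecError(
                    f"loop_seqs lengths {tuple(len(s) for s in seqs)} do not "
                    f"match loops {self.loops}"
                )
            if any("G" in s.upper() for s in seqs):
                raise FixtureSpecError("loop_seqs must be G-free")
        else:
            seqs = tuple(
                "".join(rng.choice(_BACKBONE, size=y)) for y in self.loops
            )
        tract = "G" * self.tetrads
        return tract + seqs[0] + tract + seqs[1] + tract + seqs[2] + tract


@dataclass(frozen=True)
class FixtureSpec:
    backbone_length: int = 400
    planted_motifs: Tuple[PlantedMotif, ...] = (PlantedMotif(position=180),)
    substitution_rate: float = 0.02
    indel_rate: float = 0.005
    mutate_g_tracts: bool = False
    plant_in_comparison: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate < 1 or not 0 <= self.indel_rate < 1:
            raise FixtureSpecError("mutation rates must lie in [0, 1)")
        spans = sorted(
            (m.position, m.position + m.length) for m in self.planted_motifs
        )
        for (s, e) in spans:
            if s < 0 or e > self.backbone_length:
                raise FixtureSpecError(
                    f"planted motif [{s}, {e}) outside backbone of length "
                    f"{self.backbone_length}"
                )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1 + 1:  # require a >=1 nt non-G flank between motifs
                raise FixtureSpecError(
                    f"planted motifs [{s1},{e1}) and [{s2},{e2}) overlap or touch"
                )


def generate_pair(
    spec: FixtureSpec,
    principal_id: str = "principal",
    comparison_id: str = "comparison",
) -> Tuple[Tuple[str, str], Tuple[str, str], pd.DataFrame]:
    """Build (principal, comparison, truth) from a fixture spec.

    Returns two ``(id, sequence)`` records and a truth table with one row
    per planted motif: 0-based start/end in the principal and — when the
    motif is planted in the comparison — in the comparison (accounting for
    any indel-induced coordinate shifts).
    """
    rng = np.random.default_rng(spec.seed)
    backbone = rng.choice(_BACKBONE, size=spec.backbone_length)
    motif_strings = [m.render(rng) for m in spec.planted_motifs]

    principal = backbone.copy()
    protected_sub = np.zeros(spec.backbone_length, dtype=bool)  # G-tract sites
    protected_indel = np.zeros(spec.backbone_length, dtype=bool)  # whole motifs
    for m, s in zip(spec.planted_motifs, motif_strings):
        principal[m.position : m.position + m.length] = list(s)
        protected_indel[m.position : m.position + m.length] = True
        x = m.tetrads
        t = m.position
        for y in (*m.loops, None):
            protected_sub[t : t + x] = True
            if y is None:
                break
            t += x + y

    if not spec.plant_in_comparison:
        comparison_base = backbone.copy()  # motifs never planted
        protected_sub[:] = False
        protected_indel[:] = False
    else:
        comparison_base = principal.copy()

    if spec.mutate_g_tracts:
        protected_sub[:] = False
        protected_indel[:] = False

    comparison_chars: list[str] = []
    shift = np.zeros(spec.backbone_length, dtype=np.int64)  # offset at each site
    offset = 0
    for i in range(spec.backbone_length):
        shift[i] = offset
        base = comparison_base[i]
        if not protected_indel[i] and rng.random() < spec.indel_rate:
            if rng.random() < 0.5:  # deletion
                offset -= 1
                continue
            comparison_chars.append(str(rng.choice(_BACKBONE)))  # insertion
            offset += 1
            shift[i] = offset
        if not protected_sub[i] and rng.random() < spec.substitution_rate:
            if base == "G":
                choices = [c for c in "ACT"]
            else:
                choices = [c for c in "ACT" if c != base]
            base = str(rng.choice(choices))
        comparison_chars.append(base)

    principal_seq = "".join(principal)
    comparison_seq = "".join(comparison_chars)

    rows = []
    for idx, (m, s) in enumerate(zip(spec.planted_motifs, motif_strings)):
        in_comparison = spec.plant_in_comparison and not spec.mutate_g_tracts
        c_start = int(m.position + shift[m.position]) if in_comparison else None
        rows.append(
            {
                "motif_index": idx,
                "tetrads": m.tetrads,
                "loop1": m.loops[0],
                "loop2": m.loops[1],
                "loop3": m.loops[2],
                "principal_start": m.position,
                "principal_end": m.position + m.length,
                "comparison_start": c_start,
                "comparison_end": (c_start + m.length) if c_start is not None else None,
                "motif_string": s,
            }
        )
    truth = pd.DataFrame(rows)

    _assert_backbone_clean(backbone)
    return (principal_id, principal_seq), (comparison_id, comparison_seq), truth


def _assert_backbone_clean(backbone: np.ndarray) -> None:
    """The raw backbone must be guanine-free (asserted, not assumed)."""
    if (backbone == "G").any():
        raise FixtureSpecError("internal error: backbone contains guanine")


def verify_planted_absent(sequence: str, params: ScanParams | None = None) -> bool:
    """True when a sequence contains no QGRS at all (scrubbed comparison)."""
    return not find_qgrs(sequence, params or ScanParams(), sequence_id="check")
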