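"""File input/output: FASTA, pair lists, annotations, CSV/JSON records.

FASTA parsing goes through Biopython; tabular records through pandas.
All coordinates in exported tables are 1-based inclusive (the usual
reporting convention); in-memory objects stay 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

from .align import AlignParams
from .errors import InputError
from .families import ConservationRecord, QGRSFamily
from .motifs import QGRSMotif, ScanParams
from .pipeline import RegionAnnotation, RunConfig, classify_region
from .scoring import ScoringParams

FastaRecord = Tuple[str, str]


def read_fasta(path: str | Path) -> List[FastaRecord]:
    """All records of a (multi-)FASTA file as ``(id, sequence)`` tuples."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return records


def read_fasta_dict(path: str | Path) -> Dict[str, str]:
    records = read_fasta(path)
    out = dict(records)
    if len(out) != len(records):
        raise InputError(f"duplicate sequence ids in {path}")
    return out


def read_pair_list(path: str | Path) -> List[Tuple[str, str]]:
    """Homolog pairs from a 2–3 column TSV (principal id, comparison id[, label])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"pair list {path} needs at least two tab-separated columns")
    return [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def read_region_annotations(path: str | Path) -> Dict[str, RegionAnnotation]:
    """Per-sequence CDS coordinates from a TSV: sequence_id, cds_start, cds_end."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise InputError(f"annotation file {path} needs three columns")
    out = {}
    for _, row in df.iterrows():
        annot = RegionAnnotation(
            sequence_id=str(row.iloc[0]),
            cds_start=int(row.iloc[1]),
            cds_end=int(row.iloc[2]),
        )
        out[annot.sequence_id] = annot
    return out


def motifs_to_dataframe(
    motifs: Sequence[QGRSMotif],
    annot: Optional[RegionAnnotation] = None,
    region_rule: str = "start",
) -> pd.DataFrame:
    """Scan results as a table (1-based inclusive coordinates)."""
    rows = []
    for m in motifs:
        row = {
            "sequence_id": m.sequence_id,
            "start_1based": m.start_1based,
            "end_1based": m.end_1based,
            "tetrads": m.tetrads,
            "loop1": m.loops[0],
            "loop2": m.loops[1],
            "loop3": m.loops[2],
            "length": m.length,
            "g_score": m.g_score,
            "fractional_tetrads": m.fractional_tetrads,
            "motif_string": m.motif_string,
        }
        if annot is not None:
            row["region"] = classify_region(m, annot, region_rule)
        rows.append(row)
    return pd.DataFrame(rows)


def families_to_dataframe(
    families: Sequence[QGRSFamily],
    annot: Optional[RegionAnnotation] = None,
    region_rule: str = "start",
) -> pd.DataFrame:
    """One row per family representative."""
    rows = []
    for fam in families:
        rep = fam.representative
        row = {
            "sequence_id": rep.sequence_id,
            "family_id": fam.family_id,
            "n_members": len(fam.members),
            "start_1based": rep.start_1based,
            "end_1based": rep.end_1based,
            "tetrads": rep.tetrads,
            "loop1": rep.loops[0],
            "loop2": rep.loops[1],
            "loop3": rep.loops[2],
            "length": rep.length,
            "g_score": rep.g_score,
            "fractional_tetrads": rep.fractional_tetrads,
            "motif_string": rep.motif_string,
        }
        if annot is not None:
            row["region"] = classify_region(rep, annot, region_rule)
        rows.append(row)
    return pd.DataFrame(rows)


def records_to_dataframe(
    records: Sequence[ConservationRecord],
    principal_id: str = "",
    comparison_id: str = "",
) -> pd.DataFrame:
    rows = []
    for rec in records:
        c = rec.best_components
        rows.append(
            {
                "principal_id": principal_id or rec.principal_representative.sequence_id,
                "comparison_id": comparison_id
                or rec.comparison_representative.sequence_id,
                "principal_family_id": rec.principal_family_id,
                "comparison_family_id": rec.comparison_family_id,
                "overlap": c.overlap,
                "tetrad": c.tetrad,
                "loop": c.loop,
                "length": c.length,
                "composite": c.composite,
                "principal_rep_start_1based": rec.principal_representative.start_1based,
                "comparison_rep_start_1based": rec.comparison_representative.start_1based,
                "principal_best_start_1based": rec.principal_best.start_1based,
                "comparison_best_start_1based": rec.comparison_best.start_1based,
                "principal_best_motif": rec.principal_best.motif_string,
                "comparison_best_motif": rec.comparison_best.motif_string,
            }
        )
    return pd.DataFrame(rows)


def _motif_dict(m: QGRSMotif) -> dict:
    return {
        "sequence_id": m.sequence_id,
        "start_1based": m.start_1based,
        "end_1based": m.end_1based,
        "tetrads": m.tetrads,
        "loops": list(m.loops),
        "length": m.length,
        "g_score": m.g_score,
        "fractional_tetrads": m.fractional_tetrads,
        "motif_string": m.motif_string,
    }


def records_to_json(
    records: Sequence[ConservationRecord],
    families_p: Sequence[QGRSFamily],
    families_c: Sequence[QGRSFamily],
    verbose_members: bool = False,
) -> str:
    """JSON mirror of the CSV schema, optionally with full family member lists."""
    fam_p = {f.family_id: f for f in families_p}
    fam_c = {f.family_id: f for f in families_c}
    out = []
    for rec in records:
        c = rec.best_components
        entry = {
            "principal_family_id": rec.principal_family_id,
            "comparison_family_id": rec.comparison_family_id,
            "components": {
                "overlap": c.overlap,
                "tetrad": c.tetrad,
                "loop": c.loop,
                "length": c.length,
                "composite": c.composite,
            },
            "principal_representative": _motif_dict(rec.principal_representative),
            "comparison_representative": _motif_dict(rec.comparison_representative),
            "best_member_pair": list(rec.best_member_pair),
        }
        if verbose_members:
            entry["principal_members"] = [
                _motif_dict(m) for m in fam_p[rec.principal_family_id].members
            ]
            entry["comparison_members"] = [
                _motif_dict(m) for m in fam_c[rec.comparison_family_id].members
            ]
        out.append(entry)
    return json.dumps(out, indent=2)


def read_config_file(path: str | Path, base: RunConfig | None = None) -> RunConfig:
    """Flat ``key = value`` config file mirroring RunConfig.

    Keys may address nested parameter blocks with a dotted prefix, e.g.::

        scan.min_tetrads = 3
        align.gap_open = 12
        scoring.overlap_saturation = 0.85
        min_conservation = 0.9
    """
    from dataclasses import replace

    base = base or RunConfig()
    overrides: Dict[str, Dict[str, object]] = {"": {}, "scan": {}, "align": {}, "scoring": {}}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InputError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        prefix, _, name = key.rpartition(".")
        if prefix not in overrides:
            raise InputError(f"{path}:{lineno}: unknown parameter block {prefix!r}")
        overrides[prefix][name] = _coerce(value)

    def _apply(obj, values, valid_fields):
        unknown = set(values) - valid_fields
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        return replace(obj, **values) if values else obj

    scan = _apply(base.scan, overrides["scan"], {f.name for f in dc_fields(ScanParams)})
    align = _apply(base.align, overrides["align"], {f.name for f in dc_fields(AlignParams)})
    scoring = _apply(
        base.scoring, overrides["scoring"], {f.name for f in dc_fields(ScoringParams)}
    )
    top_fields = {f.name for f in dc_fields(RunConfig)} - {"scan", "align", "scoring"}
    return _apply(
        replace(base, scan=scan, align=align, scoring=scoring),
        overrides[""],
        top_fields,
    )


def _coerce(text: str):
    low = text.lower()
    if low in ("true", "false"):
        return low == "true"
    if low in ("none", "null"):
        return None
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def write_fasta(path: str | Path, records: Sequence[FastaRecord]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
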