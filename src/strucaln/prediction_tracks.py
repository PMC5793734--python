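"""Ingestion of externally produced secondary-structure and disorder
predictions, and their conversion to rendering classes.

Two dialects are read: the classic ``.ss2`` table (``# PSIPRED VFORMAT``
header, rows of index / residue / state / coil / helix / strand confidences)
and a plain TSV with named header columns ``index residue helix strand coil
disorder``.  Disorder confidences given as reals in [0, 1] are normalized to
the 0-9 integer scale by floor(10·conf) capped at 9.
"""
from __future__ import annotations

import math
from typing import Optional

from .errors import FormatError, TrackMismatchError
from .types import AlignedSequence, Alignment, PredictionTrack


def normalize_disorder(value: float) -> int:
    """Map a disorder confidence to the 0-9 integer scale: integers pass
    through, reals in [0, 1] become floor(10·conf) capped at 9."""
    if isinstance(value, int) or float(value).is_integer() and value > 1:
        iv = int(value)
        if not 0 <= iv <= 9:
            raise FormatError(f"disorder confidence {value!r} outside 0-9")
        return iv
    f = float(value)
    if not 0.0 <= f <= 1.0:
        raise FormatError(f"disorder confidence {value!r} outside [0, 1]")
    return min(9, int(math.floor(10.0 * f)))


def _parse_tsv(lines: list[str]) -> list[dict]:
    header = lines[0].split()
    required = {"index", "residue", "helix", "strand", "coil"}
    if not required.issubset(header):
        raise FormatError(
            f"prediction TSV header must contain {sorted(required)}; got {header}")
    rows = []
    for line in lines[1:]:
        if not line.strip():
            continue
        vals = dict(zip(header, line.split()))
        if len(vals) < len(header):
            raise FormatError(f"short prediction row: {line!r}")
        rows.append({
            "residue": vals["residue"],
            "helix": float(vals["helix"]),
            "strand": float(vals["strand"]),
            "coil": float(vals["coil"]),
            "disorder": normalize_disorder(float(vals.get("disorder", 0.0))),
        })
    return rows


def _parse_ss2(lines: list[str]) -> list[dict]:
    # fixed .ss2 column order: index, residue, state, coil, helix, strand
    rows = []
    for line in lines:
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        if len(parts) < 6:
            raise FormatError(f"malformed .ss2 row (expected 6 fields): {line!r}")
        rows.append({
            "residue": parts[1],
            "coil": float(parts[3]),
            "helix": float(parts[4]),
            "strand": float(parts[5]),
            "disorder": 0,
        })
    return rows


def parse_ss_prediction(text: str, sequence: str) -> PredictionTrack:
    """Parse a prediction table and cross-check it against the ungapped
    ``sequence`` it annotates (length and residue letters must agree)."""
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        raise FormatError("empty prediction input")
    first = lines[0].split()
    if "residue" in first and "helix" in first:
        rows = _parse_tsv(lines)
    else:
        rows = _parse_ss2(lines)
    if len(rows) != len(sequence):
        raise TrackMismatchError(
            f"prediction has {len(rows)} rows but the sequence has "
            f"{len(sequence)} residues")
    for k, (row, letter) in enumerate(zip(rows, sequence), start=1):
        if row["residue"].upper() != letter.upper():
            raise TrackMismatchError(
                f"prediction residue {row['residue']!r} at position {k} does "
                f"not match sequence letter {letter!r}")
    return PredictionTrack(
        helix=[r["helix"] for r in rows],
        strand=[r["strand"] for r in rows],
        coil=[r["coil"] for r in rows],
        disorder=[r["disorder"] for r in rows],
    )


def ss_render_class(helix_conf: float, strand_conf: float,
                    strong: float = 0.7, weak: float = 0.3) -> str:
    """Rendering class of a predicted residue: the dominant confidence picks
    helix vs strand, ≥ 0.7 renders strong (dark shade), [0.3, 0.7) weak
    (light shade), below 0.3 nothing; an exact helix/strand tie renders
    nothing."""
    if helix_conf == strand_conf:
        return "none"
    family, conf = (("helix", helix_conf) if helix_conf > strand_conf
                    else ("strand", strand_conf))
    if conf >= strong:
        return f"strong-{family}"
    if conf >= weak:
        return f"weak-{family}"
    return "none"


def disorder_render_class(disorder_conf: int, minimum: int = 8) -> bool:
    """True when the 0-9 disorder confidence reaches the display minimum."""
    return disorder_conf >= minimum


def select_predicted_sequences(aln: Alignment) -> list[str]:
    """Ids of the rows eligible for prediction tracks: the first
    sequence-role row plus every model-role row, in alignment order."""
    out = []
    first_plain: Optional[str] = None
    for s in aln.sequences:
        if s.role == "model":
            out.append(s.seq_id)
        elif s.role == "sequence" and first_plain is None:
            first_plain = s.seq_id
            out.append(s.seq_id)
    return out
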