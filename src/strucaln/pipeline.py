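"""End-to-end orchestration: from a matched alignment to the complete
annotation document."""
from __future__ import annotations

from typing import Optional

from .alignment_features import (annotate_columns, percent_identity,
                                 superpose)
from .annotation_model import AnnotationDocument, build_document
from .config import AnnotationParams, DEFAULT_PARAMS
from .errors import SuperpositionError
from .structure_features import annotate_structure
from .types import Alignment, SuperpositionResult


def run_job(aln: Alignment, params: AnnotationParams = DEFAULT_PARAMS
            ) -> AnnotationDocument:
    """Annotate a matched alignment (structures already attached).

    Computes every per-residue track, superposes when at least two structures
    are present (single-structure jobs simply omit superposition and RMSD),
    assembles the column track, and the identity table of the first
    non-structure sequence against each structure.
    """
    residue_tracks = {}
    for seq in aln.sequences:
        if seq.structure is not None:
            residue_tracks[seq.seq_id] = annotate_structure(seq.structure, params)
            seq.residue_annotations = residue_tracks[seq.seq_id]
    struct_rows = [s for s in aln.sequences if s.structure is not None]
    sup: Optional[SuperpositionResult] = None
    if len(struct_rows) >= 2:
        try:
            sup = superpose(struct_rows, aln)
        except SuperpositionError:
            sup = None
    columns = annotate_columns(aln, sup, params.consensus_threshold,
                               params.rmsd_bin_edges)
    pids: list[tuple[str, float]] = []
    query = next((s for s in aln.sequences if s.role == "sequence"), None)
    if query is not None:
        for s in struct_rows:
            pid, shared = percent_identity(query, s)
            pids.append((s.seq_id, pid if shared else 0.0))
    return build_document(aln, residue_tracks, columns, sup, pids, params)
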