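"""Exception hierarchy: every validation failure raises a subclass of
:class:`AnnotationError` with a message suitable for direct display."""
from __future__ import annotations


class AnnotationError(Exception):
    """Base class for all input-validation and pipeline errors."""


class EmptyInputError(AnnotationError):
    pass


class AlignmentShapeError(AnnotationError):
    """Ragged record lengths, all-gap columns, or other MSA shape defects."""


class TooManySequencesError(AnnotationError):
    pass


class FormatError(AnnotationError):
    """Malformed FASTA/PIR/prediction input."""


class MissingChainError(AnnotationError):
    pass


class EmptyChainError(AnnotationError):
    pass


class SequenceStructureMismatchError(AnnotationError):
    """Alignment sequence differs from the observed (ATOM-record) residues.

    Carries the first mismatching ungapped position (1-based) and both letters;
    this is the classic SEQRES-vs-ATOM submission error.
    """

    def __init__(self, seq_id: str, position: int, aln_letter: str, struct_letter: str):
        self.seq_id = seq_id
        self.position = position
        self.aln_letter = aln_letter
        self.struct_letter = struct_letter
        super().__init__(
            f"sequence {seq_id!r}: alignment letter {aln_letter!r} does not match "
            f"structure residue {struct_letter!r} at ungapped position {position}; "
            "check that the alignment uses the observed ATOM sequence, not SEQRES"
        )


class TrackMismatchError(AnnotationError):
    """Prediction track disagrees with the sequence it annotates."""


class AssemblyError(AnnotationError):
    """Track lengths inconsistent when assembling the annotation document."""


class SchemaValidationError(AnnotationError):
    """Annotation XML fails schema validation; message includes element path."""


class SuperpositionError(AnnotationError):
    """Fewer than three columns shared by all structures."""
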