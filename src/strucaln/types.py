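"""Core domain types: atoms, residues, chains, aligned sequences, alignments,
and the per-residue / per-column annotation bundles."""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import AlignmentShapeError, TooManySequencesError, EmptyInputError

GAP = "-"
ROLES = ("structure", "model", "sequence")


@dataclass
class Atom:
    """One heavy atom: PDB atom name, element symbol, coordinate in Å."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")


@dataclass
class Residue:
    """One polymer residue with its named heavy atoms.

    ``seq_id`` is the author residue number plus insertion code, kept as a
    string so e.g. "100A" round-trips.
    """

    three_letter: str
    one_letter: str
    seq_id: str
    atoms: list[Atom]

    def __post_init__(self):
        if not self.atoms:
            raise ValueError(f"residue {self.three_letter} {self.seq_id}: no atoms")
        if not (len(self.one_letter) == 1 and
                (self.one_letter.isalpha() or self.one_letter == "X")):
            raise ValueError(f"invalid one-letter code {self.one_letter!r}")

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])


@dataclass
class ChainStructure:
    """One polymer chain plus everything needed for interface analysis:
    non-water hetero groups and the other polymer chains of the file."""

    source_id: str
    chain_id: str
    residues: list[Residue]
    hetero_groups: list[tuple[str, list[Atom]]] = field(default_factory=list)
    other_chains: list[tuple[str, list[Residue]]] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        """One-letter sequence of the observed (ATOM-record) residues."""
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ResidueAnnotation:
    """Per-residue structural feature bundle.

    ``ss`` is one of H (α-helix), G (3₁₀ helix), E (β-strand), C (coil).
    ``positive_phi`` is None at termini / chain breaks where φ is undefined.
    ``contacts`` holds 0-based within-chain residue indices whose nearest
    heavy-atom distance is within the contact cutoff.
    """

    ss: str = "C"
    rel_sasa: Optional[float] = None
    buried: bool = False
    positive_phi: Optional[bool] = None
    hbond_to_amide: bool = False
    hbond_to_carbonyl: bool = False
    depth: Optional[float] = None
    chain_contact: Optional[str] = None
    ligand_contact: Optional[str] = None
    contacts: frozenset = frozenset()


@dataclass
class PredictionTrack:
    """Externally produced secondary-structure / disorder confidences, one
    entry per ungapped residue; disorder normalized to the 0-9 integer scale."""

    helix: list[float]
    strand: list[float]
    coil: list[float]
    disorder: list[int]

    def __post_init__(self):
        n = len(self.helix)
        if not (len(self.strand) == len(self.coil) == len(self.disorder) == n):
            raise ValueError("prediction track arrays differ in length")
        for arr in (self.helix, self.strand, self.coil):
            if any(not (0.0 <= v <= 1.0) for v in arr):
                raise ValueError("confidence outside [0, 1]")
        if any(not (0 <= d <= 9) for d in self.disorder):
            raise ValueError("disorder confidence outside 0-9")

    def __len__(self) -> int:
        return len(self.helix)


@dataclass
class AlignedSequence:
    seq_id: str
    role: str
    gapped: str
    structure: Optional[ChainStructure] = None
    residue_annotations: Optional[list[ResidueAnnotation]] = None
    prediction: Optional[PredictionTrack] = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def ungapped(self) -> str:
        return self.gapped.replace(GAP, "")

    def residue_index_at_column(self, col: int) -> Optional[int]:
        """0-based ungapped index of the residue at 1-based column ``col``,
        or None when the column holds a gap."""
        if self.gapped[col - 1] == GAP:
            return None
        return len(self.gapped[:col].replace(GAP, "")) - 1


class Alignment:
    """A validated MSA: equal-length gapped rows, at most ``max_sequences``
    rows, and no all-gap column."""

    def __init__(self, sequences: Sequence[AlignedSequence], max_sequences: int = 25):
        sequences = list(sequences)
        if not sequences:
            raise EmptyInputError("alignment contains no sequences")
        if len(sequences) > max_sequences:
            raise TooManySequencesError(
                f"{len(sequences)} sequences exceed the configured maximum "
                f"of {max_sequences}")
        n_col = len(sequences[0].gapped)
        for s in sequences:
            if len(s.gapped) != n_col:
                raise AlignmentShapeError(
                    f"record {s.seq_id!r} has length {len(s.gapped)}, "
                    f"expected {n_col}")
        if n_col == 0:
            raise AlignmentShapeError("alignment has zero columns")
        for j in range(n_col):
            if all(s.gapped[j] == GAP for s in sequences):
                raise AlignmentShapeError(f"column {j + 1} consists entirely of gaps")
        self.sequences = sequences
        self.n_columns = n_col
        self.max_sequences = max_sequences

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def get(self, seq_id: str) -> AlignedSequence:
        for s in self.sequences:
            if s.seq_id == seq_id:
                return s
        raise KeyError(seq_id)

    def column(self, i: int) -> str:
        """1-based column as a string of letters/gaps."""
        return "".join(s.gapped[i - 1] for s in self.sequences)


@dataclass
class ColumnAnnotation:
    """Per-column feature bundle: normalized entropy with its display symbol,
    SS consensus symbol ('a'/'b'/'3' or ''), and Cα RMSD with its bin index."""

    entropy: float = 0.0
    entropy_symbol: str = "*"
    consensus_ss: str = ""
    rmsd: Optional[float] = None
    rmsd_bin: Optional[int] = None


@dataclass
class SuperpositionResult:
    """Outcome of the multi-structure variance-weighted superposition.

    ``rotations``/``translations`` map structure ids to the rigid transform
    taking the input coordinates into the common frame; ``column_coords`` maps
    1-based alignment columns to the superposed Cα coordinates present there;
    ``weights`` are the final inverse-variance column weights over the shared
    (all-structures) column set.
    """

    ids: list[str]
    rotations: dict
    translations: dict
    column_coords: dict
    weights: dict
    n_iterations: int = 0

    def transform(self, seq_id: str, coords: np.ndarray) -> np.ndarray:
        R = self.rotations[seq_id]
        t = self.translations[seq_id]
        return coords @ R.T + t
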