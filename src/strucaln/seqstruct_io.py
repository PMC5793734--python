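"""Input/output: FASTA and PIR/ALI alignments, PDB chains, and the normalized
PIR writer.

The PIR dialect follows the comparative-modelling convention: each record has
a ``>P1;id`` header, a colon-separated description line whose first field is
the role tag (``structure``/``structureX``/``structureN`` for experimental
structures, ``structureM`` for models, ``sequence`` for plain sequences), and
a ``*``-terminated gapped sequence.  A simplified dialect with only the role
field populated is accepted on input; output is always the simplified form.
"""
from __future__ import annotations

import io as _io
from typing import Iterable, Optional

import gemmi
import numpy as np
from Bio import SeqIO

from .config import THREE_TO_ONE, WATER_NAMES
from .errors import (AlignmentShapeError, EmptyChainError, EmptyInputError,
                     FormatError, MissingChainError,
                     SequenceStructureMismatchError)
from .types import (GAP, AlignedSequence, Alignment, Atom, ChainStructure,
                    Residue)

_STRUCTURE_TAGS = {"structure", "structureX", "structureN", "structureS"}


def _normalize_gaps(seq: str) -> str:
    return seq.replace(".", GAP).upper()


def parse_fasta(text: str, max_sequences: int = 25) -> Alignment:
    """Parse an aligned FASTA stream; every record gets role ``sequence``
    (roles are upgraded when structures are attached)."""
    if not text.strip():
        raise EmptyInputError("empty FASTA input")
    records = list(SeqIO.parse(_io.StringIO(text), "fasta"))
    if not records:
        raise EmptyInputError("no FASTA records found")
    seqs = [AlignedSequence(seq_id=r.id, role="sequence",
                            gapped=_normalize_gaps(str(r.seq)))
            for r in records]
    _check_shape(seqs)
    return Alignment(seqs, max_sequences=max_sequences)


def _check_shape(seqs: list[AlignedSequence]) -> None:
    n = len(seqs[0].gapped)
    for s in seqs:
        if len(s.gapped) != n:
            raise AlignmentShapeError(
                f"record {s.seq_id!r} has length {len(s.gapped)}, expected {n}")


def _role_from_tag(tag: str, seq_id: str) -> str:
    if tag == "structureM":
        return "model"
    if tag in _STRUCTURE_TAGS:
        return "structure"
    if tag == "sequence":
        return "sequence"
    raise FormatError(f"record {seq_id!r}: unknown PIR role tag {tag!r}")


def parse_pir(text: str, max_sequences: int = 25) -> Alignment:
    """Parse a PIR/ALI alignment (full or simplified dialect)."""
    if not text.strip():
        raise EmptyInputError("empty PIR input")
    lines = text.splitlines()
    seqs: list[AlignedSequence] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise FormatError(f"expected a '>' header line, got {line!r}")
        if ";" not in line:
            raise FormatError(f"PIR header missing ';': {line!r}")
        seq_id = line.split(";", 1)[1].strip()
        if not seq_id:
            raise FormatError("PIR header with empty sequence id")
        i += 1
        if i >= len(lines):
            raise FormatError(f"record {seq_id!r}: missing description line")
        desc = lines[i].strip()
        tag = desc.split(":", 1)[0].strip()
        role = _role_from_tag(tag, seq_id)
        i += 1
        body: list[str] = []
        terminated = False
        while i < len(lines):
            chunk = lines[i].strip()
            if chunk.startswith(">"):
                break
            i += 1
            if "*" in chunk:
                body.append(chunk[:chunk.index("*")])
                terminated = True
                break
            body.append(chunk)
        if not terminated:
            raise FormatError(f"record {seq_id!r}: missing '*' terminator")
        gapped = _normalize_gaps("".join(body))
        seqs.append(AlignedSequence(seq_id=seq_id, role=role, gapped=gapped))
    if not seqs:
        raise EmptyInputError("no PIR records found")
    _check_shape(seqs)
    return Alignment(seqs, max_sequences=max_sequences)


_ROLE_TO_TAG = {"structure": "structure", "model": "structureM",
                "sequence": "sequence"}


def write_pir(aln: Alignment, wrap: int = 60) -> str:
    """Serialize the alignment in the simplified PIR dialect; round-trips
    seq_ids, roles, and gapped sequences exactly."""
    if not aln.sequences:
        raise EmptyInputError("cannot write an empty alignment")
    out: list[str] = []
    for s in aln.sequences:
        out.append(f">P1;{s.seq_id}")
        out.append(f"{_ROLE_TO_TAG[s.role]}:{s.seq_id}::::::::")
        body = s.gapped + "*"
        for k in range(0, len(body), wrap):
            out.append(body[k:k + wrap])
        out.append("")
    return "\n".join(out)


def _one_letter(resname: str) -> str:
    return THREE_TO_ONE.get(resname.upper(), "X")


def _residues_from_gemmi(chain: gemmi.Chain) -> list[Residue]:
    residues = []
    for res in chain:
        # polymer residue: ATOM record, or MSE (selenomethionine appears as
        # HETATM but is read as methionine)
        if res.het_flag != "A" and res.name.upper() != "MSE":
            continue
        atoms = []
        seen: set[str] = set()
        for at in res:
            if at.name in seen:  # first altloc kept
                continue
            seen.add(at.name)
            atoms.append(Atom(name=at.name, element=at.element.name.upper(),
                              coord=np.array([at.pos.x, at.pos.y, at.pos.z])))
        if not atoms:
            continue
        seq_id = f"{res.seqid.num}{res.seqid.icode}".strip()
        residues.append(Residue(three_letter=res.name.upper(),
                                one_letter=_one_letter(res.name),
                                seq_id=seq_id, atoms=atoms))
    return residues


def parse_pdb_chain(text: str, chain_id: str, source_id: str = "") -> ChainStructure:
    """Read one polymer chain from PDB-format text.

    First altloc per atom is kept, MSE is treated as MET, non-water HETATM
    groups become hetero groups, and all other polymer chains are retained for
    interface analysis.
    """
    st = gemmi.read_pdb_string(text)
    st.remove_alternative_conformations()
    if len(st) == 0:
        raise EmptyChainError("PDB file contains no models")
    model = st[0]
    names = [ch.name for ch in model]
    if chain_id not in names:
        raise MissingChainError(
            f"chain {chain_id!r} not present (available: {', '.join(names) or 'none'})")
    residues: list[Residue] = []
    hetero: list[tuple[str, list[Atom]]] = []
    others: list[tuple[str, list[Residue]]] = []
    for ch in model:
        chain_res = _residues_from_gemmi(ch)
        if ch.name == chain_id:
            residues = chain_res
        elif chain_res:
            others.append((ch.name, chain_res))
        # hetero groups (ligands) collected file-wide, waters excluded
        for res in ch:
            if res.het_flag == "H" and res.name.upper() not in WATER_NAMES \
                    and res.name.upper() != "MSE":
                atoms = []
                seen: set[str] = set()
                for at in res:
                    if at.name in seen:
                        continue
                    seen.add(at.name)
                    atoms.append(Atom(name=at.name,
                                      element=at.element.name.upper(),
                                      coord=np.array([at.pos.x, at.pos.y, at.pos.z])))
                if atoms:
                    hetero.append((res.name.upper(), atoms))
    if not residues:
        raise EmptyChainError(f"chain {chain_id!r} has no polymer residues")
    return ChainStructure(source_id=source_id or chain_id, chain_id=chain_id,
                          residues=residues, hetero_groups=hetero,
                          other_chains=others)


def match_alignment_to_structures(aln: Alignment,
                                  structs: Iterable[ChainStructure]) -> Alignment:
    """Attach each structure to the aligned sequence whose id equals its
    ``source_id`` and enforce the identity of the ungapped alignment sequence
    with the observed ATOM-record sequence (X in the alignment matches any
    structure residue).  Idempotent."""
    by_id = {s.source_id: s for s in structs}
    for seq in aln.sequences:
        if seq.role in ("structure", "model"):
            st = seq.structure if seq.structure is not None else by_id.get(seq.seq_id)
            if st is None:
                raise MissingChainError(
                    f"no structure provided for {seq.role}-role sequence "
                    f"{seq.seq_id!r}")
            _check_identity(seq.seq_id, seq.ungapped, st.sequence)
            seq.structure = st
        elif seq.seq_id in by_id and seq.structure is None:
            st = by_id[seq.seq_id]
            _check_identity(seq.seq_id, seq.ungapped, st.sequence)
            seq.structure = st
            seq.role = "structure"
    return aln


def _check_identity(seq_id: str, aln_seq: str, struct_seq: str) -> None:
    n = min(len(aln_seq), len(struct_seq))
    for k in range(n):
        if aln_seq[k] != struct_seq[k] and aln_seq[k] != "X":
            raise SequenceStructureMismatchError(seq_id, k + 1, aln_seq[k],
                                                 struct_seq[k])
    if len(aln_seq) != len(struct_seq):
        pos = n + 1
        a = aln_seq[n] if len(aln_seq) > n else "-"
        b = struct_seq[n] if len(struct_seq) > n else "-"
        raise SequenceStructureMismatchError(seq_id, pos, a, b)


# --- minimal PDB writer (used to export fixtures and superposed structures) --

def write_pdb(struct: ChainStructure, include_others: bool = True,
              include_hetero: bool = True) -> str:
    """Serialize a ChainStructure as PDB-format text."""
    lines: list[str] = []
    serial = 1

    def emit(record: str, res_name: str, chain: str, res_num: str, atom: Atom):
        nonlocal serial
        num = res_num
        icode = " "
        if num and not num[-1].isdigit():
            icode = num[-1]
            num = num[:-1]
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
        lines.append(
            f"{record:<6s}{serial:5d} {name:<4s} {res_name:<3s} {chain:1s}"
            f"{int(num):4d}{icode}   {atom.coord[0]:8.3f}{atom.coord[1]:8.3f}"
            f"{atom.coord[2]:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f"{atom.element:>2s}")
        serial += 1

    def emit_chain(chain_id: str, residues: list[Residue]):
        for res in residues:
            for at in res.atoms:
                emit("ATOM", res.three_letter, chain_id, res.seq_id, at)
        lines.append("TER")

    emit_chain(struct.chain_id, struct.residues)
    if include_others:
        for cid, residues in struct.other_chains:
            emit_chain(cid, residues)
    if include_hetero:
        for lig_num, (name, atoms) in enumerate(struct.hetero_groups, start=1):
            for at in atoms:
                emit("HETATM", name, "Z", str(lig_num), at)
    lines.append("END")
    return "\n".join(lines) + "\n"
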