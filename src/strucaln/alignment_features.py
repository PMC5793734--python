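"""Alignment-level annotations: gap-aware normalized Shannon entropy and its
symbol row, secondary-structure consensus, percentage sequence identity,
multi-structure superposition, and per-column Cα RMSD with its bin symbols.

Entropy per column i is

    S_i = -Σ_{a=1..20} f_{i,a} · log_n f_{i,a}  +  f_{i,gap}

with f the relative frequencies over all N sequences (gaps in the
denominator), n = min(20, N), and the gap frequency added linearly (the Zhang
gap treatment).  S is 0 for a totally conserved ungapped column and 1 when
all residues differ; it is clamped to [0, 1] against floating-point drift.

The multi-structure superposition follows the maximum-likelihood rationale of
down-weighting flexible regions: an iterative generalized Procrustes fit in
which each column's weight is the inverse of its coordinate variance about
the mean structure (ε = 1e-6 Å² regularizer), iterated to convergence.
"""
from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .config import STANDARD_AA
from .errors import SuperpositionError
from .geometry import kabsch
from .types import (GAP, AlignedSequence, Alignment, ChainStructure,
                    ColumnAnnotation, SuperpositionResult)

_EPS_VARIANCE = 1e-6   # Å², weight regularizer
_CONV_TOL = 1e-6       # Å, mean-structure shift declaring convergence
_MAX_ITER = 100


# -------------------------------------------------------------------- entropy

def column_frequencies(aln: Alignment, i: int) -> tuple[dict[str, float], float]:
    """Relative frequencies at 1-based column ``i``: (per-letter dict, gap
    frequency).  All N sequences count in the denominator; nonstandard letters
    (X) appear in the dict but are excluded from the entropy sum."""
    col = aln.column(i)
    n = len(col)
    freqs: dict[str, float] = {}
    gaps = 0
    for ch in col:
        if ch == GAP:
            gaps += 1
        else:
            freqs[ch] = freqs.get(ch, 0.0) + 1.0
    for k in freqs:
        freqs[k] /= n
    return freqs, gaps / n


def shannon_entropy(freqs: dict[str, float], f_gap: float, n_seqs: int) -> float:
    """Normalized gap-aware Shannon entropy in [0, 1]; 0 by convention for a
    single-sequence alignment (the log base is undefined there)."""
    n = min(20, n_seqs)
    if n < 2:
        return 0.0
    log_n = math.log(n)
    s = 0.0
    for a, f in freqs.items():
        if a in STANDARD_AA and f > 0.0:
            s -= f * math.log(f) / log_n
    s += f_gap
    return min(1.0, max(0.0, s))


def entropy_symbol(s: float) -> str:
    """Display symbol: '*' only for S = 0, then '0' for 0 < S ≤ 0.1, '1' for
    0.1 < S ≤ 0.2, ... '9' for 0.9 < S ≤ 1."""
    if s == 0.0:
        return "*"
    k = math.ceil(10.0 * s) - 1
    return str(min(9, max(0, k)))


def column_entropy(aln: Alignment, i: int) -> float:
    freqs, f_gap = column_frequencies(aln, i)
    return shannon_entropy(freqs, f_gap, len(aln))


# ------------------------------------------------------------------ consensus

_SS_TO_CONSENSUS = {"H": "a", "E": "b", "G": "3"}


def consensus_ss(aln: Alignment, i: int, threshold: float = 0.70) -> str:
    """Consensus symbol at 1-based column ``i``: 'a'/'b'/'3' when at least
    ``threshold`` of the structure/model sequences (gaps diluting the
    denominator) share the α/β/3₁₀ class, else ''."""
    participants = [s for s in aln.sequences
                    if s.role in ("structure", "model")
                    and s.residue_annotations is not None]
    if not participants:
        return ""
    counts = {"H": 0, "E": 0, "G": 0}
    for s in participants:
        ri = s.residue_index_at_column(i)
        if ri is None:
            continue
        ss = s.residue_annotations[ri].ss
        if ss in counts:
            counts[ss] += 1
    denom = len(participants)
    for cls, symbol in _SS_TO_CONSENSUS.items():
        if counts[cls] / denom >= threshold:
            return symbol
    return ""


# ------------------------------------------------------------------------ PID

def percent_identity(query: AlignedSequence, target: AlignedSequence
                     ) -> tuple[float, int]:
    """Percentage identity over columns where both rows hold a residue,
    rounded to one decimal; returns (pid, n_shared_columns) — pid is 0.0 with
    n_shared 0 when the rows never overlap."""
    if len(query.gapped) != len(target.gapped):
        raise ValueError("sequences come from different alignments")
    shared = matches = 0
    for a, b in zip(query.gapped, target.gapped):
        if a != GAP and b != GAP:
            shared += 1
            if a == b:
                matches += 1
    if shared == 0:
        return 0.0, 0
    return round(100.0 * matches / shared, 1), shared


# -------------------------------------------------------------- superposition

def _ca_by_column(seq: AlignedSequence) -> dict[int, np.ndarray]:
    """Map 1-based alignment column -> Cα coordinate for one structure row."""
    out: dict[int, np.ndarray] = {}
    st = seq.structure
    if st is None:
        return out
    for col in range(1, len(seq.gapped) + 1):
        ri = seq.residue_index_at_column(col)
        if ri is None or ri >= len(st.residues):
            continue
        ca = st.residues[ri].atom("CA")
        if ca is not None:
            out[col] = ca.coord
    return out


def superpose(structs: list[AlignedSequence], aln: Alignment) -> SuperpositionResult:
    """Variance-weighted generalized Procrustes superposition of all
    structure/model rows over the columns where every one of them has a Cα.

    Iteration: unit-weight fit of each structure onto the running mean,
    per-column variance about the mean, weights 1/(variance + ε), refit, until
    the mean structure moves less than 1e-6 Å (or 100 iterations).
    Deterministic.
    """
    rows = [s for s in structs if s.structure is not None]
    if len(rows) < 2:
        raise SuperpositionError("at least two structures are required")
    ca_maps = {s.seq_id: _ca_by_column(s) for s in rows}
    shared = sorted(set.intersection(*(set(m) for m in ca_maps.values())))
    if len(shared) < 3:
        raise SuperpositionError(
            f"only {len(shared)} columns are shared by all structures; "
            "at least 3 are required")
    ids = [s.seq_id for s in rows]
    X = {sid: np.array([ca_maps[sid][c] for c in shared]) for sid in ids}
    m = len(shared)
    weights = np.ones(m)
    rotations: dict[str, np.ndarray] = {}
    translations: dict[str, np.ndarray] = {}
    # initial fit onto the first structure
    ref = X[ids[0]]
    for sid in ids:
        R, t = kabsch(X[sid], ref, weights)
        rotations[sid], translations[sid] = R, t
    mean = np.mean([X[sid] @ rotations[sid].T + translations[sid]
                    for sid in ids], axis=0)
    n_iter = 0
    for n_iter in range(1, _MAX_ITER + 1):
        transformed = np.stack([X[sid] @ rotations[sid].T + translations[sid]
                                for sid in ids])
        var = np.mean(np.sum((transformed - mean) ** 2, axis=2), axis=0)
        weights = 1.0 / (var + _EPS_VARIANCE)
        for sid in ids:
            R, t = kabsch(X[sid], mean, weights)
            rotations[sid], translations[sid] = R, t
        new_mean = np.mean([X[sid] @ rotations[sid].T + translations[sid]
                            for sid in ids], axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if shift < _CONV_TOL:
            break
    # superposed Cα coordinates for every column where >= 1 structure present
    column_coords: dict[int, dict[str, np.ndarray]] = {}
    for sid in ids:
        R, t = rotations[sid], translations[sid]
        for col, xyz in ca_maps[sid].items():
            column_coords.setdefault(col, {})[sid] = xyz @ R.T + t
    return SuperpositionResult(
        ids=ids, rotations=rotations, translations=translations,
        column_coords=column_coords,
        weights={c: float(w) for c, w in zip(shared, weights)},
        n_iterations=n_iter)


def column_rmsd(sup: SuperpositionResult, aln: Alignment, i: int
                ) -> Optional[float]:
    """All-pairs Cα RMSD at 1-based column ``i``:
    sqrt(mean over unordered structure pairs of the squared inter-Cα
    distance); None when fewer than two structures occupy the column."""
    coords = sup.column_coords.get(i, {})
    pts = list(coords.values())
    if len(pts) < 2:
        return None
    sq = [float(np.sum((pts[a] - pts[b]) ** 2))
          for a in range(len(pts)) for b in range(a + 1, len(pts))]
    return math.sqrt(sum(sq) / len(sq))


def rmsd_bin(rmsd: float, edges: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0)) -> int:
    """Bin index 0..len(edges) with strict upper bounds: [0,2) → 0, [2,4) → 1,
    [4,6) → 2, [6,8) → 3, ≥8 → 4 for the default edges."""
    if rmsd < 0:
        raise ValueError("negative RMSD")
    for k, edge in enumerate(edges):
        if rmsd < edge:
            return k
    return len(edges)


def superposed_structure(sup: SuperpositionResult, seq: AlignedSequence
                         ) -> ChainStructure:
    """Copy of a structure with all atoms moved into the common frame."""
    import copy
    st = copy.deepcopy(seq.structure)
    R = sup.rotations[seq.seq_id]
    t = sup.translations[seq.seq_id]
    for res in st.residues:
        for at in res.atoms:
            at.coord = at.coord @ R.T + t
    for _, residues in st.other_chains:
        for res in residues:
            for at in res.atoms:
                at.coord = at.coord @ R.T + t
    for _, atoms in st.hetero_groups:
        for at in atoms:
            at.coord = at.coord @ R.T + t
    return st


# ------------------------------------------------------------- column bundle

def annotate_columns(aln: Alignment, sup: Optional[SuperpositionResult],
                     consensus_threshold: float = 0.70,
                     rmsd_edges: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0)
                     ) -> list[ColumnAnnotation]:
    """Assemble the per-column annotation track for the whole alignment."""
    out = []
    for i in range(1, aln.n_columns + 1):
        s = column_entropy(aln, i)
        rmsd = column_rmsd(sup, aln, i) if sup is not None else None
        out.append(ColumnAnnotation(
            entropy=s,
            entropy_symbol=entropy_symbol(s),
            consensus_ss=consensus_ss(aln, i, consensus_threshold),
            rmsd=rmsd,
            rmsd_bin=None if rmsd is None else rmsd_bin(rmsd, rmsd_edges),
        ))
    return out
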