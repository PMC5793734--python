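"""Deterministic generators for test inputs: ideal secondary-structure
geometries, toy complexes, and toy alignments with matching perturbed
structures.

All generators are pure functions of their arguments (plus an explicit seed
for the random alignment builder), so every fixture is bit-reproducible.
Backbones are built by natural-extension placement from the ideal bond
lengths and angles frozen in :mod:`strucaln.config`.
"""
from __future__ import annotations

import functools
import math
from typing import Optional

import numpy as np

from .config import (ANGLE_C_N_CA, ANGLE_CA_C_N, ANGLE_CA_C_O, ANGLE_N_CA_C,
                     ANGLE_N_CA_CB, BOND_C_N, BOND_C_O, BOND_CA_C, BOND_CA_CB,
                     BOND_N_CA, OMEGA_TRANS, ONE_TO_THREE, STANDARD_AA)
from .geometry import place_atom, unit
from .types import (AlignedSequence, Alignment, Atom, ChainStructure, Residue)


def _element_of(atom_name: str) -> str:
    return atom_name[0]


def _backbone_chain(n_res: int, phi: float, psi: float) -> list[dict]:
    """N/CA/C/O/CB coordinates of an ideal poly-peptide at fixed torsions."""
    # seed triad for residue 1
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    residues = [{"N": n0, "CA": ca0, "C": c0}]
    for i in range(1, n_res):
        prev = residues[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N,
                       ANGLE_CA_C_N, psi)
        ca = place_atom(prev["CA"], prev["C"], n, BOND_N_CA,
                        ANGLE_C_N_CA, OMEGA_TRANS)
        c = place_atom(prev["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
        residues.append({"N": n, "CA": ca, "C": c})
    # carbonyl O trans to the following amide N; CB tetrahedral off CA
    for i, r in enumerate(residues):
        r["O"] = place_atom(r["N"], r["CA"], r["C"], BOND_C_O, ANGLE_CA_C_O,
                            psi + 180.0)
        b1 = unit(r["N"] - r["CA"])
        b2 = unit(r["C"] - r["CA"])
        bisector = unit(b1 + b2)
        perp = unit(np.cross(b2, b1))
        # out-of-plane tilt chosen so both N-CA-CB and C-CA-CB equal the
        # ideal tetrahedral-like angle
        half = math.radians(ANGLE_N_CA_C) / 2.0
        theta = math.acos(math.cos(math.radians(ANGLE_N_CA_CB))
                          / -math.cos(half))
        r["CB"] = r["CA"] + BOND_CA_CB * (
            -bisector * math.cos(theta) + perp * math.sin(theta))
    return residues


def _make_residue(coords: dict, one_letter: str, seq_id: str) -> Residue:
    names = ["N", "CA", "C", "O"] if one_letter == "G" else ["N", "CA", "C", "O", "CB"]
    atoms = [Atom(name=n, element=_element_of(n), coord=coords[n]) for n in names]
    return Residue(three_letter=ONE_TO_THREE.get(one_letter, "UNK"),
                   one_letter=one_letter, seq_id=seq_id, atoms=atoms)


def make_ideal_helix(n_res: int, phi: float = -57.0, psi: float = -47.0,
                     sequence: Optional[str] = None,
                     source_id: str = "helix", chain_id: str = "A",
                     start_number: int = 1) -> ChainStructure:
    """Ideal poly-Ala helix (or any torsion pair) of ``n_res`` residues."""
    if n_res < 1:
        raise ValueError("n_res must be positive")
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length must equal n_res")
    chain = _backbone_chain(n_res, phi, psi)
    residues = [_make_residue(c, aa, str(start_number + i))
                for i, (c, aa) in enumerate(zip(chain, sequence))]
    return ChainStructure(source_id=source_id, chain_id=chain_id,
                          residues=residues)


def make_extended_strand(n_res: int, source_id: str = "strand",
                         phi: float = -139.0, psi: float = 135.0
                         ) -> ChainStructure:
    """A single extended strand with no hydrogen-bonding partner."""
    return make_ideal_helix(n_res, phi=phi, psi=psi, source_id=source_id)


def _amide_h_positions(chain: list[dict]) -> list[Optional[np.ndarray]]:
    """Geometric amide H of each residue (1 Å from N, anti to the preceding
    carbonyl); None for the first residue of the strand."""
    out: list[Optional[np.ndarray]] = [None]
    for i in range(1, len(chain)):
        out.append(chain[i]["N"] + unit(chain[i - 1]["C"] - chain[i - 1]["O"]))
    return out


def _count_directed_pairs(res_a: list[dict], h_a: list, res_b: list[dict],
                          h_b: list) -> tuple[int, float]:
    """Inter-strand N-H...O=C pairs with donor-acceptor distance near 2.9 Å
    and the H pointing at the acceptor (H-N-O angle below 45°)."""
    count, dev = 0, 0.0

    def directed(donor, h, acceptor):
        d = float(np.linalg.norm(donor["N"] - acceptor["O"]))
        if not 2.7 <= d <= 3.1 or h is None:
            return None
        cosang = float(np.dot(unit(h - donor["N"]),
                              unit(acceptor["O"] - donor["N"])))
        if cosang < math.cos(math.radians(45.0)):
            return None
        return d

    for i, ra in enumerate(res_a):
        for j, rb in enumerate(res_b):
            for donor, h, acceptor in ((ra, h_a[i], rb), (rb, h_b[j], ra)):
                d = directed(donor, h, acceptor)
                if d is not None:
                    count += 1
                    dev += abs(d - 2.9)
    return count, dev


def _canonical_strand(n_res: int, phi: float, psi: float) -> list[dict]:
    """Extended strand rotated into a canonical frame: Cα axis along x and
    the hydrogen-bonding direction (carbonyl of residue 2) along y."""
    chain = _backbone_chain(n_res, phi, psi)
    u = unit(chain[-1]["CA"] - chain[0]["CA"])
    v0 = unit(chain[1]["O"] - chain[1]["C"])
    v = unit(v0 - np.dot(v0, u) * u)
    w = np.cross(u, v)
    R = np.stack([u, v, w])
    origin = chain[0]["CA"].copy()
    return [{k: R @ (p - origin) for k, p in r.items()} for r in chain]


@functools.lru_cache(maxsize=8)
def _hairpin_offset(n_per_strand: int) -> tuple[float, float, float]:
    """Grid-search the rigid offset of the antiparallel partner strand that
    maximises the number of well-oriented inter-strand N-H...O pairs."""
    chain = _canonical_strand(n_per_strand, -139.0, 135.0)
    flipped = _flip_strand(chain)
    h_a = _amide_h_positions(chain)
    h_b = _amide_h_positions(flipped)
    span = float(chain[-1]["CA"][0] - chain[0]["CA"][0])
    ca_a = np.array([r["CA"] for r in chain])
    ca_b0 = np.array([r["CA"] for r in flipped])
    best = (0, math.inf, (span, 4.8, 0.0))
    for dx in np.arange(span - 6.0, span + 6.01, 0.2):
        for dy in np.arange(-6.5, 6.51, 0.1):
            for dz in np.arange(-2.0, 2.01, 0.5):
                off = np.array([dx, dy, dz])
                clash = float(np.min(np.linalg.norm(
                    ca_a[:, None, :] - (ca_b0 + off)[None, :, :], axis=2)))
                if clash < 3.8:
                    continue
                moved = [{k: v + off for k, v in r.items()} for r in flipped]
                h_m = [None if h is None else h + off for h in h_b]
                count, dev = _count_directed_pairs(chain, h_a, moved, h_m)
                key = (-count, dev)
                if key < (best[0], best[1]):
                    best = (key[0], key[1], (float(dx), float(dy), float(dz)))
    return best[2]


def _flip_strand(chain: list[dict]) -> list[dict]:
    """180° rotation about z: the copy runs antiparallel to the original."""
    R = np.diag([-1.0, -1.0, 1.0])
    return [{k: R @ v for k, v in r.items()} for r in chain]


def make_beta_hairpin(n_per_strand: int = 6, source_id: str = "hairpin"
                      ) -> ChainStructure:
    """Two-strand antiparallel β-sheet as one chain with a numbering break in
    place of the turn; inter-strand register is optimised geometrically so the
    backbone N-H/C=O pairs sit at hydrogen-bonding distance."""
    chain = _canonical_strand(n_per_strand, -139.0, 135.0)
    off = np.array(_hairpin_offset(n_per_strand))
    partner = [{k: v + off for k, v in r.items()} for r in _flip_strand(chain)]
    residues = [_make_residue(c, "A", str(i + 1))
                for i, c in enumerate(chain)]
    residues += [_make_residue(c, "A", str(n_per_strand + 3 + i))
                 for i, c in enumerate(partner)]
    return ChainStructure(source_id=source_id, chain_id="A", residues=residues)


def _min_heavy_distance(res_a: list[Residue], coords_b: np.ndarray) -> float:
    pts_a = np.array([a.coord for r in res_a for a in r.atoms])
    d = np.linalg.norm(pts_a[:, None, :] - coords_b[None, :, :], axis=2)
    return float(d.min())


def make_toy_dimer(gap: float = 4.5, n_res: int = 3) -> ChainStructure:
    """Two identical short chains whose minimum heavy-atom separation equals
    ``gap`` (Å) to within 0.01, for interface-contact tests."""
    base = make_ideal_helix(n_res, phi=-139.0, psi=135.0, sequence="G" * n_res,
                            source_id="dimer")
    coords = np.array([a.coord for r in base.residues for a in r.atoms])

    def chain_b_at(delta: float) -> list[Residue]:
        out = []
        for r in base.residues:
            atoms = [Atom(name=a.name, element=a.element,
                          coord=a.coord + np.array([0.0, delta, 0.0]))
                     for a in r.atoms]
            out.append(Residue(three_letter=r.three_letter,
                               one_letter=r.one_letter, seq_id=r.seq_id,
                               atoms=atoms))
        return out

    lo, hi = gap, gap + 20.0
    for _ in range(60):  # bisection: min distance is monotone in the offset
        mid = 0.5 * (lo + hi)
        m = _min_heavy_distance(
            base.residues,
            coords + np.array([0.0, mid, 0.0]))
        if m < gap:
            lo = mid
        else:
            hi = mid
    return ChainStructure(source_id="dimer", chain_id="A",
                          residues=base.residues,
                          other_chains=[("B", chain_b_at(hi))])


def make_toy_ligand_complex(dist: float = 4.9, n_res: int = 5,
                            ligand_name: str = "LIG") -> ChainStructure:
    """Helix plus a one-atom ligand whose minimum distance to the chain's
    heavy atoms equals ``dist`` (Å) to within 0.01."""
    base = make_ideal_helix(n_res, source_id="ligcplx")
    coords = np.array([a.coord for r in base.residues for a in r.atoms])
    center = coords.mean(axis=0)
    anchor = base.residues[n_res // 2].atom("CA").coord
    direction = unit(anchor - center) if np.linalg.norm(anchor - center) > 1e-6 \
        else np.array([0.0, 1.0, 0.0])
    lo, hi = 0.0, dist + 30.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        p = anchor + direction * mid
        m = float(np.min(np.linalg.norm(coords - p, axis=1)))
        if m < dist:
            lo = mid
        else:
            hi = mid
    lig = Atom(name="O1", element="O", coord=anchor + direction * hi)
    base.hetero_groups = [(ligand_name, [lig])]
    return base


def make_hinge_pair(n_res: int = 30, displacement: float = 10.0,
                    core_fraction: float = 2.0 / 3.0) -> Alignment:
    """Two-structure alignment for superposition tests: identical helices,
    with the trailing (1 - core_fraction) of copy 2 rigidly displaced by
    ``displacement`` Å.  Core columns are 1..round(core_fraction*n_res); the
    core is the majority domain so the variance-weighted fit should lock onto
    it."""
    a = make_ideal_helix(n_res, source_id="copy1")
    b = make_ideal_helix(n_res, source_id="copy2")
    n_core = round(core_fraction * n_res)
    shift = np.array([0.0, 0.0, displacement])
    for res in b.residues[n_core:]:
        for at in res.atoms:
            at.coord = at.coord + shift
    seqs = [AlignedSequence(seq_id="copy1", role="structure",
                            gapped=a.sequence, structure=a),
            AlignedSequence(seq_id="copy2", role="structure",
                            gapped=b.sequence, structure=b)]
    return Alignment(seqs)


_PROFILES = ("conserved", "all-different", "random", "mixed")


def make_toy_alignment(n_seq: int, n_col: int, seed: int = 0,
                       conservation_profile: str = "conserved",
                       gap_rate: float = 0.0,
                       with_structures: bool = False,
                       noise_sigma: float = 0.0) -> Alignment:
    """Seeded random alignment drawn per-column from a conservation profile.

    Profiles: ``conserved`` (one letter per column), ``all-different``
    (n_seq distinct letters per column; requires n_seq ≤ 20), ``random``
    (uniform letters), ``mixed`` (alternating conserved / random columns).
    With ``with_structures`` every row becomes a structure-role sequence
    backed by an ideal helix of its ungapped sequence, with optional Gaussian
    coordinate noise of ``noise_sigma`` Å.
    """
    if conservation_profile not in _PROFILES:
        raise ValueError(f"unknown profile {conservation_profile!r}")
    if conservation_profile == "all-different" and n_seq > 20:
        raise ValueError("all-different profile requires n_seq <= 20")
    rng = np.random.default_rng(seed)
    aas = list(STANDARD_AA)
    rows = [[] for _ in range(n_seq)]
    for j in range(n_col):
        if conservation_profile == "conserved" or \
                (conservation_profile == "mixed" and j % 2 == 0):
            letter = aas[rng.integers(20)]
            col = [letter] * n_seq
        elif conservation_profile == "all-different":
            col = list(rng.choice(aas, size=n_seq, replace=False))
        else:
            col = [aas[rng.integers(20)] for _ in range(n_seq)]
        for k in range(n_seq):
            rows[k].append(col[k])
    if gap_rate > 0.0:
        for j in range(n_col):
            for k in range(n_seq):
                if rng.random() < gap_rate:
                    rows[k][j] = "-"
            if all(rows[k][j] == "-" for k in range(n_seq)):
                rows[rng.integers(n_seq)][j] = aas[rng.integers(20)]
    seqs = []
    for k in range(n_seq):
        gapped = "".join(rows[k])
        seq = AlignedSequence(seq_id=f"seq{k + 1}", role="sequence",
                              gapped=gapped)
        if with_structures:
            ungapped = seq.ungapped
            st = make_ideal_helix(len(ungapped), sequence=ungapped,
                                  source_id=seq.seq_id)
            if noise_sigma > 0.0:
                for res in st.residues:
                    for at in res.atoms:
                        at.coord = at.coord + rng.normal(0.0, noise_sigma, 3)
            seq.structure = st
            seq.role = "structure"
        seqs.append(seq)
    return Alignment(seqs, max_sequences=max(25, n_seq))
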