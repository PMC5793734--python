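"""Per-residue structural features of a single chain.

Implements sphere-sampling solvent accessibility (Shrake–Rupley with a
deterministic golden-spiral point set), burial classification against the
extended-tripeptide reference areas, hydrogen-bond-energy secondary-structure
assignment in the Kabsch–Sander style (α-helix, 3₁₀ helix, β-strand), backbone
torsions, sidechain→mainchain hydrogen bonds, sampled-surface residue depth,
intra-chain heavy-atom contacts, and chain/ligand interface membership.
"""
from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .config import (DEFAULT_VDW_RADIUS, MAX_SASA_GLY_X_GLY, PEPTIDE_BOND_MAX,
                     VDW_RADII, AnnotationParams, DEFAULT_PARAMS)
from .geometry import dihedral, sphere_points, unit
from .types import Atom, ChainStructure, Residue, ResidueAnnotation

MAINCHAIN_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

#: Sidechain polar atoms that can accept a hydrogen bond from a mainchain
#: amide N-H, per residue type.
SIDECHAIN_ACCEPTORS = {
    "S": ("OG",), "T": ("OG1",), "Y": ("OH",),
    "N": ("OD1",), "Q": ("OE1",),
    "D": ("OD1", "OD2"), "E": ("OE1", "OE2"),
    "H": ("ND1", "NE2"),
}
#: Sidechain polar atoms that can donate a hydrogen bond to a mainchain
#: carbonyl O.
SIDECHAIN_DONORS = {
    "S": ("OG",), "T": ("OG1",), "Y": ("OH",),
    "N": ("ND2",), "Q": ("NE2",),
    "K": ("NZ",), "R": ("NE", "NH1", "NH2"),
    "H": ("ND1", "NE2"), "W": ("NE1",),
}


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


# ---------------------------------------------------------------- SASA / depth

def _flat_atoms(struct: ChainStructure) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """All heavy atoms of the chain: coords, expanded radii, residue index."""
    coords, radii, res_idx = [], [], []
    for i, res in enumerate(struct.residues):
        for at in res.atoms:
            if at.element.upper() == "H":
                continue
            coords.append(at.coord)
            radii.append(vdw_radius(at.element))
            res_idx.append(i)
    return np.asarray(coords, dtype=float), np.asarray(radii, dtype=float), res_idx


def _sample_surface(coords: np.ndarray, radii: np.ndarray, probe_radius: float,
                    n_points: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Shrake–Rupley sampling on the probe-expanded spheres.

    Returns per-atom accessible areas and, per atom, the retained (solvent
    exposed) sample points — the discretized accessible surface reused by the
    depth computation.
    """
    n_atoms = len(coords)
    pts = sphere_points(n_points)
    R = radii + probe_radius
    areas = np.zeros(n_atoms)
    exposed: list[np.ndarray] = []
    tree = cKDTree(coords)
    rmax = R.max() if n_atoms else 0.0
    for i in range(n_atoms):
        sample = coords[i] + R[i] * pts
        keep = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], R[i] + rmax):
            if j == i:
                continue
            d2 = np.sum((sample - coords[j]) ** 2, axis=1)
            keep &= d2 > R[j] ** 2
        frac = keep.sum() / n_points
        areas[i] = 4.0 * math.pi * R[i] ** 2 * frac
        exposed.append(sample[keep])
    return areas, exposed


def compute_sasa(struct: ChainStructure, probe_radius: float = 1.4,
                 n_sphere_points: int = 256) -> list[Optional[float]]:
    """Per-residue solvent-accessible surface area (Å²) of the chain in
    isolation; None for residues without heavy atoms."""
    coords, radii, res_idx = _flat_atoms(struct)
    out: list[Optional[float]] = [None] * len(struct.residues)
    if len(coords) == 0:
        return out
    areas, _ = _sample_surface(coords, radii, probe_radius, n_sphere_points)
    totals = np.zeros(len(struct.residues))
    seen = np.zeros(len(struct.residues), dtype=bool)
    for a, i in zip(areas, res_idx):
        totals[i] += a
        seen[i] = True
    for i in range(len(struct.residues)):
        out[i] = float(totals[i]) if seen[i] else None
    return out


def classify_burial(residue_sasa: Optional[float], residue_name: str,
                    threshold_pct: float = 7.0) -> tuple[Optional[float], bool]:
    """Relative accessibility (%) against the extended Gly-X-Gly reference and
    the burial flag (strict less-than at the threshold)."""
    if residue_sasa is None:
        return None, False
    ref = MAX_SASA_GLY_X_GLY.get(residue_name.upper())
    if ref is None:
        return None, False
    rel = 100.0 * residue_sasa / ref
    return rel, rel < threshold_pct


def compute_residue_depth(struct: ChainStructure, probe_radius: float = 1.4,
                          n_sphere_points: int = 256) -> list[Optional[float]]:
    """Mean distance (Å) of each residue's heavy atoms to the sampled
    accessible surface.

    The surface is the set of retained probe-sphere sample points from the
    accessibility computation; the depth of an atom is its minimum distance to
    that point set, so a fully exposed atom has depth ≈ r_vdw + probe.
    """
    coords, radii, res_idx = _flat_atoms(struct)
    out: list[Optional[float]] = [None] * len(struct.residues)
    if len(coords) == 0:
        return out
    _, exposed = _sample_surface(coords, radii, probe_radius, n_sphere_points)
    surface = np.vstack([e for e in exposed if len(e)]) if any(len(e) for e in exposed) \
        else np.zeros((0, 3))
    if len(surface) == 0:
        return out
    tree = cKDTree(surface)
    dists, _ = tree.query(coords)
    sums = np.zeros(len(struct.residues))
    counts = np.zeros(len(struct.residues))
    for d, i in zip(dists, res_idx):
        sums[i] += d
        counts[i] += 1
    for i in range(len(struct.residues)):
        if counts[i]:
            out[i] = float(sums[i] / counts[i])
    return out


# ------------------------------------------------------------------- torsions

def _backbone(res: Residue) -> dict[str, Optional[np.ndarray]]:
    return {name: (res.atom(name).coord if res.atom(name) else None)
            for name in ("N", "CA", "C", "O")}


def _bonded(prev: Residue, nxt: Residue) -> bool:
    c = prev.atom("C")
    n = nxt.atom("N")
    return (c is not None and n is not None and
            float(np.linalg.norm(c.coord - n.coord)) <= PEPTIDE_BOND_MAX)


def compute_phi_psi(struct: ChainStructure
                    ) -> list[tuple[Optional[float], Optional[float]]]:
    """Backbone (φ, ψ) in degrees per residue; None where atoms are missing or
    the chain is broken (C–N distance above the bond limit)."""
    res = struct.residues
    out: list[tuple[Optional[float], Optional[float]]] = []
    for i in range(len(res)):
        phi = psi = None
        bb = _backbone(res[i])
        if i > 0 and _bonded(res[i - 1], res[i]):
            c_prev = res[i - 1].atom("C")
            if c_prev is not None and all(bb[n] is not None for n in ("N", "CA", "C")):
                phi = dihedral(c_prev.coord, bb["N"], bb["CA"], bb["C"])
        if i + 1 < len(res) and _bonded(res[i], res[i + 1]):
            n_next = res[i + 1].atom("N")
            if n_next is not None and all(bb[n] is not None for n in ("N", "CA", "C")):
                psi = dihedral(bb["N"], bb["CA"], bb["C"], n_next.coord)
        out.append((phi, psi))
    return out


# -------------------------------------------------- secondary structure (K&S)

_HB_ENERGY_CUTOFF = -0.5   # kcal/mol
_HB_COUPLING = 0.084 * 332.0


def _amide_hydrogens(struct: ChainStructure) -> list[Optional[np.ndarray]]:
    """Amide H positions, built 1 Å from N along the preceding C=O direction
    (the classic reconstruction); None for the first residue, prolines, and
    chain breaks."""
    res = struct.residues
    out: list[Optional[np.ndarray]] = [None] * len(res)
    for i in range(1, len(res)):
        if res[i].one_letter == "P":
            continue
        if not _bonded(res[i - 1], res[i]):
            continue
        n = res[i].atom("N")
        c = res[i - 1].atom("C")
        o = res[i - 1].atom("O")
        if n is None or c is None or o is None:
            continue
        out[i] = n.coord + unit(c.coord - o.coord)
    return out


def hbond_energy_matrix(struct: ChainStructure) -> np.ndarray:
    """E[i, j] = electrostatic energy (kcal/mol) of the bond from the C=O of
    residue i to the N-H of residue j; +inf where undefined."""
    res = struct.residues
    n = len(res)
    H = _amide_hydrogens(struct)
    E = np.full((n, n), np.inf)
    for i in range(n):
        c = res[i].atom("C")
        o = res[i].atom("O")
        if c is None or o is None:
            continue
        for j in range(n):
            if abs(i - j) < 2:
                continue
            nn = res[j].atom("N")
            h = H[j]
            if nn is None or h is None:
                continue
            d_on = np.linalg.norm(o.coord - nn.coord)
            d_ch = np.linalg.norm(c.coord - h)
            d_oh = np.linalg.norm(o.coord - h)
            d_cn = np.linalg.norm(c.coord - nn.coord)
            if min(d_on, d_ch, d_oh, d_cn) < 0.5:  # clash guard
                E[i, j] = -9.9
                continue
            E[i, j] = _HB_COUPLING * (1.0 / d_on + 1.0 / d_ch
                                      - 1.0 / d_oh - 1.0 / d_cn)
    return E


def assign_secondary_structure(struct: ChainStructure) -> list[str]:
    """Hydrogen-bond-pattern secondary structure: H (α), G (3₁₀), E (strand),
    C otherwise.

    A bond CO(i)→NH(j) exists when its energy is below −0.5 kcal/mol.  Two
    consecutive i→i+4 turns make an α-helix (priority over everything), strand
    residues come from parallel/antiparallel bridge ladders of length ≥ 2, and
    two consecutive i→i+3 turns make a 3₁₀ helix on residues not already
    assigned.
    """
    n = len(struct.residues)
    if n < 3:
        return ["C"] * n
    E = hbond_energy_matrix(struct)
    hb = E < _HB_ENERGY_CUTOFF  # hb[i, j]: CO of i accepts from NH of j

    def turn(i: int, k: int) -> bool:
        return i + k < n and hb[i, i + k]

    ss = ["C"] * n
    # α-helix: consecutive 4-turns at i-1 and i cover residues i..i+3
    for i in range(1, n - 4):
        if turn(i - 1, 4) and turn(i, 4):
            for k in range(i, i + 4):
                ss[k] = "H"
    # β-bridges
    bridge = [False] * n
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if para or anti:
                bridge[i] = bridge[j] = True
    # ladders: keep strand segments of length >= 2
    i = 0
    while i < n:
        if bridge[i] and ss[i] == "C":
            j = i
            while j < n and bridge[j] and ss[j] == "C":
                j += 1
            if j - i >= 2:
                for k in range(i, j):
                    ss[k] = "E"
            i = j
        else:
            i += 1
    # 3₁₀ helix: consecutive 3-turns cover residues i..i+2
    for i in range(1, n - 3):
        if turn(i - 1, 3) and turn(i, 3):
            if all(ss[k] in ("C", "G") for k in range(i, i + 3)):
                for k in range(i, i + 3):
                    ss[k] = "G"
    return ss


# ------------------------------------------------- sidechain-mainchain H-bonds

def detect_sidechain_mainchain_hbonds(struct: ChainStructure,
                                      cutoff: float = 3.5
                                      ) -> list[tuple[bool, bool]]:
    """Per residue: (sidechain H-bonds a mainchain amide N, sidechain H-bonds
    a mainchain carbonyl O), by donor–acceptor distance within ``cutoff`` to
    any other residue's mainchain; the donor–H–acceptor angle check applies
    only when an explicit hydrogen is present."""
    res = struct.residues
    main_n = [(i, r.atom("N").coord) for i, r in enumerate(res) if r.atom("N")]
    main_o = [(i, r.atom("O").coord) for i, r in enumerate(res) if r.atom("O")]
    out: list[tuple[bool, bool]] = []
    for i, r in enumerate(res):
        to_amide = False
        to_carbonyl = False
        for name in SIDECHAIN_ACCEPTORS.get(r.one_letter, ()):
            a = r.atom(name)
            if a is None:
                continue
            if any(j != i and np.linalg.norm(a.coord - c) <= cutoff
                   for j, c in main_n):
                to_amide = True
                break
        for name in SIDECHAIN_DONORS.get(r.one_letter, ()):
            a = r.atom(name)
            if a is None:
                continue
            if any(j != i and np.linalg.norm(a.coord - c) <= cutoff
                   for j, c in main_o):
                to_carbonyl = True
                break
        out.append((to_amide, to_carbonyl))
    return out


# ------------------------------------------------------------------- contacts

def compute_intra_contacts(struct: ChainStructure,
                           cutoff: float = 6.0) -> list[set[int]]:
    """Symmetric within-chain contact sets: residues i ≠ j are in contact when
    their nearest heavy-atom distance is ≤ cutoff (sequence neighbours
    included).  Grid-accelerated via a k-d tree."""
    coords, _, res_idx = _flat_atoms(struct)
    n = len(struct.residues)
    contacts: list[set[int]] = [set() for _ in range(n)]
    if len(coords) == 0:
        return contacts
    tree = cKDTree(coords)
    for a, b in tree.query_pairs(cutoff):
        i, j = res_idx[a], res_idx[b]
        if i != j:
            contacts[i].add(j)
            contacts[j].add(i)
    return contacts


def compute_interface_contacts(struct: ChainStructure, cutoff: float = 5.0
                               ) -> list[tuple[Optional[str], Optional[str]]]:
    """Per residue: (id of the nearest other chain within cutoff, name of the
    nearest ligand within cutoff); when several partners qualify the one with
    the smallest minimum distance wins."""
    n = len(struct.residues)
    res_coords = [np.array([a.coord for a in r.atoms if a.element.upper() != "H"])
                  for r in struct.residues]
    partners_chain: list[tuple[str, cKDTree]] = []
    for cid, residues in struct.other_chains:
        pts = np.array([a.coord for r in residues for a in r.atoms
                        if a.element.upper() != "H"])
        if len(pts):
            partners_chain.append((cid, cKDTree(pts)))
    partners_lig: list[tuple[str, cKDTree]] = []
    for name, atoms in struct.hetero_groups:
        pts = np.array([a.coord for a in atoms if a.element.upper() != "H"])
        if len(pts):
            partners_lig.append((name, cKDTree(pts)))
    out: list[tuple[Optional[str], Optional[str]]] = []
    for i in range(n):
        pts = res_coords[i]
        best_chain = best_lig = None
        if len(pts):
            d_best = math.inf
            for cid, tree in partners_chain:
                d = float(np.min(tree.query(pts)[0]))
                if d <= cutoff and d < d_best:
                    d_best, best_chain = d, cid
            d_best = math.inf
            for name, tree in partners_lig:
                d = float(np.min(tree.query(pts)[0]))
                if d <= cutoff and d < d_best:
                    d_best, best_lig = d, name
        out.append((best_chain, best_lig))
    return out


# ------------------------------------------------------------------ aggregate

def annotate_structure(struct: ChainStructure,
                       params: AnnotationParams = DEFAULT_PARAMS
                       ) -> list[ResidueAnnotation]:
    """Run every per-residue feature computation and bundle the results."""
    sasa = compute_sasa(struct, params.probe_radius, params.n_sphere_points)
    depth = compute_residue_depth(struct, params.probe_radius,
                                  params.n_sphere_points)
    ss = assign_secondary_structure(struct)
    torsions = compute_phi_psi(struct)
    hbonds = detect_sidechain_mainchain_hbonds(struct, params.hbond_cutoff)
    contacts = compute_intra_contacts(struct, params.contact_cutoff)
    interfaces = compute_interface_contacts(struct, params.interface_cutoff)
    out = []
    for i, res in enumerate(struct.residues):
        rel, buried = classify_burial(sasa[i], res.one_letter,
                                      params.burial_threshold_pct)
        phi = torsions[i][0]
        out.append(ResidueAnnotation(
            ss=ss[i],
            rel_sasa=rel,
            buried=buried,
            positive_phi=None if phi is None else phi > 0,
            hbond_to_amide=hbonds[i][0],
            hbond_to_carbonyl=hbonds[i][1],
            depth=depth[i],
            chain_contact=interfaces[i][0],
            ligand_contact=interfaces[i][1],
            contacts=frozenset(contacts[i]),
        ))
    return out


def ss_string(annotations: list[ResidueAnnotation]) -> str:
    """DSSP-style one-letter secondary-structure string for cross-checking."""
    return "".join(a.ss for a in annotations)
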