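"""Frozen constants and job parameters.

Everything tunable in the pipeline lives in :class:`AnnotationParams`; colour
tables and reference values used by the feature computations and the renderer
are module-level constants so they can be inspected and, for the reference
max-SASA table, swapped for an empirical variant.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

#: Van der Waals radii (Å) by element symbol, Chothia-style heavy-atom set.
VDW_RADII: Mapping[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "H": 1.20,
}
DEFAULT_VDW_RADIUS = 1.70

#: Theoretical maximum solvent-accessible surface areas (Å²) of residue X in an
#: extended Gly-X-Gly tripeptide (Tien et al. 2013, theoretical column), keyed
#: by one-letter code.  Used as the denominator of relative accessibility.
MAX_SASA_GLY_X_GLY: Mapping[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: The 20 standard amino acids, the alphabet of the entropy sum.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Taylor physicochemical colour scheme (canonical published hues), applied to
#: sequence rows that carry no structural annotation.
TAYLOR_COLORS: Mapping[str, str] = {
    "A": "#CCFF00", "C": "#FFFF00", "D": "#FF0000", "E": "#FF0066",
    "F": "#00FF66", "G": "#FF9900", "H": "#0066FF", "I": "#66FF00",
    "K": "#6600FF", "L": "#33FF00", "M": "#00FF00", "N": "#CC00FF",
    "P": "#FFCC00", "Q": "#FF00CC", "R": "#0000FF", "S": "#FF3300",
    "T": "#FF6600", "V": "#99FF00", "W": "#00CCFF", "Y": "#00FFCC",
    "X": "#888888",
}

THREE_TO_ONE: Mapping[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine is read as methionine
    "MSE": "M",
}
ONE_TO_THREE: Mapping[str, str] = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

# Ideal backbone geometry used by the synthetic-structure generators
# (Engh & Huber style bond lengths/angles).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.4
OMEGA_TRANS = 180.0

#: Peptide-bond continuity: consecutive residues are considered bonded when the
#: C(i)–N(i+1) distance is below this value (Å); beyond it torsions and the
#: amide H are undefined across the break.
PEPTIDE_BOND_MAX = 2.5


@dataclass(frozen=True)
class AnnotationParams:
    """All thresholds and cutoffs of one annotation job.

    Defaults are the published constants: burial below 7% relative SASA,
    intra-chain contacts within 6.0 Å, chain/ligand interfaces within 5 Å,
    secondary-structure consensus at 70%, prediction rendering at 0.7/0.3
    confidence with disorder shown from 8, and RMSD bins at 2/4/6/8 Å.
    """

    probe_radius: float = 1.4          # Å, solvent probe
    n_sphere_points: int = 256         # Shrake-Rupley samples per atom
    burial_threshold_pct: float = 7.0  # % relative SASA, strict less-than
    hbond_cutoff: float = 3.5          # Å donor-acceptor
    contact_cutoff: float = 6.0        # Å heavy-atom, intra-chain
    interface_cutoff: float = 5.0      # Å heavy-atom, chain/ligand
    consensus_threshold: float = 0.70  # fraction of participating structures
    ss_strong_conf: float = 0.7        # prediction confidence, strong shade
    ss_weak_conf: float = 0.3          # prediction confidence, weak shade
    disorder_min_conf: int = 8         # 0-9 scale
    rmsd_bin_edges: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0)
    max_sequences: int = 25
    wrap_width: int = 60               # alignment columns per HTML block
    seed: int = 0                      # synthetic-data generation only

    def as_dict(self) -> dict:
        d = asdict(self)
        d["rmsd_bin_edges"] = list(self.rmsd_bin_edges)
        return d


DEFAULT_PARAMS = AnnotationParams()
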