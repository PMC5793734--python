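"""Per-residue structural features against analytic values and independent
oracles (dense-grid SASA, full DSSP implementation, brute-force contacts)."""
import math

import numpy as np
import pytest

from conftest import brute_force_contacts, brute_force_sasa
from strucaln import structure_features as stf
from strucaln import synthetic_fixtures as sf
from strucaln.seqstruct_io import write_pdb
from strucaln.types import Atom, ChainStructure, Residue


def _chain_of_atoms(spec, name="toy"):
    """spec: list of (element, coord) per single-atom residue."""
    residues = [Residue("GLY", "G", str(i + 1),
                        [Atom("CA", el, np.array(c, float))])
                for i, (el, c) in enumerate(spec)]
    return ChainStructure(name, "A", residues)


class TestSasa:
    def test_isolated_atom_full_sphere(self):
        st = _chain_of_atoms([("C", (0, 0, 0))])
        area = stf.compute_sasa(st, n_sphere_points=512)[0]
        assert area == pytest.approx(4 * math.pi * (1.70 + 1.4) ** 2, rel=0.01)

    def test_distant_atoms_unoccluded(self):
        st = _chain_of_atoms([("C", (0, 0, 0)), ("C", (10, 0, 0))])
        areas = stf.compute_sasa(st, n_sphere_points=512)
        full = 4 * math.pi * (1.70 + 1.4) ** 2
        assert areas[0] == pytest.approx(full, rel=0.01)
        assert areas[1] == pytest.approx(full, rel=0.01)

    def test_enclosed_atom_zero(self):
        # central atom surrounded by a tight shell of 26 atoms
        shell = [("C", (2.0 * x, 2.0 * y, 2.0 * z))
                 for x in (-1, 0, 1) for y in (-1, 0, 1) for z in (-1, 0, 1)
                 if (x, y, z) != (0, 0, 0)]
        st = _chain_of_atoms([("C", (0, 0, 0))] + shell)
        areas = stf.compute_sasa(st, n_sphere_points=512)
        assert areas[0] == 0.0

    def test_occluded_pair_matches_dense_oracle(self):
        coords = np.array([[0.0, 0, 0], [2.5, 0, 0], [1.2, 2.2, 0.5]])
        radii = np.array([1.70, 1.55, 1.52])
        st = _chain_of_atoms([("C", coords[0]), ("N", coords[1]),
                              ("O", coords[2])])
        mine = stf.compute_sasa(st, n_sphere_points=1024)
        oracle = brute_force_sasa(coords, radii, n_points=20000)
        for m, o in zip(mine, oracle):
            assert m == pytest.approx(o, rel=0.02)

    def test_monotone_under_added_occlusion(self, helix12):
        lone = stf.compute_sasa(sf.make_ideal_helix(6), n_sphere_points=128)
        crowded = stf.compute_sasa(sf.make_ideal_helix(12), n_sphere_points=128)
        # first residues gain neighbours, so their area cannot increase
        for a, b in zip(crowded[:5], lone[:5]):
            assert a <= b + 1e-9


class TestBurial:
    @pytest.mark.parametrize("rel,expect", [(6.9, True), (7.0, False),
                                            (0.0, True)])
    def test_boundary_strict_less_than(self, rel, expect):
        sasa = rel / 100.0 * 129.0  # ALA reference
        rel_out, buried = stf.classify_burial(sasa, "A", 7.0)
        assert rel_out == pytest.approx(rel)
        assert buried is expect

    def test_threshold_recovered_by_scan(self):
        flips = [rel / 10.0 for rel in range(0, 150)
                 if stf.classify_burial(rel / 10.0 / 100 * 129.0, "A")[1]
                 != stf.classify_burial((rel + 1) / 10.0 / 100 * 129.0, "A")[1]]
        assert flips == [pytest.approx(6.9)]  # flips between 6.9 and 7.0

    def test_unknown_residue_undefined(self):
        rel, buried = stf.classify_burial(50.0, "Z")
        assert rel is None and buried is False


class TestSecondaryStructure:
    def _dssp(self, struct):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import mdtraj as md
        import pathlib
        import tempfile
        with tempfile.TemporaryDirectory() as d:
            p = pathlib.Path(d) / "x.pdb"
            p.write_text(write_pdb(struct))
            return list(md.compute_dssp(md.load(str(p)), simplified=False)[0])

    def test_ideal_helix_matches_oracle(self, helix12):
        mine = stf.assign_secondary_structure(helix12)
        oracle = self._dssp(helix12)
        for m, o in zip(mine, oracle):
            assert (m == "H") == (o == "H")

    def test_antiparallel_sheet_matches_oracle(self, hairpin):
        mine = stf.assign_secondary_structure(hairpin)
        oracle = self._dssp(hairpin)
        # every residue the full DSSP calls strand is strand here, and the
        # strand interiors are non-empty
        for m, o in zip(mine, oracle):
            if o == "E":
                assert m == "E"
        assert mine.count("E") >= 4

    def test_310_helix_matches_oracle(self):
        g = sf.make_ideal_helix(10, phi=-49.0, psi=-26.0)
        mine = stf.assign_secondary_structure(g)
        oracle = self._dssp(g)
        for m, o in zip(mine, oracle):
            assert (m == "G") == (o == "G")

    def test_lone_extended_strand_is_coil(self):
        lone = sf.make_extended_strand(8)
        assert stf.assign_secondary_structure(lone) == ["C"] * 8

    def test_short_chain_all_coil(self):
        st = sf.make_ideal_helix(2)
        assert stf.assign_secondary_structure(st) == ["C", "C"]


class TestTorsions:
    def test_construction_recovered(self, helix12):
        tors = stf.compute_phi_psi(helix12)
        for phi, psi in tors[1:-1]:
            assert phi == pytest.approx(-57.0, abs=0.1)
            assert psi == pytest.approx(-47.0, abs=0.1)

    def test_termini_undefined(self, helix12):
        tors = stf.compute_phi_psi(helix12)
        assert tors[0][0] is None and tors[-1][1] is None

    def test_left_handed_positive_phi(self):
        lh = sf.make_ideal_helix(8, phi=57.0, psi=47.0)
        tors = stf.compute_phi_psi(lh)
        assert all(phi > 0 for phi, _ in tors[1:-1])

    def test_single_residue_undefined(self):
        st = sf.make_ideal_helix(1)
        assert stf.compute_phi_psi(st) == [(None, None)]

    def test_chain_break_undefined(self, hairpin):
        # junction between the two strands is a numbering/coordinate break
        tors = stf.compute_phi_psi(hairpin)
        assert tors[6][0] is None  # first residue of the second strand


class TestSidechainHbonds:
    def _with_ser_og(self, distance):
        """Extended chain whose residue 3 is Ser with OG placed at the given
        distance from residue 7's carbonyl O, pointing away from the rest of
        the backbone so no other mainchain O is nearer."""
        st = sf.make_extended_strand(8)
        r7 = st.residues[6]
        target = r7.atom("O").coord
        outward = target - r7.atom("C").coord
        outward = outward / np.linalg.norm(outward)
        og = target + outward * distance
        res = st.residues[2]
        res.three_letter, res.one_letter = "SER", "S"
        res.atoms.append(Atom("OG", "O", og))
        # construction check: the nearest non-own mainchain O is the target
        others = [np.linalg.norm(og - r.atom("O").coord)
                  for i, r in enumerate(st.residues) if i != 2]
        assert min(others) == pytest.approx(distance, abs=1e-6)
        return st

    def test_alanine_no_polar_sidechain(self, helix12):
        flags = stf.detect_sidechain_mainchain_hbonds(helix12)
        assert all(f == (False, False) for f in flags)

    def test_ser_og_near_carbonyl(self):
        st = self._with_ser_og(2.9)
        flags = stf.detect_sidechain_mainchain_hbonds(st)
        assert flags[2][1] is True

    def test_ser_og_beyond_cutoff(self):
        st = self._with_ser_og(4.0)
        flags = stf.detect_sidechain_mainchain_hbonds(st)
        assert flags[2][1] is False

    def test_ser_og_is_also_amide_acceptor(self):
        st = sf.make_ideal_helix(8)
        target = st.residues[6].atom("N").coord
        res = st.residues[2]
        res.three_letter, res.one_letter = "SER", "S"
        direction = np.array([0.0, 0.0, 1.0])
        res.atoms.append(Atom("OG", "O", target + 2.8 * direction))
        assert stf.detect_sidechain_mainchain_hbonds(st)[2][0] is True


class TestDepth:
    def test_single_atom_probe_radius(self):
        st = _chain_of_atoms([("C", (0, 0, 0))])
        d = stf.compute_residue_depth(st, n_sphere_points=512)[0]
        assert d == pytest.approx(1.70 + 1.4, abs=0.01)

    def test_exposed_peptide_shallow(self):
        st = sf.make_ideal_helix(3)
        depths = stf.compute_residue_depth(st, n_sphere_points=512)
        for d in depths:
            assert d == pytest.approx(1.6 + 1.4, abs=1.0)

    def test_center_deeper_than_shell(self):
        # close-packed cluster: central atom plus two shells
        shell1 = [("C", (3.0 * x, 3.0 * y, 3.0 * z))
                  for x in (-1, 0, 1) for y in (-1, 0, 1) for z in (-1, 0, 1)
                  if (x, y, z) != (0, 0, 0)]
        shell2 = [("C", (6.0 * x, 6.0 * y, 6.0 * z))
                  for x in (-1, 0, 1) for y in (-1, 0, 1) for z in (-1, 0, 1)
                  if (x, y, z) != (0, 0, 0)]
        st = _chain_of_atoms([("C", (0, 0, 0))] + shell1 + shell2)
        depths = stf.compute_residue_depth(st, n_sphere_points=256)
        center = depths[0]
        outer = np.mean(depths[1 + len(shell1):])
        assert center > outer

    def test_burying_never_decreases_depth(self):
        core = [("C", (0, 0, 0))]
        shell = [("C", (3.0 * x, 3.0 * y, 3.0 * z))
                 for x in (-1, 0, 1) for y in (-1, 0, 1) for z in (-1, 0, 1)
                 if (x, y, z) != (0, 0, 0)]
        d_free = stf.compute_residue_depth(_chain_of_atoms(core),
                                           n_sphere_points=256)[0]
        d_buried = stf.compute_residue_depth(_chain_of_atoms(core + shell),
                                             n_sphere_points=256)[0]
        assert d_buried >= d_free - 1e-9

    def test_min_distance_vs_brute_force(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [1.5, 2.5, 0]])
        st = _chain_of_atoms([("C", c) for c in coords])
        mine = stf.compute_residue_depth(st, n_sphere_points=256)
        # brute-force: minimum distance to the dense sampled surface
        areas, exposed = stf._sample_surface(coords, np.full(3, 1.70), 1.4, 256)
        surface = np.vstack(exposed)
        for i, c in enumerate(coords):
            oracle = np.min(np.linalg.norm(surface - c, axis=1))
            assert mine[i] == pytest.approx(oracle, abs=1e-9)


class TestContacts:
    def _pair_at(self, d):
        return _chain_of_atoms([("C", (0, 0, 0)), ("C", (d, 0, 0))])

    def test_within_cutoff(self):
        contacts = stf.compute_intra_contacts(self._pair_at(5.9), 6.0)
        assert contacts[0] == {1} and contacts[1] == {0}

    def test_beyond_cutoff(self):
        contacts = stf.compute_intra_contacts(self._pair_at(6.1), 6.0)
        assert contacts == [set(), set()]

    def test_equals_brute_force_oracle(self):
        st = sf.make_ideal_helix(20)
        mine = stf.compute_intra_contacts(st, 6.0)
        oracle = brute_force_contacts(st, 6.0)
        assert mine == oracle

    def test_symmetric_irreflexive(self, helix12):
        contacts = stf.compute_intra_contacts(helix12, 6.0)
        for i, cs in enumerate(contacts):
            assert i not in cs
            for j in cs:
                assert i in contacts[j]


class TestInterfaces:
    def test_dimer_close_contact(self, dimer_close):
        iface = stf.compute_interface_contacts(dimer_close, 5.0)
        assert any(c == "B" for c, _ in iface)

    def test_dimer_far_no_contact(self):
        st = sf.make_toy_dimer(gap=5.5)
        iface = stf.compute_interface_contacts(st, 5.0)
        assert all(c is None for c, _ in iface)

    def test_ligand_within_cutoff(self, ligand_close):
        iface = stf.compute_interface_contacts(ligand_close, 5.0)
        assert any(l == "LIG" for _, l in iface)

    def test_monomer_empty(self, helix12):
        iface = stf.compute_interface_contacts(helix12, 5.0)
        assert all(c is None and l is None for c, l in iface)


class TestAggregate:
    def test_annotation_bundle_consistency(self, helix12):
        anns = stf.annotate_structure(helix12)
        assert len(anns) == 12
        for a in anns:
            if a.rel_sasa is not None:
                assert a.buried == (a.rel_sasa < 7.0)
            if a.depth is not None:
                assert a.depth >= 1.4
        assert stf.ss_string(anns) == "CHHHHHHHHHHC"
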