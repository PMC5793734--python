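"""Entropy, consensus, identity, superposition, and column RMSD."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import unweighted_kabsch_oracle
from strucaln import alignment_features as af
from strucaln import synthetic_fixtures as sf
from strucaln.errors import SuperpositionError
from strucaln.types import AlignedSequence, Alignment, ResidueAnnotation


def _aln(*rows, roles=None):
    roles = roles or ["sequence"] * len(rows)
    return Alignment([AlignedSequence(f"s{i}", roles[i], r)
                      for i, r in enumerate(rows)])


class TestFrequencies:
    def test_counting_with_gap(self):
        aln = _aln("A", "A", "C", "-")
        freqs, f_gap = af.column_frequencies(aln, 1)
        assert freqs == {"A": 0.5, "C": 0.25}
        assert f_gap == 0.25

    @given(st.lists(st.sampled_from("ACDEFG-"), min_size=2, max_size=10))
    def test_frequencies_sum_to_one(self, col):
        if all(c == "-" for c in col):
            col[0] = "A"
        aln = _aln(*col)
        freqs, f_gap = af.column_frequencies(aln, 1)
        assert sum(freqs.values()) + f_gap == pytest.approx(1.0)


class TestEntropy:
    def test_conserved_is_zero(self):
        for n in (2, 4, 10):
            aln = _aln(*["A"] * n)
            assert af.column_entropy(aln, 1) == 0.0

    def test_all_different_is_one(self):
        aln = _aln("A", "C", "D", "E")
        assert af.column_entropy(aln, 1) == pytest.approx(1.0)

    def test_half_half_closed_form(self):
        # -2 * (1/2 log_4 1/2) = 1/2
        aln = _aln("A", "A", "C", "C")
        assert af.column_entropy(aln, 1) == pytest.approx(0.5)

    def test_single_sequence_zero_by_convention(self):
        aln = _aln("A")
        assert af.column_entropy(aln, 1) == 0.0

    def test_log_base_caps_at_twenty(self):
        freqs = {a: 1.0 / 21 for a in "ACDEFGHIKLMNPQRSTVWY"}
        s21 = af.shannon_entropy(freqs, 1.0 / 21, 21)
        s20 = af.shannon_entropy(freqs, 1.0 / 21, 20)
        assert s21 == s20  # n = min(20, N)

    def test_gap_raises_entropy_of_conserved_column(self):
        conserved = af.column_entropy(_aln("A", "A", "A", "A"), 1)
        gapped = af.column_entropy(_aln("A", "A", "A", "-"), 1)
        assert gapped > conserved

    @given(st.lists(st.sampled_from("ACDEFGHIKLMNPQRSTVWY-"),
                    min_size=2, max_size=20))
    def test_bounds_and_permutation_invariance(self, col):
        if all(c == "-" for c in col):
            col[0] = "A"
        s = af.column_entropy(_aln(*col), 1)
        assert 0.0 <= s <= 1.0
        s_rev = af.column_entropy(_aln(*reversed(col)), 1)
        assert s == pytest.approx(s_rev)

    def test_zero_iff_single_symbol(self):
        assert af.column_entropy(_aln("C", "C", "C"), 1) == 0.0
        assert af.column_entropy(_aln("C", "C", "A"), 1) > 0.0


class TestEntropySymbol:
    @pytest.mark.parametrize("s,symbol", [
        (0.0, "*"), (1e-9, "0"), (0.1, "0"), (0.1000001, "1"),
        (0.2, "1"), (0.95, "9"), (1.0, "9")])
    def test_interval_mapping(self, s, symbol):
        assert af.entropy_symbol(s) == symbol

    def test_boundary_scan(self):
        # scanning a fine grid recovers edges exactly at multiples of 0.1
        edges = []
        grid = [k / 1000.0 for k in range(0, 1001)]
        for a, b in zip(grid, grid[1:]):
            if af.entropy_symbol(a) != af.entropy_symbol(b) and a > 0:
                edges.append(b)
        assert edges == pytest.approx([k / 10 + 0.001 for k in range(1, 10)])


class TestConsensus:
    def _with_ss(self, ss_lists, gapped=None):
        seqs = []
        for i, ss in enumerate(ss_lists):
            g = gapped[i] if gapped else "A" * len(ss)
            s = AlignedSequence(f"s{i}", "structure", g)
            s.residue_annotations = [ResidueAnnotation(ss=c) for c in ss]
            seqs.append(s)
        return Alignment(seqs)

    def test_seventy_percent_reached(self):
        aln = self._with_ss(["H"] * 7 + ["C"] * 3)
        assert af.consensus_ss(aln, 1) == "a"

    def test_sixty_percent_blank(self):
        aln = self._with_ss(["H"] * 6 + ["C"] * 4)
        assert af.consensus_ss(aln, 1) == ""

    def test_unanimous_strand(self):
        aln = self._with_ss(["E", "E", "E"])
        assert af.consensus_ss(aln, 1) == "b"

    def test_310_symbol(self):
        aln = self._with_ss(["G"] * 8 + ["C", "C"])
        assert af.consensus_ss(aln, 1) == "3"

    def test_gap_dilutes_denominator(self):
        # 2 of 3 structures helical at column 1, third gapped: 2/3 < 0.7
        aln2 = Alignment([
            AlignedSequence("s0", "structure", "AA"),
            AlignedSequence("s1", "structure", "AA"),
            AlignedSequence("s2", "structure", "-A")])
        for k in range(2):
            aln2.sequences[k].residue_annotations = [
                ResidueAnnotation(ss="H"), ResidueAnnotation(ss="C")]
        aln2.sequences[2].residue_annotations = [ResidueAnnotation(ss="H")]
        assert af.consensus_ss(aln2, 1) == ""

    def test_no_structures_blank(self):
        aln = _aln("A", "A")
        assert af.consensus_ss(aln, 1) == ""

    def test_threshold_recovered_by_scan(self):
        # with 10 structures, the smallest helix count rendering 'a' is 7
        counts = [k for k in range(11)
                  if af.consensus_ss(
                      self._with_ss(["H"] * k + ["C"] * (10 - k)), 1) == "a"]
        assert min(counts) == 7


class TestPercentIdentity:
    def _pair(self, a, b):
        return (AlignedSequence("a", "sequence", a),
                AlignedSequence("b", "structure", b))

    def test_identical(self):
        pid, shared = af.percent_identity(*self._pair("ACDE", "ACDE"))
        assert pid == 100.0 and shared == 4

    def test_gap_columns_excluded(self):
        pid, shared = af.percent_identity(*self._pair("ACDE", "ACD-"))
        assert pid == 100.0 and shared == 3

    def test_three_quarters(self):
        pid, _ = af.percent_identity(*self._pair("ACDE", "ACDK"))
        assert pid == 75.0

    def test_no_overlap_flagged(self):
        pid, shared = af.percent_identity(*self._pair("AC--", "--DE"))
        assert pid == 0.0 and shared == 0

    def test_symmetric(self):
        a, b = self._pair("ACDEFG", "ACD-FG")
        assert af.percent_identity(a, b) == af.percent_identity(b, a)


def _rigid_copy(struct, seed=7):
    import copy
    rng = np.random.default_rng(seed)
    M = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(M)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.normal(size=3) * 8
    out = copy.deepcopy(struct)
    for r in out.residues:
        for at in r.atoms:
            at.coord = Q @ at.coord + t
    return out, Q, t


class TestSuperposition:
    def _two_copies(self, n=15):
        a = sf.make_ideal_helix(n, source_id="a")
        b, Q, t = _rigid_copy(sf.make_ideal_helix(n, source_id="b"))
        aln = Alignment([AlignedSequence("a", "structure", a.sequence, structure=a),
                         AlignedSequence("b", "structure", b.sequence, structure=b)])
        return aln, Q

    def test_rigid_motion_recovery(self):
        aln, Q = self._two_copies()
        sup = af.superpose(list(aln.sequences), aln)
        for i in range(1, 16):
            assert af.column_rmsd(sup, aln, i) <= 1e-6
        # recovered rotation of structure b undoes the applied one
        R = sup.rotations["b"] @ Q
        np.testing.assert_allclose(R @ sup.rotations["a"].T, np.eye(3),
                                   atol=1e-6)

    def test_rotations_orthonormal_weights_positive(self):
        aln, _ = self._two_copies()
        sup = af.superpose(list(aln.sequences), aln)
        for R in sup.rotations.values():
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-9)
            assert np.linalg.det(R) == pytest.approx(1.0)
        assert all(w > 0 for w in sup.weights.values())

    def test_invariant_under_input_rigid_motion(self):
        aln1, _ = self._two_copies()
        sup1 = af.superpose(list(aln1.sequences), aln1)
        aln2, _ = self._two_copies()
        aln2.sequences[0].structure, _, _ = _rigid_copy(
            aln2.sequences[0].structure, seed=99)
        sup2 = af.superpose(list(aln2.sequences), aln2)
        for i in range(1, 16):
            assert af.column_rmsd(sup1, aln1, i) == pytest.approx(
                af.column_rmsd(sup2, aln2, i), abs=1e-6)

    def test_hinge_downweighting_beats_unweighted(self):
        aln = sf.make_hinge_pair(30, 10.0)
        n_core = 20
        sup = af.superpose(list(aln.sequences), aln)
        w_core = [af.column_rmsd(sup, aln, i) for i in range(1, n_core + 1)]
        w_hinge = [af.column_rmsd(sup, aln, i) for i in range(n_core + 1, 31)]
        assert max(w_core) < min(w_hinge)
        # unweighted oracle
        P = np.array([r.atom("CA").coord
                      for r in aln.sequences[1].structure.residues])
        Q = np.array([r.atom("CA").coord
                      for r in aln.sequences[0].structure.residues])
        R, t = unweighted_kabsch_oracle(P, Q)
        d = np.linalg.norm(P @ R.T + t - Q, axis=1)
        u_core = math.sqrt(np.mean(d[:n_core] ** 2))
        assert math.sqrt(np.mean(np.array(w_core) ** 2)) < u_core

    def test_too_few_columns_rejected(self):
        a = sf.make_ideal_helix(2, source_id="a")
        b = sf.make_ideal_helix(2, source_id="b")
        aln = Alignment([AlignedSequence("a", "structure", "AA", structure=a),
                         AlignedSequence("b", "structure", "AA", structure=b)])
        with pytest.raises(SuperpositionError):
            af.superpose(list(aln.sequences), aln)


class TestColumnRmsd:
    def test_coincident_zero(self):
        aln, _ = TestSuperposition()._two_copies(5)
        sup = af.superpose(list(aln.sequences), aln)
        assert af.column_rmsd(sup, aln, 3) == pytest.approx(0.0, abs=1e-6)

    def test_two_structures_single_pair(self):
        from strucaln.types import SuperpositionResult
        sup = SuperpositionResult(
            ids=["a", "b"], rotations={}, translations={},
            column_coords={1: {"a": np.zeros(3), "b": np.array([3.0, 0, 0])}},
            weights={})
        assert af.column_rmsd(sup, None, 1) == pytest.approx(3.0)

    def test_three_structures_brute_force_formula(self):
        from strucaln.types import SuperpositionResult
        pts = {"a": np.zeros(3), "b": np.array([2.0, 0, 0]),
               "c": np.array([0.0, 3.0, 0])}
        sup = SuperpositionResult(ids=list(pts), rotations={}, translations={},
                                  column_coords={1: pts}, weights={})
        d12 = 2.0
        d13 = 3.0
        d23 = math.sqrt(4 + 9)
        expect = math.sqrt((d12 ** 2 + d13 ** 2 + d23 ** 2) / 3)
        assert af.column_rmsd(sup, None, 1) == pytest.approx(expect)

    def test_missing_column_undefined(self):
        from strucaln.types import SuperpositionResult
        sup = SuperpositionResult(ids=["a"], rotations={}, translations={},
                                  column_coords={1: {"a": np.zeros(3)}},
                                  weights={})
        assert af.column_rmsd(sup, None, 1) is None


class TestRmsdBin:
    @pytest.mark.parametrize("rmsd,expect", [
        (0.0, 0), (1.9, 0), (2.0, 1), (3.99, 1), (4.0, 2),
        (6.0, 3), (7.9, 3), (8.0, 4), (25.0, 4)])
    def test_bin_edges(self, rmsd, expect):
        assert af.rmsd_bin(rmsd) == expect

    def test_edges_recovered_by_scan(self):
        edges = []
        grid = [k / 100.0 for k in range(0, 1001)]
        for a, b in zip(grid, grid[1:]):
            if af.rmsd_bin(a) != af.rmsd_bin(b):
                edges.append(b)
        assert edges == [2.0, 4.0, 6.0, 8.0]
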