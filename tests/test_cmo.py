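import numpy as np
import pytest

from regval.cmo import (CMOAlignment, RegisterShiftCall, align_contact_maps,
                        brute_force_cmo, contact_density_filter,
                        extract_register_shifts, kabsch_superpose, plddt_filter,
                        q_score, qscore_filter)
from regval.structures import ContactMap, Residue, StructureChain
from regval.synthetic import make_toy_fold


def shifted_map(cm: ContactMap, k: int) -> ContactMap:
    pairs = [(i + k, j + k, w) for (i, j), w in cm.pairs.items()
             if 1 <= i + k and j + k <= cm.L]
    return ContactMap(pairs, L=cm.L)


class TestAligner:
    def test_identical_maps_identity_mapping(self):
        cm = ContactMap([(1, 4), (2, 6), (3, 8), (5, 8)], L=8)
        aln = align_contact_maps(cm, cm)
        assert all(i == j for i, j in aln.mapping)
        assert aln.matched_contacts == len(cm)
        assert aln.score == pytest.approx(cm.total_weight())

    def test_identity_on_realistic_map(self):
        cm_big = make_toy_fold(80, seed=4)
        from regval.structures import observed_contact_map

        cm = observed_contact_map(cm_big, min_sep=3)
        aln = align_contact_maps(cm, cm)
        assert all(i == j for i, j in aln.mapping)
        assert aln.matched_weight == pytest.approx(cm.total_weight())

    def test_empty_map_gives_empty_alignment(self):
        cm = ContactMap([(1, 4)], L=6)
        aln = align_contact_maps(cm, ContactMap([], L=6))
        assert aln.mapping == [] and aln.matched_contacts == 0

    def test_recovers_plus_two_shift(self):
        cm = ContactMap([(1, 4), (2, 5), (3, 6), (1, 6)], L=8)
        aln = align_contact_maps(cm, shifted_map(cm, 2))
        oracle = brute_force_cmo(cm, shifted_map(cm, 2))
        assert aln.matched_weight == pytest.approx(oracle.score)
        offs = {j - i for i, j in aln.mapping if i <= 4}
        assert 2 in offs

    def test_mapping_strictly_monotone(self):
        rng = np.random.default_rng(5)
        from regval.evaluate import random_contact_map

        for _ in range(5):
            a = random_contact_map(10, 6, rng)
            b = random_contact_map(10, 6, rng)
            aln = align_contact_maps(a, b)
            ii = [i for i, _ in aln.mapping]
            jj = [j for _, j in aln.mapping]
            assert ii == sorted(set(ii)) and jj == sorted(set(jj))

    def test_never_beats_oracle(self):
        rng = np.random.default_rng(17)
        from regval.evaluate import random_contact_map

        for _ in range(20):
            a = random_contact_map(8, int(rng.integers(3, 7)), rng)
            b = random_contact_map(8, int(rng.integers(3, 7)), rng)
            heur = align_contact_maps(a, b)
            oracle = brute_force_cmo(a, b)
            assert heur.matched_weight <= oracle.score + 1e-9
            assert heur.matched_contacts <= min(len(a), len(b))


class TestBruteForce:
    def test_identical_maps(self):
        cm = ContactMap([(1, 3), (2, 5), (3, 5)], L=5)
        assert brute_force_cmo(cm, cm).score == pytest.approx(3.0)

    def test_disjoint_contact_patterns(self):
        a = ContactMap([(1, 2)], L=4)
        b = ContactMap([(1, 4)], L=4)
        # a single contact can always be matched to a single contact
        assert brute_force_cmo(a, b).score == pytest.approx(1.0)
        assert brute_force_cmo(a, ContactMap([], L=4)).score == 0.0

    def test_size_guard(self):
        cm = ContactMap([(1, 5)], L=13)
        with pytest.raises(ValueError):
            brute_force_cmo(cm, cm)


class TestExtractShifts:
    def make_aln(self, mapping):
        return CMOAlignment(mapping, 0, 0.0, 0.0)

    def test_identity_alignment_gives_no_calls(self):
        aln = self.make_aln([(i, i) for i in range(1, 30)])
        assert extract_register_shifts(aln) == []

    def test_constant_offset_run(self):
        aln = self.make_aln([(i, i + 2) for i in range(10, 41)])
        calls = extract_register_shifts(aln)
        assert len(calls) == 1
        call = calls[0]
        assert (call.start, call.end, call.shift) == (10, 40, 2)

    def test_nearby_same_shift_runs_merged(self):
        mapping = [(i, i + 1) for i in range(5, 21)] + [(i, i + 1) for i in range(23, 31)]
        calls = extract_register_shifts(self.make_aln(mapping))
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end, calls[0].shift) == (5, 30, 1)

    def test_short_runs_dropped(self):
        aln = self.make_aln([(i, i + 3) for i in range(1, 5)])
        assert extract_register_shifts(aln, min_len=5) == []

    def test_distant_runs_not_merged(self):
        mapping = ([(i, i + 1) for i in range(1, 9)]
                   + [(i, i) for i in range(9, 20)]
                   + [(i, i + 1) for i in range(20, 28)])
        calls = extract_register_shifts(self.make_aln(mapping))
        assert len(calls) == 2

    def test_zero_shift_call_rejected(self):
        with pytest.raises(ValueError):
            RegisterShiftCall(5, 10, 0)


class _StubMap:
    def __init__(self, counts):
        self._counts = np.asarray(counts)

    def degrees(self):
        return self._counts


class TestContactDensityFilter:
    def call(self, start, end):
        return RegisterShiftCall(start, end, 1)

    def test_low_mean_fails(self):
        # counts [1,1,2,2,2]: mean 1.6 < 2
        assert contact_density_filter(self.call(1, 5), _StubMap([1, 1, 2, 2, 2])) == "fail"

    def test_boundary_mean_and_median_pass(self):
        assert contact_density_filter(self.call(1, 5), _StubMap([2] * 5)) == "pass"

    def test_high_median_low_spread_passes(self):
        # counts [0,0,10,10,10]: median 10, mean 6
        assert contact_density_filter(self.call(1, 5),
                                      _StubMap([0, 0, 10, 10, 10])) == "pass"

    def test_low_median_fails(self):
        # mean 2.4 but median 1
        assert contact_density_filter(self.call(1, 5),
                                      _StubMap([1, 1, 1, 4, 5])) == "fail"

    def test_empty_range_raises(self):
        with pytest.raises(ValueError):
            contact_density_filter(self.call(6, 6), _StubMap([2] * 5))


def plddt_chain(values):
    return StructureChain([Residue(i + 1, "A", np.array([i * 3.8, 0, 0]),
                                   plddt=v) for i, v in enumerate(values)])


class TestPlddtFilter:
    def test_just_below_boundary_fails(self):
        chain = plddt_chain([64.9] * 10)
        assert plddt_filter(RegisterShiftCall(1, 10, 1), chain) == "fail"

    def test_boundary_passes(self):
        chain = plddt_chain([65.0] * 10)
        assert plddt_filter(RegisterShiftCall(1, 10, 1), chain) == "pass"

    def test_absent_plddt_skipped(self):
        chain = plddt_chain([None] * 10)
        with pytest.warns(UserWarning):
            assert plddt_filter(RegisterShiftCall(1, 10, 1), chain) == "skipped"

    def test_no_predicted_model_skipped(self):
        with pytest.warns(UserWarning):
            assert plddt_filter(RegisterShiftCall(1, 10, 1), None) == "skipped"


class TestKabsch:
    def test_identical_sets_zero_rmsd(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(10, 3))
        sup = kabsch_superpose(A, A)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert sup.q_score == pytest.approx(1.0)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(12, 3))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        B = A @ R.T + np.array([3.0, -2.0, 5.0])
        sup = kabsch_superpose(A, B)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.transform(A), B, atol=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_matches_quaternion_oracle(self):
        # independent optimal-superposition RMSD via the quaternion
        # eigenvalue method (Kearsley)
        def quaternion_rmsd(A, B):
            A = A - A.mean(axis=0)
            B = B - B.mean(axis=0)
            xm, ym, zm = (A - B).T
            xp, yp, zp = (A + B).T
            K = np.empty((4, 4))
            K[0, 0] = (xm ** 2 + ym ** 2 + zm ** 2).sum()
            K[1, 1] = (xm ** 2 + yp ** 2 + zp ** 2).sum()
            K[2, 2] = (xp ** 2 + ym ** 2 + zp ** 2).sum()
            K[3, 3] = (xp ** 2 + yp ** 2 + zm ** 2).sum()
            K[0, 1] = K[1, 0] = (yp * zm - ym * zp).sum()
            K[0, 2] = K[2, 0] = (xm * zp - xp * zm).sum()
            K[0, 3] = K[3, 0] = (xp * ym - xm * yp).sum()
            K[1, 2] = K[2, 1] = (xm * ym - xp * yp).sum()
            K[1, 3] = K[3, 1] = (xm * zm - xp * zp).sum()
            K[2, 3] = K[3, 2] = (ym * zm - yp * zp).sum()
            lam = np.linalg.eigvalsh(K)[0]
            return np.sqrt(max(lam, 0.0) / len(A))

        A = np.array([[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 3.8, 2.0]])
        B = A.copy()
        B[3] += [1.0, -0.5, 0.7]
        sup = kabsch_superpose(A, B)
        assert sup.rmsd == pytest.approx(quaternion_rmsd(A, B), abs=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_degenerate(self):
        A = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(A, A)


class TestQscoreFilter:
    def test_formula_boundary(self):
        assert q_score(10, 0.0, 10, 10) == pytest.approx(1.0)
        assert q_score(10, 3.0, 10, 10) == pytest.approx(0.5)
        assert q_score(5, 3.0, 10, 10) == pytest.approx(0.125)

    def build_pair(self, displacement):
        """Model = predicted everywhere except residues 25-34, which take
        the coordinates of predicted i+2 displaced by ``displacement`` —
        after anchor superposition the range RMSD equals |displacement|."""
        pred = make_toy_fold(40, seed=21)
        model = pred.copy()
        for i in range(25, 35):
            model[i].rep_coord = pred[i + 2].rep_coord + np.asarray(displacement)
        return model, pred

    def test_supported_register_passes(self):
        model, pred = self.build_pair([0.0, 0.0, 0.0])
        call = RegisterShiftCall(25, 34, 2)
        assert qscore_filter(call, model, pred) == "pass"

    def test_boundary_rmsd_three_angstrom_passes(self):
        model, pred = self.build_pair([3.0, 0.0, 0.0])
        call = RegisterShiftCall(25, 34, 2)
        # Q = 1 / (1 + (3/3)^2) = 0.5 exactly; "below 0.5" fails, 0.5 passes
        assert qscore_filter(call, model, pred) == "pass"

    def test_just_past_boundary_fails(self):
        model, pred = self.build_pair([3.01, 0.0, 0.0])
        call = RegisterShiftCall(25, 34, 2)
        assert qscore_filter(call, model, pred) == "fail"

    def test_unsupported_register_fails(self):
        # model identical to prediction: pairing i with i+2 compares
        # genuinely different positions -> large rmsd -> discard the call
        pred = make_toy_fold(40, seed=21)
        call = RegisterShiftCall(25, 34, 2)
        assert qscore_filter(call, pred.copy(), pred) == "fail"

    def test_no_predicted_model_skipped(self):
        model, _ = self.build_pair([0.0, 0.0, 0.0])
        with pytest.warns(UserWarning):
            assert qscore_filter(RegisterShiftCall(25, 34, 2), model, None) == "skipped"
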