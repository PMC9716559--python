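import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regval.metrics import (build_metric_table, confusion_metrics,
                            contact_confusion_profile, smooth_profile,
                            spatial_zscore_profile, wrmsd_profile,
                            METRIC_COLUMNS)
from regval.predictions import (DistancePrediction, distogram_to_distance,
                                distogram_to_contact_probabilities,
                                select_top_contacts)
from regval.structures import (ContactMap, DistanceMatrix, Residue,
                               StructureChain, observed_contact_map,
                               observed_distance_matrix)


def dm_from_values(values):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(values=values, mask=np.ones_like(values, dtype=bool))


def prediction(pred, conf=None):
    pred = np.asarray(pred, dtype=float)
    conf = np.ones_like(pred) if conf is None else np.asarray(conf, dtype=float)
    return DistancePrediction(pred_dist=pred, confidence=conf,
                              in_range=np.ones_like(pred, dtype=bool))


class TestWrmsd:
    def test_perfect_prediction_is_zero(self, helix_chain, helix_distogram):
        obs = observed_distance_matrix(helix_chain)
        pred = prediction(obs.values)
        vals, valid = wrmsd_profile(obs, pred)
        np.testing.assert_allclose(vals, 0.0)
        assert valid.all()

    def test_hand_computed_three_residue_toy(self):
        # x = {d12: 5, d13: 9, d23: 5}, xhat = {6, 9, 5}, unit weights
        x = [[0, 5, 9], [5, 0, 5], [9, 5, 0]]
        xhat = [[0, 6, 9], [6, 0, 5], [9, 5, 0]]
        vals, _ = wrmsd_profile(dm_from_values(x), prediction(xhat), min_sep=1)
        assert vals[0] == pytest.approx(np.sqrt(0.5))
        assert vals[1] == pytest.approx(np.sqrt(0.5))
        assert vals[2] == pytest.approx(0.0)

    def test_zero_confidence_flags_residues(self):
        x = np.array([[0.0, 5], [5, 0]])
        vals, valid = wrmsd_profile(dm_from_values(x),
                                    prediction(x, conf=np.zeros((2, 2))))
        np.testing.assert_allclose(vals, 0.0)
        assert not valid.any()

    def test_monotone_under_inflated_deviation(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(4, 15, (6, 6))
        x = (x + x.T) / 2
        np.fill_diagonal(x, 0)
        base = dm_from_values(x)
        prev = None
        for scale in [0.0, 1.0, 2.0, 4.0]:
            xhat = x.copy()
            xhat[0, :] += scale
            xhat[:, 0] += scale
            np.fill_diagonal(xhat, 0)
            vals, _ = wrmsd_profile(base, prediction(xhat), min_sep=1)
            if prev is not None:
                assert vals[0] >= prev - 1e-12
            prev = vals[0]

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            wrmsd_profile(dm_from_values(np.zeros((3, 3))),
                          prediction(np.zeros((4, 4))))


class TestConfusion:
    def test_identical_maps(self):
        cm = ContactMap([(1, 7), (2, 8), (3, 9)], L=10)
        counts = contact_confusion_profile(cm, cm, min_sep=5)
        assert counts.fp.sum() == 0 and counts.fn.sum() == 0
        np.testing.assert_array_equal(counts.tp, cm.degrees())

    def test_empty_prediction(self):
        obs = ContactMap([(1, 7), (2, 8)], L=10)
        counts = contact_confusion_profile(ContactMap([], L=10), obs, min_sep=5)
        assert counts.tp.sum() == 0 and counts.fp.sum() == 0
        np.testing.assert_array_equal(counts.fn, obs.degrees())

    def test_matches_exhaustive_enumeration(self):
        pred = ContactMap([(1, 4), (2, 6)], L=6)
        obs = ContactMap([(1, 4), (1, 6), (3, 6)], L=6)
        counts = contact_confusion_profile(pred, obs, min_sep=2)
        for i in range(1, 7):
            tp = fp = tn = fn = 0
            for j in range(1, 7):
                if abs(i - j) < 2:
                    continue
                p, o = (i, j) in pred, (i, j) in obs
                tp += p and o
                fp += p and not o
                fn += o and not p
                tn += (not p) and (not o)
            assert (counts.tp[i - 1], counts.fp[i - 1],
                    counts.tn[i - 1], counts.fn[i - 1]) == (tp, fp, tn, fn)

    def test_count_conservation(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            L = int(rng.integers(8, 20))
            def rand_map():
                pairs = {(int(i), int(j)) for i, j in
                         rng.integers(1, L + 1, (rng.integers(2, 10), 2))
                         if j - i >= 2}
                return ContactMap(list(pairs), L=L)
            counts = contact_confusion_profile(rand_map(), rand_map(), min_sep=2)
            np.testing.assert_array_equal(
                counts.tp + counts.fp + counts.tn + counts.fn, counts.universe)

    def test_hand_computed_rates(self):
        from regval.metrics import ConfusionCounts

        counts = ConfusionCounts(tp=np.array([2]), fp=np.array([1]),
                                 tn=np.array([90]), fn=np.array([3]),
                                 universe=np.array([96]))
        m = confusion_metrics(counts)
        assert m["accuracy"][0][0] == pytest.approx(92 / 96)
        assert m["sensitivity"][0][0] == pytest.approx(0.4)
        assert m["fp_rate"][0][0] == pytest.approx(1 / 91)
        assert m["precision"][0][0] == pytest.approx(2 / 3)
        assert m["specificity"][0][0] == pytest.approx(90 / 91)
        assert m["fn_count"][0][0] == 3 and m["fp_count"][0][0] == 1

    def test_zero_denominator_convention(self):
        from regval.metrics import ConfusionCounts

        counts = ConfusionCounts(tp=np.array([0]), fp=np.array([2]),
                                 tn=np.array([5]), fn=np.array([0]),
                                 universe=np.array([7]))
        vals, valid = confusion_metrics(counts)["sensitivity"]
        assert vals[0] == 0.0 and not valid[0]

    def test_fp_rate_specificity_complementary(self):
        rng = np.random.default_rng(9)
        pred = ContactMap([(1, 5), (2, 9), (4, 10)], L=10)
        obs = ContactMap([(2, 9), (3, 8)], L=10)
        m = confusion_metrics(contact_confusion_profile(pred, obs, min_sep=2))
        fpr, fpr_ok = m["fp_rate"]
        spec, _ = m["specificity"]
        np.testing.assert_allclose((fpr + spec)[fpr_ok], 1.0)


class TestSmoothing:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(smooth_profile(np.full(9, 3.3)), 3.3)

    def test_spike_spreads_to_window_mean(self):
        v = np.array([0, 0, 0, 0, 10, 0, 0, 0, 0], dtype=float)
        out = smooth_profile(v)
        assert out[4] == pytest.approx(2.0)
        assert out[2] == pytest.approx(2.0) and out[6] == pytest.approx(2.0)
        assert out[1] == pytest.approx(0.0) and out[7] == pytest.approx(0.0)

    def test_edge_window_shrinks(self):
        v = np.array([10.0, 0, 0, 0, 0, 0])
        assert smooth_profile(v)[0] == pytest.approx(10 / 3)

    def test_masked_positions_excluded(self):
        v = np.array([1.0, 100.0, 1.0, 1.0, 1.0])
        mask = np.array([True, False, True, True, True])
        np.testing.assert_allclose(smooth_profile(v, mask=mask), 1.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(np.zeros(5), window=4)

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=30),
           st.floats(-100, 100))
    def test_commutes_with_constant_shift(self, values, c):
        v = np.array(values)
        np.testing.assert_allclose(smooth_profile(v + c), smooth_profile(v) + c,
                                   atol=1e-9)


class TestSpatialZscore:
    def chain(self, coords):
        return StructureChain([Residue(i + 1, "A", np.asarray(c, float))
                               for i, c in enumerate(coords)])

    def test_uniform_values_give_zero(self, helix_chain):
        z = spatial_zscore_profile(np.full(helix_chain.L, 2.5), helix_chain)
        np.testing.assert_allclose(z, 0.0)

    def test_affine_invariance(self, helix_chain):
        rng = np.random.default_rng(2)
        v = rng.random(helix_chain.L)
        z1 = spatial_zscore_profile(v, helix_chain)
        z2 = spatial_zscore_profile(3.0 * v + 7.0, helix_chain)
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_collinear_neighbourhoods(self):
        coords = [[i * 4.0, 0, 0] for i in range(4)]
        v = np.array([1.0, 2.0, 3.0, 10.0])
        z = spatial_zscore_profile(v, self.chain(coords), radius=10.0)
        for i in range(4):
            sample = [v[j] for j in range(4) if abs(i - j) * 4.0 <= 10.0]
            mu, sd = np.mean(sample), np.std(sample)
            assert z[i] == pytest.approx((v[i] - mu) / sd)


class TestMetricTable:
    def test_exactly_24_metric_columns(self, helix_chain, helix_distogram):
        pred = distogram_to_distance(helix_distogram)
        P = distogram_to_contact_probabilities(helix_distogram)
        cm = select_top_contacts(P, L=helix_chain.L)
        table = build_metric_table(helix_chain, pred, cm)
        assert [c for c in table.columns if c != "mask"] == list(METRIC_COLUMNS)
        assert len(METRIC_COLUMNS) == 24

    def test_perfect_prediction_columns(self, helix_chain):
        obs = observed_distance_matrix(helix_chain)
        cm = observed_contact_map(helix_chain)
        pred = prediction(obs.values)
        table = build_metric_table(helix_chain, pred, cm)
        np.testing.assert_allclose(table["wrmsd"], 0.0)
        np.testing.assert_allclose(table["accuracy"], 1.0)
        np.testing.assert_allclose(table["fp_count"], 0.0)

    def test_rate_metrics_bounded(self, helix_chain, helix_distogram):
        pred = distogram_to_distance(helix_distogram)
        P = distogram_to_contact_probabilities(helix_distogram)
        cm = select_top_contacts(P, L=helix_chain.L)
        table = build_metric_table(helix_chain, pred, cm)
        for col in ["accuracy", "precision", "sensitivity", "specificity", "fp_rate"]:
            assert table[col].between(0, 1).all()
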