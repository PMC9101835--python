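import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsanet.evalstats import (
    SurvivalRecord, bootstrap_ci, delong_test, dice_coefficient, km_logrank,
    lesion_level_metrics, pixel_metrics, roc_auc, subgroup_report,
)


class TestDice:
    def test_identity(self):
        m = np.zeros((8, 8), int)
        m[2:5, 2:5] = 1
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((8, 8), int)
        b = np.zeros((8, 8), int)
        a[0, 0] = 1
        b[7, 7] = 1
        assert dice_coefficient(a, b) == 0.0

    def test_counted_fixture(self):
        # |P| = 100, |G| = 100, overlap 50 -> brute-force pixel count oracle
        pred = np.zeros((20, 20), int)
        gt = np.zeros((20, 20), int)
        pred.flat[:100] = 1
        gt.flat[50:150] = 1
        inter = sum(int(p and g) for p, g in zip(pred.flat, gt.flat))
        assert inter == 50
        assert dice_coefficient(pred, gt) == pytest.approx(
            2 * inter / (pred.sum() + gt.sum()))
        assert dice_coefficient(pred, gt) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), int)
        assert dice_coefficient(z, z) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros((2, 2), int), np.zeros((3, 3), int))

    @given(st.integers(0, 2 ** 16 - 1), st.integers(0, 2 ** 16 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(16)]).reshape(4, 4)
        b = np.array([(bits_b >> i) & 1 for i in range(16)]).reshape(4, 4)
        assert dice_coefficient(a, b) == dice_coefficient(b, a)


class TestPixelMetrics:
    def test_perfect(self):
        m = np.zeros((6, 6), int)
        m[1:3, 1:3] = 1
        out = pixel_metrics(m, m)
        for v in out.values():
            assert v == pytest.approx(100.0)

    def test_complement(self):
        gt = np.zeros((4, 4), int)
        gt[:2] = 1
        out = pixel_metrics(1 - gt, gt)
        assert out["sensitivity"] == 0.0
        assert out["specificity"] == 0.0

    def test_hand_counted_confusion(self):
        # 4x4 with TP=2, FP=1, FN=1, TN=12
        gt = np.zeros((4, 4), int)
        pred = np.zeros((4, 4), int)
        gt[0, 0] = gt[0, 1] = gt[0, 2] = 1      # 3 positives
        pred[0, 0] = pred[0, 1] = pred[1, 0] = 1  # hits 2, misses 1, 1 spurious
        out = pixel_metrics(pred, gt)
        assert out["sensitivity"] == pytest.approx(100 * 2 / 3, abs=0.05)
        assert out["ppv"] == pytest.approx(100 * 2 / 3, abs=0.05)
        assert out["accuracy"] == pytest.approx(100 * 14 / 16)

    def test_undefined_ratio_is_none(self):
        z = np.zeros((4, 4), int)
        out = pixel_metrics(z, z)
        assert out["sensitivity"] is None  # no positives in gt
        assert out["specificity"] == 100.0


class TestLesionMetrics:
    def test_identity_three_components(self):
        gt = np.zeros((20, 20), int)
        gt[1:4, 1:4] = 1
        gt[10:13, 10:13] = 1
        gt[16:19, 2:5] = 1
        out = lesion_level_metrics(gt, gt)
        assert out["n_gt_lesions"] == 3
        assert out["lesion_sensitivity"] == 100.0
        assert out["fpr"] == 0.0

    def test_empty_prediction(self):
        gt = np.zeros((8, 8), int)
        gt[2:4, 2:4] = 1
        out = lesion_level_metrics(np.zeros_like(gt), gt)
        assert out["lesion_sensitivity"] == 0.0
        assert out["fpr"] == 0.0

    def test_one_hit_one_spurious(self):
        gt = np.zeros((20, 20), int)
        gt[2:6, 2:6] = 1
        pred = gt.copy()
        pred[14:17, 14:17] = 1  # distant blob, no gt support
        out = lesion_level_metrics(pred, gt)
        assert out["lesion_sensitivity"] == 100.0
        assert out["fpr"] == pytest.approx(50.0)

    def test_ten_percent_coverage_rule(self):
        gt = np.zeros((20, 20), int)
        gt[0:10, 0:10] = 1  # 100 px lesion
        pred = np.zeros_like(gt)
        pred[0, 0:9] = 1    # 9 px overlap < 10 -> missed
        assert lesion_level_metrics(pred, gt)["lesion_sensitivity"] == 0.0
        pred[1, 0] = 1      # 10 px = threshold -> detected
        assert lesion_level_metrics(pred, gt)["lesion_sensitivity"] == 100.0

    def test_translation_invariance(self):
        gt = np.zeros((30, 30), int)
        gt[5:9, 5:9] = 1
        pred = np.zeros_like(gt)
        pred[5:8, 5:8] = 1
        pred[20:22, 20:22] = 1
        base = lesion_level_metrics(pred, gt)
        shifted = lesion_level_metrics(np.roll(pred, (3, 3), (0, 1)),
                                       np.roll(gt, (3, 3), (0, 1)))
        assert base == shifted

    def test_eight_connectivity(self):
        gt = np.zeros((6, 6), int)
        gt[0, 0] = gt[1, 1] = 1  # diagonal touch = one component
        assert lesion_level_metrics(gt, gt)["n_gt_lesions"] == 1


class TestBootstrap:
    def test_constant_statistic(self):
        lo, hi = bootstrap_ci(lambda d: 4.2, list(range(10)), reps=50, seed=0)
        assert lo == hi == 4.2

    def test_seeded_determinism(self):
        data = list(np.random.default_rng(0).normal(size=30))
        a = bootstrap_ci(np.mean, data, reps=200, seed=5)
        b = bootstrap_ci(np.mean, data, reps=200, seed=5)
        assert a == b

    def test_width_matches_analytic_se(self):
        data = list(np.random.default_rng(1).standard_normal(50))
        lo, hi = bootstrap_ci(np.mean, data, reps=2000, seed=2)
        expected = 2 * 1.96 * np.std(data) / np.sqrt(50)
        assert abs((hi - lo) - expected) < 0.2 * expected

    def test_monotone_in_level(self):
        data = list(np.random.default_rng(3).normal(size=40))
        lo90, hi90 = bootstrap_ci(np.mean, data, reps=500, level=0.90, seed=7)
        lo95, hi95 = bootstrap_ci(np.mean, data, reps=500, level=0.95, seed=7)
        assert lo95 <= lo90 and hi90 <= hi95

    def test_bad_reps(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.mean, [1, 2, 3], reps=0)


def _auc_enumeration_oracle(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_enumeration_fixture(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert roc_auc(scores, labels) == pytest.approx(
            _auc_enumeration_oracle(scores, labels))
        assert roc_auc(scores, labels) == pytest.approx(3 / 4)

    def test_random_matches_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=25)
        labels = rng.integers(0, 2, size=25)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            _auc_enumeration_oracle(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=12,
                    unique=True))
    @settings(max_examples=25, deadline=None)
    def test_reversal_symmetry(self, scores):
        labels = [i % 2 for i in range(len(scores))]
        a = roc_auc(scores, labels)
        b = roc_auc([-s for s in scores], labels)
        assert a + b == pytest.approx(1.0)


class TestDelong:
    def test_identical_classifiers(self):
        rng = np.random.default_rng(0)
        s = rng.random(20)
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        auc_a, auc_b, p = delong_test(s, s, y)
        assert auc_a == auc_b
        assert p == 1.0

    def test_reversal(self):
        s = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 0.95])
        y = np.array([0, 0, 0, 1, 1, 1])
        auc_a, auc_b, _ = delong_test(s, 1 - s, y)
        assert auc_b == pytest.approx(1 - auc_a)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            delong_test([0.1, 0.2], [0.3, 0.4], [1, 1])


def _logrank_oracle(records):
    """Hand O-E computation over the distinct event times (no censoring
    support needed for the fixture)."""
    times = sorted({r.pfs_months for r in records if r.event})
    O = E = V = 0.0
    for t in times:
        at_risk = [r for r in records if r.pfs_months >= t]
        n = len(at_risk)
        n1 = sum(1 for r in at_risk if r.group == "A")
        d = sum(1 for r in records if r.event and r.pfs_months == t)
        d1 = sum(1 for r in records
                 if r.event and r.pfs_months == t and r.group == "A")
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestKmLogrank:
    def test_identical_groups(self):
        recs = []
        for g in ("responder", "non_responder"):
            recs += [SurvivalRecord(t, True, g) for t in (3.0, 6.0, 9.0)]
        out = km_logrank(recs)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-9)
        assert out["p"] == pytest.approx(1.0)

    def test_hand_computed_table(self):
        recs = ([SurvivalRecord(float(t), True, "A") for t in (1, 2, 3, 4)]
                + [SurvivalRecord(float(t), True, "B") for t in (5, 6, 7, 8)])
        expected = _logrank_oracle(recs)
        # independent closed-form check of the oracle itself
        assert expected == pytest.approx((4 - (0.5 + 3 / 7 + 1 / 3 + 0.2)) ** 2
                                         / (0.25 + 12 / 49 + 8 / 36 + 4 / 25))
        out = km_logrank(recs)
        assert out["chi2"] == pytest.approx(expected, rel=1e-6)

    def test_all_censored_rejected(self):
        recs = [SurvivalRecord(0.1, False, "responder"),
                SurvivalRecord(0.1, False, "non_responder")]
        with pytest.raises(ValueError):
            km_logrank(recs)

    def test_km_curves_monotone(self):
        rng = np.random.default_rng(0)
        recs = [SurvivalRecord(float(t), bool(e),
                               "responder" if i % 2 else "non_responder")
                for i, (t, e) in enumerate(zip(rng.exponential(12, 30),
                                               rng.integers(0, 2, 30)))]
        if not any(r.event for r in recs):
            recs[0].event = True
        out = km_logrank(recs)
        for c in out["curves"].values():
            assert (np.diff(c["survival"]) <= 1e-12).all()


class TestSubgroups:
    def test_single_stratum(self):
        truths = [{"diameters_cm": [6.0], "lesion_count": 1, "fov_scale": 1.0}] * 3
        out = subgroup_report(truths, [0.8, 0.9, 0.7])
        assert out["size>=5"]["n"] == 3
        assert "size<3" not in out

    def test_partition(self):
        rng = np.random.default_rng(0)
        truths = [{"diameters_cm": [float(rng.uniform(1, 7))],
                   "lesion_count": int(rng.integers(1, 4)),
                   "fov_scale": 1.0} for _ in range(20)]
        out = subgroup_report(truths, list(rng.random(20)))
        size_n = sum(v["n"] for k, v in out.items() if k.startswith("size"))
        mult_n = sum(v["n"] for k, v in out.items() if k.startswith("mult"))
        assert size_n == mult_n == 20
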