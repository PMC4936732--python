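"""ROC curves, partial areas, standardization, DeLong and bootstrap."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tbiroc import rocm


def mann_whitney_auc(scores, labels):
    """Brute-force pair-counting oracle with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def grid_pauc(curve, axis, band, n_grid=100_000):
    """Independent integration of the piecewise-linear curve on a fine grid
    that includes the curve's own knots (trapezoid is then exact)."""
    if axis == "specificity":
        x, y = curve.specificity, curve.sensitivity
    else:
        x, y = curve.sensitivity[::-1], curve.specificity[::-1]
    lo, hi = band
    # collapse vertical segments: keep the max y at each x (curve is
    # non-increasing in y along x, so first occurrence is the upper value)
    xs = np.linspace(lo, hi, n_grid)
    knots = x[(x > lo) & (x < hi)]
    xs = np.unique(np.r_[xs, knots])
    # piecewise-linear interpolation along the polyline, vertical jumps
    # handled by integrating segment by segment
    total = 0.0
    for i in range(len(x) - 1):
        a, b = max(x[i], lo), min(x[i + 1], hi)
        if b <= a:
            continue
        seg = xs[(xs >= a) & (xs <= b)]
        seg = np.unique(np.r_[a, seg, b])
        ya = np.interp(seg, [x[i], x[i + 1]], [y[i], y[i + 1]])
        total += np.trapezoid(ya, seg)
    return total


def random_scores(rng, n=80, ties=False):
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[: n // 3 + 1]] = 1
    scores = rng.standard_normal(n) + 0.8 * labels
    if ties:
        scores = np.round(scores, 1)
    return scores, labels


class TestROCCurve:
    def test_constant_scores_give_diagonal(self):
        curve = rocm.roc_curve(np.ones(10), np.r_[np.ones(4), np.zeros(6)])
        assert len(curve.specificity) == 2
        assert rocm.auc(curve) == pytest.approx(0.5)

    def test_perfect_scores(self):
        labels = np.r_[np.zeros(5), np.ones(5)].astype(int)
        assert rocm.auc(rocm.roc_curve(labels.astype(float), labels)) == 1.0

    def test_documented_four_point_example(self):
        curve = rocm.roc_curve(np.array([0.1, 0.4, 0.35, 0.8]),
                               np.array([0, 0, 1, 1]))
        assert rocm.auc(curve) == pytest.approx(0.75)

    def test_corners_present(self, rng):
        scores, labels = random_scores(rng)
        c = rocm.roc_curve(scores, labels)
        assert c.specificity[0] == 0.0 and c.sensitivity[0] == 1.0
        assert c.specificity[-1] == 1.0 and c.sensitivity[-1] == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rocm.roc_curve(np.arange(4.0), np.ones(4, dtype=int))


class TestAUC:
    @pytest.mark.parametrize("ties", [False, True])
    def test_trapezoid_equals_pair_counting(self, rng, ties):
        for _ in range(25):
            scores, labels = random_scores(rng, ties=ties)
            got = rocm.auc(rocm.roc_curve(scores, labels))
            assert abs(got - mann_whitney_auc(scores, labels)) < 1e-12

    def test_flip_symmetry(self, rng):
        scores, labels = random_scores(rng)
        a = rocm.auc(rocm.roc_curve(scores, labels))
        b = rocm.auc(rocm.roc_curve(-scores, labels))
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_random_scores_near_half(self, rng):
        n = 2000
        labels = (rng.random(n) < 0.5).astype(int)
        scores = rng.standard_normal(n)
        se = np.sqrt(1 / (12 * labels.sum()) + 1 / (12 * (n - labels.sum())))
        assert abs(rocm.auc(rocm.roc_curve(scores, labels)) - 0.5) < 3 * se


class TestPartialAUC:
    def test_perfect_classifier_rectangle(self):
        labels = np.r_[np.zeros(50), np.ones(50)].astype(int)
        curve = rocm.roc_curve(labels.astype(float), labels)
        assert rocm.pauc(curve, "specificity", (0.9, 1.0)) == pytest.approx(0.1)
        assert rocm.pauc(curve, "sensitivity", (0.9, 1.0)) == pytest.approx(0.1)

    def test_chance_diagonal_analytic(self):
        curve = rocm.roc_curve(np.ones(20), np.r_[np.ones(8), np.zeros(12)])
        assert rocm.pauc(curve, "specificity", (0.9, 1.0)) == pytest.approx(0.005)

    @pytest.mark.parametrize("axis", ["specificity", "sensitivity"])
    @pytest.mark.parametrize("band", [(0.9, 1.0), (0.5, 0.8), (0.0, 1.0)])
    def test_matches_grid_integration(self, rng, axis, band):
        scores, labels = random_scores(rng, n=120, ties=True)
        curve = rocm.roc_curve(scores, labels)
        got = rocm.pauc(curve, axis, band)
        assert abs(got - grid_pauc(curve, axis, band)) < 1e-9

    def test_full_band_equals_auc(self, rng):
        scores, labels = random_scores(rng, n=200)
        curve = rocm.roc_curve(scores, labels)
        assert rocm.pauc(curve, "specificity", (0.0, 1.0)) == rocm.auc(curve)

    @given(st.integers(0, 2**31 - 1))
    def test_transposition_identity(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = random_scores(rng, n=60, ties=True)
        a = rocm.pauc(rocm.roc_curve(scores, labels), "sensitivity", (0.9, 1.0))
        b = rocm.pauc(rocm.roc_curve(-scores, 1 - labels), "specificity", (0.9, 1.0))
        assert abs(a - b) < 1e-12


class TestStandardization:
    @pytest.mark.parametrize("band", [(0.9, 1.0), (0.8, 0.95), (0.0, 1.0)])
    def test_mcclish_anchors(self, band):
        lo, hi = band
        assert rocm.standardize_pauc(rocm.chance_area(band), band) == pytest.approx(0.5)
        assert rocm.standardize_pauc(hi - lo, band) == pytest.approx(1.0)
        mid = 0.5 * (rocm.chance_area(band) + (hi - lo))
        assert rocm.standardize_pauc(mid, band) == pytest.approx(0.75)

    def test_strictly_increasing(self):
        band = (0.9, 1.0)
        raws = np.linspace(rocm.chance_area(band) * 0.5, 0.1, 20)
        vals = [rocm.standardize_pauc(r, band) for r in raws]
        assert np.all(np.diff(vals) > 0)

    def test_below_chance_flag(self):
        band = (0.9, 1.0)
        v = rocm.standardize_pauc(0.5 * rocm.chance_area(band), band)
        assert v < 0.5


class TestDeLong:
    def test_self_comparison(self, rng):
        scores, labels = random_scores(rng, n=100)
        res = rocm.delong_test(scores, scores.copy(), labels)
        assert res.p_value == 1.0 and res.estimate == 0.0

    def test_variance_shrinks_with_n(self, rng):
        variances = []
        for n in (100, 1000, 10000):
            scores, labels = random_scores(rng, n=n)
            variances.append(rocm.delong_variance(scores, labels))
        assert variances[0] > variances[1] > variances[2]

    def test_variance_matches_simulation(self):
        # empirical variance of the AUC estimator over many replicates
        n, mu, trials = 200, 0.8, 1500
        rng = np.random.default_rng(77)
        aucs, delong_vars = [], []
        for _ in range(trials):
            labels = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
            scores = rng.standard_normal(n) + mu * labels
            aucs.append(rocm.auc(rocm.roc_curve(scores, labels)))
            delong_vars.append(rocm.delong_variance(scores, labels))
        ratio = np.mean(delong_vars) / np.var(aucs, ddof=1)
        assert 0.85 < ratio < 1.15

    def test_unpaired_inputs_rejected(self, rng):
        scores, labels = random_scores(rng, n=50)
        with pytest.raises(ValueError):
            rocm.delong_test(scores, scores[:-1], labels)


class TestBootstrap:
    def test_identical_scores_p_one(self, rng):
        scores, labels = random_scores(rng, n=150)
        res = rocm.bootstrap_pauc_test(scores, scores.copy(), labels,
                                       reps=200, seed=1)
        assert res.p_value == 1.0

    def test_planted_difference_detected(self):
        rng = np.random.default_rng(5)
        n = 2000
        labels = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        z = rng.standard_normal(n)
        strong = z + 1.19 * labels   # AUC ~ 0.8
        weak = z + 0.36 * labels     # AUC ~ 0.6
        res = rocm.bootstrap_pauc_test(strong, weak, labels, reps=500, seed=2)
        assert res.p_value < 0.01

    def test_ci_contains_point_estimate(self, rng):
        scores, labels = random_scores(rng, n=400)
        lo, hi = rocm.pauc_ci(scores, labels, reps=400, seed=3)
        point = rocm.standardized_pauc(scores, labels)
        assert lo <= point <= hi

    def test_ci_width_stable_as_reps_double(self, rng):
        scores, labels = random_scores(rng, n=400)
        w = []
        for reps, seed in ((600, 3), (1200, 4)):
            lo, hi = rocm.pauc_ci(scores, labels, reps=reps, seed=seed)
            w.append(hi - lo)
        assert abs(w[0] - w[1]) < 0.35 * max(w)

    def test_reps_floor_enforced(self, rng):
        scores, labels = random_scores(rng)
        with pytest.raises(ValueError):
            rocm.pauc_ci(scores, labels, reps=50)
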