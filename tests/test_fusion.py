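"""Label fusion: averaging, voting, STAPLE EM and the regression combiner."""

import itertools

import numpy as np
import pytest

import segensemble as se
from segensemble import (ProbabilityMap, average_probability, majority_vote,
                         staple, staple_mask, threshold_mask)

from conftest import mask, random_mask


class TestAverageProbability:
    def test_idempotent_on_identical_masks(self, rng):
        m = random_mask(rng)
        p = average_probability([m, m, m])
        assert np.array_equal(p.voxels, m.voxels.astype(float))

    def test_two_of_four(self):
        on = mask(np.ones((2, 2, 2)))
        off = mask(np.zeros((2, 2, 2)))
        p = average_probability([on, on, off, off])
        assert np.all(p.voxels == 0.5)

    def test_degenerate_weights_select_first(self, rng):
        masks = [random_mask(rng) for _ in range(3)]
        p = average_probability(masks, weights=[1, 0, 0])
        assert np.array_equal(p.voxels, masks[0].voxels.astype(float))

    def test_weight_normalisation(self, rng):
        masks = [random_mask(rng) for _ in range(3)]
        assert np.allclose(average_probability(masks, [2, 2, 2]).voxels,
                           average_probability(masks).voxels)

    def test_all_zero_weights_rejected(self, rng):
        with pytest.raises(ValueError, match="zero"):
            average_probability([random_mask(rng)], weights=[0.0])

    def test_permutation_invariance_and_bounds(self, rng):
        masks = [random_mask(rng) for _ in range(5)]
        p1 = average_probability(masks).voxels
        p2 = average_probability(masks[::-1]).voxels
        assert np.array_equal(p1, p2)
        stack = np.stack([m.voxels for m in masks])
        assert np.all(p1 >= stack.min(axis=0)) and np.all(p1 <= stack.max(axis=0))


class TestThresholdMask:
    def test_tie_is_foreground(self):
        p = ProbabilityMap(np.full((2, 2, 2), 0.35))
        assert threshold_mask(p, 0.35).voxels.all()

    def test_two_of_sixteen_below_035(self):
        on = mask(np.ones((2, 2, 2)))
        off = mask(np.zeros((2, 2, 2)))
        p = average_probability([on, on] + [off] * 14)
        assert not threshold_mask(p, 0.35).voxels.any()

    def test_all_zero_map(self):
        p = ProbabilityMap(np.zeros((3, 3, 3)))
        assert threshold_mask(p, 0.5).is_empty()

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_threshold_domain(self, bad):
        p = ProbabilityMap(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            threshold_mask(p, bad)


class TestMajorityVote:
    def test_two_of_three_foreground(self):
        on = mask(np.ones((2, 2, 2)))
        off = mask(np.zeros((2, 2, 2)))
        assert majority_vote([on, on, off]).voxels.all()

    def test_exact_half_is_background(self):
        on = mask(np.ones((2, 2, 2)))
        off = mask(np.zeros((2, 2, 2)))
        assert not majority_vote([on, on, off, off]).voxels.any()

    @pytest.mark.parametrize("J", [3, 5])
    def test_equals_threshold_just_above_half_exhaustive(self, J):
        """For odd J, strict-majority voting equals averaging + threshold
        at 0.5 + eps, checked over all 2^J single-voxel vote patterns."""
        for eps in (1e-9, 1 / (4 * J), 1 / (2 * J)):
            for pattern in itertools.product((0, 1), repeat=J):
                masks = [mask(np.full((1, 1, 1), v)) for v in pattern]
                vote = majority_vote(masks).voxels[0, 0, 0]
                avg = threshold_mask(average_probability(masks),
                                     0.5 + eps).voxels[0, 0, 0]
                assert vote == avg, (pattern, eps)


def naive_staple_reference(masks, prior, init_p=0.9, init_q=0.9, n_iter=50):
    """Direct (non-log-space) EM iteration of the two update equations;
    independent of the library implementation."""
    D = np.stack([m.voxels.reshape(-1).astype(float) for m in masks])
    J, N = D.shape
    p = np.full(J, init_p)
    q = np.full(J, init_q)
    for _ in range(n_iter):
        a = prior * np.prod(np.where(D, p[:, None], 1 - p[:, None]), axis=0)
        b = (1 - prior) * np.prod(np.where(D, 1 - q[:, None], q[:, None]), axis=0)
        W = a / (a + b)
        p = (D * W).sum(axis=1) / W.sum()
        q = ((1 - D) * (1 - W)).sum(axis=1) / (1 - W).sum()
    return W, p, q


class TestStaple:
    def _rater_fixture(self, shape=(20, 20, 20), J=5, sens=0.9, spec=0.9):
        gt = np.zeros(shape, dtype=bool)
        gt[5:15, 5:15, 5:15] = True
        gtm = mask(gt)
        return gtm, [se.simulate_rater(gtm, sens, spec, 100 + j)
                     for j in range(J)]

    def test_degenerate_consensus(self, rng):
        m = random_mask(rng, (8, 8, 8), p=0.4)
        res = staple([m, m, m, m])
        fused = staple_mask(res.probability)
        assert np.array_equal(fused.voxels, m.voxels)
        for perf in res.performances:
            assert perf.sensitivity >= 0.9 and perf.specificity >= 0.9

    def test_single_rater_matches_hand_iteration(self, rng):
        m = random_mask(rng, (6, 6, 6), p=0.3)
        prior = float(m.voxels.mean())
        res = staple([m], prior=prior, tol=1e-12, max_iter=60)
        W_ref, p_ref, q_ref = naive_staple_reference([m], prior, n_iter=60)
        assert np.allclose(res.probability.voxels.reshape(-1), W_ref, atol=1e-6)
        assert np.array_equal(staple_mask(res.probability, 0.5).voxels, m.voxels)

    def test_matches_naive_reference_em(self):
        gtm, raters = self._rater_fixture()
        prior = float(np.mean([r.voxels.mean() for r in raters]))
        res = staple(raters, tol=0.0, max_iter=30)  # fixed iteration count
        W_ref, p_ref, q_ref = naive_staple_reference(raters, prior, n_iter=30)
        assert np.allclose([r.sensitivity for r in res.performances], p_ref,
                           atol=1e-9)
        assert np.allclose([r.specificity for r in res.performances], q_ref,
                           atol=1e-9)

    def test_matches_simpleitk(self):
        """Independent cross-check against the reference STAPLE filter."""
        sitk = pytest.importorskip("SimpleITK")
        gtm, raters = self._rater_fixture()
        f = sitk.STAPLEImageFilter()
        f.SetForegroundValue(1)
        out = f.Execute([sitk.GetImageFromArray(r.voxels.astype(np.uint8))
                         for r in raters])
        res = staple(raters, tol=1e-9, max_iter=300)
        assert np.allclose([r.sensitivity for r in res.performances],
                           f.GetSensitivity(), atol=1e-4)
        assert np.allclose([r.specificity for r in res.performances],
                           f.GetSpecificity(), atol=1e-4)
        assert np.allclose(res.probability.voxels,
                           sitk.GetArrayFromImage(out), atol=1e-5)

    def test_log_likelihood_non_decreasing(self):
        gtm, raters = self._rater_fixture(J=6, sens=0.8, spec=0.85)
        res = staple(raters)
        assert np.all(np.diff(res.log_likelihood) >= -1e-6)

    def test_threshold_insensitivity_on_converged_field(self):
        """A sharply converged weight field binarises almost identically
        anywhere well inside (0, 1)."""
        gtm, raters = self._rater_fixture(J=8, sens=0.92, spec=0.95)
        res = staple(raters)
        lo = staple_mask(res.probability, 0.05).volume_voxels
        hi = staple_mask(res.probability, 0.95).volume_voxels
        mid = staple_mask(res.probability, 0.5).volume_voxels
        assert (lo - hi) < 0.01 * mid

    def test_tie_field_all_foreground(self):
        W = ProbabilityMap(np.full((2, 2, 2), 0.5))
        assert staple_mask(W, 0.5).voxels.all()

    def test_input_validation(self, rng):
        m = random_mask(rng)
        with pytest.raises(ValueError):
            staple([m], prior=1.5)
        with pytest.raises(ValueError):
            staple([m], init_p=0.0)
        with pytest.raises(ValueError):
            staple([])


def _blocky_mask(overlap, total=10, shape=(4, 4, 4)):
    """A mask sharing `overlap` of `total` voxels with the reference block."""
    v = np.zeros(shape, dtype=bool)
    flat = v.reshape(-1)
    flat[:overlap] = True
    flat[total:total + (total - overlap)] = True
    return mask(v)


class TestRegressionCombiner:
    def test_exact_affine_relation_recovered(self):
        """With model B == reference, DSC(A, GT) == DSC(A, B) exactly, so
        the fit must interpolate with slope 1 / intercept 0 to 1e-9."""
        ref = _blocky_mask(10)
        training = [([_blocky_mask(k), ref], ref) for k in (2, 4, 6, 8, 10)]
        model = se.fit_regression_combiner(training, model_ids=["a", "b"])
        assert model.intercepts[0] == pytest.approx(0.0, abs=1e-9)
        assert model.coefficients[0, 0] == pytest.approx(1.0, abs=1e-9)
        assert model.residual_rms[0] == pytest.approx(0.0, abs=1e-9)

    def test_identical_models_rank_deficient(self, rng):
        m = [random_mask(rng, (5, 5, 5)) for _ in range(4)]
        training = [([m[i], m[i], m[i]], m[i]) for i in range(4)]
        with pytest.raises(ValueError, match="rank-deficient"):
            se.fit_regression_combiner(training)

    def test_underdetermined_rejected(self, rng):
        training = [([random_mask(rng) for _ in range(4)], random_mask(rng))
                    for _ in range(3)]  # n_train=3 < J=4
        with pytest.raises(ValueError, match="underdetermined"):
            se.fit_regression_combiner(training)

    def test_tie_breaks_to_first_model(self, rng):
        m = random_mask(rng)
        combiner = se.RegressionCombinerModel(
            ("a", "b", "c"), np.zeros(3), np.zeros((3, 2)), 5, np.zeros(3))
        selected, _, scores = se.apply_regression_combiner(combiner, [m, m, m])
        assert selected == "a"
        assert np.allclose(scores, scores[0])

    def test_selection_invariant_to_score_shift(self, rng):
        masks = [random_mask(rng) for _ in range(3)]
        base = se.RegressionCombinerModel(
            ("a", "b", "c"), np.array([0.1, 0.5, 0.2]), np.zeros((3, 2)),
            5, np.zeros(3))
        shifted = se.RegressionCombinerModel(
            ("a", "b", "c"), base.intercepts + 7.0, base.coefficients,
            5, np.zeros(3))
        assert (se.apply_regression_combiner(base, masks)[0]
                == se.apply_regression_combiner(shifted, masks)[0])

    def test_candidate_count_mismatch(self, rng):
        combiner = se.RegressionCombinerModel(
            ("a", "b"), np.zeros(2), np.zeros((2, 1)), 3, np.zeros(2))
        with pytest.raises(ValueError, match="candidate"):
            se.apply_regression_combiner(combiner, [random_mask(rng)])


class TestSweepThreshold:
    def test_single_model_constant_curve(self, rng):
        m = random_mask(rng)
        table, _ = se.sweep_threshold([[m]], [m], [0.2, 0.5, 0.8])
        assert table["dsc"].nunique() == 1
        assert table["mssd"].nunique() == 1

    def test_all_foreground_plus_truth(self):
        """With one all-foreground model and one equal to the truth, any
        threshold > 0.5 yields the intersection (= truth, DSC 1) and
        thresholds <= 0.5 yield the union."""
        gt = _blocky_mask(10)
        full = mask(np.ones(gt.shape))
        table, optima = se.sweep_threshold([[full, gt]], [gt],
                                           [0.3, 0.5, 0.7, 0.9])
        by_thr = dict(zip(table["p_thr"], table["dsc"]))
        assert by_thr[0.7] == by_thr[0.9] == 1.0
        assert by_thr[0.3] == by_thr[0.5] == pytest.approx(se.dice(full, gt))
        assert optima["dsc"] == 0.7  # smallest of the tied optima

    def test_grid_validation(self, rng):
        m = random_mask(rng)
        with pytest.raises(ValueError):
            se.sweep_threshold([[m]], [m], [])
        with pytest.raises(ValueError):
            se.sweep_threshold([[m]], [m], [0.0, 0.5])
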