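"""Estimators: propensities, IPW/AIPW micro-fixtures, weights, inference."""

import numpy as np
import pytest

import smartrar.estimators as est
from smartrar.engine import run_trial, upfront_ts
from smartrar.estimators import (
    AugmentationCache,
    DegenerateVarianceError,
    EstimationError,
    RegimeMaps,
    WeightState,
    _waipw_core,
    _wipw_core,
    estimate_values,
    joint_confidence_covariance,
    mestimation_inference,
    policy_propensity_pieces,
    propensity_matrices,
    update_stabilizing_weights,
)
from smartrar.qmodels import q2_features
from smartrar.scenario import draw_outcome
from smartrar.trial import UPFRONT, TrialData


def make_upfront(design, a1, x22, a2, y, probs, x1=None, x21=None, enroll=None):
    """Completed up-front-scheme trial data from explicit per-subject fields."""
    n = len(a1)
    data = TrialData.allocate(
        n, design, UPFRONT,
        np.asarray(enroll) if enroll is not None else np.ones(n, int),
    )
    data.a1 = np.asarray(a1, int)
    data.x22 = np.asarray(x22, int)
    data.a2 = np.asarray(a2, int)
    data.y = np.asarray(y, float)
    data.x1 = np.asarray(x1, float) if x1 is not None else np.zeros(n)
    data.x21 = np.asarray(x21, float) if x21 is not None else np.zeros(n)
    data.regime_probs = np.asarray(probs, float)
    return data


UNIFORM8 = np.full(8, 0.125)


class TestPropensities:
    def test_uniform_policy_regime1_responder(self, design):
        data = make_upfront(design, [0], [1], [0], [1.0], [UNIFORM8])
        pi1, pi2 = propensity_matrices(data)
        assert pi1[0, 0] == pytest.approx(0.5)
        assert pi2[0, 0] == pytest.approx(0.5)

    def test_skewed_policy_regime1_nonresponder(self, design):
        r = np.array([0.2, 0.1, 0.1, 0.1, 0.125, 0.125, 0.125, 0.125])
        data = make_upfront(design, [0], [0], [1], [1.0], [r])
        pi1, pi2 = propensity_matrices(data)
        assert pi1[0, 0] == pytest.approx(0.5)
        # nonresponders: regimes 1 and 4 recommend option 1
        assert pi2[0, 0] == pytest.approx((r[0] + r[3]) / 0.5)

    def test_degenerate_mass_on_regime1(self, design):
        r = np.array([1.0] + [0.0] * 7)
        data = make_upfront(design, [0], [1], [0], [1.0], [r])
        pi1, pi2 = propensity_matrices(data)
        assert pi1[0, 0] == 1.0 and pi2[0, 0] == 1.0

    def test_missing_stored_probabilities_raise(self, design):
        data = make_upfront(design, [0], [1], [0], [1.0], [UNIFORM8])
        data.regime_probs[0] = np.nan
        with pytest.raises(EstimationError, match="corrupt"):
            propensity_matrices(data)


class TestWIPW:
    def test_constant_propensity_cancels(self, design):
        data = make_upfront(
            design, [0] * 3, [1] * 3, [0] * 3, [1.7, 1.9, 1.5], [UNIFORM8] * 3
        )
        theta, _ = est.wipw_estimate(data, 1)
        assert theta == pytest.approx(np.mean([1.7, 1.9, 1.5]))

    def test_hand_weighted_ratio(self, design):
        # propensity products 0.5 and 0.25 with outcomes 1 and 2
        r_half = np.array([0.25, 0.25, 0.25, 0.25, 0, 0, 0, 0])
        data = make_upfront(
            design, [0, 0], [1, 1], [0, 0], [1.0, 2.0], [r_half, UNIFORM8]
        )
        theta, _ = est.wipw_estimate(data, 1)
        assert theta == pytest.approx((2 * 1 + 4 * 2) / (2 + 4))

    def test_no_consistent_completers_raises(self, design):
        data = make_upfront(design, [1], [1], [3], [0.5], [UNIFORM8])
        with pytest.raises(EstimationError):
            est.wipw_estimate(data, 1)

    def test_large_sample_consistency_under_fixed_policy(self, design, params, truth, rng):
        n = 40_000
        x1 = rng.normal(5, 1, n)
        a1 = rng.integers(0, 2, n)
        x21 = 0.9 * x1 - 1.5 * a1 + rng.normal(size=n)
        x22 = (x21 < 0.9 * x1).astype(int)
        # uniform stage-2 within feasible sets
        a2 = np.empty(n, int)
        for (g1, gs), opts in design.feasible_stage2.items():
            rows = (a1 == g1) & (x22 == gs)
            a2[rows] = rng.choice(sorted(opts), size=rows.sum())
        y = draw_outcome(x1, a1, x21, a2, params, rng=rng)
        data = make_upfront(design, a1, x22, a2, y, [UNIFORM8] * n, x1=x1, x21=x21)
        table = estimate_values(data, "ipw")
        assert table.theta[7] == pytest.approx(truth.theta[7], abs=3 * table.se[7])


class TestWAIPW:
    def test_single_subject_hand_value(self, design):
        # pi1 = pi2 = 0.5, Y = 2, L1 = L2 = 1  ->  2/0.25 - 1 - 2 = 5
        r = np.full(8, 0.125)
        r[:4] = 0.125  # family mass 0.5; responder-matching mass 0.25
        data = make_upfront(design, [0], [1], [0], [2.0], [r])
        maps = RegimeMaps(design)
        C1, C = est.consistency_matrices(data, maps)
        PI1, PI2 = propensity_matrices(data, maps)
        ones = np.ones((1, 8))
        theta, M, denom = _waipw_core(
            data.y, np.array([True]), C1, C, PI1, PI2, ones, ones, ones
        )
        assert theta[0] == pytest.approx(5.0)

    def test_zero_augmentation_reduces_to_horvitz_thompson(self, design, rng):
        n = 50
        a1 = rng.integers(0, 2, n)
        x22 = rng.integers(0, 2, n)
        a2 = np.array(
            [rng.choice(sorted(design.feasible_set(2, a, s))) for a, s in zip(a1, x22)]
        )
        y = rng.normal(size=n)
        data = make_upfront(design, a1, x22, a2, y, [UNIFORM8] * n)
        maps = RegimeMaps(design)
        C1, C = est.consistency_matrices(data, maps)
        PI1, PI2 = propensity_matrices(data, maps)
        zeros = np.zeros((n, 8))
        mask = np.ones(n, bool)
        theta, _, _ = _waipw_core(
            data.y, mask, C1, C, PI1, PI2, zeros, zeros, np.ones((n, 8))
        )
        prod = np.nan_to_num(PI1 * PI2)
        for j in range(8):
            ht = np.sum(C[:, j] * y / np.where(prod[:, j] > 0, prod[:, j], 1)) / n
            assert theta[j] == pytest.approx(ht)

    def test_wrong_augmentation_models_do_not_bias(self, design, params, truth, rng):
        # deliberately wrong L (constant 3): estimate still near truth
        n = 40_000
        a1 = rng.integers(0, 2, n)
        x1 = rng.normal(5, 1, n)
        x21 = 0.9 * x1 - 1.5 * a1 + rng.normal(size=n)
        x22 = (x21 < 0.9 * x1).astype(int)
        a2 = np.empty(n, int)
        for (g1, gs), opts in design.feasible_stage2.items():
            rows = (a1 == g1) & (x22 == gs)
            a2[rows] = rng.choice(sorted(opts), size=rows.sum())
        y = draw_outcome(x1, a1, x21, a2, params, rng=rng)
        data = make_upfront(design, a1, x22, a2, y, [UNIFORM8] * n)
        maps = RegimeMaps(design)
        C1, C = est.consistency_matrices(data, maps)
        PI1, PI2 = propensity_matrices(data, maps)
        L = np.full((n, 8), 3.0)
        mask = np.ones(n, bool)
        theta, M, denom = _waipw_core(data.y, mask, C1, C, PI1, PI2, L, L,
                                      np.ones((n, 8)))
        se = np.sqrt((M[:, 7] ** 2).sum()) / denom[7]
        assert theta[7] == pytest.approx(truth.theta[7], abs=3 * se)


class TestAugmentationModels:
    def _noiseless_data(self, design, params, rng, n=600):
        beta2 = np.array([-4.201, 0.3, -0.75, 0.6, -0.25, -0.75, -0.75, -0.85])
        x1 = rng.normal(5, 1, n)
        a1 = rng.integers(0, 2, n)
        x21 = 0.9 * x1 - 1.5 * a1 + rng.normal(size=n)
        x22 = (x21 < 0.9 * x1).astype(int)
        a2 = np.array(
            [rng.choice(sorted(design.feasible_set(2, a, s))) for a, s in zip(a1, x22)]
        )
        y = q2_features(x1, a1, x21, a2) @ beta2  # no noise
        data = make_upfront(design, a1, x22, a2, y, [UNIFORM8] * n,
                            x1=x1, x21=x21, enroll=np.ones(n, int))
        return data, beta2

    def test_noiseless_q2_recovered_exactly(self, design, params, rng):
        data, beta2 = self._noiseless_data(design, params, rng)
        cache = AugmentationCache(data)
        got_beta2, _ = cache.models_for_week(14)
        assert np.allclose(got_beta2, beta2, atol=1e-6)

    def test_pseudo_outcome_is_model_at_regime_action(self, design, params, rng):
        data, beta2 = self._noiseless_data(design, params, rng)
        # late enrollees are evaluated with models fitted on week-1 completers
        data.enroll_week[-100:] = 20
        cache = AugmentationCache(data)
        L1, L2 = cache.L_matrices(np.ones(len(data), bool))
        # regime 8 responders: recommended action is 4 -> hand matrix algebra
        rows = np.where((data.x22 == 1) & (data.enroll_week == 20))[0][:3]
        hand = q2_features(
            data.x1[rows], data.a1[rows], data.x21[rows], np.full(3, 4)
        ) @ beta2
        assert np.allclose(L2[rows, 7], hand, atol=1e-6)

    def test_weeks_without_completers_fall_back_to_zero(self, design, params, rng):
        data, _ = self._noiseless_data(design, params, rng)
        data.enroll_week[:] = 5  # completion week 17; no strict-past completers at 5
        cache = AugmentationCache(data)
        L1, L2 = cache.L_matrices(np.ones(len(data), bool))
        assert np.all(L1 == 0) and np.all(L2 == 0)


class TestInference:
    def test_closed_form_symmetric_terms(self):
        M = np.concatenate([np.ones(50), -np.ones(50)])
        v = mestimation_inference(M, denom=100.0, theta=0.0, n_consistent=100)
        assert v.se == pytest.approx(0.1)
        assert v.ci_high - v.theta == pytest.approx(1.96 * 0.1, abs=1e-3)
        assert v.delta_T == pytest.approx(-1.0)

    def test_single_subject_rejected(self):
        with pytest.raises(EstimationError):
            mestimation_inference(np.array([1.0]), 1.0, 0.0, n_consistent=1)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            mestimation_inference(np.zeros(10), 10.0, 0.0, n_consistent=10)

    def test_ci_contains_estimate(self, sr_ledger):
        table = estimate_values(sr_ledger.data, "ipw")
        assert np.all(table.ci_low <= table.theta)
        assert np.all(table.theta <= table.ci_high)
        assert np.all(table.se > 0)


class TestJointCovariance:
    def test_diagonal_equals_squared_se(self, sr_ledger):
        table = estimate_values(sr_ledger.data, "ipw")
        assert np.allclose(np.diag(table.covariance), table.se**2)

    def test_disjoint_regimes_uncorrelated(self, sr_ledger):
        # regimes 1 and 8 share no consistent subjects (different stage-1 arm)
        table = estimate_values(sr_ledger.data, "ipw")
        assert table.covariance[0, 7] == 0.0

    def test_shared_responder_path_positively_correlated(self, sr_ledger):
        # regimes 7 and 8 recommend the same responder option
        table = estimate_values(sr_ledger.data, "ipw")
        assert table.covariance[6, 7] > 0


@pytest.fixture(scope="module")
def adaptive_ledger(params):
    return run_trial(params, upfront_ts("wipw", 1.0),
                     seed=np.random.SeedSequence([5, 1]))


class TestEquivalences:
    def test_unit_weights_reduce_wipw_to_ipw_bitwise(self, adaptive_ledger):
        data = adaptive_ledger.data
        assert not np.allclose(data.w, 1.0)  # the trial did adapt
        saved = data.w.copy()
        data.w = np.ones_like(data.w)
        try:
            a = estimate_values(data, "wipw")
            b = estimate_values(data, "ipw")
        finally:
            data.w = saved
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.se, b.se)

    def test_unit_weights_reduce_waipw_to_aipw_bitwise(self, adaptive_ledger):
        data = adaptive_ledger.data
        saved = data.wa.copy()
        data.wa = np.ones_like(data.wa)
        try:
            a = estimate_values(data, "waipw")
            b = estimate_values(data, "aipw")
        finally:
            data.wa = saved
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.se, b.se)


class TestStabilizingWeights:
    def test_unchanged_policy_gives_unit_weight(self, sr_ledger, design):
        data = sr_ledger.data
        maps = RegimeMaps(design)
        mask = data.completed_by(40)
        pieces = policy_propensity_pieces(maps, UPFRONT, {"regimes": UNIFORM8})
        state = WeightState(8)
        update_stabilizing_weights(state, data, mask, pieces, maps, anchor_now=True)
        w = update_stabilizing_weights(state, data, mask, pieces, maps)
        assert np.allclose(w, 1.0)

    def test_square_root_ratio(self, sr_ledger, design):
        # halving every current-week probability scales Xi by 4 -> W = 0.5
        data = sr_ledger.data
        maps = RegimeMaps(design)
        mask = data.completed_by(40)
        pieces = policy_propensity_pieces(maps, UPFRONT, {"regimes": UNIFORM8})
        state = WeightState(8)
        update_stabilizing_weights(state, data, mask, pieces, maps, anchor_now=True)
        halved = (pieces[0] * 0.5, pieces[1] * 0.5)
        w = update_stabilizing_weights(state, data, mask, halved, maps)
        assert np.allclose(w, 0.5)

    def test_burnin_weights_are_one(self, params):
        ledger = run_trial(params, upfront_ts("wipw", 1.0),
                           seed=np.random.SeedSequence([5, 2]))
        t_star = min(s.week for s in ledger.snapshots if s.burnin_complete)
        early = ledger.data.enroll_week <= t_star
        assert np.all(ledger.data.w[early] == 1.0)
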