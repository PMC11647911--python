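"""Sequential TS: Q-learning fits, pseudo outcomes, projection draws, beliefs."""

import numpy as np
import pytest

from smartrar.design import SMARTDesign
from smartrar.engine import run_trial, sequential_ts
from smartrar.qmodels import q1_additive_features, q2_features
from smartrar.trial import SEQUENTIAL, TrialData
from smartrar.ts_sequential import (
    FitError,
    projection_draws,
    pseudo_outcomes,
    qfit_stage,
    sequential_beliefs,
)


class TestQFit:
    def test_noiseless_exact_recovery(self, rng):
        x = rng.normal(size=(50, 3))
        phi = np.column_stack([np.ones(50), x])
        beta = np.array([1.0, -2.0, 0.5, 3.0])
        fit = qfit_stage(phi, phi @ beta)
        assert np.allclose(fit.beta, beta, atol=1e-6)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_two_point_interpolation(self):
        phi = np.array([[1.0, 0.0], [1.0, 1.0]])
        fit = qfit_stage(phi, np.array([0.0, 1.0]))
        assert np.allclose(fit.beta, [0.0, 1.0], atol=1e-6)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_four_point_closed_form_covariance(self):
        phi = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 3.0]])
        y = np.array([0.0, 1.0, 1.0, 2.0])
        fit = qfit_stage(phi, y)
        xtx_inv = np.linalg.inv(phi.T @ phi)
        beta = xtx_inv @ phi.T @ y
        sigma2 = ((y - phi @ beta) ** 2).mean()  # denominator n
        assert np.allclose(fit.beta, beta, atol=1e-6)
        assert np.allclose(fit.cov, sigma2 * xtx_inv, atol=1e-6)

    def test_underdetermined_raises(self):
        with pytest.raises(FitError):
            qfit_stage(np.ones((2, 3)), np.zeros(2))


class TestPseudoOutcomes:
    def test_two_point_comparison_minimize(self, design):
        # group (0, 1): options {0, 1} with effects 0 and beta24
        beta2 = np.zeros(8)
        beta2[4] = 2.0  # option 1 is worse when minimizing
        v = pseudo_outcomes(
            np.array([5.0]), np.array([0]), np.array([4.0]), np.array([1]),
            np.array([9.9]), beta2, design, minimize=True,
        )
        assert v[0] == pytest.approx(0.0)  # base value 0, picks option 0

    def test_known_coefficients_hand_fixture(self, design):
        beta2 = np.array([1.0, 0.1, -0.5, 0.2, -0.25, -0.75, -0.75, -0.85])
        x1 = np.array([5.0, 4.0, 6.0])
        a1 = np.array([1, 1, 0])
        x21 = np.array([3.0, 3.5, 5.0])
        x22 = np.array([1, 0, 0])
        v = pseudo_outcomes(x1, a1, x21, x22, np.zeros(3), beta2, design)
        base = beta2[0] + beta2[1] * x1 + beta2[2] * (a1 == 1) + beta2[3] * x21
        hand = [
            base[0] + min(-0.75, -0.85),   # (1, resp): options {3,4}
            base[1] + min(-0.85, -0.75),   # (1, nonresp): {4,5}
            base[2] + min(-0.25, -0.75),   # (0, nonresp): {1,2}
        ]
        assert np.allclose(v, hand)

    def test_single_option_carries_back_outcome(self):
        d = SMARTDesign(
            treatment_sets=[{0, 1}, {1, 2}],
            feasible_stage2={(0, 1): {1}, (0, 0): {1, 2},
                             (1, 1): {1}, (1, 0): {1, 2}},
        )
        v = pseudo_outcomes(
            np.array([5.0]), np.array([0]), np.array([4.0]), np.array([1]),
            np.array([7.25]), np.zeros(8), d, minimize=True,
        )
        assert v[0] == pytest.approx(7.25)


def _completed_sequential_data(design, params, rng, n=400):
    from smartrar.scenario import draw_outcome

    data = TrialData.allocate(n, design, SEQUENTIAL, np.ones(n, int))
    data.x1 = rng.normal(5, 1, n)
    data.a1 = rng.integers(0, 2, n)
    data.x21 = 0.9 * data.x1 - 1.5 * data.a1 + rng.normal(size=n)
    data.x22 = (data.x21 < 0.9 * data.x1).astype(int)
    a2 = np.empty(n, int)
    p2 = np.zeros((n, 6))
    for (g1, gs), opts in design.feasible_stage2.items():
        rows = (data.a1 == g1) & (data.x22 == gs)
        opts = sorted(opts)
        a2[rows] = rng.choice(opts, size=rows.sum())
        p2[np.ix_(rows, opts)] = 0.5
    data.a2 = a2
    data.stage2_probs = p2
    data.stage1_probs = np.full((n, 2), 0.5)
    data.y = draw_outcome(data.x1, data.a1, data.x21, data.a2, params, rng=rng)
    return data


class TestProjectionDraws:
    def test_pool_sizes(self, design, params, rng):
        data = _completed_sequential_data(design, params, rng)
        draws = projection_draws(data, np.ones(len(data), bool), (50, 32, 32), rng)
        assert draws.beta2.shape == (8, 50)
        assert draws.beta1.shape == (3, 32 * 32)

    def test_noiseless_pool_collapses_to_point_fits(self, design, params, rng):
        # outcomes exactly linear in stage-1 features (no interim-score
        # effect, equal stage-2 effects): both stage fits interpolate
        data = _completed_sequential_data(design, params, rng)
        beta2 = np.array([-4.2, 0.3, -0.75, 0.0, -0.8, -0.8, -0.8, -0.8])
        data.y = q2_features(data.x1, data.a1, data.x21, data.a2) @ beta2
        draws = projection_draws(data, np.ones(len(data), bool), (20, 8, 8), rng)
        assert np.allclose(draws.beta2, draws.fit2.beta[:, None], atol=1e-4)
        assert np.allclose(draws.beta1, draws.fit1.beta[:, None], atol=1e-4)

    def test_stage2_pool_covariance_matches_fit(self, design, params):
        local = np.random.default_rng(777)  # independent of test ordering
        data = _completed_sequential_data(design, params, local)
        draws = projection_draws(data, np.ones(len(data), bool), (100_000, 4, 4), local)
        got, want = np.cov(draws.beta2), draws.fit2.cov
        # marginal sds within 2%; full matrix within 5% plus MC slack on
        # near-zero off-diagonal entries
        assert np.allclose(np.sqrt(np.diag(got)), np.sqrt(np.diag(want)), rtol=0.02)
        assert np.allclose(got, want, rtol=0.05, atol=3e-3)


class TestSequentialBeliefs:
    def test_identical_effects_split_evenly(self, rng):
        draws = rng.normal(size=(3, 500))
        feats = np.zeros((2, 2, 3))
        feats[:, :, 0] = 1.0  # both options have identical features
        rho = sequential_beliefs(draws, feats)
        assert np.allclose(rho, 0.5)

    def test_counting_oracle(self):
        # option-1 effect below option-0 effect in 700 of 1000 draws (minimize)
        draws = np.zeros((2, 1000))
        draws[1, :700] = -1.0
        draws[1, 700:] = 1.0
        feats = np.zeros((1, 2, 2))
        feats[0, 1, 1] = 1.0  # option 1 carries the effect coefficient
        rho = sequential_beliefs(draws, feats, minimize=True)
        assert np.allclose(rho[0], [0.3, 0.7])

    def test_beliefs_constant_within_group_under_additive_spec(self, rng):
        # no treatment-by-covariate interaction: beliefs identical across x1
        draws = rng.normal(size=(3, 2000))
        rhos = []
        for x1 in (2.0, 5.0, 9.0):
            feats = np.stack(
                [q1_additive_features(np.array([x1]), np.array([a]))[0] for a in (0, 1)]
            )[None]
            rhos.append(sequential_beliefs(draws, feats, minimize=True)[0])
        assert np.allclose(rhos[0], rhos[1]) and np.allclose(rhos[1], rhos[2])


class TestSequentialPolicyBehavior:
    def test_uniform_before_burnin_and_c0_uniform_after(self, params):
        import dataclasses

        small = dataclasses.replace(params, n_subjects=120)
        ledger = run_trial(small, sequential_ts(1.0), seed=11)
        # burn-in (25 consistent completers per regime) is unreachable at N=120
        for snap in ledger.snapshots:
            assert not snap.burnin_complete
            for vec in snap.vectors.values():
                assert np.allclose(vec, 1.0 / len(vec))

    def test_zero_damping_keeps_groups_uniform(self, params):
        ledger = run_trial(params, sequential_ts(0.0), seed=12)
        assert any(s.burnin_complete for s in ledger.snapshots)
        for snap in ledger.snapshots:
            for vec in snap.vectors.values():
                assert np.allclose(vec, 1.0 / len(vec))

    def test_dominant_group_effect_hits_clip_bound(self, design, params, rng):
        import dataclasses

        # make stage-2 maintenance (code 4) hugely better for the treated arm
        strong = dataclasses.replace(
            params, gamma2=(0.0, 0.3, -0.75, 0.6, -0.25, -0.75, -0.75, -20.0)
        )
        from smartrar.estimators import WeightState
        from smartrar.ts_sequential import update_sequential_policy

        data = _completed_sequential_data(design, strong, rng, n=800)
        cfg = sequential_ts(1.0)
        snap = update_sequential_policy(
            data, 30, cfg, WeightState(8), WeightState(8),
            np.random.default_rng(0), burnin_complete=True,
        )
        # groups (1, resp) = {3,4} and (1, nonresp) = {4,5}: code 4 dominates
        assert snap.vectors[("stage2", 1, 1)][1] == pytest.approx(0.95)
        assert snap.vectors[("stage2", 1, 0)][0] == pytest.approx(0.95)
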