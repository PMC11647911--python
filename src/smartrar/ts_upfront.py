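"""Up-front Thompson sampling over embedded regimes.

Each week, value estimates for the m embedded regimes and their joint
M-estimation covariance define an estimated confidence distribution (a
multivariate normal centered at the estimates).  B draws from it yield
beliefs -- the fraction of draws in which each regime attains the optimum
-- which are tempered by a damping exponent c_t, clipped to [lo, hi], and
renormalized once to give the week's randomization vector over regimes.
"""

from __future__ import annotations

import numpy as np

from .estimators import (
    AugmentationCache,
    RegimeMaps,
    WeightState,
    estimate_values,
    policy_propensity_pieces,
    update_stabilizing_weights,
    update_stabilizing_weights_aipw,
)
from .trial import UPFRONT, PolicySnapshot, TrialData

#: jitter added to the covariance diagonal before Cholesky
COV_JITTER = 1e-10


def draw_confidence(theta, cov, B: int, rng: np.random.Generator) -> np.ndarray:
    """B draws from the estimated confidence distribution N(theta, cov)."""
    theta = np.asarray(theta, dtype=float)
    cov = np.asarray(cov, dtype=float)
    m = theta.shape[0]
    if B < 1:
        raise ValueError("B must be >= 1")
    cov = np.where(np.isfinite(cov), cov, 0.0)
    cov = 0.5 * (cov + cov.T) + COV_JITTER * np.eye(m)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance not positive semi-definite after jitter") from err
    return theta[None, :] + rng.standard_normal((B, m)) @ chol.T


def beliefs_from_draws(draws: np.ndarray, minimize: bool = False) -> np.ndarray:
    """Fraction of draws in which each regime attains the optimum.

    Ties within a draw are split equally among the tied regimes, so the
    beliefs sum to 1 exactly.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 1:
        raise ValueError("draws must be a (B, m) matrix with B >= 1")
    vals = -draws if minimize else draws
    best = vals.max(axis=1, keepdims=True)
    hits = (vals == best).astype(float)
    hits /= hits.sum(axis=1, keepdims=True)
    return hits.mean(axis=0)


def damp_and_clip(rho, c_t: float, lo: float, hi: float) -> np.ndarray:
    """Randomization vector: beliefs^c_t, normalized, clipped once, renormalized.

    ``c_t = 0`` gives the uniform vector regardless of beliefs (with the
    convention 0^0 = 1); ``c_t = 1`` with no clipping binding returns the
    beliefs themselves.  Clip-then-normalize is a single pass, so entries
    may fall slightly below ``lo`` after the final normalization;
    strict positivity always holds.
    """
    rho = np.asarray(rho, dtype=float)
    m = rho.shape[0]
    if not 0.0 <= c_t <= 1.0:
        raise ValueError("damping constant must lie in [0, 1]")
    if not (0.0 < lo < 1.0 / m < hi <= 1.0):
        raise ValueError("clip bounds must satisfy 0 < lo < 1/m < hi <= 1")
    if np.all(rho == 0):
        return np.full(m, 1.0 / m)
    if c_t == 0.0:
        r = np.ones(m)
    else:
        with np.errstate(divide="ignore"):
            r = np.power(rho, c_t)
    r = r / r.sum()
    r = np.clip(r, lo, hi)
    return r / r.sum()


def update_upfront_policy(
    data: TrialData,
    week: int,
    config,
    weight_state: WeightState,
    weight_state_a: WeightState,
    rng: np.random.Generator,
    maps: RegimeMaps | None = None,
    aug: AugmentationCache | None = None,
    previous: np.ndarray | None = None,
    burnin_complete: bool = False,
    anchor_now: bool = False,
) -> PolicySnapshot:
    """One weekly up-front policy update.

    During burn-in (including the anchoring week itself) the vector is
    uniform and all weights are 1; afterwards the configured estimator is
    computed on the strict-past snapshot with the stored subject weights,
    B confidence draws are converted to beliefs, and the damped, clipped
    vector becomes this week's regime randomization.  If the estimator is
    undefined for any regime, the previous vector is held.
    """
    maps = maps or RegimeMaps(data.design)
    m = maps.m
    uniform = np.full(m, 1.0 / m)
    mask = data.snapshot_mask(week)

    def snap(vec, w, wa, complete):
        return PolicySnapshot(
            week=week, scheme=UPFRONT, vectors={"regimes": vec},
            burnin_complete=complete, w=tuple(w), wa=tuple(wa),
        )

    if not burnin_complete:
        return snap(uniform, np.ones(m), np.ones(m), False)
    if anchor_now:
        # burn-in just completed: anchor the weight states at the uniform
        # policy still in force this week; adaptation starts next week
        pieces = policy_propensity_pieces(maps, UPFRONT, {"regimes": uniform})
        update_stabilizing_weights(weight_state, data, mask, pieces, maps, anchor_now=True)
        if aug is not None:
            update_stabilizing_weights_aipw(
                weight_state_a, data, mask, pieces, maps, aug, anchor_now=True
            )
        return snap(uniform, np.ones(m), np.ones(m), True)

    table = estimate_values(data, config.estimator, week=week, aug=aug, maps=maps)
    if not np.all(np.isfinite(table.theta)):
        vec = previous if previous is not None else uniform
        return snap(vec, weight_state.current, weight_state_a.current, True)
    draws = draw_confidence(table.theta, table.covariance, config.B, rng)
    rho = beliefs_from_draws(draws, minimize=config.minimize)
    vec = damp_and_clip(rho, config.c_t, config.clip_lo, config.clip_hi)
    pieces = policy_propensity_pieces(maps, UPFRONT, {"regimes": vec})
    w = update_stabilizing_weights(weight_state, data, mask, pieces, maps)
    if aug is not None:
        wa = update_stabilizing_weights_aipw(weight_state_a, data, mask, pieces, maps, aug)
    else:
        wa = weight_state_a.current
    return snap(vec, w, wa, True)
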