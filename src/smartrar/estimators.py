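"""Regime-value estimation for SMARTs under (possibly adaptive) randomization.

Implements the inverse-probability-weighted (IPW) and augmented IPW (AIPW)
estimators of an embedded regime's value, their variance-stabilized
versions (WIPW / WAIPW) whose weights restore asymptotic normality under
response-adaptive randomization, and the martingale M-estimation normal
theory used for standard errors, confidence intervals, and one-sided
bounds.

For regime j with consistency indicator C^j and stage propensities
pi^j_{tau,k} evaluated at the subject's own assignment weeks, the weighted
IPW estimator is the ratio

    theta_hat^j = sum_i W_i Delta_i C_i^j Y_i / Pi_i  /
                  sum_i W_i Delta_i C_i^j / Pi_i,         Pi_i = pi_1 * pi_2,

and the weighted AIPW estimator normalizes sum_i W^A_i Delta_i g_i by
sum_i W^A_i Delta_i, where the integrand g adds to C Y / Pi a telescoping
augmentation sum built from partial-consistency indicators and fitted
models L_k of the regime's conditional mean outcome.  Setting all weights
to 1 recovers the unweighted IPW / AIPW estimators exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm

from .design import SMARTDesign
from .qmodels import (
    ols_fit,
    q1_interaction_features,
    q2_features,
)
from .trial import UPFRONT, TrialData

ESTIMATOR_NAMES = ("ipw", "wipw", "aipw", "waipw")

#: floor applied to estimated variances
VARIANCE_FLOOR = 1e-12


class EstimationError(RuntimeError):
    pass


class DegenerateVarianceError(EstimationError):
    pass


# ---------------------------------------------------------------------------
# design-derived index maps


class RegimeMaps:
    """Index maps from a design's embedded regimes, precomputed per trial.

    For each regime j (0-based): the indices of regimes sharing its stage-1
    treatment (its *family*); within the family, the indices recommending
    the same stage-2 action for each response status; and the recommended
    stage-2 codes themselves.
    """

    def __init__(self, design: SMARTDesign):
        self.design = design
        regs = design.embedded_regimes
        self.m = len(regs)
        self.stage1 = np.array([r.stage1 for r in regs])
        self.resp_action = np.array([r.responder for r in regs])
        self.nonresp_action = np.array([r.nonresponder for r in regs])
        self.family = [
            np.array([k for k, r2 in enumerate(regs) if r2.stage1 == r.stage1])
            for r in regs
        ]
        self.match = {}  # (j, s) -> regime indices with same stage-2 action
        for j, r in enumerate(regs):
            for s, act in ((1, r.responder), (0, r.nonresponder)):
                self.match[(j, s)] = np.array(
                    [
                        k
                        for k in self.family[j]
                        if (regs[k].responder if s else regs[k].nonresponder) == act
                    ]
                )
        self.stage1_options = sorted(design.treatment_sets[0])
        self.stage1_col = {a: c for c, a in enumerate(self.stage1_options)}

    def action_matrix(self, x22: np.ndarray) -> np.ndarray:
        """(N, m) recommended stage-2 code per subject given realized response."""
        resp = (x22 == 1)[:, None]
        return np.where(resp, self.resp_action[None, :], self.nonresp_action[None, :])


def consistency_matrices(data: TrialData, maps: RegimeMaps | None = None):
    """Partial and full consistency indicator matrices C1, C of shape (N, m).

    Rows whose stage-2 data are unobserved get C = 0 (they cannot yet be
    consistent through stage 2).
    """
    maps = maps or RegimeMaps(data.design)
    c1 = (data.a1[:, None] == maps.stage1[None, :]).astype(float)
    act = maps.action_matrix(data.x22)
    c = c1 * (data.a2[:, None] == act) * (data.x22 >= 0)[:, None]
    return c1, c


def propensity_matrices(data: TrialData, maps: RegimeMaps | None = None):
    """Per-regime stage propensities PI1, PI2 of shape (N, m).

    Read off the stored assignment-week probabilities: under the up-front
    scheme pi_1 is the total probability of the regimes sharing regime j's
    initial treatment and pi_2 the conditional probability of the regimes
    matching its stage-2 recommendation for the subject's realized response;
    under the sequential scheme they are the stored per-option
    probabilities.  PI2 is nan where not determined (stage 2 unobserved, or
    a sequential subject whose realized A1 differs from the regime's).
    """
    maps = maps or RegimeMaps(data.design)
    n, m = len(data), maps.m
    pi1 = np.empty((n, m))
    pi2 = np.full((n, m), np.nan)
    reached2 = data.x22 >= 0
    if data.scheme == UPFRONT:
        probs = data.regime_probs
        if probs is None or np.isnan(probs[data.a1 >= 0]).any():
            raise EstimationError("ledger corrupt: missing stored regime probabilities")
        for j in range(m):
            pi1[:, j] = probs[:, maps.family[j]].sum(axis=1)
            num = np.where(
                data.x22 == 1,
                probs[:, maps.match[(j, 1)]].sum(axis=1),
                probs[:, maps.match[(j, 0)]].sum(axis=1),
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                pi2[:, j] = np.where(reached2, num / pi1[:, j], np.nan)
    else:
        p1 = data.stage1_probs
        p2 = data.stage2_probs
        if p1 is None or np.isnan(p1[data.a1 >= 0]).any():
            raise EstimationError("ledger corrupt: missing stored stage-1 probabilities")
        act = maps.action_matrix(data.x22)
        for j in range(m):
            pi1[:, j] = p1[:, maps.stage1_col[maps.stage1[j]]]
            same_arm = (data.a1 == maps.stage1[j]) & reached2
            rows = np.where(same_arm)[0]
            pi2[rows, j] = p2[rows, act[rows, j]]
    return pi1, pi2


def regime_propensities(data: TrialData, j: int, maps: RegimeMaps | None = None):
    """Stage propensities (pi1, pi2, product) for one regime (1-based ``j``)."""
    pi1, pi2 = propensity_matrices(data, maps)
    return pi1[:, j - 1], pi2[:, j - 1], pi1[:, j - 1] * pi2[:, j - 1]


# ---------------------------------------------------------------------------
# current-policy propensity pieces (used by the stabilizing weights)


def policy_propensity_pieces(maps: RegimeMaps, scheme: str, vectors: dict):
    """Per-regime (pi_{t,1}, pi^{(s)}_{t,2}) implied by a policy's vectors.

    Returns ``pi1`` of shape (m,) and ``pi2s`` of shape (m, 2) with columns
    indexed by response status s = 0, 1.
    """
    m = maps.m
    pi1 = np.empty(m)
    pi2s = np.empty((m, 2))
    if scheme == UPFRONT:
        r = np.asarray(vectors["regimes"], dtype=float)
        for j in range(m):
            fam = r[maps.family[j]].sum()
            pi1[j] = fam
            for s in (0, 1):
                pi2s[j, s] = r[maps.match[(j, s)]].sum() / fam
    else:
        p1 = np.asarray(vectors["stage1"], dtype=float)
        for j in range(m):
            a1 = maps.stage1[j]
            pi1[j] = p1[maps.stage1_col[a1]]
            for s, act in ((0, maps.nonresp_action[j]), (1, maps.resp_action[j])):
                group = vectors[("stage2", int(a1), s)]
                opts = sorted(maps.design.feasible_set(2, int(a1), s))
                pi2s[j, s] = float(np.asarray(group)[opts.index(int(act))])
    return pi1, pi2s


# ---------------------------------------------------------------------------
# augmentation models (backward-iterative, fitted per assignment week)


class AugmentationCache:
    """Backward-fitted conditional-mean models, keyed by assignment week.

    For a subject enrolled at week tau, the augmentation terms L_k must be
    computed from models fitted on the data observable strictly before tau
    (so that the estimating function remains conditionally unbiased under
    adaptive randomization).  Fits are performed once per enrollment week
    and cached.  Weeks with fewer completers than the stage-2 feature
    dimension fall back to L == 0.

    The stage-2 model is the shared outcome regression Q2; the regime-j
    stage-1 model regresses the plug-in pseudo outcome
    Q2(x1, a1, x21, d2^j(response)) on (1, x1, a1, x1*a1); L1 is its fit
    evaluated at the regime's initial treatment.
    """

    def __init__(self, data: TrialData, maps: RegimeMaps | None = None):
        self.data = data
        self.maps = maps or RegimeMaps(data.design)
        n, m = len(data), self.maps.m
        self._models: dict[int, Optional[tuple]] = {}
        self.L1 = np.full((n, m), np.nan)
        self.L2 = np.full((n, m), np.nan)
        self._filled = np.zeros(n, dtype=bool)

    def models_for_week(self, tau: int):
        if tau in self._models:
            return self._models[tau]
        d, maps = self.data, self.maps
        mask = d.completed_by(tau - 1)
        n_fit = int(mask.sum())
        if n_fit < q2_features(0, 0, 0, 0).shape[1]:
            self._models[tau] = None
            return None
        phi2 = q2_features(d.x1[mask], d.a1[mask], d.x21[mask], d.a2[mask])
        beta2 = ols_fit(phi2, d.y[mask])
        act = maps.action_matrix(d.x22[mask])
        phi1 = q1_interaction_features(d.x1[mask], d.a1[mask])
        beta1 = np.empty((maps.m, phi1.shape[1]))
        for j in range(maps.m):
            pseudo = q2_features(d.x1[mask], d.a1[mask], d.x21[mask], act[:, j]) @ beta2
            beta1[j] = ols_fit(phi1, pseudo)
        self._models[tau] = (beta2, beta1)
        return self._models[tau]

    def ensure(self, idx: np.ndarray) -> None:
        """Fill L rows for the given subject indices (completers only)."""
        todo = idx[~self._filled[idx]]
        if todo.size == 0:
            return
        d, maps = self.data, self.maps
        for tau in np.unique(d.enroll_week[todo]):
            rows = todo[d.enroll_week[todo] == tau]
            models = self.models_for_week(int(tau))
            if models is None:
                self.L1[rows] = 0.0
                self.L2[rows] = 0.0
            else:
                beta2, beta1 = models
                act = maps.action_matrix(d.x22[rows])
                for j in range(maps.m):
                    self.L2[rows, j] = (
                        q2_features(d.x1[rows], d.a1[rows], d.x21[rows], act[:, j])
                        @ beta2
                    )
                    self.L1[rows, j] = (
                        q1_interaction_features(
                            d.x1[rows], np.full(rows.size, maps.stage1[j])
                        )
                        @ beta1[j]
                    )
            self._filled[rows] = True

    def L_matrices(self, mask: np.ndarray):
        self.ensure(np.where(mask)[0])
        return self.L1, self.L2


# ---------------------------------------------------------------------------
# core estimating-equation computations


def _wipw_core(y, mask, C, PI1, PI2, W):
    """theta, M terms, and normalizers for the (W)IPW estimating equation."""
    y = np.where(mask, y, 0.0)  # unobserved outcomes never contribute
    with np.errstate(invalid="ignore"):
        prod = PI1 * PI2
    sw = np.zeros_like(C)
    idx = (C > 0) & mask[:, None]
    sw[idx] = (W[idx] * C[idx]) / prod[idx]
    denom = sw.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = (sw * y[:, None]).sum(axis=0) / denom
    M = sw * (y[:, None] - theta[None, :])
    M[~mask] = 0.0
    return theta, M, denom


def _waipw_core(y, mask, C1, C, PI1, PI2, L1, L2, WA):
    """theta, M terms, and normalizers for the (W)AIPW estimating equation."""
    y = np.where(mask, y, 0.0)
    inv_prod = np.zeros_like(C)
    idx = (C > 0) & mask[:, None]
    with np.errstate(invalid="ignore"):
        inv_prod[idx] = C[idx] / (PI1[idx] * PI2[idx])
    c1_over = np.where(mask[:, None], C1 / PI1, 0.0)
    L1 = np.where(mask[:, None], L1, 0.0)
    L2 = np.where(mask[:, None], L2, 0.0)
    g = (
        y[:, None] * inv_prod
        + (1.0 - c1_over) * L1
        + (c1_over - inv_prod) * L2
    )
    g[~mask] = 0.0
    wa = np.where(mask[:, None], WA, 0.0)
    denom = wa.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = (wa * g).sum(axis=0) / denom
    M = wa * (g - theta[None, :])
    M[~mask] = 0.0
    return theta, M, denom


def wipw_estimate(data: TrialData, j: int, weights=None, week: int | None = None):
    """Weighted IPW value estimate for regime ``j`` (1-based).

    ``weights=None`` uses weights identically 1 (the unweighted IPW
    estimator).  Returns ``(theta, M_terms)``; raises
    :class:`EstimationError` when no consistent completer exists.
    """
    maps = RegimeMaps(data.design)
    mask = data.completed_by((week or 10**9) - 1)
    _, C = consistency_matrices(data, maps)
    PI1, PI2 = propensity_matrices(data, maps)
    W = np.ones((len(data), maps.m))
    if weights is not None:
        W[:] = np.asarray(weights, dtype=float).reshape(-1, 1)
    theta, M, denom = _wipw_core(data.y, mask, C, PI1, PI2, W)
    if denom[j - 1] == 0:
        raise EstimationError(f"no consistent completers for regime {j}")
    return float(theta[j - 1]), M[:, j - 1]


def waipw_estimate(
    data: TrialData, j: int, aug: AugmentationCache | None = None,
    weights=None, week: int | None = None,
):
    """Weighted AIPW value estimate for regime ``j`` (1-based)."""
    maps = RegimeMaps(data.design)
    mask = data.completed_by((week or 10**9) - 1)
    C1, C = consistency_matrices(data, maps)
    PI1, PI2 = propensity_matrices(data, maps)
    aug = aug or AugmentationCache(data, maps)
    L1, L2 = aug.L_matrices(mask)
    WA = np.ones((len(data), maps.m))
    if weights is not None:
        WA[:] = np.asarray(weights, dtype=float).reshape(-1, 1)
    theta, M, denom = _waipw_core(data.y, mask, C1, C, PI1, PI2, L1, L2, WA)
    if denom[j - 1] == 0 or not np.isfinite(theta[j - 1]):
        raise EstimationError(f"estimate undefined for regime {j}")
    return float(theta[j - 1]), M[:, j - 1]


# ---------------------------------------------------------------------------
# inference


@dataclass(frozen=True)
class ValueEstimate:
    """Normal-theory inference for one regime value."""

    theta: float
    se: float
    ci_low: float
    ci_high: float
    lower_bound: float
    upper_bound: float
    delta_T: float
    sigma_T: float
    n_consistent: int


def mestimation_inference(M, denom, theta, n_consistent, alpha=0.05) -> ValueEstimate:
    """Confidence interval and one-sided bounds from martingale normal theory.

    ``M`` are the per-subject estimating-function terms at ``theta`` and
    ``denom`` the (positive) sum of the estimating-function derivative
    magnitudes; the standard error is sqrt(sum M^2) / denom, which equals
    sigma_T / (|delta_T| sqrt(T)) in the estimating-equation notation.
    """
    M = np.asarray(M, dtype=float)
    if n_consistent < 2:
        raise EstimationError("need at least 2 consistent completers for inference")
    T = int(np.count_nonzero(M != 0)) or 1
    ssq = float((M**2).sum())
    if ssq <= VARIANCE_FLOOR:
        raise DegenerateVarianceError("estimating-function variance is zero")
    se = np.sqrt(ssq) / abs(denom)
    z2 = norm.isf(alpha / 2)
    z1 = norm.isf(alpha)
    return ValueEstimate(
        theta=float(theta),
        se=float(se),
        ci_low=float(theta - z2 * se),
        ci_high=float(theta + z2 * se),
        lower_bound=float(theta - z1 * se),
        upper_bound=float(theta + z1 * se),
        delta_T=float(-denom / T),
        sigma_T=float(np.sqrt(ssq / T)),
        n_consistent=int(n_consistent),
    )


def joint_confidence_covariance(M: np.ndarray, denom: np.ndarray) -> np.ndarray:
    """Stacked-estimating-equation sandwich covariance across regimes.

    Cross-regime covariances come from per-subject outer products of the
    estimating terms; the diagonal equals the squared per-regime standard
    errors by construction.  Entries are nan for regimes with no
    information (zero ``denom``); callers decide how to degrade.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (M.T @ M) / np.outer(denom, denom)
    return cov


# ---------------------------------------------------------------------------
# stabilizing weights


@dataclass
class WeightState:
    """Anchored variance-stabilization state for one weight family."""

    m: int
    anchor: np.ndarray = field(default=None)
    current: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.anchor is None:
            self.anchor = np.full(self.m, np.nan)
        if self.current is None:
            self.current = np.ones(self.m)


def _theta_tilde(y, mask, C, PI1, PI2):
    """Unweighted IPW estimates on the snapshot (reference values for mu-hat)."""
    theta, _, denom = _wipw_core(y, mask, C, PI1, PI2, np.ones_like(C))
    return theta, denom


def update_stabilizing_weights(
    state: WeightState,
    data: TrialData,
    mask: np.ndarray,
    pieces,
    maps: RegimeMaps,
    anchor_now: bool = False,
) -> np.ndarray:
    """WIPW stabilizing weights W_t = sqrt(Xi_hat_{t*} / Xi_hat_t).

    ``mask`` is the snapshot's completer set, ``pieces`` the per-regime
    current-week propensity pieces (pi1, pi2s).  mu-hat for response stratum
    s is the inverse-propensity-weighted mean of squared residuals around
    the snapshot's unweighted IPW estimate, over consistent completers in
    the stratum; Xi_hat plugs the current week's probabilities into the
    conditional-variance identity.  When a stratum has no consistent
    completer or Xi_hat is nonpositive, the previous weight is held.
    ``anchor_now=True`` records Xi_hat as the regime's burn-in anchor.
    """
    pi1_now, pi2s_now = pieces
    C1, C = consistency_matrices(data, maps)
    PI1, PI2 = propensity_matrices(data, maps)
    theta_t, denom = _theta_tilde(data.y, mask, C, PI1, PI2)
    n_t = max(int(mask.sum()), 1)
    y = data.y
    for j in range(maps.m):
        if denom[j] == 0 or not np.isfinite(theta_t[j]):
            continue  # hold previous weight
        xi = 0.0
        ok = True
        for s in (0, 1):
            rows = mask & (C[:, j] > 0) & (data.x22 == s)
            if not rows.any():
                ok = False
                break
            mu = (
                (y[rows] - theta_t[j]) ** 2 / (PI2[rows, j] * PI1[rows, j])
            ).sum() / n_t
            xi += mu / (pi2s_now[j, s] * pi1_now[j])
        if not ok or xi <= 0:
            continue
        if anchor_now or np.isnan(state.anchor[j]):
            state.anchor[j] = xi
            state.current[j] = 1.0
        else:
            state.current[j] = np.sqrt(state.anchor[j] / xi)
    return state.current


def update_stabilizing_weights_aipw(
    state: WeightState,
    data: TrialData,
    mask: np.ndarray,
    pieces,
    maps: RegimeMaps,
    aug: AugmentationCache,
    anchor_now: bool = False,
) -> np.ndarray:
    """WAIPW stabilizing weights, mirroring the WIPW construction.

    The conditional second moment of the AIPW integrand is decomposed into
    policy-free components estimated by inverse propensity weighting --
    v0 = E[(L1 - theta)^2], v1 = E[(L2* - L1)^2] on the regime's arm, and
    v2s = E[I(response=s)(Y* - L2*)^2] -- and reassembled with the current
    week's probabilities:

        Xi^A_t = v0 + v1 / pi_{t,1} + sum_s v2s / (pi^{(s)}_{t,2} pi_{t,1}).

    Anchoring and the square-root-ratio form are as for WIPW.
    """
    pi1_now, pi2s_now = pieces
    C1, C = consistency_matrices(data, maps)
    PI1, PI2 = propensity_matrices(data, maps)
    L1, L2 = aug.L_matrices(mask)
    theta_t, denom = _theta_tilde(data.y, mask, C, PI1, PI2)
    n_t = max(int(mask.sum()), 1)
    y = data.y
    for j in range(maps.m):
        if denom[j] == 0 or not np.isfinite(theta_t[j]):
            continue
        v0 = ((L1[mask, j] - theta_t[j]) ** 2).sum() / n_t
        arm = mask & (C1[:, j] > 0)
        v1 = ((L2[arm, j] - L1[arm, j]) ** 2 / PI1[arm, j]).sum() / n_t
        xi = v0 + v1 / pi1_now[j]
        ok = True
        for s in (0, 1):
            rows = mask & (C[:, j] > 0) & (data.x22 == s)
            if not rows.any():
                ok = False
                break
            v2 = (
                (y[rows] - L2[rows, j]) ** 2 / (PI2[rows, j] * PI1[rows, j])
            ).sum() / n_t
            xi += v2 / (pi2s_now[j, s] * pi1_now[j])
        if not ok or xi <= 0:
            continue
        if anchor_now or np.isnan(state.anchor[j]):
            state.anchor[j] = xi
            state.current[j] = 1.0
        else:
            state.current[j] = np.sqrt(state.anchor[j] / xi)
    return state.current


# ---------------------------------------------------------------------------
# high-level per-estimator value tables


@dataclass
class ValueTable:
    """Per-regime value estimates for one estimator on one dataset."""

    estimator: str
    theta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    lower_bound: np.ndarray
    upper_bound: np.ndarray
    n_consistent: np.ndarray
    covariance: np.ndarray

    def optimal_regime(self, minimize: bool = True) -> int:
        """1-based estimated-optimal regime (nan estimates excluded)."""
        th = np.where(np.isfinite(self.theta), self.theta, np.inf if minimize else -np.inf)
        return int(np.argmin(th) if minimize else np.argmax(th)) + 1


def estimate_values(
    data: TrialData,
    estimator: str,
    week: int | None = None,
    alpha: float = 0.05,
    aug: AugmentationCache | None = None,
    maps: RegimeMaps | None = None,
) -> ValueTable:
    """Value estimates for all embedded regimes with normal-theory inference.

    ``week=None`` uses all completed subjects (post-trial); otherwise the
    strict-past snapshot for that week.  The weighted estimators read the
    subject-level stabilizing weights stored in the ledger; under
    nonadaptive randomization those are identically 1, so WIPW == IPW and
    WAIPW == AIPW exactly.
    """
    if estimator not in ESTIMATOR_NAMES:
        raise ValueError(f"unknown estimator {estimator!r}")
    maps = maps or RegimeMaps(data.design)
    mask = data.completed_by((week or 10**9) - 1)
    C1, C = consistency_matrices(data, maps)
    PI1, PI2 = propensity_matrices(data, maps)
    if estimator in ("ipw", "wipw"):
        W = data.w if estimator == "wipw" else np.ones((len(data), maps.m))
        theta, M, denom = _wipw_core(data.y, mask, C, PI1, PI2, W)
    else:
        aug = aug or AugmentationCache(data, maps)
        L1, L2 = aug.L_matrices(mask)
        WA = data.wa if estimator == "waipw" else np.ones((len(data), maps.m))
        theta, M, denom = _waipw_core(data.y, mask, C1, C, PI1, PI2, L1, L2, WA)
    m = maps.m
    n_cons = (C * mask[:, None]).sum(axis=0).astype(int)
    out = {k: np.full(m, np.nan) for k in
           ("se", "ci_low", "ci_high", "lower_bound", "upper_bound")}
    for j in range(m):
        if denom[j] == 0 or not np.isfinite(theta[j]) or n_cons[j] < 2:
            theta[j] = np.nan
            continue
        try:
            est = mestimation_inference(M[:, j], denom[j], theta[j], n_cons[j], alpha)
        except EstimationError:
            continue
        out["se"][j] = est.se
        out["ci_low"][j] = est.ci_low
        out["ci_high"][j] = est.ci_high
        out["lower_bound"][j] = est.lower_bound
        out["upper_bound"][j] = est.upper_bound
    cov = joint_confidence_covariance(M, denom)
    return ValueTable(
        estimator=estimator,
        theta=theta,
        n_consistent=n_cons,
        covariance=cov,
        **out,
    )
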