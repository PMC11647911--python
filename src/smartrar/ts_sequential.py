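"""Sequential per-stage Thompson sampling via Q-learning.

Stage-2 treatment effects are estimated by ordinary least squares on
completers; stage-1 coefficients come from the backward Q-learning
recursion, regressing the per-subject optimized stage-2 model value (the
pseudo outcome) on stage-1 features.  Because the stage-1 estimator is a
nonregular function of the stage-2 fit, its confidence distribution is
sampled projection-style: outer draws of the stage-2 coefficients, a
stage-1 refit per outer draw, and inner draws from each conditional
normal, pooled.  Beliefs are computed per feasible group from the draws
and converted to randomization vectors exactly as in the up-front scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import SMARTDesign
from .estimators import (
    RegimeMaps,
    WeightState,
    policy_propensity_pieces,
    update_stabilizing_weights,
    update_stabilizing_weights_aipw,
)
from .qmodels import RIDGE, q1_additive_features, q2_features
from .trial import SEQUENTIAL, PolicySnapshot, TrialData
from .ts_upfront import damp_and_clip

#: stage-2 code -> column of its effect coefficient in the Q2 feature vector
CODE_COLUMN = {0: None, 1: 4, 2: 5, 3: 6, 4: 7, 5: 5}


class FitError(RuntimeError):
    pass


@dataclass
class QFit:
    """An OLS Q-model fit with its sampling covariance."""

    beta: np.ndarray
    cov: np.ndarray
    sigma2: float
    n: int


def qfit_stage(phi: np.ndarray, y: np.ndarray) -> QFit:
    """OLS fit with covariance sigma^2 (Phi'Phi)^-1, sigma^2 = mean sq. residual.

    The residual variance uses denominator n (no degrees-of-freedom
    correction).  Rank deficiency is handled by a tiny ridge on the normal
    equations.
    """
    n, p = phi.shape
    if n < p:
        raise FitError(f"need at least {p} completers, have {n}")
    xtx = phi.T @ phi
    xtx[np.diag_indices_from(xtx)] += RIDGE
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (phi.T @ y)
    resid = y - phi @ beta
    sigma2 = float((resid**2).mean())
    return QFit(beta=beta, cov=sigma2 * xtx_inv, sigma2=sigma2, n=n)


def q2_option_effect(beta2: np.ndarray, code: int):
    """Stage-2 effect coefficient(s) for a treatment code; 0 for reference codes."""
    col = CODE_COLUMN[code]
    if col is None:
        return np.zeros(beta2.shape[1:]) if beta2.ndim > 1 else 0.0
    return beta2[col]


def pseudo_outcomes(
    x1, a1, x21, x22, y, beta2: np.ndarray, design: SMARTDesign,
    minimize: bool = True,
) -> np.ndarray:
    """Optimized stage-2 model value per subject over the feasible set.

    ``beta2`` may be a single coefficient vector (p2,) or a matrix (p2, B)
    of draws, giving a (n,) or (n, B) result.  Histories whose feasible set
    has a single option carry back the observed outcome Y.
    """
    x1 = np.asarray(x1, dtype=float)
    single = beta2.ndim == 1
    b2 = beta2[:, None] if single else beta2
    n, B = x1.shape[0], b2.shape[1]
    base = q2_features(x1, a1, x21, np.zeros(n)) @ b2  # effects of a2 excluded
    out = np.empty((n, B))
    reduce = np.minimum if minimize else np.maximum
    for (g_a1, g_s), rows in _group_rows(a1, x22).items():
        opts = sorted(design.feasible_set(2, g_a1, g_s))
        if len(opts) == 1:
            out[rows] = np.asarray(y, dtype=float)[rows, None]
            continue
        vals = base[rows] + q2_option_effect(b2, opts[0])
        for code in opts[1:]:
            vals = reduce(vals, base[rows] + q2_option_effect(b2, code))
        out[rows] = vals
    return out[:, 0] if single else out


def _group_rows(a1, x22) -> dict:
    groups = {}
    a1 = np.asarray(a1)
    x22 = np.asarray(x22)
    for g_a1 in np.unique(a1):
        for g_s in np.unique(x22):
            rows = np.where((a1 == g_a1) & (x22 == g_s))[0]
            if rows.size:
                groups[(int(g_a1), int(g_s))] = rows
    return groups


@dataclass
class StageDraws:
    """Pooled confidence-distribution draws per stage (coefficients in columns)."""

    beta2: np.ndarray  # (p2, B2)
    beta1: np.ndarray  # (p1, B1)
    fit2: QFit
    fit1: QFit


def _chol(cov: np.ndarray) -> np.ndarray:
    c = 0.5 * (cov + cov.T)
    c[np.diag_indices_from(c)] += 1e-12
    return np.linalg.cholesky(c)


def projection_draws(
    data: TrialData,
    mask: np.ndarray,
    sizes: tuple[int, int, int],
    rng: np.random.Generator,
    minimize: bool = True,
) -> StageDraws:
    """Nested projection-style confidence draws for a two-stage design.

    ``sizes = (B2, b2, b1)``: B2 direct draws of the stage-2 coefficients
    from N(beta2_hat, Sigma2_hat); then b2 outer stage-2 draws, each
    inducing rebuilt pseudo outcomes, a stage-1 refit, and b1 inner draws
    from the conditional normal, pooled into B1 = b2 * b1 stage-1 draws.
    """
    B2, b2, b1 = sizes
    d = data
    x1, a1, x21, x22, y = (
        d.x1[mask], d.a1[mask], d.x21[mask], d.x22[mask], d.y[mask]
    )
    phi2 = q2_features(x1, a1, x21, d.a2[mask])
    fit2 = qfit_stage(phi2, y)
    chol2 = _chol(fit2.cov)
    p2 = fit2.beta.shape[0]
    beta2_draws = fit2.beta[:, None] + chol2 @ rng.standard_normal((p2, B2))

    phi1 = q1_additive_features(x1, a1)
    n, p1 = phi1.shape
    if n < p1:
        raise FitError(f"need at least {p1} completers, have {n}")
    xtx = phi1.T @ phi1
    xtx[np.diag_indices_from(xtx)] += RIDGE
    xtx_inv = np.linalg.inv(xtx)
    proj = xtx_inv @ phi1.T
    chol1_unit = _chol(xtx_inv)

    # point stage-1 fit (for reporting / degenerate covariance checks)
    vtilde_hat = pseudo_outcomes(x1, a1, x21, x22, y, fit2.beta, d.design, minimize)
    beta1_hat = proj @ vtilde_hat
    resid_hat = vtilde_hat - phi1 @ beta1_hat
    fit1 = QFit(
        beta=beta1_hat,
        cov=float((resid_hat**2).mean()) * xtx_inv,
        sigma2=float((resid_hat**2).mean()),
        n=n,
    )

    outer = fit2.beta[:, None] + chol2 @ rng.standard_normal((p2, b2))
    vtilde = pseudo_outcomes(x1, a1, x21, x22, y, outer, d.design, minimize)  # (n, b2)
    beta1_outer = proj @ vtilde  # (p1, b2)
    resid = vtilde - phi1 @ beta1_outer
    sigma_outer = np.sqrt((resid**2).mean(axis=0))  # (b2,)
    z = rng.standard_normal((b2, p1, b1))
    pooled = beta1_outer.T[:, :, None] + sigma_outer[:, None, None] * (chol1_unit @ z)
    beta1_draws = pooled.transpose(1, 0, 2).reshape(p1, b2 * b1)
    return StageDraws(beta2=beta2_draws, beta1=beta1_draws, fit2=fit2, fit1=fit1)


def sequential_beliefs(
    draws: np.ndarray, option_features: np.ndarray, minimize: bool = True
) -> np.ndarray:
    """Per-option beliefs at given histories.

    ``draws`` is (p, B); ``option_features`` is (n, o, p), the stage
    feature vector of each candidate option at each history.  Returns the
    (n, o) fraction of draws in which each option optimizes the model, with
    ties split equally.
    """
    vals = np.einsum("nop,pb->nob", option_features, draws)
    if minimize:
        vals = -vals
    best = vals.max(axis=1, keepdims=True)
    hits = (vals == best).astype(float)
    hits /= hits.sum(axis=1, keepdims=True)
    return hits.mean(axis=2)


def _uniform_vectors(design: SMARTDesign) -> dict:
    vectors = {"stage1": np.full(len(design.treatment_sets[0]),
                                 1.0 / len(design.treatment_sets[0]))}
    for (a1, s), opts in design.feasible_stage2.items():
        vectors[("stage2", int(a1), int(s))] = np.full(len(opts), 1.0 / len(opts))
    return vectors


def update_sequential_policy(
    data: TrialData,
    week: int,
    config,
    weight_state: WeightState,
    weight_state_a: WeightState,
    rng: np.random.Generator,
    maps: RegimeMaps | None = None,
    aug=None,
    previous: dict | None = None,
    burnin_complete: bool = False,
    anchor_now: bool = False,
) -> PolicySnapshot:
    """One weekly sequential policy update.

    Computes one stage-1 vector and one vector per stage-2 feasible group
    (a1, response).  Under the additive stage-1 and effect-coded stage-2
    feature specifications the per-subject beliefs depend on the history
    only through the components that dictate the feasible group, so the
    group-level vectors coincide with the per-subject construction; beliefs
    are evaluated at the snapshot-mean history of each group.
    """
    maps = maps or RegimeMaps(data.design)
    design = data.design
    mask = data.snapshot_mask(week)
    uniform = _uniform_vectors(design)

    def snap(vectors, w, wa, complete):
        return PolicySnapshot(
            week=week, scheme=SEQUENTIAL, vectors=vectors,
            burnin_complete=complete, w=tuple(w), wa=tuple(wa),
        )

    m = maps.m
    if not burnin_complete:
        return snap(uniform, np.ones(m), np.ones(m), False)
    if anchor_now:
        pieces = policy_propensity_pieces(maps, SEQUENTIAL, uniform)
        update_stabilizing_weights(weight_state, data, mask, pieces, maps, anchor_now=True)
        if aug is not None:
            update_stabilizing_weights_aipw(
                weight_state_a, data, mask, pieces, maps, aug, anchor_now=True
            )
        return snap(uniform, np.ones(m), np.ones(m), True)

    try:
        draws = projection_draws(
            data, mask, (config.B2, config.b2, config.b1), rng,
            minimize=config.minimize,
        )
    except FitError:
        vectors = previous if previous is not None else uniform
        return snap(vectors, weight_state.current, weight_state_a.current, True)

    x1_bar = float(data.x1[mask].mean())
    vectors = {}
    # stage 1: one group
    opts1 = sorted(design.treatment_sets[0])
    feats1 = np.stack(
        [q1_additive_features(np.array([x1_bar]), np.array([float(a)]))[0] for a in opts1]
    )[None, :, :]
    rho1 = sequential_beliefs(draws.beta1, feats1, minimize=config.minimize)[0]
    vectors["stage1"] = damp_and_clip(rho1, config.c_t, config.clip_lo, config.clip_hi)
    # stage 2: one group per (a1, response)
    for (a1, s), opts in sorted(design.feasible_stage2.items()):
        grp = mask & (data.a1 == a1) & (data.x22 == s)
        x21_bar = float(data.x21[grp].mean()) if grp.any() else 0.0
        opts_sorted = sorted(opts)
        feats2 = np.stack(
            [
                q2_features(np.array([x1_bar]), np.array([a1]),
                            np.array([x21_bar]), np.array([code]))[0]
                for code in opts_sorted
            ]
        )[None, :, :]
        rho2 = sequential_beliefs(draws.beta2, feats2, minimize=config.minimize)[0]
        vectors[("stage2", int(a1), int(s))] = damp_and_clip(
            rho2, config.c_t, config.clip_lo, config.clip_hi
        )

    pieces = policy_propensity_pieces(maps, SEQUENTIAL, vectors)
    w = update_stabilizing_weights(weight_state, data, mask, pieces, maps)
    if aug is not None:
        wa = update_stabilizing_weights_aipw(weight_state_a, data, mask, pieces, maps, aug)
    else:
        wa = weight_state_a.current
    return snap(vectors, w, wa, True)
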