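"""Discrete-time accrual/progression engine with weekly policy updates.

Time is integer weeks.  A subject enrolled at week tau receives stage-1
treatment at tau, has interim data ascertained and stage-2 treatment
assigned at tau + gap, and has the outcome recorded at tau + 2*gap.  Data
observed at week t become usable for policy updates at week t + 1 (the
strict past), and all subjects randomized in the same week and feasible
group share one probability vector.

Three independent seeded streams drive (i) arrivals and potential data,
(ii) treatment assignment, and (iii) Thompson-sampling draws, so that
different randomization methods can be compared on identical subject
streams.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .design import SMARTDesign, cancer_pain_design
from .estimators import AugmentationCache, RegimeMaps, WeightState, consistency_matrices
from .scenario import ScenarioParams, draw_baseline, draw_outcome, transition_stage2
from .trial import SEQUENTIAL, UPFRONT, PolicySnapshot, TrialData, TrialLedger
from .ts_sequential import update_sequential_policy
from .ts_upfront import update_upfront_policy

SR = "sr"
SCHEMES = (SR, UPFRONT, SEQUENTIAL)


@dataclass(frozen=True)
class MethodConfig:
    """A randomization method: scheme, driving estimator, and TS tuning."""

    scheme: str = SR
    #: estimator driving up-front adaptation: ipw | wipw | aipw | waipw
    estimator: str = "wipw"
    c_t: float = 1.0
    clip_lo: float = 0.05
    clip_hi: float = 0.95
    #: confidence draws per update (up-front)
    B: int = 1000
    #: stage-2 draws and nested stage-1 draw sizes (sequential)
    B2: int = 1000
    b2: int = 32
    b1: int = 32
    #: burn-in: minimum consistent completers required for every regime
    burnin_per_regime: int = 25
    #: weeks between policy recomputations (1 = weekly)
    update_period: int = 1
    minimize: bool = True

    @property
    def adaptive(self) -> bool:
        return self.scheme != SR

    @property
    def label(self) -> str:
        if self.scheme == SR:
            return "SR"
        if self.scheme == UPFRONT:
            return f"{self.estimator.upper()}({self.c_t:g})"
        return f"TS({self.c_t:g})"


def sr_method(**kw) -> MethodConfig:
    return MethodConfig(scheme=SR, **kw)


def upfront_ts(estimator: str = "wipw", c_t: float = 1.0, **kw) -> MethodConfig:
    return MethodConfig(scheme=UPFRONT, estimator=estimator, c_t=c_t, **kw)


def sequential_ts(c_t: float = 1.0, **kw) -> MethodConfig:
    return MethodConfig(scheme=SEQUENTIAL, c_t=c_t, **kw)


def trial_rngs(seed) -> tuple[np.random.Generator, ...]:
    """Three independent streams: data, assignment, TS draws."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return tuple(np.random.default_rng(s) for s in ss.spawn(3))


class TrialEngine:
    """Runs one SMART with weekly accrual, progression, and policy updates."""

    def __init__(
        self,
        params: ScenarioParams,
        method: MethodConfig,
        design: SMARTDesign | None = None,
        seed: int | np.random.SeedSequence = 0,
    ):
        self.params = params
        self.method = replace(method, minimize=params.minimize)
        self.design = design or cancer_pain_design()
        if self.design.stage_gap_weeks != params.stage_gap_weeks:
            self.design = replace_gap(self.design, params.stage_gap_weeks)
        self.rng_data, self.rng_assign, self.rng_ts = trial_rngs(seed)
        self.maps = RegimeMaps(self.design)
        n = params.n_subjects
        scheme = SEQUENTIAL if method.scheme == SEQUENTIAL else UPFRONT
        enroll = self.rng_data.integers(1, params.accrual_weeks + 1, size=n)
        self.data = TrialData.allocate(n, self.design, scheme, enroll)
        self.data.x1 = draw_baseline(n, params, self.rng_data)
        self._eps1 = self.rng_data.normal(0.0, params.eps1_sd, size=n)
        self._eps2 = self.rng_data.normal(0.0, params.eps2_sd, size=n)
        self.ledger = TrialLedger(self.data)
        self.week = 0
        self.t_star: int | None = None
        m = self.maps.m
        self.weight_state = WeightState(m)
        self.weight_state_a = WeightState(m)
        self.aug = AugmentationCache(self.data, self.maps) if self.method.adaptive else None
        self._previous_vectors = None
        self._last_snapshot: PolicySnapshot | None = None

    @property
    def horizon(self) -> int:
        return self.params.accrual_weeks + self.design.K * self.design.stage_gap_weeks

    # -- policy -------------------------------------------------------------

    def _burnin_status(self, week: int) -> tuple[bool, bool]:
        """(complete, newly_complete) for the week's strict-past snapshot."""
        if not self.method.adaptive:
            return False, False
        if self.t_star is not None:
            return True, False
        mask = self.data.snapshot_mask(week)
        if int(mask.sum()) < self.method.burnin_per_regime * 2:
            return False, False
        _, C = consistency_matrices(self.data, self.maps)
        counts = C[mask].sum(axis=0)
        if np.all(counts >= self.method.burnin_per_regime):
            self.t_star = week
            return True, True
        return False, False

    def _update_policy(self, week: int) -> PolicySnapshot:
        complete, newly = self._burnin_status(week)
        hold = (
            self._last_snapshot is not None
            and complete
            and not newly
            and (week - (self.t_star or 0)) % self.method.update_period != 0
        )
        if hold:
            prev = self._last_snapshot
            return PolicySnapshot(
                week=week, scheme=prev.scheme, vectors=prev.vectors,
                burnin_complete=prev.burnin_complete, w=prev.w, wa=prev.wa,
            )
        if self.method.scheme == SEQUENTIAL:
            snap = update_sequential_policy(
                self.data, week, self.method, self.weight_state, self.weight_state_a,
                self.rng_ts, maps=self.maps, aug=self.aug,
                previous=self._previous_vectors, burnin_complete=complete,
                anchor_now=newly,
            )
        elif self.method.scheme == UPFRONT:
            prev = None
            if self._previous_vectors is not None:
                prev = self._previous_vectors.get("regimes")
            snap = update_upfront_policy(
                self.data, week, self.method, self.weight_state, self.weight_state_a,
                self.rng_ts, maps=self.maps, aug=self.aug, previous=prev,
                burnin_complete=complete, anchor_now=newly,
            )
        else:  # simple uniform randomization among regimes; weights stay 1
            m = self.maps.m
            snap = PolicySnapshot(
                week=week, scheme=UPFRONT,
                vectors={"regimes": np.full(m, 1.0 / m)},
                burnin_complete=False, w=(1.0,) * m, wa=(1.0,) * m,
            )
        self._previous_vectors = dict(snap.vectors)
        return snap

    # -- one week -----------------------------------------------------------

    def advance_week(self) -> PolicySnapshot:
        """Process one calendar week: policy update, arrivals, progressions."""
        self.week += 1
        t = self.week
        d, params = self.data, self.params
        snap = self._update_policy(t)
        self._last_snapshot = snap
        self.ledger.snapshots.append(snap)

        arrivals = np.where(d.enroll_week == t)[0]
        if arrivals.size:
            w = np.asarray(snap.w)
            wa = np.asarray(snap.wa)
            d.w[arrivals] = w
            d.wa[arrivals] = wa
            if d.scheme == UPFRONT:
                vec = np.asarray(snap.vectors["regimes"], dtype=float)
                cum = np.cumsum(vec)
                regs = np.searchsorted(cum, self.rng_assign.random(arrivals.size) * cum[-1])
                d.assigned_regime[arrivals] = regs
                d.regime_probs[arrivals] = vec
                d.a1[arrivals] = self.maps.stage1[regs]
            else:
                vec = np.asarray(snap.vectors["stage1"], dtype=float)
                cum = np.cumsum(vec)
                cols = np.searchsorted(cum, self.rng_assign.random(arrivals.size) * cum[-1])
                opts = np.asarray(self.maps.stage1_options)
                d.a1[arrivals] = opts[cols]
                d.stage1_probs[arrivals] = vec

        due2 = np.where((d.stage2_week == t) & (d.a1 >= 0))[0]
        if due2.size:
            x21, x22 = transition_stage2(
                d.x1[due2], d.a1[due2], params, eps1=self._eps1[due2]
            )
            d.x21[due2] = x21
            d.x22[due2] = x22
            if d.scheme == UPFRONT:
                regs = d.assigned_regime[due2]
                d.a2[due2] = np.where(
                    x22 == 1, self.maps.resp_action[regs], self.maps.nonresp_action[regs]
                )
            else:
                for i in due2:
                    key = ("stage2", int(d.a1[i]), int(d.x22[i]))
                    vec = np.asarray(snap.vectors[key], dtype=float)
                    opts = sorted(self.design.feasible_set(2, int(d.a1[i]), int(d.x22[i])))
                    col = np.searchsorted(np.cumsum(vec), self.rng_assign.random() * vec.sum())
                    d.a2[i] = opts[min(col, len(opts) - 1)]
                    row = np.zeros(6)
                    row[list(opts)] = vec
                    d.stage2_probs[i] = row

        done = np.where((d.completion_week == t) & (d.a2 >= 0))[0]
        if done.size:
            d.y[done] = draw_outcome(
                d.x1[done], d.a1[done], d.x21[done], d.a2[done],
                params, eps2=self._eps2[done],
            )
        return snap

    def run(self) -> TrialLedger:
        while self.week < self.horizon:
            self.advance_week()
        return self.ledger


def replace_gap(design: SMARTDesign, gap: int) -> SMARTDesign:
    return SMARTDesign(
        treatment_sets=design.treatment_sets,
        feasible_stage2=dict(design.feasible_stage2),
        stage_gap_weeks=gap,
        embedded_regimes=design.embedded_regimes,
    )


def run_trial(
    params: ScenarioParams,
    method: MethodConfig,
    design: SMARTDesign | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> TrialLedger:
    """Simulate one complete trial and return its ledger."""
    return TrialEngine(params, method, design=design, seed=seed).run()
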