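"""Monte Carlo study runner: in-trial and post-trial operating characteristics.

Runs many simulated trials per randomization method and aggregates the
metrics reported for adaptive SMART designs: in-trial mean outcome,
proportion of subjects assigned the optimal stage-1 treatment, proportion
consistent with the optimal embedded regime, post-trial optimal-regime
identification rates, mean squared error of the optimal regime's value
estimate, and empirical coverage of two-sided confidence intervals and
one-sided bounds -- each with its Monte Carlo standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import cancer_pain_design
from .engine import MethodConfig, run_trial, sequential_ts, sr_method, upfront_ts
from .estimators import (
    ESTIMATOR_NAMES,
    AugmentationCache,
    RegimeMaps,
    ValueTable,
    consistency_matrices,
    estimate_values,
)
from .scenario import ScenarioParams, TruthReport, calibrated, true_regime_values
from .trial import TrialLedger


def in_trial_metrics(ledger: TrialLedger, truth: TruthReport) -> dict:
    """Mean outcome and optimal-assignment proportions for one trial."""
    d = ledger.data
    maps = RegimeMaps(d.design)
    j_opt = truth.optimal_regime - 1
    _, C = consistency_matrices(d, maps)
    opt_a1 = maps.stage1[j_opt]
    return {
        "mean_y": float(np.nanmean(d.y)),
        "prop_a1_opt": float(np.mean(d.a1 == opt_a1)),
        "prop_regime_opt": float(np.mean(C[:, j_opt])),
    }


def post_trial_report(
    ledger: TrialLedger,
    alpha: float = 0.05,
    estimators: tuple[str, ...] = ESTIMATOR_NAMES,
) -> dict[str, ValueTable]:
    """Value estimates for all regimes by each post-trial estimator.

    Requires a completed trial (every subject has an observed outcome).
    The augmentation-model cache is shared between the AIPW and WAIPW
    estimators.
    """
    d = ledger.data
    if np.isnan(d.y).any():
        raise ValueError("post-trial report requires a completed trial")
    maps = RegimeMaps(d.design)
    aug = AugmentationCache(d, maps) if {"aipw", "waipw"} & set(estimators) else None
    return {
        est: estimate_values(d, est, alpha=alpha, aug=aug, maps=maps)
        for est in estimators
    }


@dataclass
class StudyConfig:
    """One Monte Carlo study: scenario, methods, replications, seeding."""

    params: ScenarioParams
    methods: list[MethodConfig]
    reps: int = 1000
    seed: int = 1
    alpha: float = 0.05
    estimators: tuple[str, ...] = ESTIMATOR_NAMES
    #: maximum tolerated fraction of errored trials
    max_error_rate: float = 0.01

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not self.methods:
            raise ValueError("methods must be non-empty")


@dataclass
class StudyResult:
    """Aggregated metrics plus the per-trial arrays they were computed from."""

    config: StudyConfig
    truth: TruthReport
    table: pd.DataFrame
    per_trial: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_errors: dict[str, int] = field(default_factory=dict)

    def cell(self, metric: str, method_label: str) -> tuple[float, float]:
        row = self.table.loc[self.table["metric"] == metric]
        return float(row[method_label].iloc[0]), float(row[f"{method_label}_se"].iloc[0])


def _trial_row(ledger, truth, alpha, estimators, minimize) -> dict:
    row = in_trial_metrics(ledger, truth)
    j_opt = truth.optimal_regime
    theta_opt = truth.theta[j_opt - 1]
    report = post_trial_report(ledger, alpha=alpha, estimators=estimators)
    for est, table in report.items():
        best = table.optimal_regime(minimize=minimize)
        row[f"opt8_{est}"] = float(best == j_opt)
        row[f"opt78_{est}"] = float(best in (7, 8))
        th = table.theta[j_opt - 1]
        row[f"err_{est}"] = float(th - theta_opt)
        row[f"cover_ci_{est}"] = float(
            table.ci_low[j_opt - 1] <= theta_opt <= table.ci_high[j_opt - 1]
        )
        row[f"cover_lb_{est}"] = float(table.lower_bound[j_opt - 1] <= theta_opt)
        row[f"cover_ub_{est}"] = float(theta_opt <= table.upper_bound[j_opt - 1])
    return row


def run_study(config: StudyConfig, progress: bool = False) -> StudyResult:
    """Run the full Monte Carlo grid and aggregate.

    Per-trial seeds derive from (study seed, trial index), with the same
    subject data stream reused across methods.  A study fails if more than
    ``max_error_rate`` of trials error for any method.
    """
    truth = true_regime_values(config.params)
    per_trial: dict[str, pd.DataFrame] = {}
    n_errors: dict[str, int] = {}
    for method in config.methods:
        rows = []
        errors = 0
        for rep in range(config.reps):
            seed = np.random.SeedSequence([config.seed, rep])
            try:
                ledger = run_trial(config.params, method, seed=seed)
                rows.append(
                    _trial_row(ledger, truth, config.alpha, config.estimators,
                               config.params.minimize)
                )
            except Exception:
                errors += 1
                if errors > max(1, config.max_error_rate * config.reps):
                    raise
        per_trial[method.label] = pd.DataFrame(rows)
        n_errors[method.label] = errors
    table = summarize(per_trial, config)
    return StudyResult(config=config, truth=truth, table=table,
                       per_trial=per_trial, n_errors=n_errors)


def summarize(per_trial: dict[str, pd.DataFrame], config: StudyConfig) -> pd.DataFrame:
    """Aggregate per-trial metrics into the study table with MC SEs."""
    metrics: list[str] = []
    for label, df in per_trial.items():
        for col in df.columns:
            name = col if not col.startswith("err_") else f"mse100_{col[4:]}"
            if name not in metrics:
                metrics.append(name)
    out: dict[str, list] = {"metric": metrics}
    for label, df in per_trial.items():
        vals, ses = [], []
        n = len(df)
        for name in metrics:
            col = name if not name.startswith("mse100_") else f"err_{name[7:]}"
            if col not in df.columns:
                vals.append(np.nan)
                ses.append(np.nan)
                continue
            x = df[col].to_numpy(float)
            if name.startswith("mse100_"):
                x = 100.0 * x**2
            vals.append(float(np.nanmean(x)))
            ses.append(float(np.nanstd(x, ddof=1) / np.sqrt(n)) if n > 1 else np.nan)
        out[label] = vals
        out[f"{label}_se"] = ses
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# table replication grids

#: published cells replicated in scope (method label -> metric -> value)
PRINTED_TABLE_1 = {
    "SR": {
        "mean_y": -1.380, "prop_a1_opt": 0.500, "prop_regime_opt": 0.250,
        "mse100_ipw": 0.814, "mse100_aipw": 0.544,
        "cover_ci_ipw": 0.949, "cover_ci_waipw": 0.947,
    },
    "WIPW(0.5)": {"mean_y": -1.795, "prop_a1_opt": 0.691, "prop_regime_opt": 0.390},
    "WIPW(1)": {"mean_y": -1.992, "prop_a1_opt": 0.782, "prop_regime_opt": 0.470},
    "WAIPW(0.5)": {"mean_y": -1.794, "prop_a1_opt": 0.691, "prop_regime_opt": 0.401},
    "WAIPW(1)": {"mean_y": -1.996, "prop_a1_opt": 0.782, "prop_regime_opt": 0.498},
}

PRINTED_TABLE_2 = {
    "SR": {"mean_y": -1.380, "prop_a1_opt": 0.500, "prop_regime_opt": 0.250},
    "TS(0.25)": {"mean_y": -1.976, "prop_a1_opt": 0.772, "prop_regime_opt": 0.445},
    "TS(0.5)": {"mean_y": -1.999, "prop_a1_opt": 0.780, "prop_regime_opt": 0.491},
    "TS(0.75)": {"mean_y": -2.014, "prop_a1_opt": 0.785, "prop_regime_opt": 0.517},
    "TS(1)": {"mean_y": -2.206, "prop_a1_opt": 0.790, "prop_regime_opt": 0.538},
}

#: comparator methods from the literature that are outside this package's scope
NOT_IMPLEMENTED_TABLE_2 = ("AR-1", "AR-2")


def table_methods(table_id: int) -> list[MethodConfig]:
    if table_id == 1:
        return [
            sr_method(),
            upfront_ts("wipw", 0.5), upfront_ts("wipw", 1.0),
            upfront_ts("waipw", 0.5), upfront_ts("waipw", 1.0),
        ]
    if table_id == 2:
        return [sr_method()] + [sequential_ts(c) for c in (0.25, 0.5, 0.75, 1.0)]
    raise ValueError("table id must be 1 or 2")


def replicate_table(
    table_id: int,
    reps: int = 200,
    seed: int = 1,
    params: ScenarioParams | None = None,
    methods: list[MethodConfig] | None = None,
) -> pd.DataFrame:
    """Side-by-side published-vs-simulated comparison for one results table.

    Runs the in-scope method columns at ``reps`` replications and reports,
    per (method, metric), the published value, the simulated value, its MC
    standard error, and the z-distance between them.  Out-of-scope
    comparator columns are flagged ``not implemented``.
    """
    printed = PRINTED_TABLE_1 if table_id == 1 else PRINTED_TABLE_2
    params = params or calibrated()
    config = StudyConfig(
        params=params, methods=methods or table_methods(table_id),
        reps=reps, seed=seed,
    )
    result = run_study(config)
    rows = []
    for label, cells in printed.items():
        for metric, pub in cells.items():
            if label in result.per_trial:
                sim, se = result.cell(metric, label)
                z = (sim - pub) / se if se and se > 0 else np.nan
                status = "simulated"
            else:
                sim = se = z = np.nan
                status = "not run"
            rows.append(
                {"method": label, "metric": metric, "published": pub,
                 "simulated": sim, "mc_se": se, "z": z, "status": status}
            )
    if table_id == 2:
        for label in NOT_IMPLEMENTED_TABLE_2:
            rows.append(
                {"method": label, "metric": "-", "published": np.nan,
                 "simulated": np.nan, "mc_se": np.nan, "z": np.nan,
                 "status": "not implemented"}
            )
    return pd.DataFrame(rows)
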