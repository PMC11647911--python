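"""Trial ledger: per-subject longitudinal records and weekly policy snapshots.

The engine stores the trial in flat numpy arrays (:class:`TrialData`) for
speed; :class:`TrialLedger` wraps those arrays together with the weekly
policy history and provides record-level access, strict-past snapshots, and
CSV round-trips.  Sentinels: integer fields use ``-1`` and float fields use
``nan`` for "not yet observed".

A key integrity property is that every subject's record carries the exact
randomization probabilities (and stabilizing-weight values) that were in
force at each of the subject's own assignment weeks; all propensities used
by the estimators are read back from these stored values, never recomputed
from the policy rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .design import SMARTDesign, cancer_pain_design

UPFRONT = "upfront"
SEQUENTIAL = "sequential"


@dataclass
class TrialData:
    """Columnar per-subject trial data for a two-stage SMART."""

    scheme: str
    design: SMARTDesign
    enroll_week: np.ndarray
    x1: np.ndarray
    a1: np.ndarray
    x21: np.ndarray
    x22: np.ndarray
    a2: np.ndarray
    y: np.ndarray
    # stored policy in force at the subject's own assignment weeks
    regime_probs: Optional[np.ndarray] = None    # (N, m), up-front scheme
    stage1_probs: Optional[np.ndarray] = None    # (N, |A1|), sequential
    stage2_probs: Optional[np.ndarray] = None    # (N, 6) by treatment code, sequential
    assigned_regime: Optional[np.ndarray] = None  # (N,), up-front scheme, 0-based
    w: Optional[np.ndarray] = None               # (N, m) stabilizing weights (IPW class)
    wa: Optional[np.ndarray] = None              # (N, m) stabilizing weights (AIPW class)

    @classmethod
    def allocate(cls, n: int, design: SMARTDesign, scheme: str,
                 enroll_week: np.ndarray) -> "TrialData":
        m = design.n_regimes
        nan = np.full(n, np.nan)
        neg = np.full(n, -1, dtype=int)
        data = cls(
            scheme=scheme,
            design=design,
            enroll_week=np.asarray(enroll_week, dtype=int),
            x1=nan.copy(), a1=neg.copy(), x21=nan.copy(),
            x22=neg.copy(), a2=neg.copy(), y=nan.copy(),
            w=np.ones((n, m)), wa=np.ones((n, m)),
        )
        if scheme == UPFRONT:
            data.regime_probs = np.full((n, m), np.nan)
            data.assigned_regime = neg.copy()
        elif scheme == SEQUENTIAL:
            data.stage1_probs = np.full((n, len(design.treatment_sets[0])), np.nan)
            data.stage2_probs = np.full((n, 6), np.nan)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        return data

    def __len__(self) -> int:
        return self.enroll_week.shape[0]

    @property
    def stage2_week(self) -> np.ndarray:
        return self.enroll_week + self.design.stage_gap_weeks

    @property
    def completion_week(self) -> np.ndarray:
        return self.enroll_week + self.design.K * self.design.stage_gap_weeks

    def enrolled_by(self, week: int) -> np.ndarray:
        """Gamma_t: enrolled and stage-1 assigned at a week <= ``week``."""
        return (self.enroll_week <= week) & (self.a1 >= 0)

    def completed_by(self, week: int) -> np.ndarray:
        """Delta_t: outcome observed by ``week``."""
        return self.enrolled_by(week) & (self.completion_week <= week) & ~np.isnan(self.y)

    def snapshot_mask(self, week: int) -> np.ndarray:
        """Completers usable for a week-``week`` policy update (strict past)."""
        return self.completed_by(week - 1)


@dataclass(frozen=True)
class SubjectRecord:
    """Record-level view of one subject (fields None beyond the reached stage)."""

    id: int
    enroll_week: int
    x1: float
    a1: Optional[int]
    stage1_probs: Optional[tuple]
    x21: Optional[float]
    x22: Optional[int]
    a2: Optional[int]
    stage2_probs: Optional[tuple]
    y: Optional[float]
    completion_week: Optional[int]


@dataclass(frozen=True)
class PolicySnapshot:
    """Randomization vectors in force at one week.

    ``vectors`` maps a group key to a probability vector: the up-front
    scheme has a single key ``"regimes"``; the sequential scheme has
    ``"stage1"`` plus one ``("stage2", a1, response)`` key per feasible
    group.  ``w``/``wa`` are the per-regime stabilizing-weight values set
    this week.
    """

    week: int
    scheme: str
    vectors: dict
    burnin_complete: bool
    w: Optional[tuple] = None
    wa: Optional[tuple] = None

    def __post_init__(self):
        for key, vec in self.vectors.items():
            v = np.asarray(vec, dtype=float)
            if abs(v.sum() - 1.0) > 1e-10:
                raise ValueError(f"policy vector {key} at week {self.week} does not sum to 1")
            if np.any(v <= 0):
                raise ValueError(f"policy vector {key} at week {self.week} not strictly positive")


@dataclass
class TrialLedger:
    """A trial's subject records plus its weekly policy history."""

    data: TrialData
    snapshots: list[PolicySnapshot] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    def record(self, i: int) -> SubjectRecord:
        d = self.data
        reached2 = d.x22[i] >= 0
        done = not np.isnan(d.y[i])
        if d.scheme == UPFRONT:
            p1 = d.regime_probs[i]
            p2 = None
        else:
            p1 = d.stage1_probs[i]
            p2 = tuple(d.stage2_probs[i]) if reached2 else None
        return SubjectRecord(
            id=i,
            enroll_week=int(d.enroll_week[i]),
            x1=float(d.x1[i]),
            a1=int(d.a1[i]) if d.a1[i] >= 0 else None,
            stage1_probs=tuple(p1) if p1 is not None and not np.isnan(p1).any() else None,
            x21=float(d.x21[i]) if reached2 else None,
            x22=int(d.x22[i]) if reached2 else None,
            a2=int(d.a2[i]) if d.a2[i] >= 0 else None,
            stage2_probs=p2,
            y=float(d.y[i]) if done else None,
            completion_week=int(d.completion_week[i]) if done else None,
        )

    def snapshot_dataframe(self, week: int) -> pd.DataFrame:
        """The analysis dataset observable strictly before ``week``.

        Includes only subjects enrolled by ``week - 1``; stage-2 and outcome
        fields are masked for subjects who had not reached them, and the
        completion indicator is Delta_{week-1}.
        """
        df = self.to_dataframe()
        enrolled = self.data.enrolled_by(week - 1)
        df = df.loc[enrolled].copy()
        reached2 = self.data.stage2_week[enrolled] <= week - 1
        done = self.data.completed_by(week - 1)[enrolled]
        stage2_cols = [c for c in df.columns if c.startswith(("X2", "A2", "p_stage2"))]
        df.loc[~reached2, stage2_cols] = np.nan
        df.loc[~done, ["Y", "completion_week"]] = np.nan
        df["delta"] = done.astype(int)
        return df

    def to_dataframe(self) -> pd.DataFrame:
        d = self.data
        m = d.design.n_regimes
        cols: dict = {
            "subject_id": np.arange(len(d)),
            "enroll_week": d.enroll_week,
            "X1": d.x1,
            "A1": d.a1.astype(float),
        }
        if d.scheme == UPFRONT:
            cols["assigned_regime"] = np.where(
                d.assigned_regime >= 0, d.assigned_regime + 1.0, np.nan
            )
            for j in range(m):
                cols[f"p_regime_{j + 1}"] = d.regime_probs[:, j]
        else:
            opts = sorted(d.design.treatment_sets[0])
            for c, a in enumerate(opts):
                cols[f"p_stage1_{a}"] = d.stage1_probs[:, c]
        cols["X21"] = d.x21
        cols["X22"] = np.where(d.x22 >= 0, d.x22.astype(float), np.nan)
        cols["A2"] = np.where(d.a2 >= 0, d.a2.astype(float), np.nan)
        if d.scheme == SEQUENTIAL:
            for code in range(6):
                cols[f"p_stage2_{code}"] = d.stage2_probs[:, code]
        for j in range(m):
            cols[f"w_{j + 1}"] = d.w[:, j]
        for j in range(m):
            cols[f"wa_{j + 1}"] = d.wa[:, j]
        cols["Y"] = d.y
        cols["completion_week"] = np.where(~np.isnan(d.y), d.completion_week, np.nan)
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, design: SMARTDesign | None = None) -> "TrialLedger":
        return cls.from_dataframe(pd.read_csv(path), design=design)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, design: SMARTDesign | None = None) -> "TrialLedger":
        design = design or cancer_pain_design()
        scheme = UPFRONT if "p_regime_1" in df.columns else SEQUENTIAL
        n, m = len(df), design.n_regimes
        data = TrialData.allocate(n, design, scheme, df["enroll_week"].to_numpy(int))
        data.x1 = df["X1"].to_numpy(float)
        data.a1 = df["A1"].fillna(-1).to_numpy(int)
        data.x21 = df["X21"].to_numpy(float)
        data.x22 = df["X22"].fillna(-1).to_numpy(int)
        data.a2 = df["A2"].fillna(-1).to_numpy(int)
        data.y = df["Y"].to_numpy(float)
        if scheme == UPFRONT:
            if "assigned_regime" in df.columns:
                data.assigned_regime = (df["assigned_regime"].fillna(0).to_numpy(int) - 1)
            data.regime_probs = df[[f"p_regime_{j + 1}" for j in range(m)]].to_numpy(float)
        else:
            opts = sorted(design.treatment_sets[0])
            data.stage1_probs = df[[f"p_stage1_{a}" for a in opts]].to_numpy(float)
            data.stage2_probs = df[[f"p_stage2_{c}" for c in range(6)]].to_numpy(float)
        for j in range(m):
            if f"w_{j + 1}" in df.columns:
                data.w[:, j] = df[f"w_{j + 1}"].to_numpy(float)
            if f"wa_{j + 1}" in df.columns:
                data.wa[:, j] = df[f"wa_{j + 1}"].to_numpy(float)
        return cls(data=data)

    def policy_log(self) -> pd.DataFrame:
        """Long-format weekly policy record (one row per group x option)."""
        rows = []
        for snap in self.snapshots:
            for key, vec in snap.vectors.items():
                label = key if isinstance(key, str) else ":".join(map(str, key))
                for idx, p in enumerate(np.asarray(vec)):
                    rows.append(
                        {
                            "week": snap.week,
                            "scheme": snap.scheme,
                            "group_key": label,
                            "option": idx,
                            "probability": p,
                            "burnin_complete": snap.burnin_complete,
                            "w": None if snap.w is None else snap.w[min(idx, len(snap.w) - 1)],
                        }
                    )
        return pd.DataFrame(rows)
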