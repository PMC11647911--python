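"""Linear Q-function feature specifications for the two-stage cancer-pain SMART.

The stage-2 model regresses the outcome on baseline score, initial
treatment, interim score, and one indicator per distinct stage-2 effect
(codes 2 and 5 share an effect, and codes 0 and 3 are reference levels
absorbed by the intercept / initial-treatment indicator):

    Q2 = b0 + b1*x1 + b2*I(a1=1) + b3*x21
         + b4*I(a2=1) + b5*I(a2 in {2,5}) + b6*I(a2=3) + b7*I(a2=4).

Two stage-1 specifications are used: the regime-specific augmentation
models include a baseline-by-treatment interaction,
``Q1 = b0 + b1*x1 + b2*a1 + b3*x1*a1``, while the sequential Q-learning
policy uses the additive ``Q1 = b0 + b1*x1 + b2*a1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


def q2_features(x1, a1, x21, a2) -> np.ndarray:
    """Stage-2 design matrix (n, 8)."""
    x1 = np.atleast_1d(np.asarray(x1, dtype=float))
    a1 = np.atleast_1d(np.asarray(a1))
    x21 = np.atleast_1d(np.asarray(x21, dtype=float))
    a2 = np.atleast_1d(np.asarray(a2))
    return np.column_stack(
        [
            np.ones_like(x1),
            x1,
            (a1 == 1).astype(float),
            x21,
            (a2 == 1).astype(float),
            ((a2 == 2) | (a2 == 5)).astype(float),
            (a2 == 3).astype(float),
            (a2 == 4).astype(float),
        ]
    )


def q1_interaction_features(x1, a1) -> np.ndarray:
    """Stage-1 design matrix (n, 4) with x1-by-treatment interaction."""
    x1 = np.atleast_1d(np.asarray(x1, dtype=float))
    a1 = np.atleast_1d(np.asarray(a1, dtype=float))
    return np.column_stack([np.ones_like(x1), x1, a1, x1 * a1])


def q1_additive_features(x1, a1) -> np.ndarray:
    """Stage-1 design matrix (n, 3) without interaction."""
    x1 = np.atleast_1d(np.asarray(x1, dtype=float))
    a1 = np.atleast_1d(np.asarray(a1, dtype=float))
    return np.column_stack([np.ones_like(x1), x1, a1])


@dataclass(frozen=True)
class QModelSpec:
    """A linear Q-model: a feature map over (history, action) and its dimension."""

    stage: int
    dim: int
    features: Callable[..., np.ndarray]


Q2_SPEC = QModelSpec(stage=2, dim=8, features=q2_features)
Q1_SEQUENTIAL_SPEC = QModelSpec(stage=1, dim=3, features=q1_additive_features)
Q1_AUGMENTATION_SPEC = QModelSpec(stage=1, dim=4, features=q1_interaction_features)

#: ridge added to normal-equation matrices to guard near-singularity
RIDGE = 1e-8


def ols_fit(phi: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients with a tiny ridge for near-singular designs."""
    xtx = phi.T @ phi
    xtx[np.diag_indices_from(xtx)] += RIDGE
    return np.linalg.solve(xtx, phi.T @ y)
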