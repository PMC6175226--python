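"""Two-stage IPD meta-analysis.

Stage one fits an ordinary least-squares regression per study and extracts
the target coefficient (exposure or interaction) with its sampling
variance.  Stage two pools the per-study coefficients with inverse-variance
weighting under a fixed-effect, DerSimonian-Laird or REML random-effects
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .simulate import IPDDataset

__all__ = [
    "StudyEstimate",
    "PooledEstimate",
    "PoolingError",
    "first_stage",
    "pool_fixed",
    "pool_DL",
    "pool_REML",
    "estimates_to_csv",
    "estimates_from_csv",
]

Z_975 = 1.959964  # two-sided 95% normal quantile, as used throughout

#: floor applied to degenerate (numerically zero) first-stage variances
VARIANCE_FLOOR = 1e-12


class PoolingError(ValueError):
    """Raised when pooling is impossible (fewer than 2 estimable studies)."""


@dataclass(frozen=True)
class StudyEstimate:
    """One study's first-stage coefficient and its sampling variance."""

    study_id: int
    coefficient: float
    variance: float
    n_patients: int
    estimable: bool = True


@dataclass(frozen=True)
class PooledEstimate:
    """Second-stage pooled effect with inference and heterogeneity estimates."""

    theta_hat: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    k_used: int
    method: Literal["DL", "REML", "FE"]
    notes: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Stage one
# ---------------------------------------------------------------------------


def first_stage(
    dataset: IPDDataset, target: Literal["exposure", "interaction"] = "exposure"
) -> list[StudyEstimate]:
    """Per-study OLS of y on intercept, group, x (plus group*x for interaction).

    Studies whose design is singular (e.g. constant covariate or constant
    exposure) or that lack residual degrees of freedom are returned with
    ``estimable=False`` and are excluded from pooling.
    """
    if target not in ("exposure", "interaction"):
        raise ValueError(f"unknown target {target!r}")
    with_interaction = target == "interaction"
    target_col = 3 if with_interaction else 1

    out: list[StudyEstimate] = []
    for study_id, sub in dataset.data.groupby("study_id", sort=True):
        y = sub["y"].to_numpy(dtype=float)
        g = sub["group"].to_numpy(dtype=float)
        x = sub["x"].to_numpy(dtype=float)
        n = y.size
        cols = [np.ones(n), g, x]
        if with_interaction:
            cols.append(g * x)
        X = np.column_stack(cols)
        p = X.shape[1]

        estimable = n > p
        coef = math.nan
        var = math.nan
        if estimable:
            xtx = X.T @ X
            rank = np.linalg.matrix_rank(xtx)
            if rank < p:
                estimable = False
            else:
                beta = np.linalg.solve(xtx, X.T @ y)
                resid = y - X @ beta
                s2 = float(resid @ resid) / (n - p)
                cov = s2 * np.linalg.inv(xtx)
                coef = float(beta[target_col])
                var = max(float(cov[target_col, target_col]), VARIANCE_FLOOR)
        out.append(
            StudyEstimate(
                study_id=int(study_id),
                coefficient=coef,
                variance=var,
                n_patients=n,
                estimable=estimable,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Stage two
# ---------------------------------------------------------------------------


def _estimable_arrays(estimates: Iterable[StudyEstimate]) -> tuple[np.ndarray, np.ndarray]:
    usable = [e for e in estimates if e.estimable]
    if len(usable) < 2:
        raise PoolingError(
            f"pooling requires >= 2 estimable studies, got {len(usable)}"
        )
    y = np.array([e.coefficient for e in usable])
    v = np.array([e.variance for e in usable])
    if np.any(v <= 0) or not np.all(np.isfinite(v)) or not np.all(np.isfinite(y)):
        raise PoolingError("estimable studies must carry finite positive variances")
    return y, v


def _weighted_pool(y: np.ndarray, v: np.ndarray, tau2: float) -> tuple[float, float]:
    w = 1.0 / (v + tau2)
    theta = float(np.sum(w * y) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return theta, se


def _q_statistic(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    mean = np.sum(w * y) / np.sum(w)
    return float(np.sum(w * (y - mean) ** 2))


def pool_fixed(estimates: Sequence[StudyEstimate]) -> PooledEstimate:
    """Inverse-variance fixed-effect pooling (tau2 identically 0)."""
    y, v = _estimable_arrays(estimates)
    theta, se = _weighted_pool(y, v, 0.0)
    return PooledEstimate(
        theta_hat=theta,
        se=se,
        ci_low=theta - Z_975 * se,
        ci_high=theta + Z_975 * se,
        tau2=0.0,
        Q=_q_statistic(y, v),
        k_used=y.size,
        method="FE",
    )


def pool_DL(estimates: Sequence[StudyEstimate]) -> PooledEstimate:
    """DerSimonian-Laird moment estimator of tau2, then inverse-variance pooling.

    With w_j = 1/v_j and Q the weighted squared deviation of study
    coefficients around their fixed-effect mean,
    ``tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))``.
    """
    y, v = _estimable_arrays(estimates)
    k = y.size
    w = 1.0 / v
    q = _q_statistic(y, v)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    theta, se = _weighted_pool(y, v, tau2)
    return PooledEstimate(
        theta_hat=theta,
        se=se,
        ci_low=theta - Z_975 * se,
        ci_high=theta + Z_975 * se,
        tau2=tau2,
        Q=q,
        k_used=k,
        method="DL",
    )


def _reml_negloglik(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    theta = np.sum(w * y) / np.sum(w)
    return 0.5 * (
        np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (y - theta) ** 2)
    )


def pool_REML(estimates: Sequence[StudyEstimate]) -> PooledEstimate:
    """Restricted-maximum-likelihood tau2, then inverse-variance pooling.

    The restricted log-likelihood of the standard random-effects model is
    maximized over tau2 >= 0 by bounded 1-D optimization (tolerance 1e-8);
    the boundary tau2 = 0 is always evaluated as a candidate.  If the
    optimizer fails, the DerSimonian-Laird value is used and flagged.
    """
    y, v = _estimable_arrays(estimates)
    k = y.size
    notes: tuple[str, ...] = ()

    upper = max(10.0 * float(np.var(y)), 10.0 * float(np.max(v)), 1e-6)
    res = optimize.minimize_scalar(
        _reml_negloglik,
        bounds=(0.0, upper),
        args=(y, v),
        method="bounded",
        options={"xatol": 1e-8, "maxiter": 100},
    )
    if res.success:
        tau2 = float(res.x)
        if _reml_negloglik(0.0, y, v) <= res.fun:
            tau2 = 0.0
    else:  # pragma: no cover - scipy bounded search essentially never fails
        tau2 = pool_DL(estimates).tau2
        notes = ("reml-fallback-dl",)

    theta, se = _weighted_pool(y, v, tau2)
    return PooledEstimate(
        theta_hat=theta,
        se=se,
        ci_low=theta - Z_975 * se,
        ci_high=theta + Z_975 * se,
        tau2=tau2,
        Q=_q_statistic(y, v),
        k_used=k,
        method="REML",
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Aggregate-data interchange
# ---------------------------------------------------------------------------


def estimates_to_csv(estimates: Sequence[StudyEstimate], path: str | Path) -> None:
    """Write first-stage estimates as `study_id,coef,var,n,estimable` CSV."""
    pd.DataFrame(
        {
            "study_id": [e.study_id for e in estimates],
            "coef": [e.coefficient for e in estimates],
            "var": [e.variance for e in estimates],
            "n": [e.n_patients for e in estimates],
            "estimable": [int(e.estimable) for e in estimates],
        }
    ).to_csv(path, index=False)


def estimates_from_csv(path: str | Path) -> list[StudyEstimate]:
    """Read externally supplied aggregate rows in the interchange format."""
    df = pd.read_csv(path)
    return [
        StudyEstimate(
            study_id=int(r.study_id),
            coefficient=float(r.coef),
            variance=float(r.var),
            n_patients=int(r.n),
            estimable=bool(r.estimable),
        )
        for r in df.itertuples()
    ]
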