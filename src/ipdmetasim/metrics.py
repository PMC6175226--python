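"""Replication-level performance measures.

Aggregates converged fit results into mean bias, mean error, coverage,
power and convergence rate.  Non-converged iterations are excluded from
the first four denominators; the convergence rate is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .onestage import FitResult
from .twostage import Z_975

__all__ = [
    "MetricsSummary",
    "mean_bias",
    "mean_error",
    "coverage",
    "power",
    "summarize_fits",
]

#: marker for a metric whose denominator is empty
UNDEFINED = float("nan")


@dataclass(frozen=True)
class MetricsSummary:
    scenario_id: str
    model_id: str
    n_iterations_total: int
    n_converged: int
    mean_bias: float
    mean_error: float
    coverage: float
    power: float
    convergence_rate: float

    @property
    def coverage_power_mean(self) -> float:
        """Combined display metric (coverage + power) / 2."""
        return (self.coverage + self.power) / 2.0


def mean_bias(estimates: Sequence[float], truth: float) -> float:
    """Mean of (truth - estimate) over converged replications."""
    if len(estimates) == 0:
        return UNDEFINED
    return float(np.mean(truth - np.asarray(estimates, dtype=float)))


def mean_error(estimates: Sequence[float], truth: float) -> float:
    """Mean of |truth - estimate| over converged replications."""
    if len(estimates) == 0:
        return UNDEFINED
    return float(np.mean(np.abs(truth - np.asarray(estimates, dtype=float))))


def coverage(ci_list: Sequence[tuple[float, float]], truth: float) -> float:
    """Fraction of closed intervals [low, high] containing the truth."""
    if len(ci_list) == 0:
        return UNDEFINED
    hits = sum(1 for lo, hi in ci_list if lo <= truth <= hi)
    return hits / len(ci_list)


def power(fits: Iterable[FitResult], null_value: float) -> float:
    """Fraction of converged fits rejecting H0: effect = null_value.

    Two-sided Wald test at the 5% level: reject iff
    ``|estimate - null| / se > 1.959964`` (equivalently the 95% CI excludes
    the null).
    """
    usable = [f for f in fits if f.converged]
    if not usable:
        return UNDEFINED
    rejections = sum(
        1 for f in usable if abs(f.estimate - null_value) / f.se > Z_975
    )
    return rejections / len(usable)


def summarize_fits(
    fits: Sequence[FitResult],
    truth: float,
    null_value: float,
    scenario_id: str = "",
    model_id: str = "",
) -> MetricsSummary:
    """Collapse one cell's replications for one model into a MetricsSummary."""
    total = len(fits)
    usable = [f for f in fits if f.converged]
    estimates = [f.estimate for f in usable]
    cis = [(f.ci_low, f.ci_high) for f in usable]
    return MetricsSummary(
        scenario_id=scenario_id,
        model_id=model_id or (fits[0].model_id if fits else ""),
        n_iterations_total=total,
        n_converged=len(usable),
        mean_bias=mean_bias(estimates, truth),
        mean_error=mean_error(estimates, truth),
        coverage=coverage(cis, truth),
        power=power(usable, null_value),
        convergence_rate=(len(usable) / total) if total else UNDEFINED,
    )
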