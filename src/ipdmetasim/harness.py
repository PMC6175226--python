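"""Factorial simulation runner.

Iterates settings x size grid x heterogeneity grid, generating one dataset
per iteration and fitting every requested model on that same dataset (a
paired design, so relative model performance is directly comparable).
Seeding is splittable per (master seed, setting, cell, iteration), which
makes cells independently reproducible and safe to parallelize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .metrics import MetricsSummary, summarize_fits
from .onestage import FitResult, fit_onestage, model_spec
from .select import apply_small_study_filter
from .simulate import IPDDataset, generate_ipd, setting_preset
from .twostage import PoolingError, first_stage, pool_DL, pool_REML

__all__ = [
    "TABLE1_SIZES",
    "DEFAULT_HET_GRID",
    "GridSpec",
    "target_for_setting",
    "null_value_for_setting",
    "default_models_for_setting",
    "fit_twostage_model",
    "run_iteration",
    "run_cell",
    "run_grid",
]

logger = logging.getLogger("ipdmetasim")

#: (total_patients, n_studies, mean_study_size) size grid
TABLE1_SIZES: tuple[tuple[int, int, int], ...] = (
    (5000, 10, 500),
    (2000, 4, 500),
    (1000, 2, 500),
    (5000, 20, 250),
    (2000, 8, 250),
    (1000, 4, 250),
    (5000, 50, 100),
    (2000, 20, 100),
    (1000, 10, 100),
)

#: (i2_intercept, i2_exposure) heterogeneity pairs
DEFAULT_HET_GRID: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (0.5, 0.0),
    (0.0, 0.5),
    (0.33, 0.33),
    (0.5, 0.5),
    (0.67, 0.67),
)

RAW_COLUMNS = [
    "setting", "total_n", "k", "i2_int", "i2_exp", "iter", "model",
    "target", "estimate", "se", "ci_lo", "ci_hi", "converged",
]

ALL_MODELS = ("a", "b", "c", "d", "e", "f", "g")


def target_for_setting(setting: int) -> str:
    """Exposure main effect for settings 1-4, interaction for 5-8."""
    return "exposure" if setting <= 4 else "interaction"


def null_value_for_setting(setting: int) -> float:
    """Power null: 0 for the main-effect settings, 0.2 for interaction ones."""
    return 0.0 if setting <= 4 else 0.2


def default_models_for_setting(setting: int) -> tuple[str, ...]:
    """Models a-d everywhere; the random-interaction family e-g only for setting 8."""
    return ("a", "b", "c", "d", "e", "f", "g") if setting == 8 else ("a", "b", "c", "d")


@dataclass(frozen=True)
class GridSpec:
    """Configuration of a full factorial run."""

    settings: tuple[int, ...] = (1,)
    size_grid: tuple[tuple[int, int, int], ...] = TABLE1_SIZES
    heterogeneity_grid: tuple[tuple[float, float], ...] = DEFAULT_HET_GRID
    n_iterations: int = 1000
    master_seed: int = 0
    models: tuple[str, ...] | None = None  # None -> per-setting defaults

    def __post_init__(self) -> None:
        if not self.settings:
            raise ValueError("settings must be a non-empty subset of 1..8")
        for s in self.settings:
            if s not in range(1, 9):
                raise ValueError(f"invalid setting {s}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if self.models is not None:
            bad = set(self.models) - set(ALL_MODELS)
            if bad:
                raise ValueError(f"unknown models {sorted(bad)}")

    def models_for(self, setting: int) -> tuple[str, ...]:
        return self.models if self.models is not None else default_models_for_setting(setting)

    def cells(self):
        for setting in self.settings:
            for size in self.size_grid:
                for het in self.heterogeneity_grid:
                    yield setting, size, het


def _iteration_seed(master_seed: int, setting: int, size, het, iteration: int):
    total_n, k, mean_size = size
    return np.random.SeedSequence(
        [
            int(master_seed),
            int(setting),
            int(total_n),
            int(k),
            int(mean_size),
            int(round(het[0] * 10_000)),
            int(round(het[1] * 10_000)),
            int(iteration),
        ]
    )


def fit_twostage_model(dataset: IPDDataset, target: str) -> FitResult:
    """Run the two-stage pipeline and wrap it as a model-'d' FitResult.

    REML pooling supplies the reported inference (the harness default);
    the DerSimonian-Laird tau2 is computed alongside and carried in
    ``tau2_estimates``.  Fewer than 2 estimable studies counts as
    non-convergence.
    """
    estimates = first_stage(dataset, target=target)
    n_estimable = sum(e.estimable for e in estimates)
    try:
        pooled = pool_REML(estimates)
        dl = pool_DL(estimates)
    except PoolingError:
        return FitResult(
            model_id="d",
            target=target,  # type: ignore[arg-type]
            estimate=float("nan"),
            se=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            converged=False,
            tau2_estimates={},
            n_studies_used=n_estimable,
            notes=("too-few-estimable-studies",),
        )
    return FitResult(
        model_id="d",
        target=target,  # type: ignore[arg-type]
        estimate=pooled.theta_hat,
        se=pooled.se,
        ci_low=pooled.ci_low,
        ci_high=pooled.ci_high,
        converged=True,
        tau2_estimates={"tau2_reml": pooled.tau2, "tau2_dl": dl.tau2},
        n_studies_used=pooled.k_used,
        notes=pooled.notes,
    )


def run_iteration(
    setting: int,
    size: tuple[int, int, int],
    het: tuple[float, float],
    models: Sequence[str],
    seed,
) -> tuple[list[FitResult], float]:
    """Generate one dataset, fit every requested model, return fits and truth."""
    _, k, mean_size = size
    spec = setting_preset(
        setting, n_studies=k, mean_study_size=mean_size,
        i2_intercept=het[0], i2_exposure=het[1], seed=seed,
    )
    dataset = generate_ipd(spec)
    if spec.selection_fraction > 0:
        dataset = apply_small_study_filter(dataset, spec.selection_fraction)

    target = target_for_setting(setting)
    truth = spec.gamma1 if target == "exposure" else spec.gamma3

    fits: list[FitResult] = []
    for model_id in models:
        if model_id == "d":
            fits.append(fit_twostage_model(dataset, target))
        else:
            spec_m = model_spec(model_id, with_interaction=(target == "interaction"))
            fits.append(fit_onestage(dataset, spec_m, target=target))
    return fits, truth


def run_cell(
    setting: int,
    size: tuple[int, int, int],
    het: tuple[float, float],
    models: Sequence[str] | None = None,
    n_iterations: int = 1000,
    master_seed: int = 0,
) -> tuple[list[MetricsSummary], pd.DataFrame]:
    """Run every iteration of one grid cell.

    Returns one MetricsSummary per model plus the raw per-iteration
    FitResult table.  Per-iteration model failures are recorded as
    non-converged rows and never abort the cell.
    """
    if models is None:
        models = default_models_for_setting(setting)
    target = target_for_setting(setting)
    null_value = null_value_for_setting(setting)

    fits_by_model: dict[str, list[FitResult]] = {m: [] for m in models}
    truth = float("nan")
    for it in range(n_iterations):
        seed = _iteration_seed(master_seed, setting, size, het, it)
        fits, truth = run_iteration(setting, size, het, models, seed)
        for model_id, fit in zip(models, fits):
            fits_by_model[model_id].append(fit)

    raw = pd.DataFrame(
        [
            (
                setting, size[0], size[1], het[0], het[1], it, m.model_id,
                m.target, m.estimate, m.se, m.ci_low, m.ci_high, m.converged,
            )
            for m_list in fits_by_model.values()
            for it, m in enumerate(m_list)
        ],
        columns=RAW_COLUMNS,
    ).sort_values(["iter", "model"], kind="stable").reset_index(drop=True)

    scenario_id = f"s{setting}_n{size[0]}_k{size[1]}_i{het[0]:g}_e{het[1]:g}"
    summaries = [
        summarize_fits(
            fits_by_model[m], truth=truth, null_value=null_value,
            scenario_id=scenario_id, model_id=m,
        )
        for m in models
    ]
    return summaries, raw


def _summary_row(setting, size, het, s: MetricsSummary, target: str) -> dict:
    return {
        "setting": setting,
        "total_n": size[0],
        "k": size[1],
        "i2_int": het[0],
        "i2_exp": het[1],
        "model": s.model_id,
        "target": target,
        "n_iterations": s.n_iterations_total,
        "n_converged": s.n_converged,
        "mean_bias": s.mean_bias,
        "mean_error": s.mean_error,
        "coverage": s.coverage,
        "power": s.power,
        "convergence_rate": s.convergence_rate,
        "coverage_power_mean": s.coverage_power_mean,
    }


def run_grid(
    grid: GridSpec,
    n_jobs: int = 1,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every cell of a GridSpec; return (summary, raw) long-format tables.

    When ``out_dir`` is given, writes ``summary.csv``, ``raw.csv`` and a
    per-model ``convergence.csv`` there.
    """
    cells = list(grid.cells())

    def _one(cell):
        setting, size, het = cell
        models = grid.models_for(setting)
        summaries, raw = run_cell(
            setting, size, het, models,
            n_iterations=grid.n_iterations, master_seed=grid.master_seed,
        )
        target = target_for_setting(setting)
        rows = [_summary_row(setting, size, het, s, target) for s in summaries]
        n_failed = int(raw.shape[0] - raw["converged"].sum())
        logger.info(
            "cell setting=%s size=%s het=%s done (%d non-converged fits)",
            setting, size, het, n_failed,
        )
        return rows, raw

    results = Parallel(n_jobs=n_jobs)(delayed(_one)(cell) for cell in cells)

    summary = pd.DataFrame([row for rows, _ in results for row in rows])
    raw = pd.concat([r for _, r in results], ignore_index=True)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_dir / "summary.csv", index=False)
        raw.to_csv(out_dir / "raw.csv", index=False)
        conv = summary[
            ["setting", "total_n", "k", "i2_int", "i2_exp", "model", "convergence_rate"]
        ]
        conv.to_csv(out_dir / "convergence.csv", index=False)
    return summary, raw
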