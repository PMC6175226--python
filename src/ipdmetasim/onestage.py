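"""One-stage mixed-effects IPD meta-analysis (model family a, b, c, e, f, g).

Each model is a linear mixed model on the pooled patient-level data with
study as the grouping level.  The registry fixes, per model letter, how the
intercept and covariate enter (one common fixed coefficient, one fixed
coefficient per study, or a random effect) and whether the exposure-by-
covariate interaction is absent, a common fixed effect, or random.  The
exposure effect is always random across studies.  Estimation is maximum
likelihood; models pairing a random intercept with the random exposure use
an unstructured 2x2 covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .simulate import IPDDataset
from .twostage import Z_975

__all__ = ["ModelSpec", "FitResult", "MODEL_IDS", "model_spec", "fit_onestage"]

TermCoding = Literal["common_fixed", "study_fixed", "random"]
InteractionCoding = Literal["absent", "common_fixed", "random"]

MODEL_IDS = ("a", "b", "c", "e", "f", "g")

# (intercept, covariate, interaction-is-random) per model letter; the
# exposure effect is random in every model.
_REGISTRY: dict[str, tuple[TermCoding, TermCoding, bool]] = {
    "a": ("common_fixed", "common_fixed", False),
    "b": ("study_fixed", "study_fixed", False),
    "c": ("random", "study_fixed", False),
    "e": ("study_fixed", "study_fixed", True),
    "f": ("random", "study_fixed", True),
    "g": ("random", "random", True),
}


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of one member of the one-stage model family."""

    model_id: str
    intercept: TermCoding
    exposure: Literal["random"]
    covariate: TermCoding
    interaction: InteractionCoding
    random_cov_structure: Literal["independent", "unstructured"]


def model_spec(
    model_id: str,
    with_interaction: bool = False,
    random_cov_structure: str | None = None,
) -> ModelSpec:
    """Build the registry ModelSpec for a model letter.

    For models a-c, ``with_interaction`` adds a common fixed interaction
    term; models e-g always carry a random interaction.  ``"unstructured"``
    covariance applies to (intercept, exposure) random pairs (models c, f);
    model g defaults to independent components, switchable.
    """
    if model_id not in _REGISTRY:
        raise ValueError(f"unknown one-stage model {model_id!r}; expected one of {MODEL_IDS}")
    intercept, covariate, ixn_random = _REGISTRY[model_id]
    if ixn_random:
        interaction: InteractionCoding = "random"
    else:
        interaction = "common_fixed" if with_interaction else "absent"
    if random_cov_structure is None:
        random_cov_structure = "unstructured" if model_id in ("c", "f") else "independent"
    return ModelSpec(
        model_id=model_id,
        intercept=intercept,
        exposure="random",
        covariate=covariate,
        interaction=interaction,
        random_cov_structure=random_cov_structure,  # type: ignore[arg-type]
    )


@dataclass(frozen=True)
class FitResult:
    """One model's estimate of one target coefficient.

    ``converged=False`` marks the estimate/SE as unusable; such results are
    excluded from performance metrics and counted in the convergence rate.
    """

    model_id: str
    target: Literal["exposure", "interaction"]
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    converged: bool
    tau2_estimates: Mapping[str, float] = field(default_factory=dict)
    n_studies_used: int = 0
    notes: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def _independent_columns(names, cols, tol=1e-8):
    """Greedy left-to-right selection of linearly independent columns.

    Modified Gram-Schmidt; a column is kept iff its residual against the
    span of the kept columns is non-negligible.  Earlier columns win, so
    callers order mandatory terms first.
    """
    kept_names, kept_cols, dropped = [], [], []
    basis: list[np.ndarray] = []
    for name, col in zip(names, cols):
        r = col.astype(float).copy()
        for q in basis:
            r -= q @ r * q
        norm = np.linalg.norm(r)
        if norm > tol * max(1.0, np.linalg.norm(col)):
            basis.append(r / norm)
            kept_names.append(name)
            kept_cols.append(col)
        else:
            dropped.append(name)
    return kept_names, kept_cols, dropped


def _build_fixed_design(df: pd.DataFrame, spec: ModelSpec):
    """Assemble (and prune) the fixed-effects design implied by a ModelSpec."""
    g = df["group"].to_numpy(dtype=float)
    x = df["x"].to_numpy(dtype=float)
    n = len(df)
    study = df["study_id"].to_numpy()
    study_ids = np.unique(study)

    names: list[str] = []
    cols: list[np.ndarray] = []

    if spec.intercept == "study_fixed":
        for sid in study_ids:
            names.append(f"const_s{sid}")
            cols.append((study == sid).astype(float))
    else:  # common_fixed, or the fixed mean of a random intercept
        names.append("const")
        cols.append(np.ones(n))

    names.append("group")
    cols.append(g)

    if spec.covariate == "study_fixed":
        for sid in study_ids:
            names.append(f"x_s{sid}")
            cols.append(x * (study == sid))
    else:
        names.append("x")
        cols.append(x)

    if spec.interaction != "absent":
        names.append("group_x")
        cols.append(g * x)

    kept_names, kept_cols, dropped = _independent_columns(names, cols)
    X = pd.DataFrame(np.column_stack(kept_cols), columns=kept_names)
    return X, dropped


def _build_random_parts(df: pd.DataFrame, spec: ModelSpec):
    """Return (exog_re DataFrame or None, VCSpec or None, component name maps)."""
    g = df["group"].to_numpy(dtype=float)
    x = df["x"].to_numpy(dtype=float)
    n = len(df)

    corr_cols: list[tuple[str, np.ndarray]] = []  # jointly (unstructured) modelled
    vc_cols: list[tuple[str, np.ndarray]] = []  # independent variance components

    # "unstructured" covers the (intercept, exposure) pair; any further
    # random terms (covariate, interaction) are independent components.
    if spec.random_cov_structure == "unstructured" and spec.intercept == "random":
        corr_cols.append(("intercept", np.ones(n)))
        corr_cols.append(("exposure", g))
    elif spec.intercept == "random":
        corr_cols.append(("intercept", np.ones(n)))
        vc_cols.append(("exposure", g))
    else:
        corr_cols.append(("exposure", g))
    if spec.covariate == "random":
        vc_cols.append(("covariate", x))
    if spec.interaction == "random":
        vc_cols.append(("interaction", g * x))

    exog_re = pd.DataFrame({name: col for name, col in corr_cols}) if corr_cols else None

    vcspec = None
    if vc_cols:
        study = df["study_id"].to_numpy()
        labels = sorted(np.unique(study).tolist())
        masks = [study == lab for lab in labels]
        vcspec = VCSpec(
            names=[name for name, _ in vc_cols],
            colnames=[[[name] for _ in labels] for name, _ in vc_cols],
            mats=[[col[m][:, None] for m in masks] for _, col in vc_cols],
        )
    return exog_re, vcspec


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_FAILED = object()


def _try_fit(model: MixedLM, method: str | None, maxiter: int):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            if method is None:  # statsmodels' default optimizer cascade
                return model.fit(reml=False, maxiter=maxiter)
            return model.fit(reml=False, method=method, maxiter=maxiter)
        except (np.linalg.LinAlgError, ValueError, OverflowError):
            return None


def fit_onestage(
    dataset: IPDDataset,
    spec: ModelSpec | str,
    target: Literal["exposure", "interaction"] = "exposure",
    maxiter: int = 200,
) -> FitResult:
    """Fit one member of the one-stage family and extract the target effect.

    The design implied by the ModelSpec is assembled with indicator coding
    for study-fixed terms (no global intercept in that case); collinear
    study-specific columns — e.g. a constant covariate within a study — are
    dropped and recorded in the result notes.  Estimation is ML; a failed
    fit is retried once with a different optimizer before being declared
    non-converged.  The 95% CI is the normal Wald interval.
    """
    if isinstance(spec, str):
        spec = model_spec(spec, with_interaction=(target == "interaction"))
    if dataset.n_studies < 2:
        raise ValueError("one-stage meta-analysis requires at least 2 studies")
    if target == "interaction" and spec.interaction == "absent":
        raise ValueError("model has no interaction term but target='interaction'")

    df = dataset.data
    X, dropped = _build_fixed_design(df, spec)
    notes = tuple(f"dropped:{name}" for name in dropped)
    target_col = "group" if target == "exposure" else "group_x"

    def failure(extra: tuple[str, ...] = ()) -> FitResult:
        return FitResult(
            model_id=spec.model_id,
            target=target,
            estimate=float("nan"),
            se=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            converged=False,
            tau2_estimates={},
            n_studies_used=dataset.n_studies,
            notes=notes + extra,
        )

    if target_col not in X.columns:
        return failure(("target-column-inestimable",))

    exog_re, vcspec = _build_random_parts(df, spec)
    groups = df["study_id"].to_numpy()
    y = df["y"].to_numpy(dtype=float)

    model = MixedLM(
        y,
        X,
        groups,
        exog_re=exog_re,
        exog_vc=vcspec,
    )

    # powell is robust when variance components sit on the tau2=0 boundary
    # (gradient-based cascades often stall there) and MixedLM profiles the
    # fixed effects out, so only the few covariance parameters are searched
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = _try_fit(model, "powell", maxiter)
        attempts = ("",)
        if result is None or not _usable(result, X.columns.get_loc(target_col)):
            result = _try_fit(model, None, maxiter)
            attempts = ("retry:default",)
            if result is None or not _usable(result, X.columns.get_loc(target_col)):
                return failure(attempts if result is None else attempts + ("no-convergence",))

        i = X.columns.get_loc(target_col)
        est = float(np.asarray(result.fe_params)[i])
        se = float(np.asarray(result.bse_fe)[i])

    tau2: dict[str, float] = {}
    if exog_re is not None:
        cov_re = np.asarray(result.cov_re)
        for idx, name in enumerate(exog_re.columns):
            tau2[name] = float(cov_re[idx, idx])
        if spec.random_cov_structure == "unstructured" and len(exog_re.columns) > 1:
            tau2["cov_intercept_exposure"] = float(cov_re[0, 1])
    if vcspec is not None:
        for idx, name in enumerate(vcspec.names):
            tau2[name] = float(np.asarray(result.vcomp)[idx])

    return FitResult(
        model_id=spec.model_id,
        target=target,
        estimate=est,
        se=se,
        ci_low=est - Z_975 * se,
        ci_high=est + Z_975 * se,
        converged=True,
        tau2_estimates=tau2,
        n_studies_used=dataset.n_studies,
        notes=notes + (attempts if attempts != ("",) else ()),
    )


def _usable(result, target_idx: int) -> bool:
    """Optimizer success plus a finite positive SE for the target effect."""
    if not getattr(result, "converged", False):
        return False
    se = np.asarray(result.bse_fe, dtype=float)[target_idx]
    est = np.asarray(result.fe_params, dtype=float)[target_idx]
    return bool(np.isfinite(se) and se > 0 and np.isfinite(est))
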