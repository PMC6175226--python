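"""Synthetic individual-patient-data (IPD) generation.

Generates multi-study patient-level datasets with a continuous outcome, a
binary exposure, one covariate (continuous or binary) and an optional
exposure-by-covariate interaction.  Between-study heterogeneity is injected
through centred random effects on the intercept, exposure, covariate and
interaction slopes, scaled to target I-squared levels relative to the
residual variance.  Eight named scenario presets cover the base design,
small-study selection, study-varying residual SD, skewed random effects,
interaction designs, varying covariate prevalence and four-component
heterogeneity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from functools import lru_cache
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "InvalidParameterError",
    "ScenarioSpec",
    "StudyRealization",
    "IPDDataset",
    "i2_to_tau2",
    "draw_study_sizes",
    "draw_random_effects",
    "fleishman_coefficients",
    "generate_ipd",
    "setting_preset",
    "SETTING_GAMMAS",
]

CovariateKind = Literal["continuous", "binary"]
REDistribution = Literal["normal", "skew_normal"]


class InvalidParameterError(ValueError):
    """Raised when a generative parameter lies outside its valid domain."""


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------

#: Fixed mean coefficients (gamma0, gamma1, gamma2, gamma3) for each setting.
#: Settings 1-4 target the exposure main effect; 5-8 target the interaction.
SETTING_GAMMAS = {
    1: (1.0, 0.5, 0.3, 0.0),
    2: (1.0, 0.5, 0.3, 0.0),
    3: (1.0, 0.5, 0.3, 0.0),
    4: (1.0, 0.5, 0.3, 0.0),
    5: (1.0, 1.0, 0.5, 0.4),
    6: (1.0, 1.0, 0.5, 0.4),
    7: (1.0, 1.0, 0.5, 0.4),
    8: (1.0, 1.0, 0.5, 0.4),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Full generative configuration for one simulated meta-analysis.

    Parameters
    ----------
    n_studies
        Number of studies k (>= 2).
    mean_study_size
        Mean number of patients per study; actual sizes are drawn uniformly
        on ``[round(lo * mean), round(hi * mean)]`` with multipliers from
        ``size_multipliers``.
    gamma0, gamma1, gamma2, gamma3
        Mean intercept, exposure, covariate and interaction coefficients.
        ``gamma3 = 0`` together with ``i2_interaction = 0`` disables the
        interaction in generation.
    i2_intercept, i2_exposure, i2_covariate, i2_interaction
        Target I-squared heterogeneity per component, each in [0, 1).
    sigma_mean, sigma_sd
        Mean residual SD and its between-study SD (0 means every study
        shares ``sigma_mean`` exactly).
    covariate_kind
        ``"continuous"`` (N(0,1)) or ``"binary"`` (Bernoulli).
    covariate_prevalence_varying
        If True (binary covariate only), per-study prevalence is drawn
        uniformly on [0, 1] instead of being fixed at 0.5.
    exposure_prob
        Bernoulli probability of exposure (group = 1).
    re_distribution, re_skew, re_kurtosis
        Random-effect distribution; skew/kurtosis only apply to
        ``"skew_normal"``.  ``re_kurtosis`` follows the convention selected
        by ``kurtosis_convention`` ("total": normal = 3; "excess":
        normal = 0).
    selection_fraction
        Fraction of studies removed by the small-study filter (applied by
        :func:`ipdmetasim.select.apply_small_study_filter`, not here).
    seed
        Replication-level RNG seed (int or ``numpy.random.SeedSequence``).
    """

    n_studies: int
    mean_study_size: int
    gamma0: float = 1.0
    gamma1: float = 0.5
    gamma2: float = 0.3
    gamma3: float = 0.0
    i2_intercept: float = 0.0
    i2_exposure: float = 0.0
    i2_covariate: float = 0.0
    i2_interaction: float = 0.0
    sigma_mean: float = 1.0
    sigma_sd: float = 0.0
    covariate_kind: CovariateKind = "continuous"
    covariate_prevalence_varying: bool = False
    exposure_prob: float = 0.5
    re_distribution: REDistribution = "normal"
    re_skew: float = 0.0
    re_kurtosis: float = 3.0
    kurtosis_convention: Literal["total", "excess"] = "total"
    selection_fraction: float = 0.0
    seed: object = 0
    size_multipliers: tuple[float, float] = (0.5, 1.5)
    sigma_floor: float = 0.05
    centre_covariate: bool = False
    setting: int | None = None

    def __post_init__(self) -> None:
        if self.n_studies < 2:
            raise InvalidParameterError("n_studies must be >= 2")
        if self.mean_study_size < 10:
            raise InvalidParameterError("mean_study_size must be >= 10")
        for name in ("i2_intercept", "i2_exposure", "i2_covariate", "i2_interaction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1), got {v}")
        if self.sigma_mean <= 0:
            raise InvalidParameterError("sigma_mean must be positive")
        if self.sigma_sd < 0:
            raise InvalidParameterError("sigma_sd must be non-negative")
        if not 0.0 < self.exposure_prob < 1.0:
            raise InvalidParameterError("exposure_prob must be in (0, 1)")
        if not 0.0 <= self.selection_fraction < 1.0:
            raise InvalidParameterError("selection_fraction must be in [0, 1)")
        if self.covariate_kind not in ("continuous", "binary"):
            raise InvalidParameterError(f"unknown covariate_kind {self.covariate_kind!r}")
        if self.re_distribution not in ("normal", "skew_normal"):
            raise InvalidParameterError(f"unknown re_distribution {self.re_distribution!r}")
        if self.covariate_prevalence_varying and self.covariate_kind != "binary":
            raise InvalidParameterError("varying prevalence requires a binary covariate")

    @property
    def excess_kurtosis(self) -> float:
        if self.kurtosis_convention == "total":
            return self.re_kurtosis - 3.0
        return self.re_kurtosis

    def tau2(self) -> tuple[float, float, float, float]:
        """Component tau-squared values implied by the I-squared targets.

        Scaled against the mean residual variance ``sigma_mean ** 2``.
        """
        s2 = self.sigma_mean**2
        return (
            i2_to_tau2(self.i2_intercept, s2),
            i2_to_tau2(self.i2_exposure, s2),
            i2_to_tau2(self.i2_covariate, s2),
            i2_to_tau2(self.i2_interaction, s2),
        )


@dataclass(frozen=True)
class StudyRealization:
    """Realized study-level quantities for one simulated study."""

    study_id: int
    n_patients: int
    u0: float
    u1: float
    u2: float
    u3: float
    sigma_j: float
    covariate_prevalence: float | None = None


@dataclass(frozen=True)
class IPDDataset:
    """Patient-level long table plus the true parameters that generated it.

    ``data`` has columns ``study_id`` (1..k), ``y``, ``group`` (0/1) and
    ``x``.  ``realizations`` holds the per-study random-effect draws so that
    downstream code can recover true study effects.
    """

    data: pd.DataFrame
    spec: ScenarioSpec
    realizations: tuple[StudyRealization, ...]
    dropped_study_ids: tuple[int, ...] = ()

    @property
    def n_studies(self) -> int:
        return len(self.realizations)

    def study_sizes(self) -> np.ndarray:
        return np.array([r.n_patients for r in self.realizations])

    def true_beta1(self) -> np.ndarray:
        """True per-study exposure effects gamma1 + u1j."""
        return self.spec.gamma1 + np.array([r.u1 for r in self.realizations])

    def true_beta3(self) -> np.ndarray:
        """True per-study interaction effects gamma3 + u3j."""
        return self.spec.gamma3 + np.array([r.u3 for r in self.realizations])

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the long table as CSV, with true parameters in a JSON sidecar."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        if sidecar:
            spec_dict = asdict(self.spec)
            if not isinstance(spec_dict["seed"], (int, type(None))):
                spec_dict["seed"] = None  # SeedSequence objects are not serializable
            meta = {
                "spec": spec_dict,
                "realizations": [asdict(r) for r in self.realizations],
                "dropped_study_ids": list(self.dropped_study_ids),
            }
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, indent=1, default=float)
            )

    @classmethod
    def read_csv(cls, path: str | Path) -> "IPDDataset":
        path = Path(path)
        data = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        spec_dict = dict(meta["spec"])
        spec_dict["size_multipliers"] = tuple(spec_dict["size_multipliers"])
        spec = ScenarioSpec(**spec_dict)
        reals = tuple(StudyRealization(**r) for r in meta["realizations"])
        return cls(
            data=data,
            spec=spec,
            realizations=reals,
            dropped_study_ids=tuple(meta.get("dropped_study_ids", [])),
        )


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def i2_to_tau2(i2: float, sigma2: float) -> float:
    """Between-study variance implied by a target I-squared.

    Inverts ``I2 = tau2 / (tau2 + sigma2)`` to ``tau2 = I2 * sigma2 / (1 - I2)``.
    """
    if not 0.0 <= i2 < 1.0:
        raise InvalidParameterError(f"i2 must be in [0, 1), got {i2}")
    if sigma2 <= 0:
        raise InvalidParameterError(f"sigma2 must be positive, got {sigma2}")
    return i2 * sigma2 / (1.0 - i2)


def draw_study_sizes(
    k: int,
    mean_size: int,
    rng: np.random.Generator,
    multipliers: tuple[float, float] = (0.5, 1.5),
) -> np.ndarray:
    """Draw k study sizes uniformly on [round(lo*mean), round(hi*mean)]."""
    if k < 2:
        raise InvalidParameterError("a meta-analysis needs at least 2 studies")
    if mean_size < 10:
        raise InvalidParameterError("mean_size must be >= 10")
    lo_m, hi_m = multipliers
    if not 0 < lo_m <= hi_m:
        raise InvalidParameterError("size multipliers must satisfy 0 < lo <= hi")
    lo = int(round(lo_m * mean_size))
    hi = int(round(hi_m * mean_size))
    return rng.integers(lo, hi + 1, size=k)


@lru_cache(maxsize=32)
def fleishman_coefficients(skew: float, excess_kurtosis: float) -> tuple[float, float, float, float]:
    """Coefficients (a, b, c, d) of the cubic-of-normal transform.

    ``Y = a + b Z + c Z^2 + d Z^3`` with Z standard normal has mean 0,
    variance 1 and the requested standardized third/fourth moments when the
    coefficients solve the classical power-method moment system (a = -c).
    Raises :class:`InvalidParameterError` for (skew, kurtosis) pairs outside
    the feasible region of the transform.
    """

    g1, g2 = float(skew), float(excess_kurtosis)

    def system(p: np.ndarray) -> list[float]:
        b, c, d = p
        var = b * b + 6.0 * b * d + 2.0 * c * c + 15.0 * d * d - 1.0
        sk = 2.0 * c * (b * b + 24.0 * b * d + 105.0 * d * d + 2.0) - g1
        ku = (
            24.0
            * (
                b * d
                + c * c * (1.0 + b * b + 28.0 * b * d)
                + d * d * (12.0 + 48.0 * b * d + 141.0 * c * c + 225.0 * d * d)
            )
            - g2
        )
        return [var, sk, ku]

    start = np.array([1.0, 0.15 * g1, 0.01 * g2])
    sol, info, ier, _ = optimize.fsolve(system, start, full_output=True, xtol=1e-13)
    resid = np.max(np.abs(system(sol)))
    if ier != 1 or resid > 1e-9 or sol[0] <= 0:
        raise InvalidParameterError(
            f"(skew={g1}, excess kurtosis={g2}) is outside the feasible region "
            "of the polynomial-of-normal transform"
        )
    b, c, d = (float(v) for v in sol)
    return (-c, b, c, d)


def draw_random_effects(
    k: int,
    tau2_vector: Sequence[float],
    distribution: REDistribution = "normal",
    skew: float = 0.0,
    excess_kurtosis: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw centred study-level random effects, one column per component.

    Returns an array of shape ``(k, len(tau2_vector))``.  Components are
    independent across columns; each column is i.i.d. across studies with
    population mean 0 and variance equal to its tau-squared.  Under
    ``"skew_normal"`` the standardized third/fourth moments match the
    (skew, excess kurtosis) targets via the cubic-of-normal transform.
    """
    if rng is None:
        rng = np.random.default_rng()
    tau2 = np.asarray(tau2_vector, dtype=float)
    if np.any(tau2 < 0):
        raise InvalidParameterError("tau2 values must be non-negative")
    out = np.zeros((k, tau2.size))
    active = np.nonzero(tau2 > 0)[0]
    if active.size == 0:
        return out
    if distribution == "normal":
        z = rng.standard_normal((k, active.size))
    elif distribution == "skew_normal":
        a, b, c, d = fleishman_coefficients(skew, excess_kurtosis)
        z = rng.standard_normal((k, active.size))
        z = a + b * z + c * z**2 + d * z**3
    else:
        raise InvalidParameterError(f"unknown distribution {distribution!r}")
    out[:, active] = z * np.sqrt(tau2[active])
    return out


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def _draw_sigmas(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.sigma_sd == 0:
        return np.full(spec.n_studies, spec.sigma_mean)
    # truncated-below normal keeps sigma_j strictly positive
    a = (spec.sigma_floor - spec.sigma_mean) / spec.sigma_sd
    return stats.truncnorm.rvs(
        a, np.inf, loc=spec.sigma_mean, scale=spec.sigma_sd,
        size=spec.n_studies, random_state=rng,
    )


def generate_ipd(spec: ScenarioSpec) -> IPDDataset:
    """Generate one IPD meta-analysis dataset from a scenario specification.

    Per study j: realize random effects, residual SD and (binary covariate)
    prevalence; draw patient-level exposure, covariate and residual noise;
    form ``y = (g0+u0) + (g1+u1)*group + (g2+u2)*x + (g3+u3)*group*x + e``.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_studies

    sizes = draw_study_sizes(k, spec.mean_study_size, rng, spec.size_multipliers)
    u = draw_random_effects(
        k,
        spec.tau2(),
        distribution=spec.re_distribution,
        skew=spec.re_skew,
        excess_kurtosis=spec.excess_kurtosis,
        rng=rng,
    )
    sigmas = _draw_sigmas(spec, rng)

    if spec.covariate_kind == "binary":
        if spec.covariate_prevalence_varying:
            prevalences = rng.uniform(0.0, 1.0, size=k)
        else:
            prevalences = np.full(k, 0.5)
    else:
        prevalences = np.full(k, np.nan)

    frames = []
    realizations = []
    for j in range(k):
        n = int(sizes[j])
        group = (rng.random(n) < spec.exposure_prob).astype(np.int64)
        if spec.covariate_kind == "continuous":
            x = rng.standard_normal(n)
            if spec.centre_covariate:
                x = x - x.mean()
        else:
            x = (rng.random(n) < prevalences[j]).astype(np.int64)
        eps = rng.normal(0.0, sigmas[j], size=n)
        y = (
            (spec.gamma0 + u[j, 0])
            + (spec.gamma1 + u[j, 1]) * group
            + (spec.gamma2 + u[j, 2]) * x
            + (spec.gamma3 + u[j, 3]) * group * x
            + eps
        )
        frames.append(
            pd.DataFrame(
                {"study_id": np.full(n, j + 1, dtype=np.int64), "y": y, "group": group, "x": x}
            )
        )
        realizations.append(
            StudyRealization(
                study_id=j + 1,
                n_patients=n,
                u0=float(u[j, 0]),
                u1=float(u[j, 1]),
                u2=float(u[j, 2]),
                u3=float(u[j, 3]),
                sigma_j=float(sigmas[j]),
                covariate_prevalence=(
                    float(prevalences[j]) if spec.covariate_kind == "binary" else None
                ),
            )
        )

    data = pd.concat(frames, ignore_index=True)
    return IPDDataset(data=data, spec=spec, realizations=tuple(realizations))


# ---------------------------------------------------------------------------
# Named setting presets
# ---------------------------------------------------------------------------


def setting_preset(
    setting: int,
    n_studies: int,
    mean_study_size: int,
    i2_intercept: float = 0.0,
    i2_exposure: float = 0.0,
    seed: object = 0,
    **overrides,
) -> ScenarioSpec:
    """Build the ScenarioSpec for one of the 8 named simulation settings.

    Settings: 1 base continuous-covariate design; 2 adds the small-study
    selection fraction; 3 study-varying residual SD; 4 skewed random
    effects; 5 continuous-covariate interaction focus; 6 binary covariate;
    7 binary covariate with varying prevalence; 8 adds covariate and
    interaction heterogeneity (I2 = 0.5 each).
    """
    if setting not in SETTING_GAMMAS:
        raise InvalidParameterError(f"setting must be 1..8, got {setting}")
    g0, g1, g2, g3 = SETTING_GAMMAS[setting]
    kwargs: dict = dict(
        n_studies=n_studies,
        mean_study_size=mean_study_size,
        gamma0=g0,
        gamma1=g1,
        gamma2=g2,
        gamma3=g3,
        i2_intercept=i2_intercept,
        i2_exposure=i2_exposure,
        seed=seed,
        setting=setting,
    )
    if setting == 2:
        kwargs["selection_fraction"] = 0.2
    elif setting == 3:
        kwargs["sigma_sd"] = 0.5
    elif setting == 4:
        kwargs.update(re_distribution="skew_normal", re_skew=1.0, re_kurtosis=4.0)
    elif setting in (6, 7, 8):
        kwargs["covariate_kind"] = "binary"
        if setting == 7:
            kwargs["covariate_prevalence_varying"] = True
        if setting == 8:
            kwargs.update(i2_covariate=0.5, i2_interaction=0.5)
    kwargs.update(overrides)
    return ScenarioSpec(**kwargs)
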