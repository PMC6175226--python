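import numpy as np
import pandas as pd
import pytest

from ipdmetasim.simulate import IPDDataset, ScenarioSpec, StudyRealization, generate_ipd, setting_preset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def setting1_dataset():
    """Small setting-1 dataset with moderate heterogeneity."""
    spec = setting_preset(
        1, n_studies=10, mean_study_size=100,
        i2_intercept=0.5, i2_exposure=0.5, seed=42,
    )
    return generate_ipd(spec)


@pytest.fixture
def homogeneous_dataset():
    """Setting-1 data with no heterogeneity at all."""
    spec = setting_preset(1, n_studies=8, mean_study_size=200, seed=7)
    return generate_ipd(spec)


def make_manual_dataset(study_specs, gamma=(1.0, 0.5, 0.3, 0.0), sigma=0.0, seed=0):
    """Hand-built IPDDataset: study_specs is a list of dicts with keys
    n, x (array or callable), u1 (optional true exposure deviation)."""
    rng = np.random.default_rng(seed)
    g0, g1, g2, g3 = gamma
    frames, reals = [], []
    for j, s in enumerate(study_specs, start=1):
        n = s["n"]
        group = s.get("group", (np.arange(n) % 2))
        x = np.asarray(s.get("x", rng.standard_normal(n)), dtype=float)
        if np.isscalar(x) or x.ndim == 0:
            x = np.full(n, float(x))
        u1 = float(s.get("u1", 0.0))
        eps = rng.normal(0, sigma, n) if sigma > 0 else np.zeros(n)
        y = g0 + (g1 + u1) * group + g2 * x + g3 * group * x + eps
        frames.append(pd.DataFrame({"study_id": j, "y": y, "group": group, "x": x}))
        reals.append(
            StudyRealization(
                study_id=j, n_patients=n, u0=0.0, u1=u1, u2=0.0, u3=0.0,
                sigma_j=max(sigma, 1e-12),
            )
        )
    spec = ScenarioSpec(
        n_studies=len(study_specs), mean_study_size=max(10, study_specs[0]["n"]),
        gamma0=g0, gamma1=g1, gamma2=g2, gamma3=g3, sigma_mean=max(sigma, 1e-6), seed=seed,
    )
    return IPDDataset(
        data=pd.concat(frames, ignore_index=True), spec=spec, realizations=tuple(reals)
    )
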