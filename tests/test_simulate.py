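import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ipdmetasim.simulate import (
    InvalidParameterError,
    IPDDataset,
    ScenarioSpec,
    SETTING_GAMMAS,
    draw_random_effects,
    draw_study_sizes,
    fleishman_coefficients,
    generate_ipd,
    i2_to_tau2,
    setting_preset,
)


class TestI2ToTau2:
    def test_half(self):
        assert i2_to_tau2(0.5, 1.0) == pytest.approx(1.0)

    def test_zero(self):
        assert i2_to_tau2(0.0, 1.0) == 0.0

    def test_two_thirds(self):
        # tau2 = (2/3) / (1/3) = 2, and I2 = 2 / (2 + 1) round-trips
        assert i2_to_tau2(2.0 / 3.0, 1.0) == pytest.approx(2.0)

    @pytest.mark.parametrize("i2,sigma2", [(1.0, 1.0), (1.5, 1.0), (-0.1, 1.0)])
    def test_invalid_i2(self, i2, sigma2):
        with pytest.raises(InvalidParameterError):
            i2_to_tau2(i2, sigma2)

    @pytest.mark.parametrize("sigma2", [0.0, -1.0])
    def test_invalid_sigma2(self, sigma2):
        with pytest.raises(InvalidParameterError):
            i2_to_tau2(0.5, sigma2)

    @given(
        i2=st.floats(min_value=0.0, max_value=0.99),
        sigma2=st.floats(min_value=1e-6, max_value=1e6),
    )
    def test_round_trip(self, i2, sigma2):
        tau2 = i2_to_tau2(i2, sigma2)
        assert tau2 >= 0
        assert tau2 / (tau2 + sigma2) == pytest.approx(i2, abs=1e-12)


class TestDrawStudySizes:
    def test_range_contract(self, rng):
        sizes = draw_study_sizes(10, 500, rng)
        assert len(sizes) == 10
        assert all(250 <= s <= 750 for s in sizes)
        assert sizes.dtype.kind == "i"

    def test_mean_recovery(self, rng):
        sizes = draw_study_sizes(10_000, 500, rng)
        assert abs(sizes.mean() - 500) / 500 < 0.01

    def test_single_study_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            draw_study_sizes(1, 500, rng)

    def test_custom_multipliers(self, rng):
        sizes = draw_study_sizes(50, 100, rng, multipliers=(0.9, 1.1))
        assert all(90 <= s <= 110 for s in sizes)


class TestFleishman:
    def test_symmetric_case_is_identity_like(self):
        a, b, c, d = fleishman_coefficients(0.0, 0.0)
        assert a == pytest.approx(0.0, abs=1e-9)
        assert c == pytest.approx(0.0, abs=1e-9)
        assert b == pytest.approx(1.0, abs=1e-6)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_infeasible_pair_rejected(self):
        # extreme skew with sub-normal kurtosis lies outside the region
        with pytest.raises(InvalidParameterError):
            fleishman_coefficients(3.0, -2.0)


class TestDrawRandomEffects:
    def test_degenerate_variance(self, rng):
        u = draw_random_effects(100, [0.0, 0.0, 0.0, 0.0], rng=rng)
        assert u.shape == (100, 4)
        assert np.all(u == 0.0)

    def test_normal_moments(self, rng):
        u = draw_random_effects(1_000_000, [1.0], "normal", rng=rng)
        assert np.var(u[:, 0]) == pytest.approx(1.0, abs=0.01)
        assert stats.skew(u[:, 0]) == pytest.approx(0.0, abs=0.01)

    def test_skew_normal_moments(self, rng):
        u = draw_random_effects(
            1_000_000, [1.0], "skew_normal", skew=1.0, excess_kurtosis=1.0, rng=rng
        )
        col = u[:, 0]
        assert np.mean(col) == pytest.approx(0.0, abs=0.01)
        assert np.var(col) == pytest.approx(1.0, abs=0.02)
        assert stats.skew(col) == pytest.approx(1.0, abs=0.05)
        assert stats.kurtosis(col, fisher=False) == pytest.approx(4.0, abs=0.2)

    def test_negative_tau2_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            draw_random_effects(10, [-1.0], rng=rng)


class TestScenarioSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_studies": 1},
            {"i2_exposure": 1.0},
            {"sigma_mean": 0.0},
            {"sigma_sd": -0.1},
            {"exposure_prob": 0.0},
            {"selection_fraction": 1.0},
            {"covariate_kind": "ordinal"},
            {"covariate_prevalence_varying": True},  # needs binary covariate
        ],
    )
    def test_invalid_parameters(self, kwargs):
        base = dict(n_studies=10, mean_study_size=100)
        base.update(kwargs)
        with pytest.raises(InvalidParameterError):
            ScenarioSpec(**base)

    def test_tau2_vector(self):
        spec = ScenarioSpec(n_studies=5, mean_study_size=50, i2_exposure=0.5)
        assert spec.tau2() == (0.0, pytest.approx(1.0), 0.0, 0.0)


class TestSettingPresets:
    def test_setting1_gammas(self):
        spec = setting_preset(1, n_studies=10, mean_study_size=500)
        assert (spec.gamma0, spec.gamma1, spec.gamma2, spec.gamma3) == (1.0, 0.5, 0.3, 0.0)
        assert spec.covariate_kind == "continuous"
        assert spec.selection_fraction == 0.0
        assert spec.sigma_sd == 0.0
        assert spec.re_distribution == "normal"

    @pytest.mark.parametrize("setting", [5, 6, 7, 8])
    def test_interaction_settings_gammas(self, setting):
        spec = setting_preset(setting, n_studies=10, mean_study_size=100)
        assert (spec.gamma0, spec.gamma1, spec.gamma2, spec.gamma3) == (1.0, 1.0, 0.5, 0.4)

    def test_setting2_selection(self):
        assert setting_preset(2, 10, 100).selection_fraction == 0.2

    def test_setting3_sigma(self):
        spec = setting_preset(3, 10, 100)
        assert spec.sigma_sd == 0.5
        assert spec.sigma_mean == 1.0

    def test_setting4_skew(self):
        spec = setting_preset(4, 10, 100)
        assert spec.re_distribution == "skew_normal"
        assert spec.re_skew == 1.0
        assert spec.re_kurtosis == 4.0
        assert spec.excess_kurtosis == pytest.approx(1.0)

    def test_setting6_binary(self):
        spec = setting_preset(6, 10, 100)
        assert spec.covariate_kind == "binary"
        assert not spec.covariate_prevalence_varying

    def test_setting7_varying_prevalence(self):
        assert setting_preset(7, 10, 100).covariate_prevalence_varying

    def test_setting8_extra_heterogeneity(self):
        spec = setting_preset(8, 10, 100)
        assert spec.i2_covariate == 0.5
        assert spec.i2_interaction == 0.5

    def test_unknown_setting(self):
        with pytest.raises(InvalidParameterError):
            setting_preset(9, 10, 100)


class TestGenerateIPD:
    def test_setting1_shape_and_balance(self):
        spec = setting_preset(1, n_studies=10, mean_study_size=500, seed=11)
        ds = generate_ipd(spec)
        assert ds.n_studies == 10
        assert all(250 <= n <= 750 for n in ds.study_sizes())
        assert ds.data["group"].isin([0, 1]).all()
        assert ds.data["group"].mean() == pytest.approx(0.5, abs=0.02)
        counts = ds.data.groupby("study_id").size()
        assert set(counts.index) == set(range(1, 11))
        assert (counts >= 2).all()

    def test_ols_recovery_without_heterogeneity(self):
        # with all tau2 = 0 pooled least squares is consistent for the gammas
        spec = ScenarioSpec(
            n_studies=2, mean_study_size=50_000,
            gamma0=1.0, gamma1=0.5, gamma2=0.3, gamma3=0.0, seed=5,
        )
        ds = generate_ipd(spec)
        X = np.column_stack(
            [np.ones(len(ds.data)), ds.data["group"], ds.data["x"]]
        )
        beta = np.linalg.lstsq(X, ds.data["y"].to_numpy(), rcond=None)[0]
        assert beta == pytest.approx([1.0, 0.5, 0.3], abs=0.02)

    def test_seed_determinism(self):
        spec = setting_preset(1, n_studies=5, mean_study_size=50, seed=99)
        a = generate_ipd(spec)
        b = generate_ipd(spec)
        pd.testing.assert_frame_equal(a.data, b.data)
        assert a.realizations == b.realizations

    def test_sigma_constant_when_sd_zero(self):
        ds = generate_ipd(setting_preset(1, 10, 50, seed=1))
        assert all(r.sigma_j == 1.0 for r in ds.realizations)

    def test_sigma_varies_in_setting3(self):
        ds = generate_ipd(setting_preset(3, 30, 50, seed=1))
        sig = np.array([r.sigma_j for r in ds.realizations])
        assert sig.std() > 0.1
        assert (sig > 0).all()

    def test_setting7_prevalence_spread(self):
        ds = generate_ipd(setting_preset(7, 40, 50, seed=13))
        prev = np.array([r.covariate_prevalence for r in ds.realizations])
        assert prev.min() < 0.2 and prev.max() > 0.8
        assert ds.data["x"].isin([0, 1]).all()

    def test_heterogeneity_round_trip(self):
        # empirical I2 of the true exposure effects converges to the target
        target = 0.5
        spec = setting_preset(
            1, n_studies=4000, mean_study_size=10, i2_exposure=target, seed=3
        )
        ds = generate_ipd(spec)
        v = np.var(ds.true_beta1(), ddof=1)
        assert v / (v + 1.0) == pytest.approx(target, abs=0.02)

    def test_csv_round_trip(self, tmp_path):
        ds = generate_ipd(setting_preset(1, 4, 30, seed=2))
        path = tmp_path / "ds.csv"
        ds.to_csv(path)
        back = IPDDataset.read_csv(path)
        pd.testing.assert_frame_equal(ds.data, back.data)
        assert back.spec.gamma1 == ds.spec.gamma1
        assert back.realizations == ds.realizations

    def test_true_effect_accessors(self):
        ds = generate_ipd(setting_preset(8, 6, 40, i2_exposure=0.5, seed=4))
        assert ds.true_beta1() == pytest.approx(
            [1.0 + r.u1 for r in ds.realizations]
        )
        assert ds.true_beta3() == pytest.approx(
            [0.4 + r.u3 for r in ds.realizations]
        )
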