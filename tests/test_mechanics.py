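"""Strain/stress channels, Kelvin-Voigt fitting, hysteresis and EDR."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from heelpad.errors import (
    DegenerateCurveError,
    DegenerateLoopWarning,
    InvalidStateError,
    NoContactError,
    StageError,
    UnidentifiableModelError,
    UnitError,
)
from heelpad.mechanics import (
    TrialTimeSeries,
    analyze_trial,
    compute_strain,
    compute_stress,
    energy_dissipation_rate,
    fit_kelvin_voigt,
    peak_values,
    split_loading_unloading,
    strain_rate,
)


def make_ts(thickness, force=None, area=10.0, dt=0.02, h0=None):
    n = len(thickness)
    return TrialTimeSeries(
        time=np.arange(n) * dt,
        thickness=np.asarray(thickness, float),
        force=np.zeros(n) if force is None else np.asarray(force, float),
        area=area,
        h0=h0,
    )


class TestStrain:
    def test_unloaded_is_zero(self):
        ts = make_ts([16.0, 16.0, 16.0], h0=16.0)
        assert np.allclose(compute_strain(ts), 0.0)

    @pytest.mark.parametrize(
        "h0,thickness,expected",
        [(16.0, 8.0, 0.5), (15.99, 5.03685, 0.685)],
    )
    def test_arithmetic(self, h0, thickness, expected):
        ts = make_ts([h0, thickness, h0], h0=h0)
        assert compute_strain(ts)[1] == pytest.approx(expected, abs=1e-12)

    def test_unset_h0_rejected(self):
        with pytest.raises(InvalidStateError):
            compute_strain(make_ts([16.0, 15.0, 16.0]))


class TestStress:
    @pytest.mark.parametrize(
        "force,area,expected",
        [(0.0, 10.0, 0.0), (146.34, 10.0, 146.34), (50.0, 5.0, 100.0)],
    )
    def test_unit_conversion_n_cm2_to_kpa(self, force, area, expected):
        ts = make_ts([16, 15, 16], force=[force] * 3, area=area)
        assert compute_stress(ts)[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_area_in_contact_rejected(self):
        ts = make_ts([16, 15, 16], force=[0, 50, 0], area=[10, 0, 10])
        with pytest.raises(UnitError, match="frame 1"):
            compute_stress(ts)


class TestStrainRate:
    def test_constant_strain_is_zero(self):
        t = np.arange(5) * 0.02
        assert np.allclose(strain_rate(np.full(5, 0.3), t), 0.0)

    def test_linear_is_exact_everywhere(self):
        t = np.arange(0, 0.21, 0.02)
        assert np.allclose(strain_rate(0.5 * t, t), 0.5, atol=1e-12)

    def test_quadratic_exact_on_interior(self):
        # central difference of t^2 at t: ((t+d)^2-(t-d)^2)/2d = 2t exactly
        t = np.arange(0, 0.21, 0.02)
        rate = strain_rate(t**2, t)
        assert np.allclose(rate[1:-1], 2 * t[1:-1], atol=1e-12)

    def test_non_increasing_time_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            strain_rate([0, 1, 2], [0.0, 0.0, 0.1])

    def test_smoothing_recovers_noisy_linear_slope(self, rng):
        t = np.arange(0, 1, 0.02)
        eps = 0.5 * t + 1e-3 * rng.standard_normal(t.size)
        rough = strain_rate(eps, t)
        smooth = strain_rate(eps, t, smoothing=True)
        err = lambda r: np.abs(r[2:-2] - 0.5).max()
        assert err(smooth) < err(rough)


class TestKelvinVoigtFit:
    def test_pure_elastic(self):
        eps = np.linspace(0, 0.5, 10)
        epsdot = np.linspace(1, 0.1, 10)
        fit = fit_kelvin_voigt(100 * eps, eps, epsdot)
        assert fit.E == pytest.approx(100, abs=1e-9)
        assert fit.eta == pytest.approx(0, abs=1e-9)
        assert fit.rss == pytest.approx(0, abs=1e-12)

    def test_noiseless_paper_magnitude_recovery(self):
        E, eta = 192.55, 43.9
        t = np.arange(31) * 0.02
        eps = 0.685 * np.sin(np.pi * t / t[-1]) ** 2
        epsdot = np.gradient(eps, t)
        sigma = E * eps + eta * eps * epsdot
        fit = fit_kelvin_voigt(sigma[1:], eps[1:], epsdot[1:])
        assert fit.E == pytest.approx(E, rel=1e-6)
        assert fit.eta == pytest.approx(eta, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    @given(seed=st.integers(0, 10_000))
    def test_matches_normal_equations_oracle(self, seed):
        """lstsq solution equals the hand-built normal-equations solve."""
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 40)
        eps = rng.uniform(0.01, 0.8, n)
        epsdot = rng.uniform(-5, 5, n)
        sigma = rng.uniform(0, 200, n)
        X = np.column_stack([eps, eps * epsdot])
        beta = np.linalg.solve(X.T @ X, X.T @ sigma)  # independent oracle
        fit = fit_kelvin_voigt(sigma, eps, epsdot)
        assert fit.E == pytest.approx(beta[0], abs=1e-9)
        assert fit.eta == pytest.approx(beta[1], abs=1e-9)

    def test_negative_estimates_flagged_not_clipped(self):
        eps = np.linspace(0.01, 0.5, 10)
        epsdot = np.linspace(1, 0.1, 10)
        sigma = -50 * eps
        fit = fit_kelvin_voigt(sigma, eps, epsdot)
        assert fit.E < 0 and fit.negative_param_flag

    def test_zero_viscous_column_unidentifiable(self):
        eps = np.linspace(0.01, 0.5, 10)
        with pytest.raises(UnidentifiableModelError, match="viscous"):
            fit_kelvin_voigt(100 * eps, eps, np.zeros(10))

    def test_proportional_columns_unidentifiable(self):
        eps = np.linspace(0.01, 0.5, 10)
        with pytest.raises(UnidentifiableModelError):
            fit_kelvin_voigt(100 * eps, eps, np.full(10, 2.0))

    @given(c=st.floats(0.1, 10.0))
    def test_stress_scaling_covariance(self, c):
        """Scaling stress by c scales E, eta and dissipation by c; EDR fixed."""
        t = np.arange(31) * 0.02
        eps = 0.6 * np.sin(np.pi * t / t[-1]) ** 2
        epsdot = np.gradient(eps, t)
        sigma = 150 * eps + 30 * eps * epsdot
        f1 = fit_kelvin_voigt(sigma, eps, epsdot)
        f2 = fit_kelvin_voigt(c * sigma, eps, epsdot)
        assert f2.E == pytest.approx(c * f1.E, rel=1e-9)
        assert f2.eta == pytest.approx(c * f1.eta, rel=1e-9)
        d1, edr1 = energy_dissipation_rate(sigma, eps)
        d2, edr2 = energy_dissipation_rate(c * sigma, eps)
        assert d2 == pytest.approx(c * d1, rel=1e-9)
        assert edr2 == pytest.approx(edr1, rel=1e-9)


class TestSplitLoadingUnloading:
    def test_split_at_max(self):
        loading, unloading = split_loading_unloading([0, 0.3, 0.7, 0.4, 0])
        assert list(loading) == [0, 1, 2]
        assert list(unloading) == [2, 3, 4]

    def test_plateau_splits_at_first_max(self):
        loading, unloading = split_loading_unloading([0, 0.7, 0.7, 0])
        assert list(loading) == [0, 1]
        assert list(unloading) == [1, 2, 3]

    def test_monotone_series_warns(self):
        with pytest.warns(DegenerateLoopWarning):
            loading, unloading = split_loading_unloading([0, 0.2, 0.5])
        assert list(unloading) == [2]


class TestEnergyDissipation:
    def test_retraced_loop_dissipates_nothing(self):
        up = np.linspace(0, 0.5, 6)
        eps = np.concatenate([up, up[::-1]])
        sigma = 200 * eps
        d, edr = energy_dissipation_rate(sigma, eps)
        assert d == pytest.approx(0, abs=1e-9)
        assert edr == pytest.approx(0, abs=1e-9)

    def test_parallelogram_loop_hand_computed(self):
        # loading sigma=200*eps to eps=0.5, unloading offset -20 kPa:
        # loop area 20*0.5 = 10 kPa, loading area 25 kPa -> EDR 40%
        up = np.linspace(0, 0.5, 6)
        dn = np.linspace(0.5, 0, 6)
        eps = np.concatenate([up, dn])
        sigma = np.concatenate([200 * up, 200 * dn - 20])
        d, edr = energy_dissipation_rate(sigma, eps)
        assert d == pytest.approx(10.0, abs=1e-12)
        assert edr == pytest.approx(40.0, abs=1e-12)

    def test_coarse_loop_matches_dense_quadrature_oracle(self):
        """EDR of a 31-frame Kelvin-Voigt loop vs a 1e5-point oracle."""

        def loop(n):
            t = np.linspace(0, 0.6, n)
            eps = 0.685 * np.sin(np.pi * t / 0.6) ** 2
            epsdot = (
                0.685 * 2 * np.sin(np.pi * t / 0.6) * np.cos(np.pi * t / 0.6) * np.pi / 0.6
            )  # analytic rate
            sigma = 192.55 * eps + 43.9 * eps * epsdot
            return sigma, eps

        _, edr_coarse = energy_dissipation_rate(*loop(31))
        _, edr_dense = energy_dissipation_rate(*loop(100_001))
        assert edr_coarse == pytest.approx(edr_dense, rel=5e-3)

    def test_edr_increases_with_eta_on_grid(self):
        t = np.linspace(0, 0.6, 31)
        eps = 0.685 * np.sin(np.pi * t / 0.6) ** 2
        epsdot = np.gradient(eps, t)
        edrs = []
        for eta in [5.0, 15.0, 25.0, 35.0]:  # sigma stays non-negative here
            sigma = 192.55 * eps + eta * eps * epsdot
            assert sigma.min() >= 0
            _, edr = energy_dissipation_rate(sigma, eps)
            assert 0.0 <= edr <= 100.0
            edrs.append(edr)
        assert np.all(np.diff(edrs) > 0)

    def test_degenerate_loading_area_rejected(self):
        eps = np.array([0, 0.3, 0.6, 0.3, 0])
        sigma = np.zeros(5)
        with pytest.raises(DegenerateCurveError):
            energy_dissipation_rate(sigma, eps)


class TestPeakValues:
    def test_independent_maxima(self):
        eps = np.array([0, 0.4, 0.700, 0.5, 0])
        sigma = np.array([0, 162.95, 120.0, 60.0, 0])
        peak_eps, peak_sigma, i_eps, i_sigma = peak_values(sigma, eps)
        assert (peak_eps, peak_sigma) == (0.700, 162.95)
        assert (i_eps, i_sigma) == (2, 1)

    def test_monotone_channels_peak_at_last_frame(self):
        eps = np.linspace(0, 0.5, 5)
        sigma = np.linspace(0, 100, 5)
        _, _, i_eps, i_sigma = peak_values(sigma, eps)
        assert i_eps == i_sigma == 4

    def test_first_of_two_stress_maxima(self):
        sigma = np.array([0, 150, 100, 140, 0])
        assert peak_values(sigma, np.linspace(0, 0.4, 5))[1] == 150


class TestAnalyzeTrial:
    def test_noiseless_round_trip(self, noiseless_heel, noiseless_trial):
        props = analyze_trial(noiseless_trial)
        assert props.primary_thickness == noiseless_heel.h0_true
        assert props.E == pytest.approx(noiseless_heel.E_true, rel=1e-6)
        assert props.eta == pytest.approx(noiseless_heel.eta_true, rel=1e-6)
        # sampled trajectory max is within one frame of the true peak
        assert props.peak_strain == pytest.approx(
            noiseless_heel.peak_strain_true, rel=5e-3
        )

    def test_pure_elastic_trial(self, noiseless_cfg, noiseless_heel):
        from dataclasses import replace

        from heelpad.synthetic import simulate_stance

        p = replace(noiseless_heel, eta_true=0.0)
        ts = simulate_stance(p, noiseless_cfg.gait, seed=1)
        props = analyze_trial(ts)
        assert props.eta == pytest.approx(0.0, abs=1e-9)
        assert props.edr == pytest.approx(0.0, abs=1e-6)

    def test_all_zero_force_fails_at_contact_stage(self):
        ts = make_ts([16.0, 15.0, 14.0, 15.0, 16.0])
        with pytest.raises(StageError) as exc_info:
            analyze_trial(ts)
        assert exc_info.value.stage == "contact"
        assert isinstance(exc_info.value.original, NoContactError)

    def test_noise_bias_small(self, default_cfg, rng):
        """Median relative bias of E and eta < 2% at 1% stress noise."""
        from heelpad.synthetic import HeelParams, simulate_stance

        errs = []
        for k in range(100):
            p = HeelParams(
                subject_id="S001",
                side="left",
                condition="time_zero",
                age=46.5,
                bmi=24.6,
                h0_true=15.99,
                E_true=192.55,
                eta_true=43.9,
                peak_strain_true=0.685,
                noise_cv=0.01,
            )
            ts = simulate_stance(p, default_cfg.gait, seed=k)
            props = analyze_trial(ts)
            errs.append(
                (
                    (props.E - p.E_true) / p.E_true,
                    (props.eta - p.eta_true) / p.eta_true,
                )
            )
        errs = np.array(errs)
        assert abs(np.median(errs[:, 0])) < 0.02
        assert abs(np.median(errs[:, 1])) < 0.02
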