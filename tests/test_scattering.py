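"""SLS/DLS reduction: Rayleigh-ratio masses, cumulants, regularized ILT."""

import math
import warnings

import numpy as np
import pytest

import pepassoc as pa
from pepassoc.scattering import (
    diffusion_from_radius,
    excess_rayleigh_ratio,
    optical_constant,
)


class TestScatteringVector:
    def test_hand_value_532nm_90deg(self, config):
        q = pa.scattering_vector(config)
        expect = 4 * math.pi * 1.333 / 5.32e-7 * math.sin(math.radians(45))
        assert q == pytest.approx(expect, rel=1e-12)
        assert q == pytest.approx(2.227e7, rel=1e-3)

    def test_small_angle_limit(self):
        cfg = pa.InstrumentConfig(scattering_angle_deg=1e-6)
        assert pa.scattering_vector(cfg) < 1.0

    def test_linear_in_refractive_index(self, config):
        cfg2 = pa.InstrumentConfig(solvent_refractive_index=2 * 1.333)
        assert pa.scattering_vector(cfg2) == pytest.approx(
            2 * pa.scattering_vector(config)
        )


class TestApparentMass:
    def test_no_excess_scattering_returns_zero_with_warning(self, config):
        rec = pa.IntensityRecord(1000.0, 1000.0, 50000.0, 1.0)
        with pytest.warns(UserWarning, match="apparent mass set to 0"):
            assert pa.apparent_mass(rec, config) == 0.0

    def test_round_trip_is_algebraic_identity(self, config):
        m_in = 3 * 4187.6
        rec = pa.gen_intensity_record(m_in, 0.8, config)
        assert pa.apparent_mass(rec, config) == pytest.approx(m_in, rel=1e-9)

    def test_spreadsheet_oracle_encoding_12563(self):
        # independent arithmetic: K = 4 pi^2 n^2 (dn/dc)^2 / (NA lambda^4),
        # ratio = M K c / R_tol for n = n_tol
        cfg = pa.InstrumentConfig(
            reference_refractive_index=1.333,  # forced equal to solvent
            reference_rayleigh_ratio_cm=2.1e-5,
        )
        k = 4 * math.pi**2 * 1.333**2 * 0.19**2 / (6.02214076e23 * 5.32e-5**4)
        ratio = 12563.0 * k * 1e-3 / 2.1e-5
        rec = pa.IntensityRecord(
            mean_intensity_sample=1000.0 + ratio * 50000.0,
            mean_intensity_solvent=1000.0,
            mean_intensity_reference=50000.0,
            concentration_mg_ml=1.0,
        )
        assert pa.apparent_mass(rec, cfg) == pytest.approx(12563.0, rel=1e-9)

    def test_refractive_index_volume_correction(self, config):
        rec = pa.IntensityRecord(2000.0, 1000.0, 50000.0, 1.0)
        r_ex = excess_rayleigh_ratio(rec, config)
        assert r_ex == pytest.approx(
            (1000.0 / 50000.0) * 2.1e-5 * (1.333 / 1.496) ** 2
        )

    def test_invalid_concentration_rejected(self):
        with pytest.raises(ValueError):
            pa.IntensityRecord(2000.0, 1000.0, 50000.0, 0.0)


class TestRelativeMass:
    def test_identity_and_trimer(self, exendin):
        m1 = pa.average_mass(exendin)
        assert pa.relative_mass(m1, m1) == 1.0
        assert pa.relative_mass(3 * m1, m1) == pytest.approx(3.0)
        assert pa.relative_mass(12563.0, m1) == pytest.approx(3.0, rel=1e-3)


class TestCumulantFit:
    def test_noiseless_single_exponential_exact(self):
        lags = np.geomspace(1e-6, 1e-2, 80)
        acf = pa.AcfCurve(lags, 0.8 * np.exp(-2 * 500.0 * lags))
        res = pa.cumulant_fit(acf)
        assert res.mean_rate == pytest.approx(500.0, rel=1e-8)
        assert res.beta == pytest.approx(0.8, rel=1e-8)
        assert abs(res.polydispersity) < 1e-8

    def test_two_component_mean_rate_within_1pct(self, config):
        r1, r2 = 2.0, 4.0
        q = pa.scattering_vector(config)
        g1 = diffusion_from_radius(r1, config) * q**2
        g2 = diffusion_from_radius(r2, config) * q**2
        gbar = 0.5 * g1 + 0.5 * g2
        lags = np.linspace(1e-7, 1.0 / gbar, 60)
        acf = pa.gen_acf([(r1, 0.5), (r2, 0.5)], config, lags_s=lags)
        res = pa.cumulant_fit(acf)
        assert res.mean_rate == pytest.approx(gbar, rel=0.01)

    def test_flat_curve_is_degenerate(self):
        lags = np.geomspace(1e-6, 1e-3, 20)
        acf = pa.AcfCurve(lags, np.full(20, 0.5))
        with pytest.raises(ValueError, match="no decay|too few"):
            pa.cumulant_fit(acf)

    def test_too_few_usable_points(self):
        lags = np.geomspace(1e-6, 1e-3, 12)
        y = 0.8 * np.exp(-2 * 5000.0 * lags)
        y[3:] = -1e-6  # tail truncated after 3 points
        with pytest.raises(ValueError, match="too few"):
            pa.cumulant_fit(pa.AcfCurve(lags, y))


class TestIltRegularized:
    def test_noiseless_delta_recovery(self, config):
        acf = pa.gen_acf([(2.3, 1.0)], config)
        dist = pa.ilt_regularized(acf)
        q = pa.scattering_vector(config)
        g0 = diffusion_from_radius(2.3, config) * q**2
        i0 = int(np.argmin(np.abs(dist.grid - g0)))
        assert dist.weights[max(0, i0 - 1) : i0 + 2].sum() >= 0.95

    def test_bimodal_equal_weight_split(self, config):
        acf = pa.gen_acf([(1.0, 0.5), (100.0, 0.5)], config)
        dist = pa.ilt_regularized(acf)
        q = pa.scattering_vector(config)
        split = math.sqrt(
            diffusion_from_radius(1.0, config) * diffusion_from_radius(100.0, config)
        ) * q**2
        fast = dist.weights[dist.grid > split].sum()
        assert fast == pytest.approx(0.5, abs=0.05)

    def test_weights_nonnegative_and_normalized(self, config):
        acf = pa.gen_acf([(2.3, 1.0)], config, rel_noise_sigma=0.01, seed=7)
        dist = pa.ilt_regularized(acf)
        assert np.all(dist.weights >= 0)
        assert dist.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_explicit_alpha_honored(self, config):
        acf = pa.gen_acf([(2.3, 1.0)], config)
        dist = pa.ilt_regularized(acf, alpha=0.5)
        assert dist.regularization_parameter == 0.5

    def test_agrees_with_cumulants_on_unimodal(self, config):
        for seed in range(5):
            acf = pa.gen_acf([(2.3, 1.0)], config, rel_noise_sigma=0.02, seed=seed)
            cum = pa.cumulant_fit(acf)
            dist = pa.ilt_regularized(acf)
            assert dist.mean_rate() == pytest.approx(cum.mean_rate, rel=0.03)


class TestStokesRadius:
    def test_hand_value(self):
        cfg = pa.InstrumentConfig(temperature_K=296.15, solvent_viscosity_mPas=0.932)
        assert pa.stokes_radius(1.0e-10, cfg) == pytest.approx(2.33, abs=0.005)

    def test_inverse_in_viscosity_at_fixed_diffusion(self, config):
        cfg2 = pa.InstrumentConfig(solvent_viscosity_mPas=2 * 0.932)
        assert pa.stokes_radius(1e-10, cfg2) == pytest.approx(
            0.5 * pa.stokes_radius(1e-10, config)
        )

    def test_radius_linear_in_temperature_at_fixed_viscosity(self, config):
        cfg2 = pa.InstrumentConfig(temperature_K=2 * config.temperature_K)
        assert pa.stokes_radius(1e-10, cfg2) == pytest.approx(
            2 * pa.stokes_radius(1e-10, config)
        )

    def test_round_trip_with_inverse(self, config):
        d = diffusion_from_radius(2.3, config)
        assert pa.stokes_radius(d, config) == pytest.approx(2.3, rel=1e-12)


class TestAcfValidation:
    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 10"):
            pa.AcfCurve(np.geomspace(1e-6, 1e-3, 5), np.ones(5))

    def test_non_increasing_lags(self):
        lags = np.ones(12)
        with pytest.raises(ValueError, match="strictly increasing"):
            pa.AcfCurve(lags, np.ones(12))
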