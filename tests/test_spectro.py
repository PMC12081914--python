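"""Spectroscopy numerics: MRE, melts, isodichroic, bands, CAC."""

import numpy as np
import pytest

from betahelix import (
    SeriesCurve,
    find_isodichroic,
    fit_cac_breakpoint,
    fit_two_state_melt,
    gen_melt,
    gen_spectra_family,
    gen_titration,
    mre_convert,
    second_derivative_bands,
    two_state_curve,
)
from betahelix.errors import (
    DomainError,
    InsufficientDataError,
    IsodichroicNotFoundError,
    NoTransitionError,
    ResampleRequiredError,
)


class TestMreConvert:
    def test_worked_example(self):
        # 10 mdeg, 100 uM, 0.05 cm path, 18 residues
        assert mre_convert(10.0, 100e-6, 0.05, 18) == pytest.approx(11111.1, rel=1e-4)

    def test_linearity(self):
        assert mre_convert(10.0, 200e-6, 0.05, 18) == pytest.approx(
            mre_convert(10.0, 100e-6, 0.05, 18) / 2
        )

    def test_zero_signal(self):
        assert mre_convert(0.0, 100e-6, 0.05, 18) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            mre_convert(10.0, 0.0, 0.05, 18)


class TestMeltFit:
    def test_noiseless_recovery_is_exact(self):
        t = np.arange(20.0, 80.5, 1.0)
        y = two_state_curve(t, 65.0, 400.0, -11000.0, 10.0, -3000.0, 5.0)
        fit = fit_two_state_melt(SeriesCurve(t, y))
        assert fit.t_m == pytest.approx(65.0, abs=0.1)
        assert fit.derivative_t_m == pytest.approx(65.0, abs=1.0)
        assert fit.dh_vh == pytest.approx(400.0, rel=0.01)

    def test_derivative_and_fit_agree_on_noiseless_data(self):
        t = np.arange(20.0, 80.5, 1.0)
        y = two_state_curve(t, 58.0, 350.0, -9000.0, 0.0, -2000.0, 0.0)
        fit = fit_two_state_melt(SeriesCurve(t, y))
        assert fit.midpoint_discrepancy <= 1.0  # within the grid step

    def test_constant_signal_raises(self):
        t = np.arange(20.0, 80.5, 1.0)
        with pytest.raises(NoTransitionError):
            fit_two_state_melt(SeriesCurve(t, np.full_like(t, -5000.0)))

    def test_pure_linear_drift_raises(self):
        t = np.arange(20.0, 80.5, 1.0)
        with pytest.raises(NoTransitionError):
            fit_two_state_melt(SeriesCurve(t, 100.0 - 3.0 * t))

    def test_reparameterization_consistency(self):
        """An affine transform of the signal leaves T_M unchanged."""
        curve = gen_melt(20, 80, 1, 65, 400, -11000, 10, -3000, 5, 80.0, 42)
        fit1 = fit_two_state_melt(curve)
        fit2 = fit_two_state_melt(
            SeriesCurve(curve.x, 3.0 + 0.5 * curve.y)
        )
        assert fit1.t_m == pytest.approx(fit2.t_m, abs=1e-6)

    def test_recovery_median_under_two_percent_noise(self):
        """Over 100 seeded fixtures at sigma = 2% of amplitude the median
        absolute T_M error stays below 0.5 degC."""
        t = np.arange(20.0, 80.5, 1.0)
        clean = two_state_curve(t, 65.0, 400.0, -11000.0, 10.0, -3000.0, 5.0)
        sigma = 0.02 * np.ptp(clean)
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fit = fit_two_state_melt(SeriesCurve(t, clean + rng.normal(0, sigma, t.shape)))
            errors.append(abs(fit.t_m - 65.0))
        assert np.median(errors) < 0.5


class TestIsodichroic:
    def test_constructed_family_crosses_at_204(self):
        spectra = gen_spectra_family(190, 250, 1.0, 204.0, 7, 0.6, 0.02, 11)
        out = find_isodichroic(spectra)
        assert out["wavelength"] == pytest.approx(204.0, abs=0.5)

    def test_two_spectra_single_crossing(self):
        spectra = gen_spectra_family(190, 250, 1.0, 210.0, 2, 0.6, 0.0, 0)
        out = find_isodichroic(spectra)
        assert out["n_crossings"] == 1
        assert out["wavelength"] == pytest.approx(210.0, abs=1e-6)

    def test_identical_spectra_raise(self):
        wl = np.arange(190.0, 251.0, 1.0)
        y = np.sin(wl / 10)
        spectra = [SeriesCurve(wl, y.copy()) for _ in range(4)]
        with pytest.raises(IsodichroicNotFoundError):
            find_isodichroic(spectra)

    def test_mismatched_grids_rejected(self):
        s1 = SeriesCurve(np.arange(190.0, 250.0), np.zeros(60))
        s2 = SeriesCurve(np.arange(191.0, 251.0), np.ones(60))
        with pytest.raises(ResampleRequiredError):
            find_isodichroic([s1, s2, s1])


def gaussian(x, centre, width=8.0, depth=1.0):
    return depth * np.exp(-(((x - centre) / width) ** 2))


class TestSecondDerivativeBands:
    def test_single_band_position_and_assignment(self):
        wn = np.arange(1500.0, 1701.0, 2.0)
        spec = SeriesCurve(wn, gaussian(wn, 1624.0))
        bands = second_derivative_bands(spec)
        assert len(bands) == 1
        pos, label = bands[0]
        assert pos == pytest.approx(1624.0, abs=1.0)
        assert label == "intermolecular β-strand"

    def test_two_bands_resolved_and_assigned(self):
        wn = np.arange(1500.0, 1701.0, 2.0)
        spec = SeriesCurve(wn, gaussian(wn, 1624.0) + 0.6 * gaussian(wn, 1666.0))
        bands = dict(second_derivative_bands(spec))
        labels = set(bands.values())
        assert "intermolecular β-strand" in labels
        assert "β-turn" in labels

    def test_flat_spectrum_has_no_bands(self):
        wn = np.arange(1500.0, 1701.0, 2.0)
        assert second_derivative_bands(SeriesCurve(wn, np.ones_like(wn))) == []

    def test_non_uniform_grid_rejected(self):
        wn = np.array([1500.0, 1502.0, 1505.0, 1509.0, 1514.0, 1520.0, 1530.0,
                       1540.0, 1552.0, 1565.0])
        with pytest.raises(ResampleRequiredError):
            second_derivative_bands(SeriesCurve(wn, np.ones_like(wn)))


class TestCacFit:
    def test_noiseless_grid_breakpoint_recovered_exactly(self):
        curve = gen_titration(1.56, 100, 2, 12.5, 50, 1.0, 40.0, 0.0, 0)
        fit = fit_cac_breakpoint(curve)
        assert fit.breakpoint == pytest.approx(12.5, abs=1e-9)
        assert not fit.single_segment_preferred
        assert fit.slope_high > fit.slope_low

    def test_noisy_scenario_recovery(self):
        curve = gen_titration(1.56, 100, 2, 12.5, 50, 1.0, 40.0, 0.02, 103)
        fit = fit_cac_breakpoint(curve)
        assert fit.breakpoint == pytest.approx(12.5, abs=1.0)

    def test_single_line_prefers_no_breakpoint(self):
        x = np.array([1.56, 3.125, 6.25, 12.5, 25.0, 50.0, 100.0])
        fit = fit_cac_breakpoint(SeriesCurve(x, 5.0 + 2.0 * x))
        assert fit.single_segment_preferred
        assert fit.breakpoint is None

    def test_scale_equivariance(self):
        curve = gen_titration(1.56, 100, 2, 12.5, 50, 1.0, 40.0, 0.02, 7)
        fit1 = fit_cac_breakpoint(curve)
        scaled = SeriesCurve(curve.x * 3.0, curve.y)
        fit2 = fit_cac_breakpoint(scaled)
        assert fit2.breakpoint == pytest.approx(3.0 * fit1.breakpoint, rel=1e-9)

    def test_too_few_points_rejected(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        with pytest.raises(InsufficientDataError):
            fit_cac_breakpoint(SeriesCurve(x, x))
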