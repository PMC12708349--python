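"""Spectral data model, absorbance conversion and elementary arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mitopsi as m
from mitopsi import synthetic as syn
from mitopsi.errors import (
    GridAlignmentError,
    GridDomainError,
    MaskedWavelengthError,
    WindowSizeError,
)


def make_record(grid, incident, dark, transmissions, times=None):
    trans = np.atleast_2d(transmissions)
    if times is None:
        times = np.arange(trans.shape[0], dtype=float)
    return m.RawOpticalRecord(
        wavelengths_nm=grid, incident=incident, dark=dark,
        times_s=times, transmissions=trans,
    )


class TestComputeAbsorbance:
    def test_empty_path_gives_zero(self):
        grid = np.linspace(500, 600, 50)
        i0 = np.full(50, 1000.0)
        rec = make_record(grid, i0, np.zeros(50), i0)
        spec = m.compute_absorbance(rec, 0)
        assert spec.role == "absorbance"
        np.testing.assert_allclose(spec.values, 0.0, atol=1e-15)

    def test_one_decade_attenuation(self):
        grid = np.linspace(500, 600, 50)
        i0 = np.full(50, 5000.0)
        dark = np.full(50, 200.0)
        t = dark + (i0 - dark) / 10.0
        spec = m.compute_absorbance(make_record(grid, i0, dark, t), 0)
        np.testing.assert_allclose(spec.values, 1.0, rtol=1e-14)

    def test_forward_model_round_trip(self, library):
        """Counts built from a known absorbance invert back to it exactly."""
        grid = library.grid_nm
        a_true = 0.05 * library.spectra["b_L"] + 0.02 * library.spectra["c"] + 0.01
        i0 = syn.default_incident(grid)
        dark = np.full_like(grid, 400.0)
        t = dark + (i0 - dark) * 10.0 ** (-a_true)
        spec = m.compute_absorbance(make_record(grid, i0, dark, t), 0)
        np.testing.assert_allclose(spec.values, a_true, atol=1e-12)

    def test_nonpositive_corrected_counts_name_wavelengths(self):
        grid = np.linspace(500, 600, 10)
        i0 = np.full(10, 1000.0)
        dark = np.full(10, 100.0)
        t = i0.copy()
        t[3] = 50.0  # below dark: blocked channel
        with pytest.raises(MaskedWavelengthError) as err:
            m.compute_absorbance(make_record(grid, i0, dark, t), 0)
        assert err.value.wavelengths_nm is not None
        np.testing.assert_allclose(err.value.wavelengths_nm, [grid[3]])


class TestResample:
    def test_identity_grid_preserves_values(self):
        grid = np.linspace(500, 600, 40)
        s = m.Spectrum(grid, np.sin(grid / 10.0))
        out = m.resample_to_grid(s, grid)
        np.testing.assert_array_equal(out.values, s.values)

    def test_linear_spectrum_hits_exact_midpoints(self):
        grid = np.arange(500.0, 520.0, 2.0)
        s = m.Spectrum(grid, 0.3 * grid - 7.0)
        mid = (grid[:-1] + grid[1:]) / 2.0
        out = m.resample_to_grid(s, mid)
        np.testing.assert_allclose(out.values, 0.3 * mid - 7.0, rtol=1e-14)

    def test_gaussian_band_dense_grid_round_trip(self):
        """Refine 2x then coarsen: deviation stays below 1e-6 OD for a >=5 nm band."""
        grid = np.linspace(540, 580, 103)
        band = np.exp(-0.5 * ((grid - 562.0) / 5.0) ** 2)
        s = m.Spectrum(grid, band)
        fine = np.linspace(540, 580, 205)
        back = m.resample_to_grid(m.resample_to_grid(s, fine), grid)
        assert np.max(np.abs(back.values - band)) < 1e-6

    def test_extrapolation_refused(self):
        s = m.Spectrum(np.linspace(500, 600, 20), np.zeros(20))
        with pytest.raises(GridDomainError):
            m.resample_to_grid(s, np.linspace(490, 600, 20))


class TestRollingAverage:
    def test_constant_series_unchanged(self):
        out = m.rolling_average(np.full(10, 3.7), window=4)
        np.testing.assert_allclose(out, 3.7)

    def test_arithmetic_mean_and_alignment(self):
        out, t = m.rolling_average(
            np.array([1.0, 2, 3, 4, 5]), window=4, times=np.arange(5.0)
        )
        np.testing.assert_allclose(out, [2.5, 3.5])
        np.testing.assert_array_equal(t, [3.0, 4.0])  # trailing: last sample of window

    def test_window_too_large(self):
        with pytest.raises(WindowSizeError):
            m.rolling_average(np.arange(3.0), window=4)

    def test_white_noise_variance_reduction(self, rng):
        x = rng.normal(size=10_000)
        out = m.rolling_average(x, window=4)
        ratio = np.var(x) / np.var(out)
        assert 3.2 < ratio < 4.8  # ~window-fold reduction, +/-20%

    @settings(deadline=None, max_examples=25)
    @given(
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(-5, 5, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_linearity(self, a, b, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=20), r.normal(size=20)
        lhs = m.rolling_average(a * x + b * y, window=5)
        rhs = a * m.rolling_average(x, window=5) + b * m.rolling_average(y, window=5)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestDeriveReference:
    grid = np.linspace(540, 580, 60)

    def spectrum(self, values, role="reference"):
        return m.Spectrum(self.grid, values, role=role)

    def test_fraction_zero_returns_minuend(self):
        a = self.spectrum(np.sin(self.grid / 7))
        b = self.spectrum(np.cos(self.grid / 9))
        out = m.derive_reference(a, b, fraction=0.0)
        np.testing.assert_array_equal(out.values, a.values)

    def test_self_subtraction_is_zero(self):
        a = self.spectrum(np.sin(self.grid / 7))
        out = m.derive_reference(a, a, fraction=1.0)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_oxidized_fraction_removal_recovers_pure_component(self):
        """Composite 'reduced + 0.66 x oxidized' minus 0.66 x oxidized is pure."""
        pure = np.exp(-0.5 * ((self.grid - 552.0) / 4.5) ** 2)
        oxidized = 0.2 + 0.001 * (self.grid - 540.0)
        composite = self.spectrum(pure + 0.66 * oxidized)
        out = m.derive_reference(composite, self.spectrum(oxidized), fraction=0.66)
        np.testing.assert_allclose(out.values, pure, atol=1e-12)

    def test_re_adding_fraction_round_trips(self):
        a = self.spectrum(np.sin(self.grid / 7))
        b = self.spectrum(np.cos(self.grid / 9))
        diff = m.derive_reference(a, b, fraction=0.4)
        np.testing.assert_allclose(diff.values + 0.4 * b.values, a.values, atol=1e-15)

    def test_grid_mismatch_raises(self):
        a = self.spectrum(np.zeros(60))
        other = m.Spectrum(np.linspace(541, 579, 60), np.zeros(60))
        with pytest.raises(GridAlignmentError):
            m.derive_reference(a, other)


class TestHemeQuantification:
    def test_zero_delta_is_zero(self):
        assert m.quantify_heme_concentration(0.0) == 0.0

    def test_unit_arithmetic(self):
        # dA 0.012 at epsilon 12 mM^-1 cm^-1, 1 cm path -> 1 uM = 1 nmol/ml
        c = m.quantify_heme_concentration(0.012, m.HemeQuantConfig(12.0, 605.0, 1.0))
        assert c == pytest.approx(0.001)

    def test_pathlength_scaling(self):
        c1 = m.quantify_heme_concentration(0.024, m.HemeQuantConfig(pathlength_cm=1.0))
        c2 = m.quantify_heme_concentration(0.024, m.HemeQuantConfig(pathlength_cm=2.0))
        assert c1 == pytest.approx(2.0 * c2)

    def test_negative_delta_warns(self):
        with pytest.warns(UserWarning):
            c = m.quantify_heme_concentration(-0.012)
        assert c < 0


class TestReferenceLibrary:
    def test_unit_peak_invariant(self, library):
        lo, hi = library.band_nm
        mask = (library.grid_nm >= lo) & (library.grid_nm <= hi)
        for name in library.names:
            assert abs(np.max(library.spectra[name][mask]) - 1.0) < 1e-12

    def test_required_quartet_enforced(self):
        grid = np.linspace(540, 580, 50)
        with pytest.raises(ValueError, match="missing required"):
            m.ReferenceLibrary(
                grid_nm=grid,
                spectra={"b_H": np.ones(50)},
            )

    def test_csv_round_trip(self, library, tmp_path):
        path = tmp_path / "lib.csv"
        library.to_csv(path)
        back = m.ReferenceLibrary.from_csv(path)
        assert back.normalization == library.normalization
        assert back.band_nm == library.band_nm
        for name in library.names:
            np.testing.assert_allclose(back.spectra[name], library.spectra[name], atol=1e-12)

    def test_resampled_keeps_normalization(self, library):
        sub = library.resampled(np.linspace(500, 700, 512))
        lo, hi = sub.band_nm
        mask = (sub.grid_nm >= lo) & (sub.grid_nm <= hi)
        for name in sub.names:
            assert abs(np.max(sub.spectra[name][mask]) - 1.0) < 1e-12


def test_record_csv_round_trip(tmp_path, library):
    coeffs = {k: np.array([0.02, 0.03]) for k in ("b_H", "b_L", "c1", "c")}
    rec, _ = syn.simulate_spectrum_series(coeffs, library, seed=0)
    path = tmp_path / "rec.csv"
    m.write_record_csv(rec, path)
    back = m.read_record_csv(path)
    np.testing.assert_allclose(back.wavelengths_nm, rec.wavelengths_nm)
    np.testing.assert_allclose(back.transmissions, rec.transmissions, rtol=1e-10)
    np.testing.assert_allclose(back.times_s, rec.times_s)
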