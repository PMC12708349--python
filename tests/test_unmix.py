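"""Linear unmixing: oracle equivalence, fb_L, SNR flagging, series fitting."""

import numpy as np
import pandas as pd
import pytest

import mitopsi as m
from mitopsi import synthetic as syn
from mitopsi.errors import DomainError, RankDeficientError
from mitopsi.unmix import UnmixResult


def normal_equations_solve(design, y):
    """Independent closed-form least squares via the normal equations."""
    return np.linalg.solve(design.T @ design, design.T @ y)


def band_spectrum(library, coeffs, slope=0.0, intercept=0.0):
    """Noise-free absorbance on the full library grid from true coefficients."""
    grid = library.grid_nm
    a = slope * grid + intercept
    for name, c in coeffs.items():
        a = a + c * library.spectra[name]
    return m.Spectrum(grid, a)


@pytest.fixture(scope="module")
def unmixer(library):
    return m.SpectralUnmixer(library).fit()


class TestFitSpectrum:
    def test_single_reference_identity_recovery(self, library, unmixer):
        spec = m.Spectrum(library.grid_nm, library.spectra["c1"])
        res = m.fit_spectrum(spec, unmixer)
        assert res.coefficients["c1"] == pytest.approx(1.0, abs=1e-9)
        for other in ("b_H", "b_L", "c"):
            assert abs(res.coefficients[other]) < 1e-9
        assert abs(res.baseline_slope) < 1e-9
        assert res.ssr < 1e-18

    def test_forward_model_coefficients_recovered(self, library, unmixer):
        coeffs = {"b_H": 0.021, "b_L": 0.034, "c1": 0.012, "c": 0.046}
        spec = band_spectrum(library, coeffs, slope=-3e-5, intercept=0.06)
        res = m.fit_spectrum(spec, unmixer)
        for name, true in coeffs.items():
            assert res.coefficients[name] == pytest.approx(true, rel=1e-8)
        assert res.baseline_slope == pytest.approx(-3e-5, rel=1e-6)
        assert res.baseline_intercept == pytest.approx(0.06, rel=1e-6)

    def test_matches_normal_equations_closed_form(self, library, unmixer, rng):
        for _ in range(20):
            coeffs = {k: rng.uniform(0.005, 0.08) for k in ("b_H", "b_L", "c1", "c")}
            spec = band_spectrum(
                library, coeffs,
                slope=rng.uniform(-1e-4, 1e-4), intercept=rng.uniform(-0.1, 0.1),
            )
            res = m.fit_spectrum(spec, unmixer)
            beta_oracle = normal_equations_solve(unmixer.design_, res.data)
            beta = np.array(
                [res.coefficients[n] for n in unmixer.chromophore_names_]
                + [res.baseline_slope, res.baseline_intercept]
            )
            np.testing.assert_allclose(beta, beta_oracle, rtol=1e-8)

    def test_noise_error_scale_matches_linear_model_covariance(self, library, unmixer):
        """Coefficient errors under OD noise follow the analytic covariance."""
        sigma = 1e-4
        coeffs = {"b_H": 0.02, "b_L": 0.03, "c1": 0.015, "c": 0.04}
        spec = band_spectrum(library, coeffs, intercept=0.05)
        X = unmixer.design_
        cov = sigma**2 * np.linalg.inv(X.T @ X)
        sd_bL = np.sqrt(cov[unmixer.chromophore_names_.index("b_L"),
                             unmixer.chromophore_names_.index("b_L")])
        r = np.random.default_rng(7)
        errors = []
        for _ in range(200):
            noisy = m.Spectrum(spec.wavelengths_nm, spec.values + r.normal(0, sigma, len(spec)))
            res = m.fit_spectrum(noisy, unmixer)
            errors.append(res.coefficients["b_L"] - coeffs["b_L"])
        # empirical sd within 20% of the analytic prediction
        assert np.std(errors) == pytest.approx(sd_bL, rel=0.2)
        # and the error scale is ~sigma-proportional: tiny relative to coefficients
        assert np.median(np.abs(errors)) < 10 * sd_bL

    def test_duplicated_reference_raises_conditioning_error(self, library):
        spectra = dict(library.spectra)
        spectra["b_L"] = spectra["b_H"]  # exact duplicate
        dup = m.ReferenceLibrary(
            grid_nm=library.grid_nm, spectra=spectra, band_nm=library.band_nm,
            normalization=library.normalization,
        )
        with pytest.raises(RankDeficientError) as err:
            m.SpectralUnmixer(dup).fit()
        assert err.value.condition_number is None or err.value.condition_number > 1e10


class TestInvariances:
    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_pathlength_scaling_leaves_fbl_unchanged(self, library, unmixer, k):
        coeffs = {"b_H": 0.02, "b_L": 0.03, "c1": 0.015, "c": 0.04}
        spec = band_spectrum(library, coeffs, slope=-2e-5, intercept=0.05)
        res1 = m.fit_spectrum(spec, unmixer)
        res2 = m.fit_spectrum(
            m.Spectrum(spec.wavelengths_nm, k * spec.values), unmixer
        )
        for name in coeffs:
            assert res2.coefficients[name] == pytest.approx(
                k * res1.coefficients[name], rel=1e-8
            )
        f1, f2 = m.compute_fbl(res1), m.compute_fbl(res2)
        assert abs(f1.value - f2.value) < 1e-10

    def test_added_line_changes_only_baseline_terms(self, library, unmixer):
        coeffs = {"b_H": 0.02, "b_L": 0.03, "c1": 0.015, "c": 0.04}
        spec = band_spectrum(library, coeffs)
        res1 = m.fit_spectrum(spec, unmixer)
        shifted = m.Spectrum(
            spec.wavelengths_nm, spec.values + 4e-4 * spec.wavelengths_nm - 0.12
        )
        res2 = m.fit_spectrum(shifted, unmixer)
        for name in coeffs:
            assert res2.coefficients[name] == pytest.approx(
                res1.coefficients[name], rel=1e-8, abs=1e-12
            )
        assert res2.baseline_slope - res1.baseline_slope == pytest.approx(4e-4, rel=1e-6)

    def test_residuals_orthogonal_to_design(self, library, unmixer, rng):
        y = rng.normal(0.05, 0.01, size=unmixer.design_.shape[0])
        spec_grid = library.grid_nm[unmixer.band_mask_]
        res = m.fit_spectrum(m.Spectrum(spec_grid, y), unmixer)
        projections = unmixer.design_.T @ res.residuals
        np.testing.assert_allclose(projections, 0.0, atol=1e-10)

    def test_fitted_plus_residuals_reconstruct_data(self, library, unmixer):
        coeffs = {"b_H": 0.02, "b_L": 0.03, "c1": 0.015, "c": 0.04}
        spec = band_spectrum(library, coeffs, intercept=0.02)
        res = m.fit_spectrum(spec, unmixer)
        np.testing.assert_allclose(res.fitted + res.residuals, res.data, atol=1e-15)
        comp_sum = sum(res.component_spectra.values())
        line = res.baseline_slope * res.wavelengths_nm + res.baseline_intercept
        np.testing.assert_allclose(res.fitted, comp_sum + line, atol=1e-12)


class TestFbl:
    def test_equal_amplitudes_give_half(self, library, unmixer):
        spec = band_spectrum(library, {"b_H": 0.03, "b_L": 0.03, "c1": 0.0, "c": 0.0})
        assert m.compute_fbl(m.fit_spectrum(spec, unmixer)).value == pytest.approx(0.5, abs=1e-10)

    def test_fraction_arithmetic(self):
        res = _make_result(b_L=0.2, b_H=0.8)
        assert m.compute_fbl(res).value == pytest.approx(0.20)

    def test_forward_simulated_fraction_recovered(self, library, unmixer):
        fbl_true, b_total = 0.62, 0.05
        spec = band_spectrum(
            library,
            {"b_H": (1 - fbl_true) * b_total, "b_L": fbl_true * b_total,
             "c1": 0.02, "c": 0.03},
            intercept=0.04,
        )
        out = m.compute_fbl(m.fit_spectrum(spec, unmixer))
        assert out.value == pytest.approx(fbl_true, abs=1e-8)

    def test_zero_total_is_undefined(self):
        with pytest.raises(DomainError):
            m.compute_fbl(_make_result(b_L=0.0, b_H=0.0))

    def test_negative_amplitude_flagged_not_fatal(self):
        out = m.compute_fbl(_make_result(b_L=-0.01, b_H=0.05))
        assert out.negative_amplitude
        assert out.value == pytest.approx(-0.01 / 0.04)


def _make_result(b_L, b_H):
    grid = np.linspace(540, 580, 5)
    zeros = np.zeros(5)
    return UnmixResult(
        wavelengths_nm=grid, data=zeros,
        coefficients={"b_H": b_H, "b_L": b_L, "c1": 0.0, "c": 0.0},
        baseline_slope=0.0, baseline_intercept=0.0,
        component_spectra={}, fitted=zeros, residuals=zeros, ssr=0.0,
    )


class TestSnr:
    def test_zero_residuals_infinite_snr_not_excluded(self, library, unmixer):
        grid = library.grid_nm[unmixer.band_mask_]
        comp = {n: np.full(grid.size, 0.01) for n in ("b_H", "b_L", "c1", "c")}
        res = UnmixResult(
            wavelengths_nm=grid, data=np.zeros(grid.size),
            coefficients={n: 0.01 for n in comp},
            baseline_slope=0.0, baseline_intercept=0.0,
            component_spectra=comp, fitted=np.zeros(grid.size),
            residuals=np.zeros(grid.size), ssr=0.0,
        )
        flagged = m.compute_snr_and_flag(res, unmixer)
        assert np.isinf(flagged.snr)
        assert not flagged.excluded

    def test_near_exact_fit_has_enormous_snr(self, library, unmixer):
        spec = band_spectrum(library, {"b_H": 0.02, "b_L": 0.03, "c1": 0.01, "c": 0.02})
        res = m.fit_spectrum(spec, unmixer)
        assert res.snr > 1e12
        assert not res.excluded

    def test_threshold_arithmetic(self, library, unmixer):
        # quartet amplitudes summing to 1.0 OD over ssr 0.02 -> snr 50 < 100
        grid = library.grid_nm[unmixer.band_mask_]
        res = UnmixResult(
            wavelengths_nm=grid, data=np.zeros(grid.size),
            coefficients={"b_H": 0.25, "b_L": 0.25, "c1": 0.25, "c": 0.25},
            baseline_slope=0.0, baseline_intercept=0.0,
            component_spectra={}, fitted=np.zeros(grid.size),
            residuals=np.zeros(grid.size), ssr=0.02,
        )
        flagged = m.compute_snr_and_flag(res, unmixer)
        assert flagged.snr == pytest.approx(50.0)
        assert flagged.excluded  # 50 < 100

    def test_noise_ladder_monotone_and_matches_direct_formula(self, library, unmixer):
        coeffs = {"b_H": 0.02, "b_L": 0.03, "c1": 0.015, "c": 0.04}
        spec = band_spectrum(library, coeffs, intercept=0.05)
        r = np.random.default_rng(11)
        noise = r.normal(0, 1, len(spec))
        snrs = []
        for sigma in (1e-5, 1e-4, 1e-3, 1e-2):
            noisy = m.Spectrum(spec.wavelengths_nm, spec.values + sigma * noise)
            res = m.fit_spectrum(noisy, unmixer)
            direct = sum(
                res.coefficients[n] * unmixer.peak_od_[n]
                for n in ("b_H", "b_L", "c1", "c")
            ) / res.ssr
            assert res.snr == pytest.approx(direct, rel=1e-12)
            assert res.excluded == (direct < unmixer.snr_threshold)
            snrs.append(res.snr)
        assert all(a > b for a, b in zip(snrs, snrs[1:]))


class TestFitSeries:
    def test_constant_input_gives_constant_coefficients(self, library):
        coeffs = {k: np.full(12, v) for k, v in
                  [("b_H", 0.02), ("b_L", 0.03), ("c1", 0.015), ("c", 0.04)]}
        rec, _ = syn.simulate_spectrum_series(coeffs, library, baseline_intercept=0.05)
        table = m.fit_series(rec, m.SpectralUnmixer(library), window=4)
        assert len(table) == 9  # N - window + 1
        for name, v in [("b_H", 0.02), ("b_L", 0.03)]:
            np.testing.assert_allclose(table[name], v, rtol=1e-8)

    def test_step_change_settles_within_window(self, library):
        n, t0, window = 30, 15, 4
        fbl = np.where(np.arange(n) < t0, 0.3, 0.6)
        coeffs = {
            "b_H": (1 - fbl) * 0.05, "b_L": fbl * 0.05,
            "c1": np.full(n, 0.02), "c": np.full(n, 0.03),
        }
        rec, _ = syn.simulate_spectrum_series(coeffs, library)
        table = m.fit_series(rec, m.SpectralUnmixer(library), window=window)
        t = table["time_s"].to_numpy()
        settled = table.loc[t >= t0 + window - 1, "fbl"]
        np.testing.assert_allclose(settled, 0.6, atol=1e-8)
        before = table.loc[t < t0, "fbl"]
        np.testing.assert_allclose(before, 0.3, atol=1e-8)

    def test_injected_noisy_spectra_flagged_by_direct_construction(self, library):
        n, window = 100, 4
        coeffs = {k: np.full(n, v) for k, v in
                  [("b_H", 0.02), ("b_L", 0.03), ("c1", 0.015), ("c", 0.04)]}
        rec, _ = syn.simulate_spectrum_series(
            coeffs, library, baseline_intercept=0.05, noise_sigma_counts=1.0, seed=5
        )
        # corrupt 5 consecutive spectra with a sharp artifact no reference fits
        trans = rec.transmissions.copy()
        artifact = 0.15 * np.exp(-0.5 * ((rec.wavelengths_nm - 570.0) / 1.5) ** 2)
        trans[40:45] = rec.dark + (trans[40:45] - rec.dark) * 10.0 ** (-artifact)
        rec = m.RawOpticalRecord(
            rec.wavelengths_nm, rec.incident, rec.dark, rec.times_s, trans,
            rec.sample_period_s,
        )
        model = m.SpectralUnmixer(library)
        table = m.fit_series(rec, model, window=window)
        # direct evaluation of the exclusion rule on each averaged spectrum
        model.fit()
        from mitopsi.spectra import absorbance_matrix, rolling_average
        _, A = absorbance_matrix(rec, band_nm=model.band_nm_)
        A_avg = rolling_average(A, window)
        expected_flags = []
        for row in A_avg:
            res = model._package(rec.wavelengths_nm[model.band_mask_], row,
                                 model._solve(row))
            expected_flags.append(res.excluded)
        assert int(table["excluded"].sum()) == sum(expected_flags)
        assert table["excluded"].sum() > 0
        np.testing.assert_array_equal(table["excluded"].to_numpy(), expected_flags)


def test_myoglobin_model_widens_band_and_fits_mb(self=None):
    lib, _ = syn.make_reference_library(include_myoglobin=True)
    model = m.SpectralUnmixer(lib, include_myoglobin=True).fit()
    assert model.band_nm_ == (535.0, 585.0)
    coeffs = {"b_H": 0.02, "b_L": 0.03, "c1": 0.015, "c": 0.04, "MbO": 0.06, "MbD": 0.01}
    grid = lib.grid_nm
    a = 0.03 + sum(c * lib.spectra[n] for n, c in coeffs.items())
    res = model.unmix(m.Spectrum(grid, a))
    for name, true in coeffs.items():
        assert res.coefficients[name] == pytest.approx(true, rel=1e-7, abs=1e-10)
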