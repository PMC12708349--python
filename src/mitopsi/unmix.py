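"""Multi-wavelength least-squares decomposition of absorbance spectra.

An experimental absorbance spectrum over the alpha band is modelled as a
linear combination of reduced-chromophore reference spectra plus a line,

    A(lambda) = a*bH(lambda) + b*bL(lambda) + c*c1(lambda) + d*cytc(lambda)
                + e*lambda + f,

optionally extended with oxygenated/deoxygenated myoglobin terms for
myoglobin-containing tissue (fit band then widens from 540-580 nm to
535-585 nm).  The line absorbs residual scattering and the weak, featureless
absorbance of the oxidized cytochromes.

Because the model is linear in its coefficients, the least-squares solution
is computed directly (lstsq/QR); an iterative NLS routine would have to
converge to the same point, so the closed form doubles as its own oracle.

The module also implements the two derived statistics:

* ``fb_L = b_L/(b_L + b_H)`` — the membrane-potential-sensitive fraction of
  reduced b-heme absorbance.  Amplitudes are coefficient x reference peak
  OD, which equals the raw coefficient under the library's unit-peak
  normalization.  fb_L is a ratio of amplitudes from the same spectrum, so
  uniform optical-path-length changes cancel.
* the fit-quality statistic ``snr`` — the summed calculated absorbances of
  the four quartet chromophores divided by the sum of squared residuals;
  points with snr below a threshold (default 100) are flagged for exclusion.
  Two numerator conventions are supported, because "summed calculated
  absorbance" is ambiguous between the four scalar amplitudes and the
  band-integrated component spectra: ``"amplitude"`` (default; sum of the
  four peak-OD amplitudes) and ``"band_sum"`` (sum of the reconstructed
  component spectra over every band wavelength, whose scale grows with grid
  density).  The exclusion threshold of 100 is calibrated to the default
  convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .errors import ConfigurationError, DomainError, GridAlignmentError, RankDeficientError
from .spectra import (
    MYOGLOBIN_CHROMOPHORES,
    REQUIRED_CHROMOPHORES,
    RawOpticalRecord,
    ReferenceLibrary,
    Spectrum,
    absorbance_matrix,
    rolling_average,
)

__all__ = [
    "SpectralUnmixer",
    "UnmixResult",
    "FblValue",
    "fit_spectrum",
    "compute_fbl",
    "compute_snr_and_flag",
    "fit_series",
]

#: Maximum design condition number before the fit refuses to proceed.
MAX_CONDITION = 1e10

#: Quartet whose reconstructed absorbances enter the snr numerator.
SNR_CHROMOPHORES = REQUIRED_CHROMOPHORES


@dataclass(frozen=True)
class UnmixResult:
    """Outcome of unmixing one absorbance spectrum."""

    wavelengths_nm: np.ndarray
    data: np.ndarray
    coefficients: Mapping[str, float]       # chromophore coefficients
    baseline_slope: float                    # e, OD per nm
    baseline_intercept: float                # f, OD
    component_spectra: Mapping[str, np.ndarray]
    fitted: np.ndarray
    residuals: np.ndarray
    ssr: float
    snr: float = np.nan
    excluded: bool = False

    def amplitude(self, name: str) -> float:
        """Peak-OD amplitude of a chromophore (= coefficient under unit-peak norm)."""
        return float(self.coefficients[name])


@dataclass(frozen=True)
class FblValue:
    """fb_L = b_L/(b_L + b_H) with its constituent amplitudes."""

    value: float
    b_L_amp: float
    b_H_amp: float
    negative_amplitude: bool = False


class SpectralUnmixer:
    """Linear spectral unmixer with scikit-learn estimator conventions.

    Parameters
    ----------
    library : ReferenceLibrary
        Reference spectra; must contain the quartet {b_H, b_L, c1, c}.
    chromophores : sequence of str, optional
        Which members to fit.  Defaults to the quartet, plus MbO/MbD when
        ``include_myoglobin`` is set.
    band_nm : (float, float), optional
        Fit interval.  Defaults to (540, 580), or (535, 585) when myoglobin
        terms are included.
    include_baseline : bool
        Fit the linear e*lambda + f term (default True).
    nonneg : bool
        Constrain chromophore coefficients to be >= 0 (baseline stays free).
    snr_threshold : float
        Exclusion threshold for the fit-quality statistic (default 100).

    After :meth:`fit`, the design matrix and its conditioning are available
    as ``design_``, ``column_names_`` and ``condition_number_``.
    """

    def __init__(
        self,
        library: ReferenceLibrary,
        chromophores: Sequence[str] | None = None,
        band_nm: tuple[float, float] | None = None,
        include_baseline: bool = True,
        include_myoglobin: bool = False,
        nonneg: bool = False,
        snr_threshold: float = 100.0,
        snr_numerator: str = "amplitude",
    ):
        self.library = library
        self.chromophores = chromophores
        self.band_nm = band_nm
        self.include_baseline = include_baseline
        self.include_myoglobin = include_myoglobin
        self.nonneg = nonneg
        self.snr_threshold = snr_threshold
        self.snr_numerator = snr_numerator

    # -- sklearn plumbing --------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "library": self.library,
            "chromophores": self.chromophores,
            "band_nm": self.band_nm,
            "include_baseline": self.include_baseline,
            "include_myoglobin": self.include_myoglobin,
            "nonneg": self.nonneg,
            "snr_threshold": self.snr_threshold,
            "snr_numerator": self.snr_numerator,
        }

    def set_params(self, **params) -> "SpectralUnmixer":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting -----------------------------------------------------------
    def _resolve_chromophores(self) -> tuple[str, ...]:
        if self.chromophores is not None:
            names = tuple(self.chromophores)
        elif self.include_myoglobin:
            names = REQUIRED_CHROMOPHORES + MYOGLOBIN_CHROMOPHORES
        else:
            names = REQUIRED_CHROMOPHORES
        if len(names) < 2:
            raise ConfigurationError("at least two chromophores are required")
        missing = [n for n in names if n not in self.library]
        if missing:
            raise ConfigurationError(f"library lacks requested chromophores: {missing}")
        return names

    def _resolve_band(self, names) -> tuple[float, float]:
        if self.band_nm is not None:
            return tuple(self.band_nm)
        if any(n in MYOGLOBIN_CHROMOPHORES for n in names):
            return (535.0, 585.0)
        return (540.0, 580.0)

    def fit(self, X=None, y=None) -> "SpectralUnmixer":
        """Build and validate the design matrix.  X and y are unused."""
        if not self.snr_threshold > 0:
            raise ConfigurationError("snr_threshold must be positive")
        if self.snr_numerator not in ("amplitude", "band_sum"):
            raise ConfigurationError(
                "snr_numerator must be 'amplitude' or 'band_sum'"
            )
        names = self._resolve_chromophores()
        band = self._resolve_band(names)
        grid = self.library.grid_nm
        mask = (grid >= band[0]) & (grid <= band[1])
        if mask.sum() < len(names) + (2 if self.include_baseline else 0):
            raise ConfigurationError("fit band has fewer grid points than parameters")
        cols = [self.library.spectra[n][mask] for n in names]
        col_names = list(names)
        if self.include_baseline:
            cols.append(grid[mask])
            cols.append(np.ones(mask.sum()))
            col_names += ["slope", "intercept"]
        design = np.column_stack(cols)
        cond = float(np.linalg.cond(design))
        if not np.isfinite(cond) or cond > MAX_CONDITION:
            raise RankDeficientError(
                f"design matrix is rank deficient or ill conditioned "
                f"(condition number {cond:.3g}); check for duplicated references",
                condition_number=cond,
            )
        self.chromophore_names_ = names
        self.band_nm_ = band
        self.band_mask_ = mask
        self.column_names_ = col_names
        self.design_ = design
        self.condition_number_ = cond
        # peak OD in the band: amplitude = coefficient x peak (1 under unit-peak)
        self.peak_od_ = {
            n: float(np.max(self.library.spectra[n][mask])) for n in names
        }
        return self

    def _check_fitted(self):
        if not hasattr(self, "design_"):
            self.fit()

    def _solve(self, A_band: np.ndarray) -> np.ndarray:
        """Least-squares coefficients for one or many spectra (rows of A_band)."""
        if self.nonneg:
            n_chromo = len(self.chromophore_names_)
            lb = np.full(self.design_.shape[1], -np.inf)
            lb[:n_chromo] = 0.0
            if A_band.ndim == 1:
                return lsq_linear(self.design_, A_band, bounds=(lb, np.inf)).x
            return np.array(
                [lsq_linear(self.design_, row, bounds=(lb, np.inf)).x for row in A_band]
            )
        beta, *_ = np.linalg.lstsq(self.design_, A_band.T, rcond=None)
        return beta.T if A_band.ndim > 1 else beta

    def transform(self, absorbance: np.ndarray) -> np.ndarray:
        """Coefficient matrix for absorbance rows given on the library grid."""
        self._check_fitted()
        A = np.atleast_2d(np.asarray(absorbance, dtype=float))[:, self.band_mask_]
        return self._solve(A)

    def unmix(self, spectrum: Spectrum) -> UnmixResult:
        """Full decomposition of one absorbance spectrum."""
        self._check_fitted()
        grid = self.library.grid_nm
        if spectrum.wavelengths_nm.shape == grid.shape and np.allclose(
            spectrum.wavelengths_nm, grid, rtol=0, atol=1e-9
        ):
            A_band = spectrum.values[self.band_mask_]
            band_grid = grid[self.band_mask_]
        else:
            # spectrum may already be band-sliced onto the band grid
            band_grid = grid[self.band_mask_]
            if spectrum.wavelengths_nm.shape == band_grid.shape and np.allclose(
                spectrum.wavelengths_nm, band_grid, rtol=0, atol=1e-9
            ):
                A_band = spectrum.values
            else:
                raise GridAlignmentError(
                    "spectrum grid matches neither the library grid nor its fit "
                    "band; resample the spectrum onto the library grid"
                )
        beta = self._solve(A_band)
        return self._package(band_grid, A_band, beta)

    def _package(self, band_grid, A_band, beta) -> UnmixResult:
        names = self.chromophore_names_
        coeffs = {n: float(b) for n, b in zip(names, beta)}
        if self.include_baseline:
            slope, intercept = float(beta[-2]), float(beta[-1])
        else:
            slope = intercept = 0.0
        components = {
            n: coeffs[n] * self.library.spectra[n][self.band_mask_] for n in names
        }
        fitted = self.design_ @ beta
        residuals = A_band - fitted
        ssr = float(residuals @ residuals)
        result = UnmixResult(
            wavelengths_nm=band_grid,
            data=A_band,
            coefficients=coeffs,
            baseline_slope=slope,
            baseline_intercept=intercept,
            component_spectra=components,
            fitted=fitted,
            residuals=residuals,
            ssr=ssr,
        )
        return compute_snr_and_flag(result, self)

    # -- series ------------------------------------------------------------
    def unmix_series(self, record: RawOpticalRecord, window: int = 1) -> pd.DataFrame:
        """Absorbance -> trailing rolling average -> per-spectrum unmixing.

        Returns a tidy table with one row per averaged spectrum (N - window
        + 1 rows), in time order.  Failed rows are flagged via ``excluded``
        and NaN columns rather than aborting the series.
        """
        self._check_fitted()
        if record.wavelengths_nm.shape != self.library.grid_nm.shape or not np.allclose(
            record.wavelengths_nm, self.library.grid_nm, rtol=0, atol=1e-9
        ):
            raise GridAlignmentError(
                "record grid differs from library grid; resample the library "
                "onto the experimental grid"
            )
        band_grid, A = absorbance_matrix(record, band_nm=self.band_nm_)
        A_avg, t_avg = rolling_average(A, window, times=record.times_s)
        beta = self._solve(A_avg)
        fitted = beta @ self.design_.T
        residuals = A_avg - fitted
        ssr = np.einsum("ij,ij->i", residuals, residuals)
        numer = np.zeros(len(A_avg))
        for i, name in enumerate(self.chromophore_names_):
            if name in SNR_CHROMOPHORES:
                if self.snr_numerator == "amplitude":
                    numer += beta[:, i] * self.peak_od_[name]
                else:
                    numer += beta[:, i] * float(
                        np.sum(self.library.spectra[name][self.band_mask_])
                    )
        with np.errstate(divide="ignore"):
            snr = np.where(ssr > 0, numer / np.where(ssr > 0, ssr, 1.0), np.inf)
        excluded = snr < self.snr_threshold
        rows = {"time_s": t_avg}
        for i, name in enumerate(self.chromophore_names_):
            rows[name] = beta[:, i]
        if self.include_baseline:
            rows["slope"] = beta[:, -2]
            rows["intercept"] = beta[:, -1]
        b_L = beta[:, self.chromophore_names_.index("b_L")]
        b_H = beta[:, self.chromophore_names_.index("b_H")]
        total = b_L + b_H
        with np.errstate(divide="ignore", invalid="ignore"):
            fbl = np.where(total != 0, b_L / total, np.nan)
        rows["b_L_amp"] = b_L
        rows["b_H_amp"] = b_H
        rows["fbl"] = fbl
        rows["cytc_amp"] = beta[:, self.chromophore_names_.index("c")]
        for name in MYOGLOBIN_CHROMOPHORES:
            if name in self.chromophore_names_:
                rows[f"{name}_amp"] = beta[:, self.chromophore_names_.index(name)]
        rows["ssr"] = ssr
        rows["snr"] = snr
        rows["excluded"] = excluded
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_spectrum(absorbance: Spectrum, model: SpectralUnmixer) -> UnmixResult:
    """Decompose one absorbance spectrum with the given unmixer."""
    return model.unmix(absorbance)


def compute_fbl(result: UnmixResult) -> FblValue:
    """fb_L from an unmixing result.

    Negative amplitudes are arithmetically valid but flagged; both
    amplitudes zero is undefined.
    """
    b_L = result.amplitude("b_L")
    b_H = result.amplitude("b_H")
    total = b_L + b_H
    if total == 0:
        raise DomainError("fb_L undefined: b_L + b_H amplitudes sum to zero")
    return FblValue(
        value=b_L / total,
        b_L_amp=b_L,
        b_H_amp=b_H,
        negative_amplitude=(b_L < 0) or (b_H < 0),
    )


def compute_snr_and_flag(result: UnmixResult, model: SpectralUnmixer) -> UnmixResult:
    """Attach the fit-quality statistic and the exclusion flag.

    snr = [summed calculated quartet absorbances] / SSR, with the numerator
    convention taken from the model (``"amplitude"``: sum of the four
    peak-OD amplitudes; ``"band_sum"``: band-integrated component spectra).
    Zero SSR (an exact fit) reports +inf and is never excluded.
    """
    model._check_fitted()
    numer = 0.0
    if getattr(model, "snr_numerator", "amplitude") == "amplitude":
        for name in result.coefficients:
            if name in SNR_CHROMOPHORES:
                numer += result.coefficients[name] * model.peak_od_.get(name, 1.0)
    else:
        for name, comp in result.component_spectra.items():
            if name in SNR_CHROMOPHORES:
                numer += float(np.sum(comp))
    if result.ssr == 0:
        snr = np.inf
    else:
        snr = numer / result.ssr
    return replace(result, snr=snr, excluded=bool(snr < model.snr_threshold))


def fit_series(
    record: RawOpticalRecord, model: SpectralUnmixer, window: int = 1
) -> pd.DataFrame:
    """Rolling-averaged per-timepoint unmixing of a raw record."""
    return model.unmix_series(record, window=window)
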