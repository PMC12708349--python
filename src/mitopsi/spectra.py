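"""Spectral data model, I/O and elementary spectral arithmetic.

The instruments record transmitted-light intensity ``T(lambda, t)`` at one
spectrum per second, together with a daily incident-light spectrum ``I0`` and
the spectrometer dark current ``D``.  Absorbance is the base-10 log of the
dark-corrected intensity ratio,

    A(lambda) = log10( (I0 - D) / (T - D) ),

which is zero for an empty light path.  Everything downstream (unmixing,
fb_L, calibration) operates on these absorbance spectra.

This module also carries the reference-library container used by the
unmixer.  Reference spectra for the reduced chromophores have arbitrary
absolute optical density (they come from biochemical derivations, not from
known concentrations), so a normalization convention is fixed here: unit
peak OD within the active fit band.  The convention is stamped on the
library so that a calibration curve built with one library can refuse to be
applied with a differently normalized one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    GridAlignmentError,
    GridDomainError,
    MaskedWavelengthError,
    WindowSizeError,
)

__all__ = [
    "Spectrum",
    "RawOpticalRecord",
    "ReferenceLibrary",
    "HemeQuantConfig",
    "compute_absorbance",
    "resample_to_grid",
    "rolling_average",
    "derive_reference",
    "quantify_heme_concentration",
    "read_record_csv",
    "write_record_csv",
]

#: Chromophores that must be present in every reference library.
REQUIRED_CHROMOPHORES = ("b_H", "b_L", "c1", "c")

#: Optional myoglobin members used for wild-type (Mb-containing) tissue.
MYOGLOBIN_CHROMOPHORES = ("MbO", "MbD")


def _as_grid(wavelengths_nm) -> np.ndarray:
    grid = np.asarray(wavelengths_nm, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("wavelength grid must be a 1-D array with >= 2 points")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    if not np.all(np.isfinite(grid)):
        raise ValueError("wavelength grid must be finite")
    return grid


@dataclass(frozen=True)
class Spectrum:
    """A single wavelength-indexed optical trace.

    Parameters
    ----------
    wavelengths_nm : array
        Strictly increasing wavelength grid in nm.
    values : array
        Intensity counts, absorbance (OD), or reference OD, depending on role.
    role : {"intensity", "absorbance", "reference"}
        What the values mean.  Immutable after construction.
    name : str
        Free-form label.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    role: str = "absorbance"
    name: str = ""

    _ROLES = ("intensity", "absorbance", "reference")

    def __post_init__(self):
        grid = _as_grid(self.wavelengths_nm)
        values = np.asarray(self.values, dtype=float)
        if values.shape != grid.shape:
            raise ValueError(
                f"values shape {values.shape} does not match grid {grid.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("spectrum values must be finite")
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}, got {self.role!r}")
        object.__setattr__(self, "wavelengths_nm", grid)
        object.__setattr__(self, "values", values)

    def band(self, lo_nm: float, hi_nm: float) -> "Spectrum":
        """Slice to wavelengths in ``[lo_nm, hi_nm]`` (inclusive)."""
        mask = (self.wavelengths_nm >= lo_nm) & (self.wavelengths_nm <= hi_nm)
        if mask.sum() < 2:
            raise GridDomainError(
                f"band [{lo_nm}, {hi_nm}] nm contains fewer than 2 grid points"
            )
        return replace(
            self, wavelengths_nm=self.wavelengths_nm[mask], values=self.values[mask]
        )

    def __len__(self) -> int:
        return self.wavelengths_nm.size


@dataclass(frozen=True)
class RawOpticalRecord:
    """Raw spectrometer record: incident light, dark current and transmissions.

    ``transmissions`` has shape (n_times, n_wavelengths); ``times_s`` is the
    acquisition timestamp of each transmission spectrum.
    """

    wavelengths_nm: np.ndarray
    incident: np.ndarray
    dark: np.ndarray
    times_s: np.ndarray
    transmissions: np.ndarray
    sample_period_s: float = 1.0

    def __post_init__(self):
        grid = _as_grid(self.wavelengths_nm)
        incident = np.asarray(self.incident, dtype=float)
        dark = np.asarray(self.dark, dtype=float)
        times = np.asarray(self.times_s, dtype=float)
        trans = np.asarray(self.transmissions, dtype=float)
        if incident.shape != grid.shape or dark.shape != grid.shape:
            raise ValueError("incident and dark must match the wavelength grid")
        if trans.ndim != 2 or trans.shape[1] != grid.size:
            raise ValueError(
                "transmissions must be (n_times, n_wavelengths) on the shared grid"
            )
        if times.shape != (trans.shape[0],):
            raise ValueError("times_s must have one entry per transmission spectrum")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.sample_period_s > 0:
            raise ValueError("sample_period_s must be positive")
        object.__setattr__(self, "wavelengths_nm", grid)
        object.__setattr__(self, "incident", incident)
        object.__setattr__(self, "dark", dark)
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "transmissions", trans)

    @property
    def n_times(self) -> int:
        return self.times_s.size


@dataclass(frozen=True)
class HemeQuantConfig:
    """Beer-Lambert settings for cytochrome a+a3 quantification.

    The reduced-minus-oxidized difference extinction coefficient at 605 nm
    defaults to 12 mM^-1 cm^-1.
    """

    epsilon_mM_cm: float = 12.0
    wavelength_nm: float = 605.0
    pathlength_cm: float = 1.0

    def __post_init__(self):
        if not (self.epsilon_mM_cm > 0 and self.wavelength_nm > 0 and self.pathlength_cm > 0):
            raise ValueError("all HemeQuantConfig fields must be positive")


UNIT_PEAK = "unit-peak"


@dataclass(frozen=True)
class ReferenceLibrary:
    """Named reduced-chromophore reference spectra on a common grid.

    The required quartet is {b_H, b_L, c1, c}; MbO/MbD are optional and only
    fit for myoglobin-containing (wild-type) tissue.  ``normalization`` is a
    convention stamp; with the default unit-peak convention every member has
    max OD exactly 1 within ``band_nm``.
    """

    grid_nm: np.ndarray
    spectra: Mapping[str, np.ndarray]
    band_nm: tuple[float, float] = (540.0, 580.0)
    normalization: str = UNIT_PEAK
    peak_nm: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        grid = _as_grid(self.grid_nm)
        spectra = {}
        for name, values in self.spectra.items():
            arr = np.asarray(values, dtype=float)
            if arr.shape != grid.shape:
                raise GridAlignmentError(
                    f"reference {name!r} is not on the library grid; resample first"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"reference {name!r} has non-finite values")
            spectra[name] = arr
        missing = [n for n in REQUIRED_CHROMOPHORES if n not in spectra]
        if missing:
            raise ValueError(f"reference library is missing required members: {missing}")
        lo, hi = self.band_nm
        mask = (grid >= lo) & (grid <= hi)
        if mask.sum() < 2:
            raise ValueError("fit band contains fewer than 2 grid points")
        if self.normalization == UNIT_PEAK:
            for name, arr in spectra.items():
                peak = float(np.max(arr[mask]))
                if abs(peak - 1.0) > 1e-12:
                    raise ValueError(
                        f"reference {name!r} violates unit-peak normalization in "
                        f"band {self.band_nm}: peak = {peak!r}"
                    )
        object.__setattr__(self, "grid_nm", grid)
        object.__setattr__(self, "spectra", spectra)
        object.__setattr__(self, "peak_nm", dict(self.peak_nm))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.spectra)

    def __contains__(self, name: str) -> bool:
        return name in self.spectra

    def __getitem__(self, name: str) -> Spectrum:
        return Spectrum(self.grid_nm, self.spectra[name], role="reference", name=name)

    @classmethod
    def from_spectra(
        cls,
        spectra: Mapping[str, np.ndarray],
        grid_nm,
        band_nm=(540.0, 580.0),
        peak_nm=None,
        normalize: bool = True,
    ) -> "ReferenceLibrary":
        """Build a library, normalizing each member to unit band peak."""
        grid = _as_grid(grid_nm)
        lo, hi = band_nm
        mask = (grid >= lo) & (grid <= hi)
        out = {}
        for name, values in spectra.items():
            arr = np.asarray(values, dtype=float)
            if normalize:
                peak = float(np.max(arr[mask]))
                if peak <= 0:
                    raise ValueError(
                        f"reference {name!r} has non-positive peak in the fit band"
                    )
                arr = arr / peak
            out[name] = arr
        return cls(
            grid_nm=grid,
            spectra=out,
            band_nm=tuple(band_nm),
            normalization=UNIT_PEAK if normalize else "raw",
            peak_nm=peak_nm or {},
        )

    def resampled(self, grid_nm) -> "ReferenceLibrary":
        """Linear-interpolate every member onto a new grid and renormalize."""
        grid = _as_grid(grid_nm)
        _check_domain(self.grid_nm, grid)
        spectra = {
            name: np.interp(grid, self.grid_nm, vals) for name, vals in self.spectra.items()
        }
        return ReferenceLibrary.from_spectra(
            spectra,
            grid,
            band_nm=self.band_nm,
            peak_nm=self.peak_nm,
            normalize=self.normalization == UNIT_PEAK,
        )

    def subset(self, names: Sequence[str]) -> "ReferenceLibrary":
        missing = [n for n in names if n not in self.spectra]
        if missing:
            raise KeyError(f"library has no members {missing}")
        return ReferenceLibrary(
            grid_nm=self.grid_nm,
            spectra={n: self.spectra[n] for n in names},
            band_nm=self.band_nm,
            normalization=self.normalization,
            peak_nm={n: w for n, w in self.peak_nm.items() if n in names},
        )

    # ---- persistence -----------------------------------------------------
    def to_csv(self, path, metadata_path=None) -> None:
        """Write members as CSV plus a JSON sidecar with the convention stamp."""
        path = Path(path)
        df = pd.DataFrame({"wavelength_nm": self.grid_nm, **self.spectra})
        df.to_csv(path, index=False)
        meta = {
            "normalization": self.normalization,
            "band_nm": list(self.band_nm),
            "peak_nm": dict(self.peak_nm),
        }
        meta_path = Path(metadata_path) if metadata_path else path.with_suffix(".meta.json")
        meta_path.write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path, metadata_path=None) -> "ReferenceLibrary":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = Path(metadata_path) if metadata_path else path.with_suffix(".meta.json")
        meta = json.loads(meta_path.read_text())
        grid = df["wavelength_nm"].to_numpy(float)
        spectra = {c: df[c].to_numpy(float) for c in df.columns if c != "wavelength_nm"}
        return cls(
            grid_nm=grid,
            spectra=spectra,
            band_nm=tuple(meta["band_nm"]),
            normalization=meta["normalization"],
            peak_nm=meta.get("peak_nm", {}),
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_absorbance(record: RawOpticalRecord, index: int, band_nm=None) -> Spectrum:
    """Absorbance A = log10((I0 - D)/(T - D)) for the transmission at ``index``.

    Both the incident and transmitted intensities are dark-corrected before
    the ratio, so an empty path (T = I0) gives A = 0 at every wavelength.
    Non-positive dark-corrected intensity raises
    :class:`~mitopsi.errors.MaskedWavelengthError` naming the offending
    wavelengths rather than silently clipping.
    """
    grid = record.wavelengths_nm
    if band_nm is not None:
        mask = (grid >= band_nm[0]) & (grid <= band_nm[1])
    else:
        mask = np.ones_like(grid, dtype=bool)
    i0 = record.incident[mask] - record.dark[mask]
    t = record.transmissions[index][mask] - record.dark[mask]
    bad = (i0 <= 0) | (t <= 0)
    if np.any(bad):
        offenders = grid[mask][bad]
        raise MaskedWavelengthError(
            f"non-positive dark-corrected intensity at {bad.sum()} wavelengths "
            f"(first offenders: {np.round(offenders[:5], 2).tolist()} nm)",
            wavelengths_nm=offenders,
        )
    values = np.log10(i0 / t)
    return Spectrum(grid[mask], values, role="absorbance", name=f"t={record.times_s[index]:g}s")


def absorbance_matrix(record: RawOpticalRecord, band_nm=None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized absorbance for every timepoint.

    Returns ``(grid, A)`` with ``A`` of shape (n_times, n_wavelengths).
    Used by the series-fitting path where per-spectrum Spectrum objects
    would be needless overhead.
    """
    grid = record.wavelengths_nm
    if band_nm is not None:
        mask = (grid >= band_nm[0]) & (grid <= band_nm[1])
    else:
        mask = np.ones_like(grid, dtype=bool)
    i0 = record.incident[mask] - record.dark[mask]
    t = record.transmissions[:, mask] - record.dark[mask]
    bad = (i0 <= 0) | np.any(t <= 0, axis=0)
    if np.any(bad):
        offenders = grid[mask][bad]
        raise MaskedWavelengthError(
            f"non-positive dark-corrected intensity at {bad.sum()} wavelengths",
            wavelengths_nm=offenders,
        )
    return grid[mask], np.log10(i0 / t)


def _check_domain(src_grid: np.ndarray, target_grid: np.ndarray) -> None:
    if target_grid.min() < src_grid.min() - 1e-12 or target_grid.max() > src_grid.max() + 1e-12:
        raise GridDomainError(
            f"target grid [{target_grid.min():g}, {target_grid.max():g}] nm extends "
            f"outside source support [{src_grid.min():g}, {src_grid.max():g}] nm"
        )


def resample_to_grid(spectrum: Spectrum, grid_nm) -> Spectrum:
    """Linear interpolation onto ``grid_nm``; extrapolation is refused.

    Values at grid points shared with the source are unchanged.
    """
    grid = _as_grid(grid_nm)
    _check_domain(spectrum.wavelengths_nm, grid)
    values = np.interp(grid, spectrum.wavelengths_nm, spectrum.values)
    return Spectrum(grid, values, role=spectrum.role, name=spectrum.name)


def rolling_average(values, window: int, times=None):
    """Trailing (causal) rolling mean over the leading axis.

    Output row ``i`` is the mean of input rows ``i .. i+window-1`` and carries
    the timestamp of the *last* sample in its window; output length is
    ``N - window + 1``.

    Parameters
    ----------
    values : array, shape (N,) or (N, k)
    window : int
    times : array, optional
        If given, the matching timestamps are returned alongside.
    """
    arr = np.asarray(values, dtype=float)
    if window < 1:
        raise WindowSizeError("window must be >= 1")
    n = arr.shape[0]
    if window > n:
        raise WindowSizeError(f"window {window} exceeds series length {n}")
    # cumulative-sum trick keeps this O(N) for the 1 Hz, hour-long records
    csum = np.cumsum(arr, axis=0, dtype=float)
    head = csum[window - 1 :]
    tail = np.concatenate([np.zeros_like(csum[:1]), csum[: n - window]], axis=0)
    out = (head - tail) / window
    if times is None:
        return out
    t = np.asarray(times, dtype=float)[window - 1 :]
    return out, t


def derive_reference(minuend: Spectrum, subtrahend: Spectrum, fraction: float = 1.0) -> Spectrum:
    """Reference derivation arithmetic: ``minuend - fraction * subtrahend``.

    This is how the reduced-chromophore references are constructed from
    measured composites: e.g. the reduced cytochrome c1 reference is the
    ascorbate-reduced spectrum minus 66% of the fully oxidized one (removing
    the oxidized b-heme contribution), and the b_L reference is an
    anoxia-minus-uncoupled difference (fraction = 1).
    """
    if minuend.wavelengths_nm.shape != subtrahend.wavelengths_nm.shape or not np.allclose(
        minuend.wavelengths_nm, subtrahend.wavelengths_nm, rtol=0, atol=1e-9
    ):
        raise GridAlignmentError(
            "spectra are on different wavelength grids; use resample_to_grid first"
        )
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    return Spectrum(
        minuend.wavelengths_nm,
        minuend.values - fraction * subtrahend.values,
        role="reference",
        name=minuend.name or "derived",
    )


def quantify_heme_concentration(delta_A: float, config: HemeQuantConfig = HemeQuantConfig()) -> float:
    """Beer-Lambert concentration (mM) from a reduced-minus-oxidized delta-OD.

    c = dA / (epsilon * pathlength).  1 mM = 1 nmol/ul = 1000 nmol/ml.
    Negative delta-A yields a negative concentration with a warning; the
    caller decides whether that is noise or a sign error.
    """
    c = float(delta_A) / (config.epsilon_mM_cm * config.pathlength_cm)
    if delta_A < 0:
        warnings.warn(
            f"negative delta-absorbance ({delta_A:g}) gives negative concentration",
            UserWarning,
            stacklevel=2,
        )
    return c


# ---------------------------------------------------------------------------
# record file I/O
# ---------------------------------------------------------------------------

def write_record_csv(record: RawOpticalRecord, path) -> None:
    """Write a raw record in the instrument CSV layout.

    First column wavelength_nm, then I0 and dark, then one column per
    transmission spectrum with the acquisition time (seconds) as header.
    """
    cols = {"wavelength_nm": record.wavelengths_nm, "I0": record.incident, "dark": record.dark}
    for t, row in zip(record.times_s, record.transmissions):
        cols[f"{t:g}"] = row
    pd.DataFrame(cols).to_csv(path, index=False)


def read_record_csv(path, sample_period_s: float | None = None) -> RawOpticalRecord:
    """Read the instrument CSV layout written by :func:`write_record_csv`."""
    df = pd.read_csv(path)
    for required in ("wavelength_nm", "I0", "dark"):
        if required not in df.columns:
            raise ValueError(f"record CSV is missing the {required!r} column")
    time_cols = [c for c in df.columns if c not in ("wavelength_nm", "I0", "dark")]
    times = np.array([float(c) for c in time_cols])
    order = np.argsort(times)
    times = times[order]
    trans = df[time_cols].to_numpy(float).T[order]
    if sample_period_s is None:
        sample_period_s = float(np.median(np.diff(times))) if times.size > 1 else 1.0
    return RawOpticalRecord(
        wavelengths_nm=df["wavelength_nm"].to_numpy(float),
        incident=df["I0"].to_numpy(float),
        dark=df["dark"].to_numpy(float),
        times_s=times,
        transmissions=trans,
        sample_period_s=sample_period_s,
    )
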