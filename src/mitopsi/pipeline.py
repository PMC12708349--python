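"""End-to-end ischemia-reperfusion analysis.

Chains the optical inference: raw record -> absorbance -> trailing rolling
average (default 4 spectra at 1 Hz) -> multi-wavelength unmixing -> SNR
quality flagging -> fb_L -> calibrated (possibly censored) delta-psi, one
row per averaged spectrum.  On top of the time series it provides phase
checkpoint summaries, secondary-decline event detection during ischemia,
heart rate from the pulsatile coronary flow trace, and the small metabolite
arithmetic used alongside the optics (succinate against an internal
standard, CoQ percent reduction, monotone timecourse interpolation).

Censoring discipline: a summary window containing censored potential rows
reports a bound, never a numeric average that pretends the censored values
were observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import find_peaks

from .calibration import CalibrationCurve, invert_curve
from .errors import ConfigurationError, DomainError, WindowSizeError
from .spectra import RawOpticalRecord, ReferenceLibrary
from .unmix import SpectralUnmixer

__all__ = [
    "ExperimentTimeline",
    "run_pipeline",
    "phase_summary",
    "detect_secondary_decline",
    "heart_rate_from_flow",
    "succinate_content",
    "percent_reduction",
    "interpolate_timecourse",
]

PHASE_NAMES = ("control", "ischemia", "reperfusion")


@dataclass(frozen=True)
class ExperimentTimeline:
    """Ordered, contiguous experiment phases (control/ischemia/reperfusion)."""

    phases: tuple

    def __post_init__(self):
        phases = tuple((str(n), float(a), float(b)) for n, a, b in self.phases)
        if not phases:
            raise ValueError("timeline needs at least one phase")
        for name, start, end in phases:
            if name not in PHASE_NAMES:
                raise ValueError(f"phase name must be one of {PHASE_NAMES}, got {name!r}")
            if not start < end:
                raise ValueError(f"phase {name!r} has start >= end")
        for (_, _, e0), (_, s1, _) in zip(phases, phases[1:]):
            if abs(e0 - s1) > 1e-9:
                raise ValueError("phases must be contiguous and non-overlapping")
        object.__setattr__(self, "phases", phases)

    @classmethod
    def standard(cls, control_s: float, ischemia_s: float, reperfusion_s: float) -> "ExperimentTimeline":
        t0 = control_s
        t1 = t0 + ischemia_s
        t2 = t1 + reperfusion_s
        return cls((("control", 0.0, t0), ("ischemia", t0, t1), ("reperfusion", t1, t2)))

    def phase_of(self, time_s: np.ndarray) -> np.ndarray:
        t = np.asarray(time_s, dtype=float)
        out = np.full(t.shape, "", dtype=object)
        for name, start, end in self.phases:
            out[(t >= start) & (t < end)] = name
        # closed right edge of the final phase
        name, start, end = self.phases[-1]
        out[t == end] = name
        return out

    def bounds(self, name: str) -> tuple[float, float]:
        for n, a, b in self.phases:
            if n == name:
                return a, b
        raise KeyError(f"no phase named {name!r}")


def run_pipeline(
    record: RawOpticalRecord,
    library: ReferenceLibrary,
    curve: CalibrationCurve,
    timeline: ExperimentTimeline | None = None,
    window: int = 4,
    margin: float = 0.01,
    unmixer: SpectralUnmixer | None = None,
    **unmixer_kwargs,
) -> pd.DataFrame:
    """Raw record -> calibrated potential time series.

    One row per averaged spectrum (N - window + 1 rows).  Rows failing the
    SNR rule are excluded and carry no potential estimate; censored inverse
    predictions report the domain bound with the censoring direction.

    The calibration curve carries the normalization stamp of the reference
    library it was built with; applying it with a differently normalized
    library is a hard configuration error.
    """
    if record.n_times < window:
        raise WindowSizeError(
            f"record has {record.n_times} spectra, fewer than window {window}"
        )
    if (
        curve.library_normalization is not None
        and curve.library_normalization != library.normalization
    ):
        raise ConfigurationError(
            f"calibration curve was built with {curve.library_normalization!r}-"
            f"normalized references but the library is {library.normalization!r}"
        )
    if unmixer is None:
        unmixer = SpectralUnmixer(library, **unmixer_kwargs)
    unmixer.fit()
    table = unmixer.unmix_series(record, window=window)
    psi = np.full(len(table), np.nan)
    censored = np.full(len(table), "none", dtype=object)
    fbl = table["fbl"].to_numpy()
    excluded = table["excluded"].to_numpy()
    for i in range(len(table)):
        if excluded[i] or not np.isfinite(fbl[i]) or not (0.0 <= fbl[i] <= 1.0):
            continue
        est = invert_curve(curve, float(fbl[i]), margin=margin)
        psi[i] = est.delta_psi_mV
        censored[i] = est.censored
    table["delta_psi_mV"] = psi
    table["censored"] = censored
    if timeline is not None:
        table["phase"] = timeline.phase_of(table["time_s"].to_numpy())
    return table


def phase_summary(
    series: pd.DataFrame,
    checkpoints: Sequence[tuple[str, float]],
    window_s: float = 30.0,
) -> pd.DataFrame:
    """Checkpoint means over the potential time series.

    ``checkpoints`` is a sequence of (label, center_time_s); each is
    summarized over a window of ``window_s`` seconds centered on it.
    Windows containing censored potential rows report the censoring bound
    instead of a mean; all-excluded windows are flagged missing.
    """
    rows = []
    t = series["time_s"].to_numpy()
    for label, center in checkpoints:
        lo, hi = center - window_s / 2.0, center + window_s / 2.0
        sel = series[(t >= lo) & (t <= hi)]
        n_total = len(sel)
        if n_total == 0:
            raise DomainError(f"checkpoint {label!r} window [{lo:g}, {hi:g}] s is empty")
        used = sel[~sel["excluded"]]
        n_used, n_excluded = len(used), n_total - len(used)
        row = {
            "label": label,
            "t_start_s": lo,
            "t_end_s": hi,
            "n_used": n_used,
            "n_excluded": n_excluded,
            "missing": n_used == 0,
        }
        for col in ("fbl", "cytc_amp"):
            if n_used:
                row[f"{col}_mean"] = float(used[col].mean())
                row[f"{col}_sd"] = float(used[col].std(ddof=1)) if n_used > 1 else 0.0
            else:
                row[f"{col}_mean"] = np.nan
                row[f"{col}_sd"] = np.nan
        cens = used["censored"].to_numpy() if n_used else np.array([])
        has_above = np.any(cens == "above")
        has_below = np.any(cens == "below")
        if n_used == 0:
            kind, value, sd = "missing", np.nan, np.nan
        elif has_above and has_below:
            kind, value, sd = "indeterminate", np.nan, np.nan
        elif has_above:
            # every censored-above row is pinned to the same domain bound
            kind = "lower_bound"
            value = float(np.min(used.loc[cens == "above", "delta_psi_mV"]))
            sd = np.nan
        elif has_below:
            kind = "upper_bound"
            value = float(np.max(used.loc[cens == "below", "delta_psi_mV"]))
            sd = np.nan
        else:
            vals = used["delta_psi_mV"].to_numpy()
            vals = vals[np.isfinite(vals)]
            if vals.size:
                kind = "mean"
                value = float(np.mean(vals))
                sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            else:
                kind, value, sd = "missing", np.nan, np.nan
        row["delta_psi_kind"] = kind
        row["delta_psi_value_mV"] = value
        row["delta_psi_sd_mV"] = sd
        rows.append(row)
    return pd.DataFrame(rows)


def detect_secondary_decline(
    time_s,
    psi_mV,
    smooth_s: float = 5.0,
    slope_threshold_mV_per_s: float = -0.1,
    plateau_slope_eps: float = 0.05,
    min_plateau_s: float = 60.0,
) -> dict | None:
    """Detect the late, rapid potential decline during ischemia.

    The trace is smoothed (centered moving average over ``smooth_s``) and
    its slope is estimated by a centered difference across +/- ``smooth_s``
    (a 2-sample gradient at 1 Hz is far too noisy to threshold).  The first
    sustained near-zero-slope plateau is located, and the event is the
    earliest subsequent time at which the slope drops below
    ``slope_threshold_mV_per_s``.  Returns None if no plateau or crossing
    exists; otherwise a dict with the event time, the plateau level and the
    trace minimum.
    """
    t = np.asarray(time_s, dtype=float)
    x = np.asarray(psi_mV, dtype=float)
    finite = np.isfinite(x)
    t, x = t[finite], x[finite]
    if t.size < 5:
        return None
    dt = float(np.median(np.diff(t)))
    if t[-1] - t[0] < 2.0 * smooth_s:
        raise DomainError("series shorter than twice the smoothing window")
    k = max(1, int(round(smooth_s / dt)))
    kernel = np.ones(k) / k
    sm_full = np.convolve(x, kernel, mode="same")
    # trim the biased edges of the 'same' convolution plus the slope baseline
    half = k // 2
    lo, hi = half + k, x.size - half - k
    if hi - lo < 3:
        return None
    t_s = t[lo:hi]
    sm = sm_full[lo:hi]
    slope = (sm_full[lo + k : hi + k] - sm_full[lo - k : hi - k]) / (2.0 * k * dt)
    min_run = max(1, int(round(min_plateau_s / dt)))
    flat = np.abs(slope) <= plateau_slope_eps
    plateau_start = None
    run = 0
    for i, ok in enumerate(flat):
        run = run + 1 if ok else 0
        if run >= min_run:
            plateau_start = i - min_run + 1
            break
    if plateau_start is None:
        return None
    after = slope[plateau_start:] < slope_threshold_mV_per_s
    idx = np.argmax(after)
    if not after[idx]:
        return None
    event_i = plateau_start + int(idx)
    min_i = int(np.argmin(sm))
    return {
        "event_time_s": float(t_s[event_i]),
        "plateau_value_mV": float(np.mean(sm[plateau_start:event_i]))
        if event_i > plateau_start
        else float(sm[plateau_start]),
        "min_value_mV": float(sm[min_i]),
        "min_time_s": float(t_s[min_i]),
    }


def heart_rate_from_flow(
    flow,
    fs_hz: float,
    min_prominence: float | None = None,
    min_interval_s: float = 0.08,
    window_s: float = 60.0,
    presmooth_s: float = 0.02,
) -> pd.DataFrame:
    """Beats per minute from the sinusoidal coronary-flow trace.

    Each flow wave peak counts as one beat; the rate is the peak count over
    a trailing window (default one minute) scaled to per-minute units.  The
    trace is lightly low-passed (moving average over ``presmooth_s``) first
    so wideband sensor noise does not masquerade as beats.  A flat trace
    yields 0 bpm everywhere.
    """
    x = np.asarray(flow, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("flow must be a 1-D trace")
    k = int(round(presmooth_s * fs_hz))
    if k > 1:
        x = np.convolve(x, np.ones(k) / k, mode="same")
    span = float(np.ptp(x))
    if min_prominence is None:
        min_prominence = 0.25 * span if span > 0 else np.inf
    if span == 0:
        peaks = np.array([], dtype=int)
    else:
        peaks, _ = find_peaks(
            x, prominence=min_prominence, distance=max(1, int(min_interval_s * fs_hz))
        )
    peak_times = peaks / fs_hz
    duration = x.size / fs_hz
    out_t = np.arange(1.0, duration + 1e-9, 1.0)
    bpm = np.empty_like(out_t)
    for i, te in enumerate(out_t):
        t0 = max(0.0, te - window_s)
        n = np.searchsorted(peak_times, te, side="right") - np.searchsorted(
            peak_times, t0, side="left"
        )
        bpm[i] = n * 60.0 / (te - t0)
    return pd.DataFrame({"time_s": out_t, "bpm": bpm})


# ---------------------------------------------------------------------------
# metabolite arithmetic
# ---------------------------------------------------------------------------

def succinate_content(
    area_analyte: float, area_is: float, is_amount_nmol: float, tissue_mg: float
) -> float:
    """Succinate per tissue mass against a 13C4 internal standard (nmol/mg)."""
    if area_analyte < 0 or area_is <= 0:
        raise DomainError("peak areas must be >= 0 and internal standard > 0")
    if tissue_mg <= 0:
        raise DomainError("tissue mass must be positive")
    return area_analyte / area_is * is_amount_nmol / tissue_mg


def percent_reduction(area_qh2: float, area_q: float) -> float:
    """CoQ redox poise: 100 * QH2 / (QH2 + Q)."""
    if area_qh2 < 0 or area_q < 0:
        raise DomainError("peak areas must be non-negative")
    total = area_qh2 + area_q
    if total == 0:
        raise DomainError("both peak areas are zero")
    return 100.0 * area_qh2 / total


def interpolate_timecourse(times, values) -> PchipInterpolator:
    """Shape-preserving monotone-segment cubic through sparse timepoints.

    Passes through every input point and introduces no new local extrema
    between points (PCHIP), which avoids overshoot on sparse biochemical
    timecourses.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValueError("need >= 2 matching timepoints")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    return PchipInterpolator(t, y)
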