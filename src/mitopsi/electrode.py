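"""TPMP+/TPP+ ion-selective electrode processing.

A lipophilic cation (TPMP+ or TPP+; the chemistry is identical for this
analysis, the probe name is metadata) distributes across the inner
mitochondrial membrane according to the Nernst equation.  The electrode
reports the *external* probe concentration; depletion of the external pool
after energization measures mitochondrial uptake, which, normalized to
mitochondrial protein and scaled by an empirical binding correction
(0.17 mg protein per ul), gives the free matrix concentration.  Then

    delta_psi = 61.5 * log10(c_in / c_out)   [mV at 37 C]

Calibration: the electrode is Nernstian in log10 of the external probe
concentration, so stepwise probe additions (six additions up to 2.17 uM
total by default) in the presence of de-energized mitochondria give
plateaus whose (log10 c, V) pairs are fit by a line.

Units: uptake is in nmol; uptake/protein is nmol/mg; multiplying by the
binding correction (mg/ul) yields nmol/ul = mM for the matrix free
concentration, while c_out is in uM, so c_out is converted to mM before
the Nernst ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, DomainError

__all__ = [
    "ElectrodeTrace",
    "ElectrodeCalibration",
    "NERNST_SLOPE_MV",
    "nernst_potential",
    "calibrate_electrode",
    "trace_to_potential",
    "steady_state_mean",
]

#: Nernst slope in mV per decade of concentration ratio (monovalent, 37 C).
NERNST_SLOPE_MV = 61.5

#: Default binding correction, mg mitochondrial protein per ul.
DEFAULT_BINDING_MG_PER_UL = 0.17


@dataclass(frozen=True)
class ElectrodeTrace:
    """A voltage trace with its addition schedule and suspension constants.

    ``additions`` is a sequence of (time_s, added_nmol) events, in time
    order.  ``total_probe_uM`` is the external concentration after the final
    calibration addition (default 2.17 uM, in a 5.5 ml bath).
    """

    time_s: np.ndarray
    voltage_mV: np.ndarray
    additions: tuple = ()
    bath_volume_ml: float = 5.5
    protein_mg: float = 1.0
    total_probe_uM: float = 2.17
    probe: str = "TPMP+"

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        v = np.asarray(self.voltage_mV, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("time_s and voltage_mV must be matching 1-D arrays")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time_s must be strictly increasing")
        adds = tuple((float(at), float(amt)) for at, amt in self.additions)
        if any(adds[i][0] > adds[i + 1][0] for i in range(len(adds) - 1)):
            raise ValueError("additions must be non-decreasing in time")
        if not (self.bath_volume_ml > 0 and self.protein_mg > 0):
            raise ValueError("bath volume and protein load must be positive")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "voltage_mV", v)
        object.__setattr__(self, "additions", adds)


@dataclass(frozen=True)
class ElectrodeCalibration:
    """Fitted Nernstian electrode response V = intercept + slope*log10(c_uM)."""

    slope_mV_per_decade: float
    intercept_mV: float
    r_squared: float
    plateau_windows: tuple = ()
    plateau_concentrations_uM: tuple = ()
    plateau_voltages_mV: tuple = ()

    def voltage(self, c_uM):
        c = np.asarray(c_uM, dtype=float)
        if np.any(c <= 0):
            raise DomainError("concentration must be positive")
        return self.intercept_mV + self.slope_mV_per_decade * np.log10(c)

    def concentration(self, voltage_mV):
        v = np.asarray(voltage_mV, dtype=float)
        return 10.0 ** ((v - self.intercept_mV) / self.slope_mV_per_decade)


def nernst_potential(c_in, c_out, slope_mV: float = NERNST_SLOPE_MV):
    """Membrane potential (mV) from the in/out concentration ratio.

    Concentrations must be positive and share units.  A tenfold ratio gives
    exactly ``slope_mV`` (61.5 mV by default).
    """
    c_in = np.asarray(c_in, dtype=float)
    c_out = np.asarray(c_out, dtype=float)
    if np.any(c_in <= 0) or np.any(c_out <= 0):
        raise DomainError("nernst_potential requires positive concentrations")
    out = slope_mV * np.log10(c_in / c_out)
    return float(out) if out.ndim == 0 else out


def calibrate_electrode(
    trace: ElectrodeTrace,
    settle_s: float = 10.0,
    end_time_s: float | None = None,
) -> ElectrodeCalibration:
    """Fit the Nernstian electrode line from stepwise-addition plateaus.

    Each addition event defines a plateau window from ``event + settle_s``
    to the next event (or ``end_time_s``); the mean voltage over each window
    is paired with the cumulative external concentration and the line
    V = intercept + slope*log10(c) is fit by least squares.
    """
    if len(trace.additions) < 2:
        raise CalibrationError(
            f"need >= 2 addition plateaus, got {len(trace.additions)}"
        )
    t, v = trace.time_s, trace.voltage_mV
    add_times = [at for at, _ in trace.additions]
    cumulative_nmol = np.cumsum([amt for _, amt in trace.additions])
    conc_uM = cumulative_nmol / trace.bath_volume_ml  # nmol/ml == uM
    if end_time_s is None:
        # default the final plateau to the median inter-addition spacing, so
        # post-calibration (energized) samples never leak into it
        spacing = float(np.median(np.diff(add_times))) if len(add_times) > 1 else settle_s * 2
        end_time_s = min(add_times[-1] + spacing, t[-1] + trace_dt(trace))
    boundaries = add_times[1:] + [end_time_s]
    plateaus, windows = [], []
    for start, stop, c in zip(add_times, boundaries, conc_uM):
        mask = (t >= start + settle_s) & (t < stop)
        if mask.sum() == 0:
            raise CalibrationError(
                f"no samples in plateau window [{start + settle_s:g}, {stop:g}) s"
            )
        plateaus.append(float(np.mean(v[mask])))
        windows.append((float(start + settle_s), float(stop)))
    plateaus = np.asarray(plateaus)
    if len(plateaus) < 2:
        raise CalibrationError("fewer than 2 usable plateaus")
    x = np.log10(conc_uM)
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), res, *_ = np.linalg.lstsq(design, plateaus, rcond=None)
    fitted = design @ [slope, intercept]
    ss_tot = float(np.sum((plateaus - plateaus.mean()) ** 2))
    ss_res = float(np.sum((plateaus - fitted) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if np.any(np.diff(plateaus) * np.sign(slope) < 0):
        import warnings

        warnings.warn(
            f"non-monotone plateau voltages (r^2 = {r2:.4f}); electrode may be "
            "drifting",
            UserWarning,
            stacklevel=2,
        )
    return ElectrodeCalibration(
        slope_mV_per_decade=float(slope),
        intercept_mV=float(intercept),
        r_squared=r2,
        plateau_windows=tuple(windows),
        plateau_concentrations_uM=tuple(conc_uM.tolist()),
        plateau_voltages_mV=tuple(plateaus.tolist()),
    )


def trace_dt(trace: ElectrodeTrace) -> float:
    if trace.time_s.size > 1:
        return float(np.median(np.diff(trace.time_s)))
    return 1.0


def trace_to_potential(
    trace: ElectrodeTrace,
    cal: ElectrodeCalibration,
    binding_mg_per_uL: float = DEFAULT_BINDING_MG_PER_UL,
    start_time_s: float | None = None,
    negative_uptake_tol: float = 0.02,
    nernst_slope_mV: float = NERNST_SLOPE_MV,
) -> pd.DataFrame:
    """Convert a voltage trace to external/matrix concentrations and delta-psi.

    For each sample at/after ``start_time_s`` (default: after the last
    calibration addition):

    * ``c_out_uM = 10**((V - intercept)/slope)``
    * ``uptake_nmol = (total_uM - c_out_uM) * bath_volume_ml``
    * ``c_in_mM = uptake/protein * binding``  (nmol/mg * mg/ul = nmol/ul = mM)
    * ``delta_psi_mV = 61.5 * log10(c_in_mM / (c_out_uM/1000))``

    Apparent uptake within ``negative_uptake_tol`` of zero (as a fraction of
    the total probe content) is clipped to zero and flagged; larger
    negative uptake raises.  Rows with zero uptake carry NaN delta-psi and
    the ``no_uptake`` flag.
    """
    if start_time_s is None:
        start_time_s = trace.additions[-1][0] if trace.additions else trace.time_s[0]
    mask = trace.time_s >= start_time_s
    t = trace.time_s[mask]
    v = trace.voltage_mV[mask]
    c_out = cal.concentration(v)
    if np.any(c_out <= 0):
        raise DomainError("inferred external concentration is non-positive")
    total_nmol = trace.total_probe_uM * trace.bath_volume_ml
    uptake = (trace.total_probe_uM - c_out) * trace.bath_volume_ml
    overshoot = -uptake / total_nmol
    if np.any(overshoot > negative_uptake_tol):
        raise DomainError(
            f"apparent uptake is negative beyond tolerance "
            f"(max {float(np.max(overshoot)) * 100:.1f}% of total probe); "
            "check calibration or total probe concentration"
        )
    negative_flag = uptake < 0
    uptake = np.clip(uptake, 0.0, None)
    # uptake indistinguishable from zero at float precision is zero
    uptake[uptake < 1e-9 * total_nmol] = 0.0
    c_in_mM = uptake / trace.protein_mg * binding_mg_per_uL
    c_out_mM = c_out / 1000.0
    no_uptake = c_in_mM <= 0
    delta_psi = np.full_like(c_in_mM, np.nan)
    ok = ~no_uptake
    delta_psi[ok] = nernst_slope_mV * np.log10(c_in_mM[ok] / c_out_mM[ok])
    return pd.DataFrame(
        {
            "time_s": t,
            "voltage_mV": v,
            "c_out_uM": c_out,
            "uptake_nmol": uptake,
            "c_in_mM": c_in_mM,
            "delta_psi_mV": delta_psi,
            "no_uptake": no_uptake,
            "clipped_negative_uptake": negative_flag,
        }
    )


def plateau_potential(
    trace: ElectrodeTrace,
    cal: ElectrodeCalibration,
    window: tuple[float, float],
    binding_mg_per_uL: float = DEFAULT_BINDING_MG_PER_UL,
    negative_uptake_tol: float = 0.02,
    nernst_slope_mV: float = NERNST_SLOPE_MV,
) -> dict:
    """Steady-state potential from one voltage plateau.

    Averages the voltage over the window *first* and converts once; for
    low-uptake states (near-zero depletion) this is far better conditioned
    than averaging per-sample potentials, whose log blows up sample noise.
    Returns a dict with the mean voltage, c_out, uptake, c_in and delta_psi
    (NaN with ``no_uptake`` set when the averaged uptake is zero).
    """
    v_mean, v_sd = steady_state_mean(trace.time_s, trace.voltage_mV, window)
    tiny = ElectrodeTrace(
        time_s=np.array([0.0]),
        voltage_mV=np.array([v_mean]),
        additions=(),
        bath_volume_ml=trace.bath_volume_ml,
        protein_mg=trace.protein_mg,
        total_probe_uM=trace.total_probe_uM,
        probe=trace.probe,
    )
    row = trace_to_potential(
        tiny, cal,
        binding_mg_per_uL=binding_mg_per_uL,
        negative_uptake_tol=negative_uptake_tol,
        nernst_slope_mV=nernst_slope_mV,
    ).iloc[0]
    return {
        "voltage_mV": v_mean,
        "voltage_sd_mV": v_sd,
        "c_out_uM": float(row["c_out_uM"]),
        "uptake_nmol": float(row["uptake_nmol"]),
        "c_in_mM": float(row["c_in_mM"]),
        "delta_psi_mV": float(row["delta_psi_mV"]),
        "no_uptake": bool(row["no_uptake"]),
    }


def steady_state_mean(time_s, values, window: tuple[float, float]):
    """Mean and SD of a scalar trace over a closed time window.

    Requires at least 3 samples in the window.  SD is the sample standard
    deviation (ddof=1).
    """
    t = np.asarray(time_s, dtype=float)
    x = np.asarray(values, dtype=float)
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    n = int(mask.sum())
    if n < 3:
        raise DomainError(
            f"steady-state window [{lo:g}, {hi:g}] s contains {n} samples (< 3)"
        )
    sel = x[mask]
    return float(np.mean(sel)), float(np.std(sel, ddof=1))
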