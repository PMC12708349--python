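"""Ground-truth generators for every input the inference chain consumes.

The real reference spectra were derived biochemically and were not
published as data, so the generators emulate them with Gaussian alpha-band
models at the documented peak positions (cyt c 550 nm, c1 552 nm, b_H
562 nm, b_L 564 nm with a 558 nm shoulder; myoglobin MbO twin bands near
542/580 nm, MbD a broad band near 556 nm).  Band parameters are plain
config, so empirical references can be substituted without code changes.

All generators are seed-deterministic and emit a truth table aligned
row-for-row with the data product, which is what makes closed-loop
(simulate -> infer -> compare) testing possible.  Noise is applied in the
count domain (on transmitted intensity), matching the physical instrument
and inducing the mild heteroscedasticity in absorbance that the SNR-based
exclusion rule has to handle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve
from .electrode import ElectrodeTrace, NERNST_SLOPE_MV
from .spectra import RawOpticalRecord, ReferenceLibrary, UNIT_PEAK

__all__ = [
    "BandModel",
    "ScenarioTruth",
    "heart_grid",
    "mitochondria_grid",
    "default_band_models",
    "default_true_curve",
    "make_reference_library",
    "simulate_spectrum_series",
    "simulate_electrode_trace",
    "simulate_titration_experiment",
    "simulate_ir_experiment",
    "simulate_flow_trace",
    "ir_trajectory",
    "make_calibration_points",
]


def heart_grid() -> np.ndarray:
    """The heart spectrometer grid: 1,024 points between 400 and 800 nm."""
    return np.linspace(400.0, 800.0, 1024)


def mitochondria_grid() -> np.ndarray:
    """The mitochondrial-suspension grid: 1,044 points between 348 and 745 nm."""
    return np.linspace(348.0, 745.0, 1044)


@dataclass(frozen=True)
class BandModel:
    """Gaussian sub-band model of one chromophore's alpha-band absorbance.

    ``subbands`` is a sequence of (center_nm, sigma_nm, relative_height).
    """

    name: str
    subbands: tuple

    def __post_init__(self):
        bands = tuple((float(c), float(s), float(h)) for c, s, h in self.subbands)
        if not bands:
            raise ValueError("BandModel needs at least one sub-band")
        if any(s <= 0 for _, s, _ in bands):
            raise ValueError("sub-band widths must be positive")
        if any(h < 0 for _, _, h in bands):
            raise ValueError("sub-band heights must be non-negative")
        object.__setattr__(self, "subbands", bands)

    @property
    def peak_nm(self) -> float:
        return max(self.subbands, key=lambda b: b[2])[0]

    def evaluate(self, grid_nm: np.ndarray) -> np.ndarray:
        out = np.zeros_like(grid_nm, dtype=float)
        for center, sigma, height in self.subbands:
            out += height * np.exp(-0.5 * ((grid_nm - center) / sigma) ** 2)
        return out


def default_band_models(include_myoglobin: bool = False) -> list[BandModel]:
    """Band models at the documented alpha-band peak positions."""
    models = [
        BandModel("c", ((550.0, 4.0, 1.0),)),
        BandModel("c1", ((552.0, 4.5, 1.0),)),
        BandModel("b_H", ((562.0, 5.0, 1.0),)),
        # b_L: main peak at 564 nm plus the 558 nm shoulder
        BandModel("b_L", ((564.0, 5.0, 1.0), (558.0, 4.0, 0.35))),
    ]
    if include_myoglobin:
        models += [
            BandModel("MbO", ((542.0, 7.0, 0.95), (580.0, 7.0, 1.0))),
            BandModel("MbD", ((556.0, 11.0, 1.0),)),
        ]
    return models


@dataclass
class ScenarioTruth:
    """Per-timepoint ground truth aligned row-for-row with a data product."""

    table: pd.DataFrame
    seed: int | None = None
    noise: Mapping[str, float] = field(default_factory=dict)
    events: Mapping[str, float] = field(default_factory=dict)
    params: Mapping[str, object] = field(default_factory=dict)


def default_true_curve() -> CalibrationCurve:
    """The reference 4PL used by the simulation studies.

    bottom 0.15, top 0.65, v50 140 mV, hill 0.03 per mV, calibrated domain
    60-208 mV — a curve of the shape and range seen in isolated heart
    mitochondria.
    """
    return CalibrationCurve(
        bottom=0.15,
        top=0.65,
        v50_mV=140.0,
        hill=0.03,
        domain_mV=(60.0, 208.0),
        fbl_ceiling=0.6456,
        library_normalization=UNIT_PEAK,
    )


def make_reference_library(
    models: Sequence[BandModel] | None = None,
    grid_nm: np.ndarray | None = None,
    band_nm: tuple[float, float] | None = None,
    include_myoglobin: bool = False,
) -> tuple[ReferenceLibrary, dict]:
    """Build a unit-peak-normalized library from Gaussian band models.

    Returns the library and an info dict containing the condition number of
    the unmixing design (references + line restricted to the fit band).
    Coincident band centers trigger a collinearity warning.
    """
    if models is None:
        models = default_band_models(include_myoglobin=include_myoglobin)
    if grid_nm is None:
        grid_nm = heart_grid()
    if band_nm is None:
        band_nm = (535.0, 585.0) if any(m.name in ("MbO", "MbD") for m in models) else (540.0, 580.0)
    centers = [m.peak_nm for m in models]
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            if abs(centers[i] - centers[j]) < 0.5:
                warnings.warn(
                    f"band models {models[i].name!r} and {models[j].name!r} have "
                    f"nearly coincident peak centers ({centers[i]:g} nm); the "
                    "design will be ill conditioned",
                    UserWarning,
                    stacklevel=2,
                )
    spectra = {m.name: m.evaluate(grid_nm) for m in models}
    library = ReferenceLibrary.from_spectra(
        spectra,
        grid_nm,
        band_nm=band_nm,
        peak_nm={m.name: m.peak_nm for m in models},
    )
    mask = (grid_nm >= band_nm[0]) & (grid_nm <= band_nm[1])
    design = np.column_stack(
        [library.spectra[m.name][mask] for m in models] + [grid_nm[mask], np.ones(mask.sum())]
    )
    info = {"condition_number": float(np.linalg.cond(design)), "band_nm": band_nm}
    return library, info


# ---------------------------------------------------------------------------
# optical forward model
# ---------------------------------------------------------------------------

def default_incident(grid_nm: np.ndarray) -> np.ndarray:
    """A smooth tungsten-like incident spectrum in counts."""
    return 20000.0 * np.exp(-0.5 * ((grid_nm - 620.0) / 160.0) ** 2) + 12000.0


def simulate_spectrum_series(
    coefficients: Mapping[str, np.ndarray],
    library: ReferenceLibrary,
    baseline_slope=0.0,
    baseline_intercept=0.0,
    noise_sigma_counts: float = 0.0,
    seed: int | None = None,
    incident: np.ndarray | None = None,
    dark: np.ndarray | None = None,
    sample_period_s: float = 1.0,
    start_time_s: float = 0.0,
) -> tuple[RawOpticalRecord, ScenarioTruth]:
    """Forward-model a raw record from true coefficient trajectories.

    A(lambda, t) = sum_i c_i(t) * ref_i(lambda) + e(t)*lambda + f(t) is
    converted to transmitted counts T = D + (I0 - D) * 10**(-A), then
    Gaussian count noise is added.  The truth table carries the injected
    coefficients and the implied fb_L.
    """
    if noise_sigma_counts < 0:
        raise ValueError("noise sigma must be >= 0")
    names = list(coefficients)
    trajs = {n: np.atleast_1d(np.asarray(c, dtype=float)) for n, c in coefficients.items()}
    n_t = len(next(iter(trajs.values())))
    if any(len(c) != n_t for c in trajs.values()):
        raise ValueError("coefficient trajectories must share a length")
    grid = library.grid_nm
    slope = np.broadcast_to(np.asarray(baseline_slope, dtype=float), (n_t,))
    intercept = np.broadcast_to(np.asarray(baseline_intercept, dtype=float), (n_t,))
    A = slope[:, None] * grid[None, :] + intercept[:, None]
    for n in names:
        A = A + trajs[n][:, None] * library.spectra[n][None, :]
    if incident is None:
        incident = default_incident(grid)
    if dark is None:
        dark = np.full_like(grid, 400.0)
    T = dark[None, :] + (incident - dark)[None, :] * 10.0 ** (-A)
    rng = np.random.default_rng(seed)
    if noise_sigma_counts > 0:
        T = T + rng.normal(0.0, noise_sigma_counts, size=T.shape)
    if np.any(T - dark[None, :] <= 0):
        raise ValueError(
            "forward model produced non-positive dark-corrected counts; "
            "reduce absorbance or noise"
        )
    times = start_time_s + np.arange(n_t) * sample_period_s
    record = RawOpticalRecord(
        wavelengths_nm=grid,
        incident=incident,
        dark=dark,
        times_s=times,
        transmissions=T,
        sample_period_s=sample_period_s,
    )
    truth_cols = {"time_s": times}
    truth_cols.update({n: trajs[n] for n in names})
    truth_cols["slope"] = np.asarray(slope, dtype=float)
    truth_cols["intercept"] = np.asarray(intercept, dtype=float)
    if "b_L" in trajs and "b_H" in trajs:
        total = trajs["b_L"] + trajs["b_H"]
        with np.errstate(divide="ignore", invalid="ignore"):
            truth_cols["fbl_true"] = np.where(total != 0, trajs["b_L"] / total, np.nan)
    truth = ScenarioTruth(
        table=pd.DataFrame(truth_cols),
        seed=seed,
        noise={"sigma_counts": noise_sigma_counts},
    )
    return record, truth


# ---------------------------------------------------------------------------
# electrode forward model
# ---------------------------------------------------------------------------

def equilibrium_c_out_uM(
    psi_mV: float,
    total_uM: float,
    bath_volume_ml: float,
    protein_mg: float,
    binding_mg_per_uL: float,
    nernst_slope_mV: float = NERNST_SLOPE_MV,
) -> float:
    """External probe concentration at Nernstian equilibrium.

    Mass balance (total*V = c_out*V + uptake) with uptake determined by the
    Nernst ratio and the binding correction is linear in c_out:

        c_out = total*V / (V + R * protein / (1000 * binding)),  R = 10**(psi/61.5)
    """
    R = 10.0 ** (psi_mV / nernst_slope_mV)
    return total_uM * bath_volume_ml / (
        bath_volume_ml + R * protein_mg / (1000.0 * binding_mg_per_uL)
    )


def simulate_electrode_trace(
    psi_schedule_mV: Sequence[tuple[float, float | None]],
    electrode_slope_mV: float = 59.0,
    electrode_intercept_mV: float = -10.0,
    total_probe_uM: float = 2.17,
    bath_volume_ml: float = 5.5,
    protein_mg: float = 6.0,
    binding_mg_per_uL: float = 0.17,
    n_additions: int = 6,
    addition_interval_s: float = 60.0,
    post_calibration_gap_s: float = 60.0,
    noise_mV: float = 0.0,
    sample_period_s: float = 1.0,
    seed: int | None = None,
) -> tuple[ElectrodeTrace, ScenarioTruth]:
    """Simulate a stepwise calibration followed by energized steady states.

    The calibration period makes ``n_additions`` equal probe additions up to
    ``total_probe_uM``; afterwards the suspension steps through
    ``psi_schedule_mV`` as (duration_s, psi_mV) plateaus (psi None means no
    uptake).  Voltages follow the ideal Nernstian electrode line plus
    Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    add_times = [(i + 1) * addition_interval_s for i in range(n_additions)]
    per_add_nmol = total_probe_uM * bath_volume_ml / n_additions
    additions = tuple((t, per_add_nmol) for t in add_times)
    cal_end = add_times[-1] + post_calibration_gap_s
    total_dur = cal_end + sum(d for d, _ in psi_schedule_mV)
    t = np.arange(0.0, total_dur, sample_period_s)
    c_out = np.empty_like(t)
    psi_true = np.full_like(t, np.nan)
    # calibration period: cumulative external concentration, no uptake
    cum_conc = np.cumsum([per_add_nmol] * n_additions) / bath_volume_ml
    c_out[t < add_times[0]] = 1e-3  # pre-addition trace; tiny background level
    for i, at in enumerate(add_times):
        stop = add_times[i + 1] if i + 1 < n_additions else cal_end
        c_out[(t >= at) & (t < stop)] = cum_conc[i]
    # energized plateaus
    cursor = cal_end
    for duration, psi in psi_schedule_mV:
        mask = (t >= cursor) & (t < cursor + duration)
        if psi is None:
            c_out[mask] = total_probe_uM
        else:
            c_out[mask] = equilibrium_c_out_uM(
                psi, total_probe_uM, bath_volume_ml, protein_mg, binding_mg_per_uL
            )
            psi_true[mask] = psi
        cursor += duration
    v = electrode_intercept_mV + electrode_slope_mV * np.log10(c_out)
    if noise_mV > 0:
        v = v + rng.normal(0.0, noise_mV, size=v.shape)
    trace = ElectrodeTrace(
        time_s=t,
        voltage_mV=v,
        additions=additions,
        bath_volume_ml=bath_volume_ml,
        protein_mg=protein_mg,
        total_probe_uM=total_probe_uM,
    )
    uptake = np.clip((total_probe_uM - c_out) * bath_volume_ml, 0.0, None)
    truth = ScenarioTruth(
        table=pd.DataFrame(
            {
                "time_s": t,
                "psi_true_mV": psi_true,
                "c_out_true_uM": c_out,
                "uptake_true_nmol": uptake,
            }
        ),
        seed=seed,
        noise={"voltage_mV": noise_mV},
        events={"calibration_end_s": cal_end},
        params={
            "electrode_slope_mV": electrode_slope_mV,
            "electrode_intercept_mV": electrode_intercept_mV,
            "binding_mg_per_uL": binding_mg_per_uL,
        },
    )
    return trace, truth


# ---------------------------------------------------------------------------
# paired titration (calibration-building) experiment
# ---------------------------------------------------------------------------

def simulate_titration_experiment(
    psi_schedule_mV: Sequence[tuple[float, float]],
    curve: CalibrationCurve | None = None,
    library: ReferenceLibrary | None = None,
    b_total: float = 0.05,
    c1_coeff: float = 0.03,
    c_coeff: float = 0.04,
    baseline_slope: float = -2e-5,
    baseline_intercept: float = 0.05,
    noise_sigma_counts: float = 0.0,
    noise_mV: float = 0.0,
    seed: int | None = None,
    **electrode_kwargs,
) -> tuple[RawOpticalRecord, ElectrodeTrace, ScenarioTruth]:
    """Paired optical + electrode recording over a stepped-psi titration.

    fb_L*(t) follows the true calibration curve at the scheduled psi, with
    b-heme coefficients split as b_L = fbl*b_total, b_H = (1-fbl)*b_total.
    Levels outside the curve's calibrated domain are flagged censored in the
    truth table.  The schedule needs at least two distinct levels to support
    a downstream calibration fit.
    """
    levels = {psi for _, psi in psi_schedule_mV}
    if len(levels) < 2:
        raise ValueError("psi schedule must contain >= 2 distinct levels")
    if curve is None:
        curve = default_true_curve()
    if library is None:
        library, _ = make_reference_library()
    seed_seq = np.random.SeedSequence(seed)
    s_opt, s_el = seed_seq.spawn(2)
    trace, el_truth = simulate_electrode_trace(
        psi_schedule_mV,
        noise_mV=noise_mV,
        seed=int(s_el.generate_state(1)[0] % (2**31)),
        **electrode_kwargs,
    )
    cal_end = el_truth.events["calibration_end_s"]
    mask = trace.time_s >= cal_end
    times = trace.time_s[mask]
    psi_t = el_truth.table["psi_true_mV"].to_numpy()[mask]
    fbl_t = curve.evaluate(psi_t)
    censored = (psi_t < curve.domain_mV[0]) | (psi_t > curve.domain_mV[1])
    coeffs = {
        "b_H": (1.0 - fbl_t) * b_total,
        "b_L": fbl_t * b_total,
        "c1": np.full_like(fbl_t, c1_coeff),
        "c": np.full_like(fbl_t, c_coeff),
    }
    record, opt_truth = simulate_spectrum_series(
        coeffs,
        library,
        baseline_slope=baseline_slope,
        baseline_intercept=baseline_intercept,
        noise_sigma_counts=noise_sigma_counts,
        seed=int(s_opt.generate_state(1)[0] % (2**31)),
        start_time_s=float(times[0]),
    )
    table = opt_truth.table.copy()
    table["psi_true_mV"] = psi_t
    table["censored_true"] = censored
    table["c_out_true_uM"] = el_truth.table["c_out_true_uM"].to_numpy()[mask]
    truth = ScenarioTruth(
        table=table,
        seed=seed,
        noise={"sigma_counts": noise_sigma_counts, "voltage_mV": noise_mV},
        events=dict(el_truth.events),
        params={**dict(el_truth.params), "b_total": b_total, "curve": curve},
    )
    return record, trace, truth


# ---------------------------------------------------------------------------
# ischemia-reperfusion scenario
# ---------------------------------------------------------------------------

def ir_trajectory(
    times_s: np.ndarray,
    control_end_s: float,
    ischemia_end_s: float,
    control_psi_mV: float = 166.0,
    ischemic_plateau_mV: float = 133.0,
    minimum_mV: float = 92.0,
    reperfusion_psi_mV: float = 157.0,
    secondary_onset_s: float | None = None,
    secondary_duration_s: float = 240.0,
    drop_tau_s: float = 20.0,
    rebound_tau_s: float = 30.0,
    late_drift_mV_per_s: float = 0.0,
) -> np.ndarray:
    """Piecewise delta-psi trajectory for a global ischemia-reperfusion run.

    Control plateau -> exponential drop to the ischemic plateau at the onset
    of ischemia -> linear secondary decline to the minimum starting at
    ``secondary_onset_s`` (default: 13 min into ischemia) -> exponential
    rebound at reperfusion with optional late drift.
    """
    t = np.asarray(times_s, dtype=float)
    if secondary_onset_s is None:
        secondary_onset_s = control_end_s + 13.0 * 60.0
    psi = np.full_like(t, control_psi_mV)
    isch = (t >= control_end_s) & (t < ischemia_end_s)
    dt = t[isch] - control_end_s
    psi[isch] = ischemic_plateau_mV + (control_psi_mV - ischemic_plateau_mV) * np.exp(
        -dt / drop_tau_s
    )
    ramp = isch & (t >= secondary_onset_s)
    frac = np.clip((t[ramp] - secondary_onset_s) / secondary_duration_s, 0.0, 1.0)
    psi[ramp] = ischemic_plateau_mV + frac * (minimum_mV - ischemic_plateau_mV)
    rep = t >= ischemia_end_s
    dt = t[rep] - ischemia_end_s
    psi[rep] = (
        reperfusion_psi_mV
        - (reperfusion_psi_mV - minimum_mV) * np.exp(-dt / rebound_tau_s)
        + late_drift_mV_per_s * dt
    )
    return psi


def simulate_flow_trace(
    duration_s: float,
    beat_freq_hz: float = 5.0,
    fs_hz: float = 1000.0,
    amplitude: float = 1.0,
    offset: float = 2.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sinusoidal coronary-flow trace: one flow wave per heart beat."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, 1.0 / fs_hz)
    flow = offset + amplitude * np.sin(2.0 * np.pi * beat_freq_hz * t)
    if noise_sd > 0:
        flow = flow + rng.normal(0.0, noise_sd, size=flow.shape)
    return pd.DataFrame({"time_s": t, "flow": flow})


def simulate_ir_experiment(
    control_s: float = 600.0,
    ischemia_s: float = 1200.0,
    reperfusion_s: float = 1200.0,
    library: ReferenceLibrary | None = None,
    curve: CalibrationCurve | None = None,
    include_myoglobin: bool = False,
    b_total: float = 0.5,
    c1_coeff: float = 0.35,
    cytc_control: float = 0.25,
    cytc_ischemia: float = 0.6,
    baseline_slope: float = -1e-4,
    baseline_intercept: float = 0.3,
    pathlength_step: float = 1.3,
    pathlength_ramp_s: float = 60.0,
    noise_sigma_counts: float = 0.0,
    sample_period_s: float = 1.0,
    seed: int | None = None,
    trajectory_kwargs: Mapping | None = None,
) -> tuple[RawOpticalRecord, ScenarioTruth]:
    """Full ischemia-reperfusion optical scenario with injected ground truth.

    The delta-psi trajectory follows :func:`ir_trajectory`; fb_L is derived
    from it through the true calibration curve; cytochrome c amplitude rises
    during ischemia (reduction on anoxia) and reverts on reperfusion; a
    path-length multiplier ramps in at the hypercontracture event (the
    secondary-decline onset), scaling every chromophore coefficient equally
    — which must leave fb_L untouched.
    """
    if curve is None:
        curve = default_true_curve()
    if library is None:
        library, _ = make_reference_library(include_myoglobin=include_myoglobin)
    tk = dict(trajectory_kwargs or {})
    total = control_s + ischemia_s + reperfusion_s
    times = np.arange(0.0, total, sample_period_s)
    ischemia_end = control_s + ischemia_s
    secondary_onset = tk.pop("secondary_onset_s", control_s + 13.0 * 60.0)
    psi = ir_trajectory(
        times,
        control_end_s=control_s,
        ischemia_end_s=ischemia_end,
        secondary_onset_s=secondary_onset,
        **tk,
    )
    fbl = curve.evaluate(psi)
    # cytochrome c redox: reduced (high amplitude) while anoxic
    cytc = np.full_like(times, cytc_control)
    isch = (times >= control_s) & (times < ischemia_end)
    tau = 30.0
    cytc[isch] = cytc_ischemia + (cytc_control - cytc_ischemia) * np.exp(
        -(times[isch] - control_s) / tau
    )
    rep = times >= ischemia_end
    cytc[rep] = cytc_control + (cytc_ischemia - cytc_control) * np.exp(
        -(times[rep] - ischemia_end) / tau
    )
    # path-length multiplier ramps in at hypercontracture
    plm = np.ones_like(times)
    ramp = times >= secondary_onset
    plm[ramp] = 1.0 + (pathlength_step - 1.0) * np.clip(
        (times[ramp] - secondary_onset) / pathlength_ramp_s, 0.0, 1.0
    )
    coeffs = {
        "b_H": (1.0 - fbl) * b_total * plm,
        "b_L": fbl * b_total * plm,
        "c1": np.full_like(times, c1_coeff) * plm,
        "c": cytc * plm,
    }
    if include_myoglobin:
        # oxygenated myoglobin deoxygenates during ischemia and recovers
        mb_hi, mb_lo = 0.8, 0.08
        span = mb_hi - mb_lo
        mbo = np.full_like(times, mb_hi)
        mbd = np.full_like(times, mb_lo)
        mbo[isch] = mb_lo + span * np.exp(-(times[isch] - control_s) / tau)
        mbd[isch] = mb_hi - span * np.exp(-(times[isch] - control_s) / tau)
        mbo[rep] = mb_hi - span * np.exp(-(times[rep] - ischemia_end) / tau)
        mbd[rep] = mb_lo + span * np.exp(-(times[rep] - ischemia_end) / tau)
        coeffs["MbO"] = mbo * plm
        coeffs["MbD"] = mbd * plm
    record, base_truth = simulate_spectrum_series(
        coeffs,
        library,
        baseline_slope=baseline_slope,
        baseline_intercept=baseline_intercept,
        noise_sigma_counts=noise_sigma_counts,
        seed=seed,
        sample_period_s=sample_period_s,
    )
    table = base_truth.table.copy()
    table["psi_true_mV"] = psi
    table["fbl_true"] = fbl
    table["pathlength_multiplier"] = plm
    truth = ScenarioTruth(
        table=table,
        seed=seed,
        noise={"sigma_counts": noise_sigma_counts},
        events={
            "control_end_s": control_s,
            "ischemia_end_s": ischemia_end,
            "secondary_onset_s": secondary_onset,
            "hypercontracture_s": secondary_onset,
        },
        params={
            "curve": curve,
            "b_total": b_total,
            "pathlength_step": pathlength_step,
            "include_myoglobin": include_myoglobin,
        },
    )
    return record, truth


def make_calibration_points(
    psi_values_mV: Sequence[float],
    curve: CalibrationCurve | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Condition-mean calibration points from a known curve plus fb_L noise."""
    if curve is None:
        curve = default_true_curve()
    rng = np.random.default_rng(seed)
    psi = np.asarray(psi_values_mV, dtype=float)
    fbl = curve.evaluate(psi)
    if noise_sd > 0:
        fbl = np.clip(fbl + rng.normal(0.0, noise_sd, size=fbl.shape), 0.0, 1.0)
    if labels is None:
        labels = [f"condition_{i}" for i in range(psi.size)]
    return pd.DataFrame({"label": list(labels), "delta_psi_mV": psi, "fbl": fbl})
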