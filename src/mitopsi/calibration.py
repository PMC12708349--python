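"""Four-parameter logistic calibration between delta-psi and fb_L.

The calibration points (one per steady-state condition in isolated
mitochondria) relate the electrode-derived membrane potential to the
optically derived fb_L.  They are fit with the variable-slope
four-parameter sigmoid in its decade-logistic (Prism-style dose-response)
form, with the potential in mV left untransformed:

    fbl(psi) = bottom + (top - bottom) / (1 + 10**((v50 - psi) * hill))

``hill`` has units 1/mV; for hill > 0 the curve increases monotonically
from ``bottom`` to ``top`` with midpoint at ``v50``.

Inverse prediction (fb_L -> delta-psi) uses the closed-form inverse on the
curve interior.  Near the asymptotes the inverse is unreliable, so fb_L
values within a guard margin of either asymptote — or implying a potential
outside the calibrated domain — are returned as *censored* bounds pinned to
the calibration domain, mirroring how potentials beyond the standard curve
can only be reported as "at least the largest calibrated value".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import CalibrationError, DegenerateFitError, DomainError

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "PotentialEstimate",
    "SigmoidCalibration",
    "four_param_logistic",
    "fit_calibration",
    "evaluate_curve",
    "invert_curve",
    "confidence_band",
]


def four_param_logistic(psi_mV, bottom, top, v50_mV, hill):
    """Variable-slope 4PL, decade base, abscissa in untransformed mV."""
    psi_mV = np.asarray(psi_mV, dtype=float)
    with np.errstate(over="ignore"):  # deep-tail overflow saturates to an asymptote
        out = bottom + (top - bottom) / (1.0 + 10.0 ** ((v50_mV - psi_mV) * hill))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CalibrationPoint:
    """One condition-mean (delta-psi, fb_L) pair."""

    delta_psi_mV: float
    fbl: float
    label: str = ""
    weight: float = 1.0

    def __post_init__(self):
        if not np.isfinite(self.delta_psi_mV):
            raise ValueError("delta_psi_mV must be finite")
        if not 0.0 <= self.fbl <= 1.0:
            raise ValueError(f"fbl must be within [0, 1], got {self.fbl}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted 4PL with covariance and validity domain."""

    bottom: float
    top: float
    v50_mV: float
    hill: float
    covariance: np.ndarray | None = None
    domain_mV: tuple[float, float] = (-np.inf, np.inf)
    fbl_ceiling: float = np.nan
    library_normalization: str | None = None

    def __post_init__(self):
        if not self.bottom < self.top:
            raise DegenerateFitError(
                f"bottom ({self.bottom:g}) must be below top ({self.top:g})"
            )
        if not (0.0 <= self.bottom <= 1.0 and 0.0 <= self.top <= 1.0):
            raise ValueError("asymptotes must lie within [0, 1]")
        if not self.hill > 0:
            raise ValueError("hill must be positive for an increasing curve")

    @property
    def span(self) -> float:
        return self.top - self.bottom

    def evaluate(self, psi_mV):
        return four_param_logistic(psi_mV, self.bottom, self.top, self.v50_mV, self.hill)

    def parameters(self) -> np.ndarray:
        return np.array([self.bottom, self.top, self.v50_mV, self.hill])

    # -- serialization -----------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "bottom": self.bottom,
            "top": self.top,
            "v50_mV": self.v50_mV,
            "hill": self.hill,
            "covariance": None if self.covariance is None else np.asarray(self.covariance).tolist(),
            "domain_mV": [float(self.domain_mV[0]), float(self.domain_mV[1])],
            "fbl_ceiling": None if np.isnan(self.fbl_ceiling) else self.fbl_ceiling,
            "library_normalization": self.library_normalization,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            bottom=d["bottom"],
            top=d["top"],
            v50_mV=d["v50_mV"],
            hill=d["hill"],
            covariance=None if d.get("covariance") is None else np.asarray(d["covariance"]),
            domain_mV=tuple(d.get("domain_mV", (-np.inf, np.inf))),
            fbl_ceiling=d["fbl_ceiling"] if d.get("fbl_ceiling") is not None else np.nan,
            library_normalization=d.get("library_normalization"),
        )


@dataclass(frozen=True)
class PotentialEstimate:
    """An inverse-calibration result; possibly a censored bound.

    ``censored == "above"`` means the true potential is *at least*
    ``delta_psi_mV`` (pinned to the domain upper bound); ``"below"`` is the
    mirror case.
    """

    delta_psi_mV: float
    censored: str = "none"
    ci_mV: tuple[float, float] | None = None

    def __post_init__(self):
        if self.censored not in ("none", "above", "below"):
            raise ValueError("censored must be one of none/above/below")


class SigmoidCalibration:
    """Variable-slope 4PL calibration estimator (scikit-learn conventions).

    ``fit(psi, fbl)`` estimates (bottom, top, v50, hill) by least squares
    with a fixed, deterministic multi-start grid; ``predict(psi)`` evaluates
    the sigmoid; ``inverse_predict(fbl)`` returns (possibly censored)
    potential estimates.

    Parameters
    ----------
    margin : float
        Asymptote guard for inverse prediction, as a fraction of the fitted
        span (default 0.01).
    hill_starts : tuple of float
        Initial slope values tried in fixed order.
    maxfev : int
        Per-start function-evaluation budget for the optimizer.
    """

    def __init__(self, margin: float = 0.01, hill_starts=(0.01, 0.03, 0.1), maxfev: int = 10000):
        self.margin = margin
        self.hill_starts = hill_starts
        self.maxfev = maxfev

    def get_params(self, deep: bool = True) -> dict:
        return {"margin": self.margin, "hill_starts": self.hill_starts, "maxfev": self.maxfev}

    def set_params(self, **params) -> "SigmoidCalibration":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, psi_mV, fbl, sample_weight=None) -> "SigmoidCalibration":
        psi = np.asarray(psi_mV, dtype=float)
        y = np.asarray(fbl, dtype=float)
        if psi.shape != y.shape or psi.ndim != 1:
            raise ValueError("psi and fbl must be matching 1-D arrays")
        if psi.size < 6:
            raise CalibrationError(f"need >= 6 calibration points, got {psi.size}")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("fbl values must lie within [0, 1]")
        if np.ptp(y) < 1e-6:
            raise DegenerateFitError(
                "fbl is constant across calibration points; bottom and top "
                "are not identifiable"
            )
        sigma = None
        if sample_weight is not None:
            w = np.asarray(sample_weight, dtype=float)
            sigma = 1.0 / np.sqrt(w)
        lo_q, hi_q = np.quantile(y, [0.05, 0.95])
        b0 = max(lo_q - 0.02, 0.0)
        t0 = min(hi_q + 0.02, 1.0)
        v0 = float(np.median(psi))
        bounds = ([0.0, 0.0, -1000.0, 1e-6], [1.0, 1.0, 1000.0, 1000.0])
        best = None
        diagnostics = []
        for hill0 in self.hill_starts:
            p0 = [b0, t0, v0, hill0]
            try:
                popt, pcov = curve_fit(
                    four_param_logistic,
                    psi,
                    y,
                    p0=p0,
                    sigma=sigma,
                    absolute_sigma=False,
                    bounds=bounds,
                    maxfev=self.maxfev,
                )
            except (RuntimeError, ValueError) as exc:  # non-convergence of one start
                diagnostics.append((p0, str(exc)))
                continue
            ssr = float(np.sum((four_param_logistic(psi, *popt) - y) ** 2))
            if best is None or ssr < best[0] - 1e-15:
                best = (ssr, popt, pcov)
        if best is None:
            raise CalibrationError(
                f"4PL fit failed to converge from all starts: {diagnostics}"
            )
        ssr, popt, pcov = best
        bottom, top, v50, hill = popt
        if top - bottom < 1e-6:
            raise DegenerateFitError(
                "fitted span collapsed (bottom == top); data do not define a sigmoid"
            )
        at_bound = bool(
            np.any(np.isclose(popt, bounds[0], atol=1e-9))
            or np.any(np.isclose(popt, bounds[1], atol=1e-9))
        )
        domain = (float(psi.min()), float(psi.max()))
        curve = CalibrationCurve(
            bottom=float(bottom),
            top=float(top),
            v50_mV=float(v50),
            hill=float(hill),
            covariance=pcov,
            domain_mV=domain,
            fbl_ceiling=float(four_param_logistic(domain[1], *popt)),
        )
        self.curve_ = curve
        self.ssr_ = ssr
        self.at_bound_ = at_bound
        self.n_points_ = psi.size
        return self

    def _require_fit(self) -> CalibrationCurve:
        if not hasattr(self, "curve_"):
            raise CalibrationError("SigmoidCalibration is not fitted")
        return self.curve_

    def predict(self, psi_mV):
        return self._require_fit().evaluate(psi_mV)

    def inverse_predict(self, fbl) -> list[PotentialEstimate]:
        curve = self._require_fit()
        arr = np.atleast_1d(np.asarray(fbl, dtype=float))
        return [invert_curve(curve, float(v), margin=self.margin) for v in arr]


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_calibration(
    points: Sequence[CalibrationPoint] | pd.DataFrame,
    margin: float = 0.01,
    weighted: bool = False,
) -> CalibrationCurve:
    """Fit the 4PL calibration from condition-mean points (unweighted default)."""
    if isinstance(points, pd.DataFrame):
        psi = points["delta_psi_mV"].to_numpy(float)
        y = points["fbl"].to_numpy(float)
        w = points["weight"].to_numpy(float) if "weight" in points else None
    else:
        psi = np.array([p.delta_psi_mV for p in points])
        y = np.array([p.fbl for p in points])
        w = np.array([p.weight for p in points])
    est = SigmoidCalibration(margin=margin)
    est.fit(psi, y, sample_weight=w if weighted else None)
    return est.curve_


def evaluate_curve(curve: CalibrationCurve, psi_mV):
    """Closed-form 4PL evaluation (defined on all of R)."""
    return curve.evaluate(psi_mV)


def invert_curve(curve: CalibrationCurve, fbl: float, margin: float = 0.01) -> PotentialEstimate:
    """Closed-form inverse prediction with asymptote-guard censoring.

    fb_L values within ``margin * span`` of an asymptote, or implying a
    potential outside the calibrated domain, are returned as censored
    bounds pinned to the corresponding domain endpoint.
    """
    if not 0.0 <= fbl <= 1.0:
        raise DomainError(f"fbl must be within [0, 1], got {fbl}")
    guard = margin * curve.span
    lo_dom, hi_dom = curve.domain_mV
    if fbl >= curve.top - guard:
        return PotentialEstimate(delta_psi_mV=hi_dom, censored="above")
    if fbl <= curve.bottom + guard:
        return PotentialEstimate(delta_psi_mV=lo_dom, censored="below")
    ratio = curve.span / (fbl - curve.bottom) - 1.0
    psi = curve.v50_mV - np.log10(ratio) / curve.hill
    if psi > hi_dom:
        return PotentialEstimate(delta_psi_mV=hi_dom, censored="above")
    if psi < lo_dom:
        return PotentialEstimate(delta_psi_mV=lo_dom, censored="below")
    return PotentialEstimate(delta_psi_mV=float(psi), censored="none")


def confidence_band(
    curve: CalibrationCurve,
    points: Sequence[CalibrationPoint] | pd.DataFrame,
    grid_mV,
    level: float = 0.95,
    B: int = 500,
    seed: int | None = None,
    max_failure_fraction: float = 0.10,
) -> pd.DataFrame:
    """Pointwise case-resampling bootstrap confidence band for the curve.

    Refits the 4PL on ``B`` resampled point sets (each refit initialized at
    the original fit for speed and determinism) and returns percentile
    bands on ``grid_mV``.
    """
    if B < 200:
        raise ValueError("B must be >= 200 for a stable percentile band")
    if isinstance(points, pd.DataFrame):
        psi = points["delta_psi_mV"].to_numpy(float)
        y = points["fbl"].to_numpy(float)
    else:
        psi = np.array([p.delta_psi_mV for p in points])
        y = np.array([p.fbl for p in points])
    rng = np.random.default_rng(seed)
    grid = np.asarray(grid_mV, dtype=float)
    n = psi.size
    curves = np.empty((B, grid.size))
    p_orig = curve.parameters()
    bounds = ([0.0, 0.0, -1000.0, 1e-6], [1.0, 1.0, 1000.0, 1000.0])
    failures = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            if np.ptp(y[idx]) < 1e-9:
                raise RuntimeError("degenerate resample")
            popt, _ = curve_fit(
                four_param_logistic,
                psi[idx],
                y[idx],
                p0=p_orig,
                bounds=bounds,
                maxfev=5000,
            )
            curves[b] = four_param_logistic(grid, *popt)
        except (RuntimeError, ValueError):
            failures += 1
            curves[b] = np.nan
    if failures > max_failure_fraction * B:
        raise CalibrationError(
            f"{failures}/{B} bootstrap refits failed (> {max_failure_fraction:.0%})"
        )
    alpha = 1.0 - level
    lo = np.nanpercentile(curves, 100 * alpha / 2, axis=0)
    hi = np.nanpercentile(curves, 100 * (1 - alpha / 2), axis=0)
    return pd.DataFrame(
        {
            "delta_psi_mV": grid,
            "fbl_fit": curve.evaluate(grid),
            "fbl_lo": lo,
            "fbl_hi": hi,
        }
    )
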