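# Methods

This note documents the models implemented in `mitopsi`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer would want recorded.

## Optical model

Raw records hold transmitted-light counts `T(λ, t)` (1 spectrum/s),
a daily incident spectrum `I₀(λ)` and the spectrometer dark current
`D(λ)`.  Absorbance is

    A(λ) = log10((I₀(λ) − D(λ)) / (T(λ) − D(λ))).

The dark current is subtracted from *both* intensities.  Whether the
stored `I₀` is already dark-corrected is ambiguous in practice; symmetric
treatment is the only convention for which an empty light path gives
A ≡ 0, so it is fixed here.  Non-positive dark-corrected counts raise an
error naming the offending wavelengths rather than being clipped: they
indicate saturated or blocked channels, and silent clipping would bias
every downstream coefficient.

Two instrument grids are built in: 1,044 points over 348–745 nm
(suspension spectrometer) and 1,024 points over 400–800 nm (heart
spectrometer).  Reference libraries are resampled (linear interpolation,
no smoothing) onto the experimental grid, never the reverse, so raw data
are never altered.

## Unmixing

Over the α band the absorbance is modelled as a linear combination of
reduced-chromophore reference spectra plus a line:

    A(λ) = a·b_H(λ) + b·b_L(λ) + c·c₁(λ) + d·cytc(λ) + e·λ + f.

The line absorbs residual scattering and the weak, featureless absorbance
of oxidized cytochromes.  The model is linear in its coefficients, so the
least-squares solution is computed directly (`lstsq`/QR) — deterministic,
and testable against the normal-equations closed form, which an iterative
NLS routine would also have to reach.  Fit bands: 540–580 nm for
myoglobin-free spectra; 535–585 nm when MbO/MbD are co-fit (wild-type
heart).  Coefficients are unconstrained by default; an optional
non-negative mode (`nonneg=True`, bounded least squares on the chromophore
terms only) exists for noisy low-signal data.  Rank-deficient designs
(condition number > 1e10) are refused outright rather than regularized:
ridge shrinkage would silently bias fb_L.

**Reference normalization.** The empirical reference spectra have
arbitrary absolute OD (they come from biochemical derivations, not known
concentrations), so a convention must be fixed: every library member is
normalized to unit peak OD within the fit band, and the convention is
stamped on the library.  Under unit-peak normalization the chromophore
amplitude (coefficient × peak OD) equals the raw coefficient.  A
calibration curve records the stamp of the library it was built with and
refuses to be applied with a differently normalized one — calibration and
application must share the convention or fb_L values are not comparable.

**fb_L.** `fb_L = b_L/(b_L + b_H)` using peak-OD amplitudes.  Because it
is a ratio of amplitudes from the same spectrum, uniform path-length
changes (tissue geometry, hypercontracture) cancel exactly; this is tested
to 1e-10 at scale factors 0.5–10.  Negative amplitudes are arithmetically
tolerated but flagged for QC; a zero b-heme sum is an error.

**Quality statistic.** `snr = (a + b + c + d) / SSR` — the summed
calculated absorbances (peak-OD amplitudes) of the four quartet
chromophores over the sum of squared residuals, with exclusion below 100.
The phrase "summed calculated absorbances" admits two readings: the four
scalar amplitudes, or the band-integrated component spectra (whose scale
grows with grid density).  The amplitude sum is the default and is the
convention under which the threshold of 100 separates usable from
unusable fits at physiological absorbance scales: at transmural-tissue
amplitudes (≈0.5 OD per chromophore) snr = 100 corresponds to residuals
large enough to leave fb_L errors near 0.06, while snr ≈ 1,000 brings the
fb_L RMSE to ≈0.012.  Under the band-sum convention no physically
plausible absorbance scale gives usable fb_L at snr within an order of
magnitude of 100 (the error scales as 1/√amplitude and would require
OD ≈ 10), so that reading is provided only as an option
(`snr_numerator="band_sum"`).  Myoglobin terms never enter the numerator.

## Electrode processing

TPMP⁺ and TPP⁺ distribute Nernstianly; the probe name is metadata and the
arithmetic is identical.  The electrode is calibrated in the presence of
de-energized mitochondria by stepwise additions (default six equal steps
to 2.17 µM total in a 5.5 ml bath); each addition defines a plateau
(settling exclusion 10 s, then mean to the next event — adequate and
deterministic for 1 Hz traces), and `V = intercept + slope·log10(c)` is
fit through the plateau pairs.

Conversion of a voltage trace:

    c_out(t) = 10^((V − intercept)/slope)                    [µM]
    uptake(t) = (total − c_out)·volume                        [nmol]
    c_in(t)  = uptake/protein × 0.17                          [nmol/µl = mM]
    ΔΨ_m(t)  = 61.5 · log10(c_in / (c_out/1000))              [mV]

The unit chain matters and is deliberately explicit: uptake per mg protein
(nmol/mg) times the binding correction (mg protein/µl) yields nmol/µl =
mM, while c_out is in µM and is converted to mM before the ratio.  The
binding correction of 0.17 mg protein µl⁻¹ is applied verbatim as a lumped
empirical factor; whether it is an apparent-volume correction in the
Brand tradition or a pure binding factor does not change the arithmetic.

Apparent negative uptake within 2% of the total probe content is clipped
to zero and flagged (electrode noise); beyond 2% it is an error (wrong
calibration or total).  For steady-state plateau values use
`plateau_potential`, which averages the voltage *before* the log-domain
conversion — at low potentials (small depletion) per-sample conversion
amplifies noise badly and can hit the clip.

Default suspension conditions: 2.17 µM probe, 5.5 ml bath, 6 mg protein
(suspensions of ~2 nmol cytochrome a+a₃ per ml at the measured
protein-to-oxidase ratio of ≈0.55 mg/nmol give ≈1.1 mg/ml).  At 6 mg the
probe depletion at ΔΨ_m = 60 mV is ≈6%, enough to condition the recovery;
noise-free recovery is exact to <1e-13 mV and 0.2 mV plateau noise keeps
worst-case errors under ~2 mV across 60–180 mV.

## Sigmoid calibration

The fb_L ↔ ΔΨ_m relation is fit with the variable-slope four-parameter
logistic in decade form, abscissa in untransformed mV:

    fbl(ψ) = bottom + (top − bottom)/(1 + 10^((v50 − ψ)·hill)).

Base-10 versus base-e is a pure reparametrization of `hill`; the decade
form matches the dose–response convention the curve shape was originally
fit in.  Points are unweighted by default (condition means with
unknown replicate variances).  Fitting uses `scipy.optimize.curve_fit`
from a fixed multi-start grid — bottom/top from the 5/95% data quantiles,
v50 from the median ψ, hill ∈ {0.01, 0.03, 0.1} per mV, tried in fixed
order with the best SSR kept — making the fit deterministic and
order-invariant.  Constant fb_L is rejected as degenerate (bottom = top is
not identifiable).  The covariance comes from the final Jacobian.

**Inverse prediction and censoring.**  The closed-form inverse is used on
the curve interior.  Within a guard margin (default 1% of the span) of
either asymptote, or when the implied ψ falls outside the calibrated
domain (the observed ψ range of the calibration points), the estimate is
returned *censored*: pinned to the domain bound with a direction flag.  A
censored-above estimate means "at least this potential" — the highest
calibrated value — mirroring how potentials beyond a standard curve can
only be bounded, not measured.  Downstream summaries never average
censored values: a window containing censored-above rows reports a lower
bound; mixed directions are reported indeterminate.

**Uncertainty.** Pointwise confidence bands use a case-resampling
bootstrap (refits initialized at the original solution; ≥200 replicates;
percentile band; error if >10% of refits fail).  Bootstrap was chosen
over the delta method because the inverse is strongly nonlinear near the
asymptotes, exactly where censoring matters.  At n = 23 calibration
points the 95% percentile band undercovers slightly (measured ≈90–92%
pointwise coverage across simulation replicates), a known small-sample
property of percentile bands; the band is reported as-is rather than
inflated.

## Ischemia–reperfusion pipeline

`run_pipeline` composes absorbance → trailing rolling average (default 4
consecutive spectra, matching 1 Hz acquisition; trailing because the
chain is causal/real-time) → unmixing → SNR flagging → fb_L → censored
inverse calibration, one row per averaged spectrum.  Excluded rows carry
no potential estimate.  Output tables are deterministic to the byte for
fixed inputs.

Checkpoint summaries use 30 s windows centered on named offsets (the
averaging windows behind "1 min of reperfusion"-style values are not
standardized; 30 s is wide enough to average noise and narrow enough not
to straddle transients).

**Secondary-decline detection** (the late ischemic event): the ΔΨ_m trace
is smoothed (centered moving average, default 5 s) and its slope is
estimated by a centered difference across ±5 s — a 2-sample gradient at
1 Hz is far too noisy to threshold.  The first sustained near-flat run
(|slope| ≤ 0.05 mV/s for 60 s) marks the ischemic plateau; the event is
the earliest later time with slope below the threshold.  The default
threshold is −0.1 mV/s: the phenomenon itself (a fall of ~40 mV over a
few minutes) has slopes of −0.1 to −0.3 mV/s, so a much stricter
threshold would never fire.  This is a descriptive detector with exposed
parameters, not formal changepoint inference.

**Heart rate** counts flow-wave peaks (each wave = one beat) over a
trailing one-minute window, after a light 20 ms moving-average low-pass so
wideband sensor noise does not masquerade as beats.  **Metabolite
utilities** implement ratio-to-internal-standard quantification
(succinate), percent reduction `100·QH₂/(QH₂+Q)` (CoQ pool), and
shape-preserving monotone cubic (PCHIP) interpolation for sparse
timecourses — PCHIP because ordinary cubic splines overshoot between
sparse biochemical timepoints.

Path-length artifacts (hypercontracture) are deliberately *not* corrected
in the cytochrome c amplitude — they are reported as apparent amplitude
changes — while fb_L needs no correction by construction.

## Synthetic data

Generators emulate every upstream input with known ground truth:

* **Reference libraries** — Gaussian sub-bands at the documented peaks
  (cyt c 550, c₁ 552, b_H 562, b_L 564 nm with a 0.35-height shoulder at
  558 nm; MbO twin bands 542/580 nm, MbD broad 556 nm), unit-peak
  normalized; the unmixing design's condition number is reported, and
  near-coincident centers trigger a collinearity warning.
* **Spectral records** — Eq.-style forward model to absorbance, converted
  to counts against a smooth tungsten-like `I₀` (≈12,000–32,000 counts)
  and dark level 400, with Gaussian *count-domain* noise — matching the
  physical instrument and inducing the heteroscedasticity the SNR rule
  must handle.
* **Electrode traces** — ideal Nernstian electrode (default slope
  59 mV/decade, intercept −10 mV), six-step calibration, then stepped-ψ
  plateaus with the external concentration from the closed-form mass
  balance `c_out = total·V/(V + R·protein/(1000·binding))`,
  `R = 10^(ψ/61.5)`.
* **Scenarios** — a titration experiment pairing both instruments (the
  calibration-curve construction route), and an ischemia–reperfusion
  scenario: control plateau 166 mV → exponential drop (τ = 20 s) to the
  133 mV ischemic plateau → linear secondary decline to 92 mV starting
  13 min into ischemia → exponential reperfusion rebound toward 157 mV;
  cytochrome c amplitude rises during ischemia (reduction under anoxia)
  and reverts on reperfusion; a path-length multiplier (default ×1.3 over
  60 s) ramps in at the hypercontracture event, scaling all chromophore
  coefficients equally.

Amplitude scales: ≈0.05 OD per chromophore for suspension scenarios,
≈0.5 OD (b-heme total) for transmural heart scenarios — tens of µM
cytochrome over ≈1 cm of tissue.  Myoglobin, when present, dominates at
≈0.8 OD.

Every generator is seed-deterministic and emits a truth table aligned
row-for-row with its data product.

**What the generators do not emulate** — and hence what passing tests do
not demonstrate about real data: wavelength-dependent scattering beyond
the linear baseline term, instrument line-shape and wavelength-calibration
drift, electrode drift and probe toxicity, empirical reference band
shapes (real references are asymmetric; Gaussians are a stand-in, and
band-shape mismatch between generator and fitting library is *not*
explored by the default tests), hemodynamic motion artifacts, and
plasma-membrane potential contamination.  Recovery results on synthetic
data are therefore a check of the inference chain's correctness, not of
its robustness to instrument pathology.

## Problem sizes

The test suite and acceptance script size their simulations for a
single-CPU run: 1,000 spectra for the oracle-equivalence study, 200
replicates for the noisy fb_L study, 100 seeds × 5 levels for the
electrode study, 300 replicates for 4PL bias and 100 replicates × 200
bootstrap refits for band coverage, and one 50-minute 1 Hz record (2,997
fitted rows) for the full scenario.  All are large enough that the Monte
Carlo error is well below the tolerance being checked.

## Known limitations

* The sigmoid calibration assumes a single curve across conditions; no
  hierarchical (per-replicate) calibration is provided.
* The censoring domain is the observed calibration range; extrapolating
  the sigmoid beyond it is deliberately unsupported.
* The secondary-decline detector requires a discernible plateau before
  the event; monotone declines return no event by design.
* Temperature dependence of the Nernst slope is not modelled (61.5
  mV/decade is the 37 °C value and is used as a constant).
* The SNR exclusion threshold is convention- and scale-dependent; it is
  configurable and the convention is stamped in the documentation above.
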