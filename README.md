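# mitopsi

Optical estimation of mitochondrial membrane potential (ΔΨ_m) from
cytochrome *b*-heme absorbance spectroscopy, with the supporting electrode
calibration, sigmoid calibration-curve machinery and an end-to-end
ischemia–reperfusion analysis pipeline.

## The problem

ΔΨ_m — the electrical potential across the inner mitochondrial membrane —
drives ATP synthesis, but classical probes (TPMP⁺/TPP⁺ electrodes,
potentiometric dyes) cannot report it continuously in intact tissue.  The
cytochrome *bc*₁ complex offers an endogenous readout: its two *b* hemes,
*b*_L (low reduction potential, outer face) and *b*_H (high potential,
matrix face), exchange electrons across the membrane, so their relative
reduction depends on ΔΨ_m.  Both hemes absorb in the α band (540–580 nm)
with distinct spectra (peaks at 564 and 562 nm), as do cytochromes *c*
(550 nm) and *c*₁ (552 nm).

`mitopsi` implements the full inference chain:

1. **Absorbance** from raw spectrometer counts:
   `A(λ) = log10((I₀ − D) / (T − D))`, with symmetric dark-current
   correction.
2. **Spectral unmixing** over the α band (linear least squares, QR):

   `A(λ) = a·b_H(λ) + b·b_L(λ) + c·c₁(λ) + d·cytc(λ) + e·λ + f`

   with optional MbO/MbD terms (band widened to 535–585 nm) for
   myoglobin-containing tissue, and an SNR-based quality rule
   (Σ quartet amplitudes / SSR, exclusion below 100).
3. **fb_L = b_L / (b_L + b_H)** — a normalized statistic insensitive to
   optical path length (tissue geometry, contracture).
4. **Electrode ground truth**: Nernstian TPMP⁺ electrode calibration from
   stepwise additions, uptake accounting with the 0.17 mg protein µl⁻¹
   binding correction, and `ΔΨ_m = 61.5·log10([TPMP⁺]_in/[TPMP⁺]_out)` mV.
5. **4PL calibration** fb_L ↔ ΔΨ_m (variable-slope decade logistic) with
   bootstrap confidence bands and *censored* inverse prediction outside
   the calibrated range.
6. **Ischemia–reperfusion pipeline**: rolling average (4 spectra at 1 Hz)
   → unmixing → QC → fb_L → calibrated ΔΨ_m time series, phase summaries,
   secondary-decline event detection, heart rate from pulsatile flow, and
   metabolite ratio utilities.

No raw experimental data ship with the package; the `mitopsi.synthetic`
module generates every input (reference libraries, noisy records,
electrode traces, calibration points, full scenarios) with known ground
truth, which is how the test suite closes the simulate → infer → compare
loop.

## Worked example

```python
import numpy as np
import mitopsi as m
from mitopsi import synthetic as syn

library, info = syn.make_reference_library()
record, truth = syn.simulate_ir_experiment(
    control_s=300, ischemia_s=900, reperfusion_s=300,
    noise_sigma_counts=10.0, seed=11,
    trajectory_kwargs={"secondary_onset_s": 300 + 8 * 60},
)

points = syn.make_calibration_points(np.linspace(60, 208, 23), noise_sd=0.01, seed=1)
curve = m.fit_calibration(points)

timeline = m.ExperimentTimeline.standard(300, 900, 300)
series = m.run_pipeline(record, library, curve, timeline=timeline, window=4)
summary = m.phase_summary(series, [("control", 150.0), ("ischemia_10min", 900.0),
                                   ("reperfusion_4min", 1440.0)], window_s=30.0)
```

Output:

```
4PL fit: bottom=0.151 top=0.652 v50=140.3 mV hill=0.0293 /mV
         control: fb_L = 0.579, delta-psi = 166.5 mV (mean, n=31)
  ischemia_10min: fb_L = 0.216, delta-psi = 111.9 mV (mean, n=31)
reperfusion_4min: fb_L = 0.532, delta-psi = 157.4 mV (mean, n=31)
secondary decline detected at t = 780 s (injected at 780 s); minimum 87.6 mV
```

The fitted sigmoid recovers the generating parameters (bottom 0.15, top
0.65, v50 140 mV, hill 0.03/mV); the pipeline recovers the injected
control plateau (166 mV), tracks the ischemic decline, and pinpoints the
injected secondary-decline event.  fb_L values beyond the calibrated
sigmoid's reliable range come back as censored bounds ("at least X mV"),
and summaries over windows containing censored rows report bounds, never
means.

A `mitopsi` command-line tool exposes the same stages
(`simulate`, `fit`, `calibrate`, `invert`, `pipeline`); run
`mitopsi --help`.

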