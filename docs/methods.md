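# Methods

## The measurement model

The simulator emulates a dispersive Raman instrument measuring liquid
samples in a quartz cuvette. A pixel index p on the CCD maps to a Raman
shift w(p) through a smooth polynomial (default quadratic,
w(p) = 400 + 1.45·p − 5·10⁻⁵·p² over 1024 pixels, spanning roughly
400–1830 cm⁻¹ and strictly increasing by construction). Three kinds of
acquisitions are produced:

- **Toluene** — six Lorentzian reference lines of unit amplitude at the
  literature band positions, used only for calibration.
- **Distilled water** — a broad Lorentzian centered at 1640 cm⁻¹
  (FWHM 200 cm⁻¹, amplitude 0.5) plus a gentle linear cuvette term; no
  narrow features.
- **Serum** — six Lorentzian bands (default FWHM 10 cm⁻¹) at 1005, 1156,
  1239, 1450, 1520 and 1650 cm⁻¹ with amplitudes (1.0, 0.7, 0.5, 0.8, 0.6,
  0.9), a 4th-order polynomial fluorescence baseline that is positive and
  slowly decaying across the span, and the water/cuvette background.

Lorentzian line shapes are the natural choice for Raman bands; widths and
amplitudes are free parameters of the simulator, chosen to give
realistic-looking serum spectra with band-to-baseline ratios well below 1
(fluorescence dominates raw serum spectra, which is why baseline correction
matters).

Disease is modelled as a multiplicative attenuation of the two carotenoid
bands (1156, 1520 cm⁻¹) in the patient group — patients' amplitudes are
scaled by (1 − a) with a = 0.3 by default. Between-subject biological
variability is a log-normal factor (σ = 0.15) drawn per subject and band.
Detector noise is i.i.d. Gaussian (σ = 0.01 intensity units per point and
scan). Cosmic rays arrive as a Poisson process (default 0.1 spikes per
scan), 1–2 pixels wide, with amplitude 30× the tallest serum band jittered
±20%. All injected quantities — the calibration map, spike coordinates,
contaminated-scan indices, per-subject amplitudes, the baseline — are
recorded as ground truth.

The attenuation size and band amplitudes are simulator conventions, not
measured values: no public data exist to calibrate them, so they are free
parameters chosen once for plausibility. What the simulator deliberately
omits: photon-count (shot) noise scaling with exposure, wavelength-dependent
instrument response, peak-position drift, water-band shape changes between
serum and reference, and any biochemical covariance structure between
bands. Consequently, passing tests demonstrate that the *pipeline* recovers
what it is designed to recover under the stated noise model — not that the
classification performance would transfer to real sera.

## Pre-processing

Order of operations per measurement: calibrate → despike → cull → average
scans; then per subject: average measurements → subtract water background →
subtract spline baseline → vector-normalize. Processing state is tracked on
each spectrum and enforced, so e.g. a baseline correction on a spectrum
whose background has not been subtracted raises an error.

- **Peak detection** — local maxima ranked by prominence; apexes refined by
  a 3-point parabolic fit (bias < 0.01 px on a 10 cm⁻¹ FWHM Lorentzian).
- **Calibration fit** — least-squares polynomial, degree 2 by default
  (configurable 1–3); the fitted map must be strictly increasing over the
  calibrated range, and residuals per reference band are stored. All scans
  are linearly interpolated onto a common 1 cm⁻¹ grid over 450–1729 cm⁻¹
  (the widest candidate region).
- **Despiking** — per grid point, |x − median| across scans is compared to
  8 robust standard deviations (1.4826 × MAD). At 14 scans this yields a
  measured false-positive rate of ~1.6·10⁻⁴ on clean Gaussian data while
  flagging 30×-amplitude spikes essentially always. A spike hitting the
  same pixel in *every* scan contaminates the median and is not detected —
  a structural limitation of cross-scan despiking. Fewer than 3 scans is
  rejected rather than silently falling back to single-scan heuristics.
- **Scan culling** — "higher variance" is operationalized as the summed
  squared deviation from the cross-scan mean; the worst 4 of 14 scans are
  dropped, ties keeping the earlier scan. Kept scans are never modified.
- **Background subtraction** — plain 1:1 subtraction of the averaged water
  spectrum (no scaling factor); negative values are allowed.
- **Baseline** — a not-a-knot cubic spline through the spectrum's values at
  12 fixed anchor wavenumbers (identical for every sample in a run, for
  objectivity). Default anchors: 455, 600, 700, 800, 900, 960, 1080, 1310,
  1400, 1580, 1700, 1725 cm⁻¹ — placed in the band-free zones of the
  simulated serum model and recorded in the run configuration. A not-a-knot
  spline reproduces cubic polynomials exactly, and on 12 anchors ~100 cm⁻¹
  apart its approximation error for the smooth quartic baseline is
  negligible (≪ 1% RMS); the practical error floor is the Lorentzian tail
  leaking into anchor positions.
- **Normalization** — division by the Euclidean norm, applied over the full
  processed span *before* region truncation (normalize-then-truncate order).

## Features and classification

PCA uses mean centering only — rows are already unit-norm spectra, and
per-column autoscaling would inflate noise in flat regions. Components are
computed by SVD of the centered training matrix; the retained count is the
smallest n whose cumulative variance share reaches the TVE threshold
(default 95%). Loading signs are fixed (largest-magnitude element positive)
to make outputs reproducible. The retained-count rule, not any particular
count, is the contract: simulated cohorts typically need 4–8 components
depending on noise and cohort size.

Classifier presets: 1-NN Euclidean; 10-NN with squared-inverse-distance
votes (a coincident query point gets a capped-but-dominant weight via a
10⁻¹² distance floor); SVMs with polynomial kernels of degree 2 and 3,
C = 1, coef0 = 1, `gamma="scale"`, on training-standardized features.
Residual vote ties resolve to "control" (the negative class). These mirror
the common "fine"/"weighted" kNN and "quadratic"/"cubic" SVM presets of
GUI classification tools; all hyperparameters are configurable.

Cross-validation is stratified 5-fold with shuffling, and the PCA is refit
on each fold's training part — the selection and accuracy estimates contain
no feature-extraction leakage. Region selection runs 10 independent CV
repetitions (fresh fold seeds drawn from the master seed) per
region × family cell and picks the region of the best cell by mean
accuracy; ties go to the wider region. No multiple-testing correction is
applied across the 16 cells — selection is by raw mean accuracy, and the
reported per-cell SDs make the repetition noise visible.

The 85/15 split is stratified with proportional rounding by default. The
published 41/39 vs 8/6 partition of a 49/45 cohort is *not* an exact 85%
stratification, so explicit target counts can be supplied to reproduce such
a partition exactly.

Metrics treat "patient" as positive. A metric whose denominator is zero
(e.g. PPV with no positive predictions) is flagged undefined rather than
forced to 0 or 100.

## Determinism and numerics

A single master seed drives everything: child seeds for the toluene, water
and cohort simulations, fold shuffling, region-selection repetitions and
the train/test split are derived through `numpy.random.SeedSequence`
spawning (all below 2³¹). Identical configuration + seed gives bit-identical
run reports. Calibration span checks tolerate a 10⁻⁹ relative float
residue; the TVE threshold comparison uses a 10⁻⁹ slack so that an exact
cumulative hit (e.g. 60+30 ≥ 90) retains the minimal count.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data at
the study's own scale: 94-subject cohorts (49/45) with 2 × 14 scans of 1024
pixels for end-to-end runs, 200 subjects for the null-calibration check,
and 100-block ensembles for the artifact-rejection rates. A full
end-to-end run (4 regions × 4 families × 10 CV repetitions) completes in
well under a minute on one CPU.

## Known limitations

- The despiker cannot detect a spike replicated across all scans at one
  pixel, and the culling score conflates high noise with genuine intensity
  drift.
- Water subtraction is unscaled; if the real water path length differed
  between reference and serum acquisitions, a scaled fit would be needed.
- Anchor placement assumes band-free zones are known; on real sera with a
  different band set the default anchors should be re-examined.
- Simulated test-set performance (often 100%) reflects the simulator's
  clean separability at the default effect size, not expected clinical
  performance.
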