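# Methods

## Scope and signal path

The package quantifies spontaneous cardiac baroreflex sensitivity (cBRS)
and heart-rate variability (HRV) from short resting recordings. The
chain is:

1. **Beat detection.** R peaks from a lead-II ECG; per-cardiac-cycle
   systolic (max), diastolic (min) and mean (time-average) pressure from
   the continuous arterial waveform; breaths from respiratory flow.
2. **Beat series.** RR intervals (ms) aligned with per-cycle SBP (mmHg),
   artifact/ectopy flagging, suitability decision.
3. **Resampling.** Natural cubic spline through valid beats, sampled at
   4 Hz (no extrapolation beyond the first/last valid beat).
4. **Spectra.** Welch auto/cross spectra of the SBP and RR tracks;
   transfer-function gain/phase/coherence; VLF/LF/HF band means; the
   LF-band mean gain is the cBRS index.
5. **HRV.** RMSSD and pNN50 on the raw beat series; band powers,
   normalized units and LF/HF integrated from the same RR autospectrum
   used by the transfer-function stage (one spectral code path).

The method assumes approximate stationarity over the analyzed span and
sinus rhythm; frequent ectopy invalidates the spontaneous-baroreflex
interpretation, which is why flagging and the suitability gate exist.

## Spectral estimation details

* **Segmentation.** For K segments at 50% overlap the segment length is
  L = floor(2N/(K+1)), forced even; K = 5 by default. A 5-min record at
  4 Hz (N = 1200) gives 100 s segments and 0.01 Hz resolution. This is
  the unique length that covers the whole record with K half-overlapping
  segments.
* **Per segment:** least-squares linear detrend, periodic Hann taper,
  FFT. One-sided densities are averaged over segments and normalized by
  fs·Σw², so the integrated autospectrum equals the detrended,
  window-corrected signal variance (verified against a direct-DFT
  re-implementation to 1e-9 and by a Parseval identity check).
* **Cross-spectrum convention** is conj(X)·Y with SBP as input, so a
  delayed RR response produces negative phase (RR lags SBP), matching
  the reporting convention for baroreflex phase.
* **Bands** are half-open [lo, hi): VLF (0, 0.04), LF [0.04, 0.15), HF
  [0.15, 0.40] with the HF upper edge closed and the DC bin excluded —
  every bin belongs to exactly one band. Band statistics are unweighted
  means of per-bin gain/phase/coherence (the mean-of-bins reading; the
  gain-of-averaged-spectra alternative is deliberately not the default).
  No coherence threshold is applied by default; `coherence_min` enables
  the thresholded variant, and a band emptied by the gate reports a
  missing value with its bin count, never zero.
* **Degenerate inputs.** Where the SBP autospectrum is numerically zero
  (below 1e-20 mmHg²/Hz or 1e-12 of its maximum), gain, phase and
  coherence are reported missing rather than infinite. Band powers below
  1e-12 ms² make normalized units and LF/HF missing rather than
  meaningless ratios.

## HRV conventions

* RMSSD = sqrt(mean((rr_{k+1} − rr_k)²)); pNN50 uses the strict
  "> 50 ms" comparison and the number of successive pairs as the
  denominator. Difference pairs spanning a flagged beat are excluded
  (a flag allows including them).
* Time-domain metrics use the raw, unevenly sampled beat series;
  frequency-domain metrics use the 4 Hz resampled series — interpolation
  exists for spectral analysis only.
* total power = VLF + LF + HF (≤ 0.40 Hz), which makes
  LFnu + HFnu = 100 exact by the definition
  nu = 100·band/(total − VLF); a flag extends the total to Nyquist.
* LF/HF is the ratio of absolute powers.

## Detectors

* **R peaks:** 5–25 Hz zero-phase band-pass, squaring, 150 ms
  moving-average envelope, adaptive threshold at 0.5× the rolling 2-s
  envelope maximum, 250 ms refractory period. The R time is the sample
  of maximum band-passed amplitude in the detected complex: identical
  to the raw maximum for a symmetric QRS and markedly more noise-robust.
  Designed for clean resting recordings; it is not an arrhythmia-grade
  detector.
* **Pressure cycles** are R-to-R windows; MAP is the trapezoidal
  time-average over the full cycle. The diastolic minimum sits at the
  cycle boundary, so beat-time jitter can attribute the trough to the
  neighboring cycle — SBP is unaffected, which is why accuracy claims
  are made for SBP.
* **Breaths** are delimited by negative-to-positive zero crossings of
  1 Hz low-pass-filtered flow; VT integrates positive (inspiratory) flow
  per breath; V̇e = Rf × mean VT.

## Artifact flagging and suitability

A cycle is flagged when its RR deviates from the centered 11-beat
rolling median by more than 30% of that median — tuned to the
"halved RR" signature of a premature beat, and exposed as parameters.
Flagged beats are interpolated over (never repaired in place), and a
session with more than 5% flagged cycles is rejected as unsuitable for
cBRS/HRV analysis unless the caller forces it, mirroring the common
practice of excluding participants with frequent ectopy. The boundary
(exactly 5%) counts as suitable.

## RR/SBP pairing

rr_k — the interval opened by beat k — pairs with sbp_k, the systole of
that same cycle (0-lag pairing), both timestamped at the interval onset.
A `lag_beats` option shifts the pairing for users following lagged
conventions. Whether ectopic beats should be interpolated over or
removed entirely is not settled usage; interpolation-over is the default
here and the flagging is pure annotation, so alternatives are cheap.

## The simulator

The generator is event-driven rather than a continuous
integral-pulse-frequency-modulation model:

    sbp_k = sbp0 + a_lf sin(2π f_lf t_k) + a_hf sin(2π f_hf t_k) + ε_k
    rr_k  = rr0 + G (sbp_{k−d} − sbp0) + rsa sin(2π f_hf t_k) + η_k
    t_{k+1} = t_k + rr_k/1000

with Gaussian ε, η; ectopy is emulated by halving RR at random beats.
At f_lf the SBP→RR transfer function is exactly G with the delay phase,
which is what recovery tests measure. The first beat falls after a 1 s
lead-in so synthesized waveforms always contain a complete first QRS.
One master seed feeds independent substreams for SBP noise, RR noise and
ectopy, so channels can be toggled without disturbing each other; the
output is bit-identical for a given configuration.

Defaults emulate a 5-min resting recording: rr0 800 ms, sbp0 120 mmHg,
Mayer wave 3 mmHg at 0.10 Hz, respiratory SBP 2 mmHg, RSA 20 ms, SBP/RR
noise 1/5 ms-or-mmHg SD. Condition presets (`day0`, `day1`, `day4`,
`hyperoxia`, `controlled`) encode the direction and approximate
magnitude of group-level changes across a normobaric baseline and days
1 and 4 of hypobaric hypoxia: baseline gain 12.5 ms/mmHg falling to 8.9
and 7.4, RR interval shortening from ~0.87 to ~0.70–0.75 s, respiratory
rate rising (f_hf 0.23 → 0.27 → 0.30 Hz), RSA amplitude falling (HF
power down), hyperoxic restoration at 10.6 ms/mmHg, and controlled
breathing with slower respiration and an ~8 mmHg higher SBP level.
Preset constants are documented package choices targeting those group
means, not fitted per-subject values.

What the simulator does **not** emulate: realistic pulse contours and
pulse-wave phenomena, nonstationarity and slow drifts, respiratory
pattern variability, measurement artifacts other than white noise and
half-RR ectopy, or mechanistic sympathetic/vagal dynamics. Passing
recovery tests therefore demonstrates correctness of the estimation
chain under the stated model, not robustness to every property of real
recordings.

Waveform synthesis renders ECG as unit Gaussian R waves (20 ms width,
optional white noise at a stated mean-power SNR), arterial pressure as a
smooth per-cycle template rising from DBP to SBP at 30% of the cycle,
and flow as a sinusoid whose amplitude yields the requested tidal
volume — sufficient to exercise the detectors, not hemodynamically
realistic.

## Inspired-O2 utility

Fo2 = PIO2_target / (P_B − 47 mmHg), with 47 mmHg the water-vapor
pressure of saturated air at 37 °C. At a chamber pressure of 493.5 mmHg
a 145 mmHg target requires a fraction of 0.3247, i.e. 32% O2; at
760 mmHg the formula returns ~21%, the normoxic self-consistency check.

## Group summaries

Descriptive only: mean ± sample SD (ddof = 1) for variables flagged
normal, median [IQR] otherwise, with quartiles by linear interpolation
between order statistics (the quartile rule is configurable in code).
`n` counts non-missing sessions per variable. Inferential statistics
(normality tests, ANOVA, post-hoc) are intentionally out of scope:
standard statistical packages already do them well.

## Problem sizes in the test suite

Tests run the pipeline at the scale the method targets — 5-min
recordings (~350–400 beats, N = 1200 at 4 Hz) — with 20–50 seed
replicates for stochastic claims (gain recovery, condition ordering,
ectopy recall, coherence bias) and 100–1000 replicates for cheap
formula-level oracles. The whole suite completes in a few seconds.

## Known limitations

* The R-peak detector expects a dominant positive R deflection and
  clean baseline; it is untested on pathological morphologies.
* cBRS via transfer-function gain characterizes the operating point of
  the reflex, not the full stimulus–response curve; sequence-method and
  alpha-index variants are not implemented.
* DBP/MAP extraction near cycle boundaries inherits beat-time jitter
  (see Detectors above).
* Missing-data handling is flag-based; no beat-insertion/deletion
  repair is attempted.
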