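# Methods

## The quality-assessment problem

Photoplethysmography (PPG) measures blood-volume changes optically and is
quasi-periodic at the heart rate. Motion is its dominant noise source and is
itself often periodic, with frequency components that overlap the cardiac
band — so a conventional spectrum cannot always tell pulse from artifact.
The modulation spectrogram separates them by a second-order analysis: after
a short-time Fourier transform (STFT), the temporal trajectory of each
spectral magnitude is Fourier-transformed again, producing a
frequency–frequency representation S(f_m, f) indexed by modulation frequency
f_m and conventional frequency f. A clean PPG is amplitude-modulated by the
cardiac cycle, so its energy concentrates in lobes at f_m = HR and
harmonics; noise smears energy across the modulation axis even when it
overlaps the pulse in conventional frequency.

## Proposed signal-quality indexes

Per 8 s epoch:

1. STFT with a 0.625 s Hamming window, 90% overlap (frame rate fs/hop;
   116 frames at fs = 250 Hz). Frames are zero-padded to 512 points so the
   conventional-frequency grid (~0.49 Hz) samples the 2–8 Hz band well; the
   un-padded grid would put only 3 bins in that band.
2. Per conventional bin, the temporal mean of |S(t, f)| is removed (without
   this the f_m = 0 ridge dominates every descriptor), a Hamming window is
   applied over frames, and the DFT magnitude is taken, zero-padded to the
   next power of two ≥ 4× the frame count (modulation resolution ≈ 0.03 Hz).
3. The magnitudes are summed over conventional frequencies 2–8 Hz, where
   most pulse energy lies, giving the aggregated modulation spectrum p_k.
4. The fundamental lobe f_main is the argmax of p_k within 0.8–3.6 Hz
   (48–216 bpm; ties to the lower frequency). If a harmonic lobe exists near
   2·f_main — i.e. 2·f_main ≤ 3.6 Hz and a local maximum within ±2 bins of
   2·f_main reaches ≥ 5% of the fundamental's height — the descriptor band
   narrows to (0.8, 1.5·f_main) Hz so only the main lobe is analyzed;
   otherwise the full (0.8, 3.6) Hz band is used, inclusive of both edges.
5. Three shape descriptors of the band-normalized spectrum
   (p_k scaled to sum to 1 over the N band bins):
   - **entMS** = −Σ p_k log p_k / log N ∈ [0, 1] (uniformity);
   - **sprdMS** = sqrt(Σ (f_k − centroid)² p_k) in Hz (bandwidth about the
     centroid); the un-rooted variance is available via `sqrt=False`;
   - **crstMS** = max p_k / mean p_k ∈ [1, N] (peakedness).

Clean epochs give one concentrated lobe: low entMS and sprdMS, high crstMS.
All three are invariant to amplitude scaling of the input.

Numerical choices worth noting: the entropy normalizer is the **bin count**
of the selected band (the only reading that bounds entMS by 1 independent of
zero-padding); the spread is reported as a standard deviation in Hz; the
harmonic rule requires 2·f_main inside the search range (the alternative,
requiring f_main > 1.8 Hz, makes the narrowing branch unreachable and is
retained as `harmonic_rule="literal"`). The 5% harmonic height threshold was
set from the measured harmonic geometry of clean synthetic pulses, whose
first envelope harmonic ranges from ~9% of the fundamental at high heart
rates to ~37% at low ones; the parameter is exposed.

## Benchmark SQIs

Three standard families, computed per epoch:

- **benchstat** — zero-crossing count (after mean-centering; raw PPG has a
  DC offset), sample skewness, Pearson kurtosis (normal → 3), the ratio
  var(|x|)/var(x), and the heights of the first two local maxima of the
  normalized autocorrelation beyond a 0.25 s refractory lag.
- **benchfreq** — Welch band-power ratios (2 s Hamming segments, 50%
  overlap): RelP = P(1–2.25)/P(1–8), iorSQI = P(1–8)/(P(0–1)+P(8–f_N)),
  fSNR = P(1–2.25)/P(0–f_N), and the no-DC variants with P(1–f_N)
  denominators. The asymmetric denominators follow the definitions as used
  in the PPG-quality literature.
- **benchtemplate** — beats are detected by a multiple-moving-average (MMA)
  consensus: for window lengths 0.5/1/1.5/2 s, candidates are the signal
  maxima inside regions exceeding the centered moving average (edge
  reflection), and a final peak needs a matching candidate (±0.1 s) at every
  scale; the consensus suppresses diastolic peaks, which survive only the
  shortest scales. Templates are cut ±half the median inter-peak interval
  (edge-truncated beats dropped). Per-beat P(1–2.25)/P(0–8) and
  var(|x|)/var(x) reduce by the median (MedRelP, beatElg); treating each
  template (shifted non-negative, mass-normalized) as a probability
  distribution over time, its skewness and Pearson kurtosis reduce by the
  mean (beatSSQI, beatKSQI). cardioSQI divides the count of first-difference
  sign changes by the number of detected peaks.

Metrics that cannot be computed (flat epochs, < 2 detected beats) are NaN —
flagged, never silently imputed at extraction time.

## Synthetic cohort

The evaluation data are synthetic: eight subjects, three wavelengths
(green / red / infrared), 300 s per record at 250 Hz, with ground-truth
annotations. What the generator emulates, and how:

- **Beats**: one cardiac cycle is a sum of wrapped Gaussian bumps — systolic
  peak, diastolic bump on the systolic shoulder, and a narrow negative bump
  carving the dicrotic notch — starting at the inter-beat trough so
  concatenated cycles are continuous. Cycle length gets 2% multiplicative
  jitter (quasi-periodicity without widening the modulation lobe beyond a
  bin); relative amplitudes and widths also jitter a few percent per beat,
  and each subject draws their own baseline morphology and resting heart
  rate (uniform over 0.9–1.8 Hz).
- **Motion artifacts**: a quasi-periodic oscillation whose instantaneous
  frequency drifts (AR(1), ~5% std), with 2–5 harmonics at a random decay, a
  stride-rate subharmonic at half the step rate (on arm-worn devices walking
  noise carries energy at the stride frequency, inside the cardiac band), a
  slowly varying amplitude envelope, and sparse sharp transients (sensor
  displacement at foot strikes). `motion_amp` is the ratio of the
  fundamental's peak-to-peak to the clean signal's peak-to-peak.
- **Protocol layout**: per subject, a squat bout (cadence 0.45–0.65 Hz,
  amplitude 1.7–3.0), an incremental treadmill bout (four 10 s segments
  ramping amplitude ×0.35/0.7/1.2/2.2 with step rate rising 5% per
  increment), and a 15 s broadband span (contact loss, 0 dB SNR), bracketed
  by rest. Roughly a fifth of each record is noisy-level corruption, with
  clean epochs the clear majority.
- **Labels**: motion spans with amplitude ≥ 1 are noisy (morphology
  destroyed), 0.3–1 okay (periodicity visible), < 0.3 negligible (clean);
  broadband spans at ≤ 5 dB SNR are noisy, milder ones okay. Everything
  else is clean. Ground-truth systolic peak times are stored per record.
- **Wavelengths**: the three records of a subject share beat timing; motion
  amplitude is scaled ×0.6 (green), ×1.0 (red), ×1.1 (infrared), so green is
  the most artifact-robust and collects the fewest noisy epochs.
- **Noise floor**: a 15 Hz-low-passed noise floor at 30 dB SNR emulates the
  band-limited analog front end. A white floor would make derivative-based
  metrics (cardioSQI) measure the floor instead of waveform extrema.
- **Determinism**: one master `SeedSequence`; per-subject and per-record
  substreams. Identical seeds give bit-identical cohorts.

What it does **not** emulate: optical physics (no light-absorption model),
blood pressure or SpO2, accelerometer channels, human annotation error, and
— importantly — the full diversity of real artifacts. Parametric motion
noise is more stereotyped than reality; in particular, detected "beats"
inside synthetic noise have very uniform template statistics, so
template-distribution moments (beatKSQI) separate clean from noisy more
strongly here (AUC ≈ 0.98) than any single feature does on real recordings.
Passing the cohort-level tests therefore shows the pipeline reproduces the
qualitative physics of modulation-domain quality assessment — descriptor
directions, fundamental-lobe tracking, detector accuracy — not that the
feature ranking on real data would be identical. The entMS separability
itself (AUCtrans ≈ 0.94–0.97 across wavelengths) matches the magnitudes
reported for annotated multi-wavelength recordings.

## Preprocessing and evaluation protocol

Respiratory content is attenuated with a zero-phase 4th-order Butterworth
high-pass (0.5 Hz default; rejected if ≥ 0.8 Hz to protect the HR band);
records are epoched into 8 s windows with 4 s steps (trailing partials
discarded so every epoch suits the modulation transform), and each window
takes the majority label of its annotations, ties resolved toward the worse
quality so borderline windows are never called clean.

Classification is clean vs. noisy (okay epochs excluded) with logistic
regression (L2, C = 1) under leave-3-of-8-subjects-out: all C(8,3) = 56
subject subsets serve once as the test set. Per split, median imputation,
standardization and mRMR feature selection are fit on training subjects
only. mRMR uses 5-bin equal-frequency discretization, contingency-table
mutual information and the greedy MID criterion (MIQ selectable); it is
exposed as a scikit-learn compatible selector (`MRMRSelector`). Figures of
merit: sensitivity, specificity, BACC = (Sens+Spec)/2 and F1, with noisy as
the positive class; single-class test folds are excluded and counted.
Per-SQI separability uses the rank-based AUC folded about 0.5 (AUCtrans).
Cross-wavelength transfer trains on all binary epochs of one wavelength and
tests on another, with features selected on the training wavelength.

Recovery checks compare the fundamental-lobe estimate against the epoch's
*realized* beat rate (from ground-truth beat times) rather than the nominal
heart rate: with 2% cycle jitter the realized 8 s rate legitimately deviates
from nominal by up to about half a modulation bin on its own.

## Problem sizes and defaults

Default cohort: 8 subjects × 3 wavelengths × 300 s ≈ 1750 epochs
(~74 per record), of which ~20% are noisy at unit wavelength scaling. All
tunable parameters (filter cutoff, STFT geometry, aggregation and search
bands, harmonic thresholds, Welch parameters, MMA windows and tolerance,
mRMR bins and scheme, regularization strength) are keyword arguments with
the defaults above.

## Known limitations

- The breathing filter is a documented high-pass substitute, not a
  Hilbert-envelope method; it removes sub-0.5 Hz content including any
  squat-cadence fundamental below the cutoff.
- cardioSQI and zcSQI are sensitive to the noise-floor bandwidth; the
  band-limited floor keeps them meaningful but their absolute values are
  front-end-dependent.
- With 8 s epochs the modulation main lobe spans ~0.5 Hz, which bounds how
  low clean-epoch entMS can go and caps descriptor contrast; shorter epochs
  are not supported by the second transform (≥ 8 STFT frames required).
- The three-level annotation is generated, not human; the okay/noisy
  boundary is an amplitude threshold rather than a perceptual judgment.
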