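# ppgsqi

Modulation-spectrum shape quality indexes for photoplethysmography (PPG),
with the standard statistical / frequency / template benchmark SQIs and a
subject-wise clean-vs-noisy evaluation protocol, exercised end-to-end on a
synthetic multi-wavelength PPG cohort.

## Who this is for

Wearable-sensing and biosignal researchers who need to decide, per 8 s
window, whether a PPG trace is clean enough for downstream physiology
(heart-rate variability, blood pressure estimation, ...). Motion artifacts
often share conventional-frequency bands with the pulse, so spectral power
ratios are not enough; this package implements quality features in the
*modulation* domain, where cardiac amplitude modulation and artifact
variability separate.

## The method

For a signal s(t), the STFT gives S(t, f); Fourier-transforming |S(t, f)|
along t (per conventional-frequency bin f) yields the modulation
spectrogram S(f_m, f). Summing it over f ∈ [2, 8] Hz gives the aggregated
modulation spectrum p_k. A clean PPG concentrates p_k in one lobe at the
heart rate f_main (plus harmonics); noise spreads it. After locating f_main
(argmax in 0.8–3.6 Hz) and restricting to the main-lobe band
(0.8, 1.5·f_main) Hz when a harmonic lobe is present — else (0.8, 3.6) Hz —
three shape descriptors are computed over the band bins b1..b2 with p_k
normalized to sum to 1 (N = b2 − b1 + 1):

- spectral entropy  entMS = −Σ p_k log p_k / log N ∈ [0, 1]
- spectral spread   sprdMS = √( Σ (f_k − centroid)² p_k ) [Hz],
  centroid = Σ f_k p_k
- spectral crest    crstMS = max(p_k) / mean(p_k) ∈ [1, N]

Clean signals: low entMS and sprdMS, high crstMS. Sixteen benchmark SQIs
(zero crossings, skewness, kurtosis, var(|x|)/var(x), autocorrelation
peaks; five Welch band-power ratios; five beat-template metrics on peaks
from a multiple-moving-average consensus detector) are computed alongside,
and a leave-3-of-8-subjects-out logistic-regression protocol with mRMR
top-3 selection reports BACC / F1 / sensitivity / specificity and AUCtrans
separability per feature. See `docs/methods.md` for every default and the
design rationale.

## Worked example

```python
import ppgsqi as p

record = p.synthesize_record(
    "S01", "green", duration_s=60, hr_profile=1.2,
    noise_specs=[p.NoiseSpec("periodic_motion", motion_freq_hz=2.1,
                             motion_amp=2.0, onset_s=28, offset_s=48)],
    seed=42,
)
filtered = p.attenuate_breathing(record)
epochs = p.epoch_record(filtered)
for epoch in (epochs[2], epochs[9]):          # one clean, one noisy window
    s = p.compute_proposed_sqis(epoch.samples, epoch.fs)
    print(f"{epoch.start_s:5.1f} s  {epoch.label:6s}  "
          f"fmain={s.fmain_hz:.2f} Hz  entMS={s.entms:.3f}  "
          f"sprdMS={s.sprdms:.3f} Hz  crstMS={s.crstms:.2f}")
```

prints

```
  8.0 s  clean   fmain=1.19 Hz  entMS=0.805  sprdMS=0.138 Hz  crstMS=3.63
 36.0 s  noisy   fmain=2.04 Hz  entMS=0.910  sprdMS=0.633 Hz  crstMS=4.14
```

On the clean window the fundamental lobe sits at the heart rate
(1.19 ≈ 1.2 Hz) with a concentrated spectrum (low entropy, 0.14 Hz spread).
On the noisy window the lobe locks onto the walking cadence (2.04 ≈ 2.1 Hz)
and the spectrum spreads out: entMS rises to 0.91 and sprdMS more than
quadruples. The crest ratio is band-dependent per window; its clean > noisy
direction holds on cohort averages.

Full pipeline from the shell:

```bash
ppgsqi simulate --subjects 8 --duration 300 --seed 1 --out data/
ppgsqi sqi --in data/ --metrics all --out features.csv
ppgsqi evaluate --features features.csv --mode within --wavelength red --out report.json
```

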