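# Methods

## Signal model and processing chain

The accelerometric method assumes reflux of liquid gastric contents
distends the lower esophagus and moves the overlying chest wall, producing
low-frequency (< 30 Hz) oscillatory acceleration at the sub-xiphoid skin
surface, while the principal contaminants are 60 Hz mains pickup from
NICU equipment and broadband (> 60 Hz) transients from handling and gross
body movement. The chain separates these three regimes spectrally:

1. **Notch** (60 Hz, Q = 30). The second-order IIR notch is applied as
   its exact squared-magnitude (forward–backward) response in the
   frequency domain. A time-domain `filtfilt` realizes the same transfer
   function but leaves edge transients on finite recordings whose
   residual 60 Hz projection (~1–2 µV on a 100 µV tone) is larger than
   the filter's own stopband leakage by orders of magnitude; the
   frequency-domain application has no transient and is exactly
   zero-phase. Passband distortion at ≤ 30 Hz is < 0.01%.

2. **Stage-1 FFT** (1024 samples at 200 Hz, Δf ≈ 0.195 Hz,
   non-overlapping, rectangular window, per-segment mean removal).
   Rectangular windowing keeps the µV amplitude interpretation exact at
   bin-centered frequencies, which is what the de-jitter floor and the
   artifact threshold act on; a Hann option exists for users who prefer
   leakage suppression over amplitude exactness. Non-overlapping
   segments keep excision semantics unambiguous (a segment is kept or
   dropped whole). The trailing remainder shorter than one window is
   dropped.

3. **De-jitter**: every bin amplitude is floored by 200 µV and clamped
   at zero. This is a spectral noise gate: stationary sensor/amplifier
   noise spreads its power over all 513 bins, so even ~3 mV RMS baseline
   noise stays below the floor per bin and is removed entirely, while
   coherent reflux oscillation concentrated in few bins survives with
   200 µV subtracted. The floor operates on per-segment single-sided bin
   amplitudes; phases are preserved for reconstruction.

4. **Excision**: a segment is discarded whole when any de-jittered bin
   strictly above 60 Hz strictly exceeds 200 µV. Both comparisons are
   strict; the boundary behaviour is not observable from the scoring
   rule itself and is configurable. Excised segments are removed, not
   zero-filled, and their positions are logged so downstream episode
   runs break at the gaps (artifacts can therefore never extend an
   episode, only interrupt one).

5. **Reconstruction and resampling**: retained floored spectra are
   inverse-transformed with their original phases, concatenated, and
   resampled 200 → 60 Hz with `scipy.signal.resample_poly` (×3/10,
   Kaiser-windowed polyphase FIR, delay-compensated so the result is
   effectively zero-phase; stopband ≫ 40 dB, so the 60 Hz output carries
   no meaningful energy above 30 Hz). Reconstruction was chosen over
   scoring stage-1 spectra directly because the published chain
   describes a resampled signal feeding a second spectrogram; the
   direct path is retained as `direct_band_mean` and must agree with
   the canonical path within 5% on tones centered on bins of both
   stages (it is normalized to the stage-2 bin density — 257 bins —
   so the two scores share a scale; for noise-like inputs the two
   binnings weight leakage differently and only the canonical path is
   reported).

6. **Stage-2 spectrogram and score** (512 samples at 60 Hz, Δf ≈ 0.117
   Hz, columns of 8.53 s, same windowing and normalization). The score
   is the arithmetic mean over all cells with 0 ≤ f ≤ 30 Hz — i.e. the
   full single-sided spectrum at this rate — across all columns; gap
   columns are absent, not zero. The DC bin is included: after mean
   removal it is ≈ 0 and does not move the score. A recording-wide mean
   ≥ 1 µV (inclusive) is positive.

## Episode features and pattern labels

A column is *active* when its band mean is at/above the 1 µV cutoff;
episodes are maximal runs of active columns, broken at excision gaps.
Reported features: episode count, longest episode (run length × 8.53 s),
% time positive (active/total columns), and the highest column mean.

Patterns: *negative* (no episode); *continuous* (longest episode ≥ 1200 s,
motivated by continuously-positive recordings exceeding 20 min);
*rhythmic* when the 1 s RMS envelope of the clean signal has a dominant
autocorrelation peak at a period within ±50% of the 4/min rate (7.5–22.5 s)
with normalized autocorrelation ≥ 0.2 — the 8.53 s spectrogram columns are
too coarse to resolve 4/min directly; otherwise *intermittent*. The
autocorrelation search spans lags of 3–60 s, excluding the short lags
dominated by within-burst correlation.

Scores computed from under 30 min of retained signal are flagged
(`short_recording_flag`); clinical recordings run 3–6 h.

## pH-metry comparator

Acid episodes are maximal runs of pH < 4 lasting ≥ 15 s (the debounce
suppresses probe-contact spikes; configurable, with optional hysteresis
on the recovery threshold). The Boix-Ochoa composite sums six normalized
components — % time pH < 4 (total, upright, supine), episode count,
episodes ≥ 5 min, longest episode in minutes — as
Σ max((obs − μ)/σ + 1, 0), positive when strictly > 16.6. The % time
component uses all below-threshold samples (the classic definition);
counts and durations use the debounced episodes. The normative (μ, σ)
per component are **required configuration**: they are not bundled, an
identity set (μ = 0, σ = 1) supports worked examples, and
`placeholder_norms()` is an explicitly synthetic stand-in for pipeline
exercises only. When no body-position track is supplied, the upright and
supine components take the total-time value (preterm infants are nursed
supine) and the mode is echoed in the result. Studies under 24 h are
flagged, since episode counts and % time statistics scale with duration.

## Concordance

Cell counts and rates are exact rational arithmetic (`fractions.Fraction`),
reported as percentages to 1 decimal; undefined rates (zero denominator)
are reported as undefined, never 0. Neither method is treated as ground
truth: `diagnostics(table, reference=...)` names which method plays the
test. The bundled fixtures encode the three published cohort margins as
per-study rows: 85 paired studies (18/42/2/23), the 11-infant surgical
subgroup (2 both-positive, 8 accelerometry-positive/pH-negative, 1
both-negative — following the detailed results; the abstract's "all but
1 had negative pH scores" is inconsistent with those counts and was not
used), and the 20-infant medication subgroup (19 pH-negative of which 13
accelerometry-positive; the single pH-positive study accelerometry-
positive).

## Synthetic generator

`simulate_pair` emulates the signal structure the pipeline assumes:
Gaussian baseline noise (50 µV RMS), a 60 Hz mains sinusoid (300 µV),
reflux events as Tukey-tapered band-limited (0.5–10 Hz) Gaussian noise
bursts, broadband 61–100 Hz artifact transients, and a paired pH trace
(1 Hz, baseline 6.5 with slow drift) in which acid events dip
exponentially to ~3.0 and non-acid events are clipped at pH ≥ 4.2 by
construction. Event strength is parameterized as the **target stage-1
per-bin spectral amplitude**: the burst RMS is `amp·√(M/2)` for M
occupied stage-1 bins, so the default 600 µV events floor to ~400 µV
per bin and a 150 µV "weak event" setting vanishes below the 200 µV
floor (negative control). Defaults — one 30 s event per 10 min recording
(6 events/h), 30% of events acid — reflect the event rate and acid
fraction regime of preterm reflux, where roughly three quarters of
episodes are non-acid. Event amplitudes are a synthetic calibration
chosen to straddle the 1 µV decision boundary cleanly, not a
physiological calibration: no published µV-per-g conversion exists for
the sensor, so recovery results on this generator demonstrate pipeline
correctness, not clinical sensitivity. Other unmodelled features of real
data: cardiac/respiratory coupling, feeding peristalsis (reported not to
register), electrode drift, and non-stationary mains.

Cohorts derive all per-subject randomness from one master seed via
`SeedSequence.spawn`, so generation order cannot change any subject's
data.

## Problem sizes

The test suite and the acceptance script use 10-minute recordings
(120 000 samples at 200 Hz, 117 stage-1 segments) and 50-subject
cohorts at prevalence 0.5; at these sizes a full end-to-end score takes
~30 ms and the whole recovery experiment a few seconds, while every
spectral property (notch depth, floor arithmetic, excision recall,
reconstruction accuracy) is already exercised at its operating scale.

## Known limitations

- The de-jitter floor and excision threshold are fixed spectral-µV
  constants; recordings from sensors with different gain need
  recalibration of both (configurable in `QcConfig`).
- The 1 µV cutoff was a best-fit choice on the original cohort and is
  not validated across ages or devices; `ScoreConfig.positive_cutoff`
  exposes it.
- Rhythmicity detection is a single dominant-period heuristic; irregular
  mixed patterns are labelled intermittent.
- The concordance fixtures reproduce printed margins; per-study scores
  (the scatter of mean µV vs composite) are not recoverable from the
  publication and are not fabricated.
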