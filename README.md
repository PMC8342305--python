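# gerscore

Non-invasive accelerometric scoring of gastroesophageal reflux (GER),
with the comparator Boix-Ochoa pH-metry score and paired diagnostic
concordance analysis.

## The problem

GER is common in preterm infants and carries a real aspiration risk, yet
most of it is **non-acid** (milk feeds buffer gastric pH), so esophageal
pH probes — invasive in themselves — systematically miss it. A skin-taped
sub-xiphoid accelerometer offers a non-invasive alternative: liquid
refluxate distending the lower esophagus produces low-frequency,
sub-audible chest-wall motion that a z-axis accelerometer picks up
regardless of acidity. This package implements the complete signal
pipeline that turns such a recording into a diagnostic score, the pH
comparator it is judged against, and the 2×2 concordance analysis, plus
a seeded synthetic generator so every stage is testable without patient
data.

## The method

For a 200 Hz accelerometer trace *x(t)* in µV:

1. **Mains removal** — zero-phase band-stop (IIR notch, f₀ = 60 Hz, Q = 30).
2. **Segmentation** — consecutive non-overlapping 1024-sample FFT windows;
   single-sided amplitude spectra *A_k* in µV (a sinusoid of amplitude
   *a* at a bin-centered frequency gives *A_k = a*).
3. **De-jitter** — per-bin noise flooring: *A_k ← max(A_k − 200 µV, 0)*.
4. **Artifact excision** — any segment with a de-jittered bin above 60 Hz
   exceeding 200 µV is discarded whole (broadband motion/handling noise).
5. **Reconstruction & resampling** — retained floored spectra are
   inverse-transformed, concatenated, and resampled to 60 Hz (polyphase,
   anti-aliased).
6. **Scoring** — a 512-sample spectrogram of the clean 60 Hz signal over
   the focused 0–30 Hz band; the **score is the mean cell amplitude in
   µV**, and a recording with score **≥ 1 µV is called positive**.
   Per-column activity yields episode features (% time positive, highest
   amplitude, longest episode, episode count) and a pattern label:
   negative, intermittent, rhythmic (≈4 bursts/min) or continuous
   (≥ 20 min uninterrupted).

The pH comparator detects acid episodes (pH < 4, debounced at 15 s) and
computes the Boix-Ochoa composite — six normalized acid-exposure
components Σ max((obsᵢ − μᵢ)/σᵢ + 1, 0) — positive when strictly > 16.6.
`concordance` tabulates paired calls into a 2×2 table and derives PPV,
sensitivity, specificity and NPV as exact fractions, with either method
as the reference.

## Worked example

```python
from gerscore import SimConfig, simulate_pair, score_recording

rec, ph, truth = simulate_pair(SimConfig(seed=2))   # 10 min paired recording
report = score_recording(rec)
print(report.mean_amplitude, report.positive, report.pattern)
# 4.692 True intermittent
```

The synthetic recording carries one 30 s reflux burst (band-limited
0.5–10 Hz oscillation at ~600 µV per spectral bin) on 50 µV sensor
noise with 60 Hz mains and one broadband artifact: the artifact segment
is excised, the mains line is notched out, the burst survives the
200 µV de-jitter floor, and the recording-wide mean of 4.69 µV exceeds
the 1 µV cut-off — a positive call, matching `truth.expected_positive`.

The same from the command line:

```bash
gerscore simulate --seed 2 --out sim/
gerscore score --input sim/subject001_accel.csv --out scored/
gerscore concordance --fixture full_cohort --out conc/
```

`concordance --fixture full_cohort` rebuilds the 85-study cohort table
(18 concurrent-positive / 42 accelerometry-positive-pH-negative / 2 /
23) and reports a PPV of 90.0% (18/20) for a positive pH score
predicting a positive accelerometric score, and a 70.0% (42/60)
fraction of accelerometry-positive studies with negative pH — the
non-acid-reflux signature.

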