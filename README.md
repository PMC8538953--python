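# ppg-hrv

Offline detection of heartbeat-to-heartbeat (RR) intervals in
photoplethysmography (PPG) signals, with automatic identification of
corrupted signal parts, for heart-rate-variability (HRV) estimation.

PPG recorded from a healthy person at rest — typically with a finger
over a smartphone camera — carries one waveform peak per heartbeat, and
the peak-to-peak intervals can substitute for ECG RR intervals in basic
HRV metrics. Signals collected in uncontrolled conditions, however,
contain abrupt steps, dropouts and noise bursts where no reliable peak
detection is possible. This package detects the beats *and* scores each
detected interval so that intervals found in corrupted regions are
discarded rather than silently polluting the HRV estimate.

## Method

For a signal x(t), the continuous wavelet transform with the Mexican-hat
mother wavelet ψ(t) = (2/√3)·π^(−1/4)·(1−t²)·e^(−t²/2),

    X_w(a, b) = ∫ x(t) · a^(−1/2) ψ((t−b)/a) dt,

acts as a multi-scale peak matcher. Local maxima of b ↦ X_w(a, b) are
*ridge points*; linked across 50 geometric scales a_k = 0.05·1.0376^(k−1)
(0.05–0.3 s) they form *ridge lines*. Genuine heartbeats persist at
every level of smoothing, so their ridge lines span the full scale
range, and the line's position at the smallest scale localizes the beat.

The pipeline:

1. **Preprocess** — interpolate to 100 Hz, rescale to (0, 255), zero
   abrupt steps (running 1 s amplitude > 4× its median) and constant
   stretches (amplitude < 0.1), drop valid chunks shorter than 2 s,
   detrend with a 2 s running mean, low-pass at 10 Hz.
2. **Track heart rate** — STFT power over 80 frequencies on [0.5, 3.3] Hz
   (5 s Dirichlet window, 0.5 s stride), convolved with a fan kernel
   that amplifies curves drifting ≤ 0.3 Hz per 10 s; a continuous curve
   hrf(t) follows the column maxima, seeded and re-seeded by a rough
   rate estimate from peak / zero-crossing counts of a band-passed copy.
3. **Select ridge lines** — lines spanning scales ≥ 0.244 s down to
   ≤ 0.069 s are accepted outright; shorter candidates are added only if
   they do not decrease the log-normal likelihood
   −(1/k)·Σ (log rr_i − log(1/hrf_i))² of the resulting intervals.
4. **Score and filter intervals** — each interval gets
   q = q_sim · q_cwt, where q_sim compares the waveform of neighbouring
   intervals (shape correlation × amplitude-ratio sigmoid) and q_cwt is
   a sigmoid of the spread (in ms) of the bounding ridge lines'
   separation across scales. A rigid 0.8 threshold, an adaptive cutoff
   at argmax_i i·q′_i over the sorted qualities, and a rule-based
   interval-length outlier pass discard unreliable intervals.
5. **Summarize** — SDNN, RMSSD (successive differences only across
   intervals that survived adjacently) and the discarded ratio
   n_discarded / n_total. The analysis runs per channel (R, G, B) and
   per polarity (valleys can be the better landmark); the pair with the
   smallest discarded ratio is the output.

## Worked example

Generate a 60 s synthetic recording with known ground truth and analyze
it:

```sh
$ ppg-hrv synth --seed 0 --duration 60 --out rec.json --truth truth.json
wrote rec.json (67 intervals)
$ ppg-hrv analyze rec.json --channel G
{
  "sdnn_ms": 61.16503589602165,
  "rmssd_ms": 34.64101615137755,
  "discarded_ratio": 0.029411764705882353,
  "n_total": 68,
  "n_kept": 66,
  "channel": "G",
  "polarity": "pos"
}
```

The detector found 68 intervals, kept 66 after quality filtration
(discarded ratio 0.03 — a clean signal), and estimates SDNN ≈ 61 ms and
RMSSD ≈ 35 ms from the kept intervals. `--out csv` prints the
per-interval quality table (`peak_time_ms, rr_ms, q_sim, q_cwt, q,
kept, outlier`) instead.

The same entry points are available as a library:

```python
from ppg_hrv import SynthSpec, synth_recording, analyze_channel, AnalysisResult

raw, truth = synth_recording(SynthSpec(duration_s=120.0, seed=0))
best = AnalysisResult(analyze_channel(raw, "G")).best
print(best.hrv_summary().to_dict())
```

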