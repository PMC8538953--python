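# Methods

This note documents the model, the tunable parameters, the numerical
choices, what the synthetic-data generator does and does not emulate,
and known limitations.

## Signal model and assumptions

The detector assumes a PPG recorded from a subject **at rest**: the
heart rate varies gradually (it is assumed to trace a curve in the
spectrogram drifting no faster than ~0.3 Hz per 10 s) and lies in
[0.5, 3.3] Hz (30–198 bpm). Each heartbeat produces a single dominant
waveform peak; the waveform repeats almost periodically in clean signal
and decoheres in corrupted signal. Both assumptions fail during
exercise, so the method is explicitly not applicable there.

## Preprocessing

* Linear interpolation to f = 100 Hz. Linear is monotone and
  artifact-free for 30 → 100 Hz upsampling; higher-order schemes would
  ring at frame-grid discontinuities.
* Rescale to (0, 255), the standard camera intensity range, so that the
  constant-signal amplitude threshold 0.1 has a fixed meaning. A
  totally constant channel is flagged unanalyzable. Detection runs
  after rescaling for exactly this reason.
* Step detection: running 1 s max−min amplitude > 4× its median. The
  whole 1 s window containing the exceedance is flagged, since the step
  contaminates every window that straddles it. If the median amplitude
  is 0 the signal is degenerate-constant and step detection flags
  nothing (constant detection handles it).
* All running windows (amplitude 1 s, detrend mean 2 s) are centred
  with truncation at the edges — causal windows would phase-shift the
  detections relative to the artefacts.
* Chunks shorter than 2 s are zeroed: they cannot hold even two beats
  plus filter transients.
* Detrend by subtracting the centred 2 s running mean, then low-pass
  with a zero-phase (forward–backward) 4th-order Butterworth at 10 Hz.
  Zero phase is essential: a causal filter would shift peak positions
  by a frequency-dependent delay and bias every RR interval.

## Heart-rate tracking

The STFT uses a rectangular (Dirichlet) 5 s window, 0.5 s stride, and
80 frequencies uniform on [0.5, 3.3] Hz. Windows are 5f samples long,
which makes the column count exactly floor((N − 5f)/(0.5f)) + 1. The
continuity kernel is the union of one-pixel-rasterized straight lines
through the kernel centre, spanning 10 s × 0.3 Hz, normalized to unit
sum; convolution is zero-padded at the edges.

Column local maxima are strict interior maxima; flat plateaus count
once at their midpoint, ties resolved toward lower frequency. The curve
accepts the nearest of the three largest column maxima when it lies
within 0.1 Hz of the previous value; otherwise it relaxes toward the
rough estimate with weight 0.05 per column, which bounds re-seeding
jumps to 5 % of the distance to the new estimate. The rough estimate
band-passes (2nd-order zero-phase Butterworth) a ≤ 10 s test segment
between 0.1 Hz and an adaptive cutoff in {1.5, 2, 2.5} Hz chosen from
the column's argmax frequency, then averages the local-maxima rate and
half the zero-crossing rate; counts are normalized by the segment
length in seconds. An exact zero-touch counts as one crossing.
Spectrogram columns whose window overlaps invalidated samples carry the
previous curve value forward, and the rough-estimate segment is clipped
to the contiguous valid run containing the window start.

## Scalogram and ridge lines

Scales a_k = 0.05·1.0376^(k−1), k = 1..50, i.e. geometric from 0.05 s
to ≈ 0.305 s. The wavelet is truncated at |t| ≤ 5a (|ψ| < 1e−4
beyond), making each scalogram row a finite convolution; boundaries are
zero-padded, which is consistent because preprocessing already zeroes
chunk borders. Ridge points are strict row-wise local maxima (plateau
midpoint fallback).

Linking is deliberately simple: greedy nearest-neighbour from the
coarsest scale downward, with tolerance 0.5·a_k·f samples between
adjacent rows. Peak-position drift between adjacent scales is
proportional to the scale, and starting from the coarse end anchors
each line on the most stable maxima. Ambiguous matches resolve globally
by increasing distance; unmatched points start new lines, so the lines
partition the ridge points and each line covers a contiguous scale
range. The linking rule (tolerance and tie-breaks) is a design choice
of this package — different rules can split or merge borderline lines
and thereby shift individual quality scores.

Orientation convention: a line's *bottom* is its largest scale, its
*top* its smallest; beats correspond to lines whose bottom reaches
≥ 0.244 s (grid index ≈ 44) and whose top reaches ≤ 0.069 s (grid
index ≈ 10), thresholds compared inclusively against the line's extreme
scales.

## Ridge-line selection

Full-height lines are accepted unconditionally. Candidates (bottom
scale strictly between 0.069 and 0.244 s, top ≤ 0.069 s) are swept
deepest-reaching first; one is accepted only if the average
log-likelihood of the merged interval set strictly increases,
modelling log RR as normally distributed around log(1/hrf). The hrf
value for an interval is read at the spectrogram column whose window
centre is nearest the interval midpoint. With fewer than two chosen
lines the likelihood is 0 by convention, so candidates cannot attach to
an empty or singleton set — a signal with no persistent lines yields no
intervals rather than noise-derived ones. Selection runs independently
per chunk; intervals never span chunk boundaries.

## Quality scores and filtration

* q_sim: for each neighbouring pair of intervals, the geometric mean of
  (a) Pearson correlation of the two waveforms resampled to 50 points,
  clipped at 0, and (b) σ(2·(3.5 − r_amp)) where r_amp ≥ 1 is the
  amplitude ratio; interior intervals take the geometric mean of their
  two pair scores, end intervals use their single neighbour, and a lone
  interval scores 0 (no evidence of periodicity is treated
  conservatively).
* q_cwt: σ((50 − rr_std)/5) where rr_std is the standard deviation (ms)
  of the distance between the two bounding ridge lines over their
  shared scales. The sigmoid direction rewards *stable* separation,
  which is what distinguishes clean beats; the constructor flag
  `cwt_quality_as_printed` flips the sign for comparison experiments, since
  the opposite direction also circulates. Lines sharing fewer than two
  scale levels score 0.
* Filtration: keep q > 0.8, sort survivors descending, cut at
  q′_{i0} with i0 = argmax i·q′_i (ties toward larger i, which keeps
  more intervals). Then a rule-based pass over interval lengths flags,
  within a ±13-interval window (truncated at the edges, percentiles by
  linear interpolation, amp := p90 − p10): spike pairs (one beat split
  asymmetrically), double-detection pairs (both < 0.7·median with
  plausible sum), missed-beat singles (> 1.6·median) and short singles
  (< min(0.7·median, p10)). The outlier pass runs on the intervals the
  adaptive threshold kept; flags from either pass discard the interval
  and both feed the discarded ratio.

## HRV summaries

SDNN uses the population (1/n) divisor. RMSSD uses 1/(n−1) over
successive differences, and a discarded interval breaks the difference
chain: differences are taken only between kept intervals that were
adjacent in the detected sequence. Interpolating across discarded gaps
would manufacture "successive" differences that never happened.

## Synthetic data generator

The generator emulates a smartphone finger-camera recording: frames at
30 Hz, intensities in (0, 255), a two-Gaussian pulse template (systolic
peak σ = 0.10 s plus a dicrotic wave of relative amplitude 0.3 delayed
0.30 s), baseline wander (0.5 pulse amplitudes at 0.1 Hz), and white
Gaussian noise at a prescribed power SNR (default 20 dB versus the
clean pulse train). RR sequences come from a first-order
autoregressive log-RR process with AR coefficient
φ = 1 − (RMSSD/SDNN)²/2, matching target SDNN/RMSSD in the stationary
limit; defaults (mean RR 850 ms, SDNN 50 ms, RMSSD 30 ms) describe a
healthy resting adult. Corruption segments overwrite rendered frames
with white noise, a constant, or a +10-amplitude step.

What it does **not** emulate: respiration-coupled amplitude modulation,
slow morphology drift, motion artefacts with PPG-like spectra, sensor
quantization, or frame-rate jitter. Passing the recovery tests
therefore shows that the chain of estimators is correct and robust to
broadband noise and gross corruption — not that it has been validated
against physiological recordings.

## Problem sizes

Tests and the acceptance script use 120 s recordings (≈ 140 beats) at
100 Hz, 10 seeds for the clean-recovery experiment, a 60 s sweep for
rate tracking, and 1000 random cases for each combinatorial
equivalence check; these sizes give stable statistics while keeping a
full run in tens of seconds.

## Numerical notes and edge cases

* Spectrogram phases use absolute sample times; the per-window global
  phase factor is dropped because only squared magnitudes are used.
* Scalogram convolutions use scipy's auto-selected method; FFT and
  direct paths agree with the literal defining sum to ~1e−14 relative.
* A constant input, an all-flagged signal, or a signal shorter than the
  5 s STFT window yields an explicit "unanalyzable" result with zero
  intervals, never an exception.
* Degenerate quality inputs (constant chunk, zero amplitude, < 2 shared
  ridge levels) score 0, so they cannot pass the 0.8 threshold.
* All pipeline stages are deterministic; identical input bytes give
  identical output bytes. Randomness exists only in the generator,
  behind a single seed.

## Known limitations

* Peak positions are integer sample indices at 100 Hz, so RR intervals
  are quantized to 10 ms. Under broadband noise at 20 dB SNR the
  finest-scale ridge position additionally jitters by σ ≈ 8 ms, which
  inflates detected RMSSD by several ms on synthetic recordings; SDNN
  is much less affected. Coarser scales localize more robustly but the
  beat position is defined at the smallest scale.
* The linking rule is under-determined by the method description;
  per-interval quality values (not the aggregate behaviour) can depend
  on its tie-breaks.
* Channel/polarity selection assumes at least one clean-ish channel; if
  all four (channel, polarity) runs are unanalyzable the recording is
  reported as such.
* Not applicable to exercise or arrhythmia recordings; ectopic beats in
  a reference belong to evaluation-side exclusion, not to this
  pipeline.
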