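"""Synthetic smartphone-PPG generator with known ground truth.

Emulates a finger-over-camera pulse recording: a train of pulse
templates (a systolic Gaussian plus a smaller, delayed dicrotic wave)
placed at beat times drawn from a first-order autoregressive log-normal
RR process, riding on slow baseline wander, with additive Gaussian
noise at a prescribed SNR.  Frames are emitted at 30 Hz — the typical
smartphone camera rate — with intensities in the standard (0, 255)
range.  Controlled corruption segments (white noise, constant dropout,
abrupt step) exercise the quality-filtering stages.

Defaults model a healthy adult at rest: mean RR 850 ms, SDNN 50 ms,
RMSSD 30 ms, SNR 20 dB.  The generator does not attempt hemodynamic
realism (no respiration-coupled amplitude modulation, no slow
morphology drift); it provides peak positions a wavelet peak detector
must recover and artefacts it must reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import RawChannel

CAMERA_FS = 30.0


@dataclass
class PulseShape:
    """Two-Gaussian pulse template (times in s, unit systolic amplitude)."""

    systolic_width_s: float = 0.10
    dicrotic_delay_s: float = 0.30
    dicrotic_amplitude: float = 0.30
    dicrotic_width_s: float = 0.12

    def __call__(self, t: np.ndarray) -> np.ndarray:
        main = np.exp(-t * t / (2 * self.systolic_width_s ** 2))
        d = t - self.dicrotic_delay_s
        dicrotic = self.dicrotic_amplitude * np.exp(
            -d * d / (2 * self.dicrotic_width_s ** 2))
        return main + dicrotic


@dataclass
class SynthSpec:
    """Conditions for one synthetic recording."""

    duration_s: float = 120.0
    camera_fs: float = CAMERA_FS
    mean_rr_ms: float = 850.0
    sdnn_ms: float = 50.0
    rmssd_ms: float = 30.0
    pulse: PulseShape = field(default_factory=PulseShape)
    noise_snr_db: float = 20.0
    drift_amplitude: float = 0.5     # in units of pulse amplitude
    drift_freq_hz: float = 0.1
    # (start_s, end_s, kind) with kind in {white_noise, constant, step}
    corruption: list[tuple[float, float, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for start, end, kind in self.corruption:
            if not (0 <= start < end <= self.duration_s):
                raise ValueError("corruption segment outside the recording")
            if kind not in ("white_noise", "constant", "step"):
                raise ValueError(f"unknown corruption kind {kind!r}")


@dataclass
class GroundTruth:
    beat_times_s: np.ndarray
    rr_ms: np.ndarray
    corruption_mask: np.ndarray  # per emitted frame


def generate_rr(spec: SynthSpec, n_intervals: int | None = None) -> np.ndarray:
    """AR(1) log-RR sequence tuned to the SDNN/RMSSD targets.

    For an AR(1) process with stationary std sigma and coefficient phi,
    SDNN ~= mean * sigma_log and RMSSD ~= SDNN * sqrt(2 (1 - phi)), so
    phi = 1 - (rmssd/sdnn)^2 / 2.  Targets with rmssd >= 2 * sdnn are
    unreachable (phi <= -1) and raise.  Deterministic per seed.
    """
    if n_intervals is None:
        n_intervals = int(np.ceil(spec.duration_s * 1000.0 / spec.mean_rr_ms)) + 2
    if spec.sdnn_ms == 0:
        return np.full(n_intervals, spec.mean_rr_ms)
    ratio = spec.rmssd_ms / spec.sdnn_ms
    phi = 1.0 - ratio * ratio / 2.0
    if phi <= -1.0:
        raise ValueError("rmssd target must be below 2 x sdnn for an AR(1) model")
    rng = np.random.default_rng(spec.seed)
    sigma_log = spec.sdnn_ms / spec.mean_rr_ms
    innov_sd = sigma_log * np.sqrt(1.0 - phi * phi)
    x = np.empty(n_intervals)
    x[0] = rng.normal(0.0, sigma_log)
    eps = rng.normal(0.0, innov_sd, size=n_intervals - 1)
    for i in range(1, n_intervals):
        x[i] = phi * x[i - 1] + eps[i - 1]
    # centre the log process on log(mean) - sigma^2/2 so E[rr] = mean
    rr = spec.mean_rr_ms * np.exp(x - sigma_log ** 2 / 2.0)
    return np.clip(rr, 300.0, 2000.0)


def render_ppg(rr_ms: np.ndarray, spec: SynthSpec,
               ) -> tuple[RawChannel, GroundTruth]:
    """Render a raw 30 Hz channel from an RR sequence.

    Beats are placed at the cumulative RR times starting 1 s into the
    recording; corruption segments overwrite the rendered frames.
    """
    rr_ms = np.asarray(rr_ms, dtype=float)
    if rr_ms.size == 0:
        raise ValueError("need at least one interval")
    beat_times = 1.0 + np.concatenate(([0.0], np.cumsum(rr_ms) / 1000.0))
    beat_times = beat_times[beat_times < spec.duration_s - 0.5]

    n_frames = int(np.floor(spec.duration_s * spec.camera_fs)) + 1
    t = np.arange(n_frames) / spec.camera_fs
    clean = np.zeros(n_frames)
    for b in beat_times:
        near = np.abs(t - b) < 1.5  # template support
        clean[near] += spec.pulse(t[near] - b)

    rng = np.random.default_rng(spec.seed + 1)
    drift = spec.drift_amplitude * np.sin(
        2 * np.pi * spec.drift_freq_hz * t + rng.uniform(0, 2 * np.pi))
    sig_power = float(np.var(clean))
    noise_sd = np.sqrt(sig_power / 10 ** (spec.noise_snr_db / 10.0))
    values = clean + drift + rng.normal(0.0, noise_sd, size=n_frames)

    corruption_mask = np.zeros(n_frames, dtype=bool)
    pulse_amp = 1.0 + spec.pulse.dicrotic_amplitude
    for start, end, kind in spec.corruption:
        seg = (t >= start) & (t < end)
        corruption_mask |= seg
        if kind == "white_noise":
            values[seg] = rng.normal(0.0, pulse_amp / 2.0, size=int(seg.sum()))
        elif kind == "constant":
            values[seg] = float(values[np.flatnonzero(seg)[0]])
        elif kind == "step":
            values[seg] += 10.0 * pulse_amp

    # map into the standard camera intensity range
    lo, hi = float(values.min()), float(values.max())
    values = 40.0 + (values - lo) / (hi - lo) * 175.0

    rr_truth = np.diff(beat_times) * 1000.0
    truth = GroundTruth(beat_times, rr_truth, corruption_mask)
    return RawChannel(t * 1000.0, values), truth


def synth_recording(spec: SynthSpec) -> tuple[RawChannel, GroundTruth]:
    """Convenience: RR sequence + rendering in one call."""
    rr = generate_rr(spec)
    return render_ppg(rr, spec)


def chirp_recording(duration_s: float = 60.0, f_start_hz: float = 1.2,
                    f_end_hz: float = 1.9, seed: int = 0,
                    noise_snr_db: float = 20.0) -> tuple[RawChannel, np.ndarray]:
    """Pulse train whose rate sweeps linearly from f_start to f_end.

    Successive beats are spaced by the reciprocal of the instantaneous
    rate, so the realized beat frequency follows the linear law.
    Returns the raw channel and the rendered beat times in seconds.
    """
    rate = lambda t: f_start_hz + (f_end_hz - f_start_hz) * t / duration_s
    beats = []
    t_beat = 0.5
    while t_beat < duration_s - 0.3:
        beats.append(t_beat)
        t_beat += 1.0 / rate(t_beat)
    beat_times = np.array(beats)
    rr = np.diff(beat_times) * 1000.0
    spec = SynthSpec(duration_s=duration_s, seed=seed,
                     noise_snr_db=noise_snr_db, sdnn_ms=0.0, rmssd_ms=0.0)
    raw, truth = render_ppg(rr, spec)
    return raw, truth.beat_times_s
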