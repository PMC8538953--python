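"""Preprocessing of raw photoplethysmography channels.

A raw channel is a pair of arrays (capture times in ms, mean colour
intensity per frame), typically captured at ~30 frames per second by a
smartphone camera.  Before spectral and wavelet analysis the channel is

1. interpolated to a uniform 100 Hz grid,
2. rescaled to the standard (0, 255) intensity range,
3. scanned for abrupt steps (finger removed / reapplied) and for
   constant stretches (no finger, colour rendering stuck),
4. split into contiguous valid chunks, dropping chunks shorter than 2 s,
5. detrended with a centred 2 s running mean and low-pass filtered at
   10 Hz inside each surviving chunk.

Everything outside the surviving chunks is zeroed and marked invalid so
that downstream stages never detect beats there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

DEFAULT_FS = 100.0
STANDARD_RANGE = (0.0, 255.0)
STEP_FACTOR = 4.0          # running amplitude > 4 x median => step
CONSTANT_AMPLITUDE = 0.1   # running amplitude below this => constant signal
AMPLITUDE_WINDOW_S = 1.0
MIN_CHUNK_S = 2.0
DETREND_WINDOW_S = 2.0
LOWPASS_HZ = 10.0
LOWPASS_ORDER = 4


class InvalidSignalError(ValueError):
    """Raised when an input series cannot be analysed."""


@dataclass
class RawChannel:
    """A single colour channel as captured: times in ms, values in a.u."""

    times_ms: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_ms.ndim != 1 or self.times_ms.shape != self.values.shape:
            raise InvalidSignalError("times and values must be 1-D and equally long")
        if self.times_ms.size < 2:
            raise InvalidSignalError("need at least two samples")
        if not np.all(np.diff(self.times_ms) > 0):
            raise InvalidSignalError("capture times must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return float(self.times_ms[-1] - self.times_ms[0]) / 1000.0


@dataclass
class UniformSignal:
    """Uniformly sampled, cleaned signal with validity bookkeeping.

    ``samples`` are zero outside ``chunks``; ``valid_mask`` is False
    there.  Chunk ranges are half-open ``[start, end)`` sample indices.
    """

    samples: np.ndarray
    f: float
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    chunks: list[tuple[int, int]] = field(default_factory=list)
    constant_input: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.samples.size, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n / self.f

    def negated(self) -> "UniformSignal":
        return UniformSignal(-self.samples, self.f, self.valid_mask.copy(),
                             list(self.chunks), self.constant_input)


def resample_uniform(raw: RawChannel, f: float = DEFAULT_FS) -> UniformSignal:
    """Linearly interpolate a raw channel onto a uniform grid at ``f`` Hz.

    The grid covers [times[0], times[-1]]; the sample count is
    ``floor((t_last - t_0)/1000 * f) + 1``.
    """
    if f <= 0:
        raise InvalidSignalError("sampling frequency must be positive")
    t0 = raw.times_ms[0]
    span_s = (raw.times_ms[-1] - t0) / 1000.0
    n = int(np.floor(span_s * f)) + 1
    t_uniform_ms = t0 + np.arange(n) / f * 1000.0
    samples = np.interp(t_uniform_ms, raw.times_ms, raw.values)
    return UniformSignal(samples, f)


def rescale_to_standard(samples: np.ndarray,
                        observed_range: tuple[float, float] | None = None,
                        ) -> tuple[np.ndarray, bool]:
    """Affinely map ``observed_range`` onto (0, 255).

    Returns ``(rescaled, constant_flag)``; a constant input maps to all
    zeros with the flag set.
    """
    samples = np.asarray(samples, dtype=float)
    if observed_range is None:
        observed_range = (float(np.min(samples)), float(np.max(samples)))
    lo, hi = observed_range
    if hi <= lo:
        return np.zeros_like(samples), True
    out = (samples - lo) / (hi - lo) * (STANDARD_RANGE[1] - STANDARD_RANGE[0])
    return out + STANDARD_RANGE[0], False


def _window_size(window_s: float, f: float) -> int:
    # odd-sized centred window covering window_s seconds
    w = int(round(window_s * f))
    return w + 1 if w % 2 == 0 else w


def running_amplitude(samples: np.ndarray, f: float,
                      window_s: float = AMPLITUDE_WINDOW_S) -> np.ndarray:
    """Per-sample max - min over a centred window, truncated at edges."""
    samples = np.asarray(samples, dtype=float)
    size = _window_size(window_s, f)
    if size < 2:
        raise InvalidSignalError("amplitude window must span at least 2 samples")
    hi = ndimage.maximum_filter1d(samples, size=size, mode="constant",
                                  cval=-np.inf)
    lo = ndimage.minimum_filter1d(samples, size=size, mode="constant",
                                  cval=np.inf)
    return hi - lo


def detect_steps(samples: np.ndarray, f: float) -> np.ndarray:
    """Flag samples whose running amplitude exceeds 4x its median.

    The flag is dilated over the full 1 s window that produced the
    exceeding amplitude, since the step contaminates that whole window.
    A zero median (degenerate constant input) flags nothing.
    """
    amp = running_amplitude(samples, f)
    med = float(np.median(amp))
    if med <= 0:
        return np.zeros(amp.size, dtype=bool)
    mask = amp > STEP_FACTOR * med
    size = _window_size(AMPLITUDE_WINDOW_S, f)
    return ndimage.binary_dilation(mask, structure=np.ones(size, dtype=bool))


def detect_constant(samples: np.ndarray, f: float) -> np.ndarray:
    """Flag samples where the running amplitude falls below 0.1.

    The threshold presumes the signal was rescaled to (0, 255) first.
    """
    return running_amplitude(samples, f) < CONSTANT_AMPLITUDE


def _valid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) ranges of contiguous True values."""
    padded = np.concatenate(([False], valid, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, edges.size, 2)]


def _running_mean_truncated(x: np.ndarray, size: int) -> np.ndarray:
    """Centred running mean with edge truncation (no padding bias)."""
    kernel = np.ones(size)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def chunk_and_clean(samples: np.ndarray, f: float,
                    bad_mask: np.ndarray | None = None) -> UniformSignal:
    """Zero flagged samples, keep chunks >= 2 s, detrend and low-pass each.

    Detrending subtracts a centred 2 s running mean; the low-pass is a
    zero-phase 4th-order Butterworth at 10 Hz (peak positions must not
    shift).  Regions outside the surviving chunks are exactly zero.
    """
    samples = np.asarray(samples, dtype=float)
    if bad_mask is None:
        bad_mask = np.zeros(samples.size, dtype=bool)
    valid = ~np.asarray(bad_mask, dtype=bool)
    min_len = int(round(MIN_CHUNK_S * f))
    chunks = [(a, b) for a, b in _valid_runs(valid) if b - a >= min_len]

    out = np.zeros_like(samples)
    mask = np.zeros(samples.size, dtype=bool)
    if chunks:
        nyq = f / 2.0
        sos = signal.butter(LOWPASS_ORDER, LOWPASS_HZ / nyq, btype="low",
                            output="sos")
        size = _window_size(DETREND_WINDOW_S, f)
        for a, b in chunks:
            chunk = samples[a:b]
            detrended = chunk - _running_mean_truncated(chunk, size)
            out[a:b] = signal.sosfiltfilt(sos, detrended)
            mask[a:b] = True
    return UniformSignal(out, f, mask, chunks)


def preprocess_channel(raw: RawChannel, f: float = DEFAULT_FS) -> UniformSignal:
    """Full preprocessing chain: resample, rescale, mask, chunk, clean."""
    uniform = resample_uniform(raw, f)
    rescaled, constant = rescale_to_standard(uniform.samples)
    if constant:
        sig = UniformSignal(np.zeros_like(rescaled), f,
                            np.zeros(rescaled.size, dtype=bool), [])
        sig.constant_input = True
        return sig
    bad = detect_steps(rescaled, f) | detect_constant(rescaled, f)
    return chunk_and_clean(rescaled, f, bad)
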