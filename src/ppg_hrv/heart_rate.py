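"""Heart-rate frequency tracking from the STFT spectrogram.

A resting heartbeat traces a slowly evolving curve through the
spectrogram of the pulse signal.  The tracker

1. computes the power spectrogram over 80 frequencies uniformly spaced
   on [0.5, 3.3] Hz with a sliding 5 s rectangular (Dirichlet) window
   and 0.5 s stride,
2. convolves it with a fan-shaped kernel that amplifies curves whose
   frequency drifts no faster than 0.3 Hz per 10 s,
3. seeds the curve with a rough rate estimate obtained by counting
   peaks and zero crossings of a narrow band-pass filtration of the
   signal, and
4. follows nearest column-wise local maxima, falling back to
   exponential smoothing toward the rough estimate whenever no maximum
   lies within 0.1 Hz of the previous value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import UniformSignal

FREQ_MIN = 0.5
FREQ_MAX = 3.3
N_FREQS = 80
WINDOW_S = 5.0
STRIDE_S = 0.5
FAN_SPAN_S = 10.0        # horizontal extent of the continuity kernel
FAN_SPAN_HZ = 0.3        # vertical extent of the continuity kernel
CONTINUITY_TOL_HZ = 0.1  # max accepted jump between adjacent columns
SMOOTHING = 0.05         # weight of the rough estimate when re-initializing
ROUGH_SEGMENT_S = 10.0


class SignalTooShortError(ValueError):
    pass


@dataclass
class Spectrogram:
    """Power over [frequency x window] with window bookkeeping."""

    power: np.ndarray            # (N_FREQS, n_windows)
    freqs: np.ndarray            # Hz, strictly increasing
    f: float                     # signal sampling frequency
    window_s: float = WINDOW_S
    stride_s: float = STRIDE_S
    column_valid: np.ndarray | None = None  # windows fully inside valid chunks

    @property
    def n_windows(self) -> int:
        return int(self.power.shape[1])

    def window_start_sample(self, j: int) -> int:
        return int(round(self.stride_s * self.f * j))

    def window_center_time(self, j: int) -> float:
        """Centre of window j in seconds."""
        return self.stride_s * j + self.window_s / 2.0

    def column_for_time(self, t_s: float) -> int:
        j = int(round((t_s - self.window_s / 2.0) / self.stride_s))
        return int(np.clip(j, 0, self.n_windows - 1))


@dataclass
class HeartRateCurve:
    hrf: np.ndarray  # Hz, one value per spectrogram column

    def at_column(self, j: int) -> float:
        return float(self.hrf[int(np.clip(j, 0, self.hrf.size - 1))])


def compute_spectrogram(sig: UniformSignal) -> Spectrogram:
    """Squared-magnitude STFT with a 5 s Dirichlet window, 0.5 s stride.

    ``power[k, j] = |sum_n x[n] exp(-2 pi i f_k t_n) dt|^2`` over the
    5 s window starting at sample ``0.5 f j``.  Columns whose window
    overlaps invalidated samples are marked in ``column_valid``.
    """
    x = sig.samples
    f = sig.f
    win = int(round(WINDOW_S * f))
    stride = int(round(STRIDE_S * f))
    if x.size < win:
        raise SignalTooShortError("signal shorter than the 5 s STFT window")
    n_windows = (x.size - win) // stride + 1
    freqs = np.linspace(FREQ_MIN, FREQ_MAX, N_FREQS)
    dt = 1.0 / f
    # Absolute-time phase differs per window only by a unit-modulus
    # factor, which the squared magnitude discards.
    basis = np.exp(-2j * np.pi * np.outer(freqs, np.arange(win) * dt)) * dt
    starts = stride * np.arange(n_windows)
    windows = np.lib.stride_tricks.sliding_window_view(x, win)[starts]
    power = np.abs(basis @ windows.T) ** 2
    col_valid = np.array([bool(np.all(sig.valid_mask[s:s + win]))
                          for s in starts])
    return Spectrogram(power, freqs, f, column_valid=col_valid)


def fan_kernel(freqs: np.ndarray) -> np.ndarray:
    """Binary fan of straight lines through the centre, unit-normalized.

    Spans 10 s horizontally (20 stride columns) and 0.3 Hz vertically;
    every line through the centre with |slope| <= 0.3 Hz / 10 s is
    rasterized at one-pixel width.
    """
    half_cols = int(round(FAN_SPAN_S / STRIDE_S / 2))           # 10
    df = float(freqs[1] - freqs[0])
    half_rows = int(round(FAN_SPAN_HZ / df / 2))                # ~4
    kernel = np.zeros((2 * half_rows + 1, 2 * half_cols + 1))
    cols = np.arange(-half_cols, half_cols + 1)
    for end_row in range(-half_rows, half_rows + 1):
        rows = np.round(cols * end_row / half_cols).astype(int)
        kernel[rows + half_rows, cols + half_cols] = 1.0
    return kernel / kernel.sum()


def continuity_filter(spec: Spectrogram) -> Spectrogram:
    """Convolve the power with the fan kernel (same shape, zero padding)."""
    kernel = fan_kernel(spec.freqs)
    filtered = sps.convolve2d(spec.power, kernel, mode="same", boundary="fill")
    return Spectrogram(filtered, spec.freqs, spec.f, spec.window_s,
                       spec.stride_s, spec.column_valid)


def _local_maxima_1d(y: np.ndarray) -> np.ndarray:
    """Strict interior local maxima; plateaus count once at their midpoint."""
    n = y.size
    if n < 3:
        return np.array([], dtype=int)
    out = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j < n - 1 and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return np.array(out, dtype=int)


def column_peaks(spec: Spectrogram, j: int, top: int = 3) -> np.ndarray:
    """Indices of the ``top`` largest local maxima in column ``j``."""
    col = spec.power[:, j]
    idx = _local_maxima_1d(col)
    if idx.size == 0:
        return idx
    order = np.argsort(col[idx])[::-1]
    return idx[order[:top]]


def _count_zero_crossings(x: np.ndarray) -> int:
    """Sign changes; an exact zero-touch counts as one crossing."""
    s = np.sign(x)
    nz = s[s != 0]
    crossings = int(np.count_nonzero(np.diff(nz)))
    # zero-runs flanked by equal signs are touches, counted once each
    is_zero = s == 0
    for a, b in _runs(is_zero):
        left = s[a - 1] if a > 0 else 0
        right = s[b] if b < s.size else 0
        if left != 0 and left == right:
            crossings += 1
    return crossings


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, edges.size, 2)]


def rough_hr_estimate(sig: UniformSignal, column: int,
                      spec: Spectrogram) -> float:
    """Rough rate from peak/zero-crossing counts, snapped to a column peak.

    A test segment of up to 10 s starting at the column's window start
    (clipped to the containing contiguous valid run) is band-pass
    filtered between 0.1 Hz and an adaptive cutoff chosen from the
    column's argmax frequency; the estimate averages the local-maxima
    rate and half the zero-crossing rate, then the column peak closest
    to the estimate is returned.
    """
    col = spec.power[:, column]
    f_max = float(spec.freqs[int(np.argmax(col))])
    peaks = column_peaks(spec, column)
    if f_max > 2:
        cutoff = 2.5
    elif f_max < 1:
        cutoff = 1.5
    else:
        cutoff = 2.0

    start = spec.window_start_sample(column)
    # clip the test segment to the contiguous valid run containing it
    end_limit = sig.n
    for a, b in _runs(sig.valid_mask):
        if a <= start < b:
            end_limit = b
            break
    end = min(start + int(round(ROUGH_SEGMENT_S * sig.f)), end_limit)
    x = sig.samples[start:end]
    if peaks.size == 0:
        return f_max
    if x.size < int(round(1.0 * sig.f)):
        return float(spec.freqs[peaks[0]])

    nyq = sig.f / 2.0
    sos = sps.butter(2, [0.1 / nyq, cutoff / nyq], btype="band", output="sos")
    xsm = sps.sosfiltfilt(sos, x)
    xsm = xsm - xsm.mean()
    test_len_s = x.size / sig.f
    n_loc_max = _local_maxima_1d(xsm).size
    n_zero_cross = _count_zero_crossings(xsm)
    upper = n_loc_max / test_len_s
    lower = 0.5 * n_zero_cross / test_len_s
    estimate = 0.5 * (upper + lower)
    freqs = spec.freqs[peaks]
    return float(freqs[int(np.argmin(np.abs(freqs - estimate)))])


def build_hr_curve(spec: Spectrogram, sig: UniformSignal) -> HeartRateCurve:
    """Follow column local maxima continuously; re-seed by smoothing.

    ``spec`` should be the continuity-filtered spectrogram.  Columns
    whose window overlaps invalid samples carry the previous value
    forward.
    """
    n = spec.n_windows
    hrf = np.empty(n)
    valid = (spec.column_valid if spec.column_valid is not None
             else np.ones(n, dtype=bool))
    first = int(np.argmax(valid)) if valid.any() else 0
    hrf[: first + 1] = rough_hr_estimate(sig, first, spec)
    for i in range(first + 1, n):
        if not valid[i]:
            hrf[i] = hrf[i - 1]
            continue
        peaks = column_peaks(spec, i)
        if peaks.size:
            freqs = spec.freqs[peaks]
            f_cl = float(freqs[int(np.argmin(np.abs(freqs - hrf[i - 1])))])
            if abs(f_cl - hrf[i - 1]) < CONTINUITY_TOL_HZ:
                hrf[i] = f_cl
                continue
        f_next = rough_hr_estimate(sig, i, spec)
        hrf[i] = (1 - SMOOTHING) * hrf[i - 1] + SMOOTHING * f_next
    return HeartRateCurve(hrf)
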