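"""Per-interval quality scoring, adaptive filtration and outlier removal.

A clean pulse signal is almost periodic: the waveform inside one
beat-to-beat interval closely resembles its neighbours, and the ridge
lines bounding a beat keep an almost constant separation across scales.
Two scores capture this:

* similarity quality ``q_sim`` — geometric mean of waveform similarity
  (shape correlation x amplitude ratio, each squashed to [0, 1]) with
  the two neighbouring intervals;
* wavelet quality ``q_cwt`` — a sigmoid of the standard deviation (in
  ms) of the distance between the two bounding ridge lines across their
  shared scales; parallel lines score ~1, diverging lines ~0.

The product ``q = q_sim * q_cwt`` feeds a two-stage filter: a rigid 0.8
pre-threshold followed by an adaptive cutoff at the sorted quality
``q'_{i0}`` maximizing ``i * q'_i`` (drop the stragglers while keeping
as many intervals as possible).  A rule-based length-outlier pass then
removes interval-length artefacts that survive with high quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scalogram_ridges import RidgeLine

RESAMPLE_POINTS = 50
RIGID_THRESHOLD = 0.8
AMP_SIGMOID_CENTER = 3.5
AMP_SIGMOID_SLOPE = 2.0
CWT_SIGMOID_CENTER_MS = 50.0
CWT_SIGMOID_SCALE_MS = 5.0
OUTLIER_HALF_WINDOW = 13


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def _resample(x: np.ndarray, n: int = RESAMPLE_POINTS) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.interp(np.linspace(0, x.size - 1, n), np.arange(x.size), x)


def correlation_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of both chunks resampled to 50 points, clipped at 0."""
    xr = _resample(x)
    yr = _resample(y)
    if np.std(xr) == 0 or np.std(yr) == 0:
        return 0.0
    return max(float(np.corrcoef(xr, yr)[0, 1]), 0.0)


def amplitude_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Sigmoid penalty on the ratio of the two chunk amplitudes.

    Equal amplitudes give ~0.993; a 3.5x ratio gives 0.5; >= 4x is
    heavily penalized.
    """
    amp_x = float(np.max(x) - np.min(x))
    amp_y = float(np.max(y) - np.min(y))
    if amp_x <= 0 or amp_y <= 0:
        return 0.0
    r = max(amp_x, amp_y) / min(amp_x, amp_y)
    return _sigmoid(AMP_SIGMOID_SLOPE * (AMP_SIGMOID_CENTER - r))


def shape_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Geometric mean of correlation and amplitude similarity."""
    return float(np.sqrt(correlation_similarity(x, y) * amplitude_similarity(x, y)))


def similarity_quality(samples: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """q_sim per interval from similarities with neighbouring intervals.

    ``s_i`` compares interval i-1 with interval i; interior intervals
    take sqrt(s_i * s_{i+1}); the first and last interval use their
    single available neighbour.  A lone interval has no neighbour and
    conservatively scores 0.
    """
    peaks = np.asarray(peaks, dtype=int)
    n = peaks.size - 1  # number of intervals
    if n < 1:
        return np.array([])
    if n == 1:
        return np.array([0.0])
    s = np.empty(n + 1)  # s[i] for i = 2..n (1-based), stored at index i
    s[:2] = np.nan
    for i in range(2, n + 1):
        x = samples[peaks[i - 2]:peaks[i - 1] + 1]
        y = samples[peaks[i - 1]:peaks[i] + 1]
        s[i] = shape_similarity(x, y)
    q = np.empty(n)
    q[0] = s[2]
    q[n - 1] = s[n]
    for i in range(2, n):  # 1-based interior interval i
        q[i - 1] = np.sqrt(s[i] * s[i + 1])
    return q


def cwt_quality(line1: RidgeLine, line2: RidgeLine, f: float,
                as_printed: bool = False) -> float:
    """Sigmoid of the spread (ms) of the two lines' separation over scales.

    The published formula reads sigma((rr_std - 50)/5), which rewards
    unstable separation; the stated principle — bounding lines of a
    true beat keep approximately the same distance at every scale —
    requires the opposite sign, so the default is sigma((50 - rr_std)/5).
    Pass ``as_printed=True`` for the literal published form.
    """
    ks = line1.shared_levels(line2)
    if ks.size < 2:
        return 0.0
    d = np.array([abs(line1.position_at(k) - line2.position_at(k))
                  for k in ks], dtype=float)
    rr_std = float(np.std(d)) / f * 1000.0
    arg = (rr_std - CWT_SIGMOID_CENTER_MS) if as_printed \
        else (CWT_SIGMOID_CENTER_MS - rr_std)
    return _sigmoid(arg / CWT_SIGMOID_SCALE_MS)


def adaptive_threshold_filter(qualities: np.ndarray,
                              rigid: float = RIGID_THRESHOLD,
                              ) -> tuple[np.ndarray, float]:
    """Keep flags + cutoff from the rigid 0.8 pre-filter and i*q'_i rule.

    Ties in argmax i*q'_i break toward larger i (keeps more intervals).
    With no quality above the rigid threshold everything is discarded
    (cutoff reported as NaN).
    """
    q = np.asarray(qualities, dtype=float)
    surv = q[q > rigid]
    if surv.size == 0:
        return np.zeros(q.size, dtype=bool), float("nan")
    q_sorted = np.sort(surv)[::-1]
    products = (np.arange(1, q_sorted.size + 1)) * q_sorted
    # argmax with ties toward the largest index
    i0 = q_sorted.size - 1 - int(np.argmax(products[::-1]))
    cutoff = float(q_sorted[i0])
    return (q > rigid) & (q >= cutoff), cutoff


def outlier_filter(rr_ms: np.ndarray) -> np.ndarray:
    """Rule-based length-outlier flags over a 27-interval sliding window.

    For each interval i, with p10/median/p90 of the window
    rr[i-13..i+13] (truncated at the edges) and amp = p90 - p10:

    * a short/long adjacent pair straddling the window statistics
      (min < min(m-50, p10-0.2 amp), max > max(m+50, p90+0.2 amp),
      midpoint inside (p10, p90)) flags both — a spike split one beat;
    * an adjacent pair both < 0.7 m whose sum lies in (p10, p90) flags
      both — one beat detected as two;
    * a single interval > 1.6 m flags itself — a missed beat;
    * a single interval < min(0.7 m, p10) flags itself.
    """
    rr = np.asarray(rr_ms, dtype=float)
    n = rr.size
    flags = np.zeros(n, dtype=bool)
    if n < 2:
        return flags
    for i in range(n):
        lo = max(0, i - OUTLIER_HALF_WINDOW)
        hi = min(n, i + OUTLIER_HALF_WINDOW + 1)
        window = rr[lo:hi]
        p10, m, p90 = np.percentile(window, [10, 50, 90])
        amp = p90 - p10
        if i + 1 < n:
            rr_max = max(rr[i], rr[i + 1])
            rr_min = min(rr[i], rr[i + 1])
            if (rr_min < min(m - 50, p10 - 0.2 * amp)
                    and rr_max > max(m + 50, p90 + 0.2 * amp)
                    and p10 < (rr_max + rr_min) / 2 < p90):
                flags[i] = flags[i + 1] = True
            if (rr[i] < 0.7 * m and rr[i + 1] < 0.7 * m
                    and p10 < rr[i] + rr[i + 1] < p90):
                flags[i] = flags[i + 1] = True
        if rr[i] > 1.6 * m:
            flags[i] = True
        if rr[i] < min(0.7 * m, p10):
            flags[i] = True
    return flags


@dataclass
class IntervalQuality:
    """Quality breakdown for one detected beat-to-beat interval."""

    rr_ms: float
    q_sim: float
    q_cwt: float
    q: float
    kept: bool
    outlier: bool


def assess_intervals(samples: np.ndarray, peaks: np.ndarray,
                     lines: list[RidgeLine], f: float,
                     cwt_quality_as_printed: bool = False,
                     ) -> list[IntervalQuality]:
    """Score, threshold and outlier-filter the intervals of one chunk.

    ``lines`` must be the chosen ridge lines sorted by top position so
    that interval i is bounded by lines i and i+1.  The adaptive
    threshold runs first; the length-outlier pass runs on the intervals
    it kept, and flags from either pass discard the interval.
    """
    peaks = np.asarray(peaks, dtype=int)
    n = peaks.size - 1
    if n < 1:
        return []
    rr = np.diff(peaks) / f * 1000.0
    q_sim = similarity_quality(samples, peaks)
    q_cwt = np.array([cwt_quality(lines[i], lines[i + 1], f,
                                  as_printed=cwt_quality_as_printed)
                      for i in range(n)])
    q = q_sim * q_cwt
    kept, _cutoff = adaptive_threshold_filter(q)
    out_flags = np.zeros(n, dtype=bool)
    kept_idx = np.flatnonzero(kept)
    if kept_idx.size:
        out_flags[kept_idx] = outlier_filter(rr[kept_idx])
    final = kept & ~out_flags
    return [IntervalQuality(float(rr[i]), float(q_sim[i]), float(q_cwt[i]),
                            float(q[i]), bool(final[i]), bool(out_flags[i]))
            for i in range(n)]
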