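"""Mexican-hat wavelet scalogram and ridge-line extraction.

The continuous wavelet transform with the Mexican-hat mother wavelet is
a multi-scale peak matcher: its coefficient at (scale a, position b)
measures how much the signal around b resembles a single peak of width
~a.  A per-scale local maximum of the coefficients is a *ridge point*;
ridge points linked across adjacent scales form *ridge lines*.  Peaks
produced by heartbeats persist across the whole scale range, so their
ridge lines span the scalogram from the coarsest to the finest scale,
and the line's position at the finest scale localizes the beat.

Scales: 50 values in geometric progression, a_k = 0.05 * 1.0376^(k-1)
seconds, spanning 0.05-0.3 s.  The progression is fine enough for peak
positions to drift only a few samples between adjacent scales, which is
what the greedy coarse-to-fine linking relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

N_SCALES = 50
SCALE_MIN_S = 0.05
SCALE_RATIO = 1.0376
WAVELET_SUPPORT = 5.0      # truncate psi at |t| <= 5a (psi < 2e-5 beyond)
LINK_TOL_FACTOR = 0.5      # linking tolerance: 0.5 * a_k * f samples


def mexican_hat(t: np.ndarray | float) -> np.ndarray | float:
    """psi(t) = (2/sqrt(3)) pi^(-1/4) (1 - t^2) exp(-t^2/2).

    The (negated, normalized) second derivative of a Gaussian; even,
    zero-mean, with zeros at t = +-1.
    """
    t = np.asarray(t, dtype=float)
    return (2.0 / np.sqrt(3.0)) * np.pi ** (-0.25) * (1.0 - t * t) * np.exp(-t * t / 2.0)


def scale_grid() -> np.ndarray:
    """The 50 analysis scales in seconds, geometric from 0.05 to ~0.3."""
    return SCALE_MIN_S * SCALE_RATIO ** np.arange(N_SCALES)


@dataclass
class Scalogram:
    """CWT coefficients, shape (n_scales, n_samples)."""

    coef: np.ndarray
    scales: np.ndarray
    f: float

    @property
    def n(self) -> int:
        return int(self.coef.shape[1])


def compute_scalogram(samples: np.ndarray, f: float,
                      scales: np.ndarray | None = None) -> Scalogram:
    """Discretized CWT: coef[k, n] = sum_m x_m a_k^{-1/2} psi((t_m-t_n)/a_k) dt.

    Realized as convolution with the sampled wavelet truncated at
    |t| <= 5 a_k, zero-padded at the boundaries (chunk borders are
    already zeroed by preprocessing).
    """
    x = np.asarray(samples, dtype=float)
    if scales is None:
        scales = scale_grid()
    dt = 1.0 / f
    if x.size == 0:
        return Scalogram(np.zeros((scales.size, 0)), scales, f)
    coef = np.empty((scales.size, x.size))
    for k, a in enumerate(scales):
        m = int(np.floor(WAVELET_SUPPORT * a * f))
        tt = np.arange(-m, m + 1) * dt
        kernel = mexican_hat(tt / a) / np.sqrt(a) * dt
        coef[k] = sps.convolve(x, kernel, mode="same", method="auto")
    return Scalogram(coef, np.asarray(scales, dtype=float), f)


def _local_maxima_row(y: np.ndarray) -> np.ndarray:
    """Strict local maxima; flat tops contribute their midpoint index."""
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


def find_ridge_points(scal: Scalogram) -> list[np.ndarray]:
    """Per scale row, sample indices of strict local maxima."""
    return [_local_maxima_row(scal.coef[k]) for k in range(scal.scales.size)]


@dataclass(eq=False)
class RidgeLine:
    """A contiguous-in-scale path of ridge points.

    ``scale_indices`` run from the smallest scale reached (top) to the
    largest (bottom); ``positions`` holds the matching sample indices.
    """

    scale_indices: np.ndarray   # increasing, contiguous
    positions: np.ndarray       # one sample index per scale level

    @property
    def top_scale_index(self) -> int:
        return int(self.scale_indices[0])

    @property
    def bottom_scale_index(self) -> int:
        return int(self.scale_indices[-1])

    @property
    def top_position(self) -> int:
        """Sample index at the smallest scale reached — the peak estimate."""
        return int(self.positions[0])

    def position_at(self, k: int) -> int | None:
        i = k - self.top_scale_index
        if 0 <= i < self.scale_indices.size:
            return int(self.positions[i])
        return None

    def shared_levels(self, other: "RidgeLine") -> np.ndarray:
        lo = max(self.top_scale_index, other.top_scale_index)
        hi = min(self.bottom_scale_index, other.bottom_scale_index)
        return np.arange(lo, hi + 1) if hi >= lo else np.array([], dtype=int)


def link_ridge_lines(ridge_points: list[np.ndarray], scales: np.ndarray,
                     f: float) -> list[RidgeLine]:
    """Greedy nearest-neighbour linking from the coarsest scale down.

    A line whose current point sits at scale row k connects to the
    nearest unclaimed ridge point at row k-1 within 0.5 * a_k * f
    samples; ambiguous matches are resolved globally by increasing
    distance.  Unmatched points start new lines, so every ridge point
    belongs to exactly one line.
    """
    n_scales = len(ridge_points)
    # active lines: (list of (k, pos)) with current point at row k
    finished: list[list[tuple[int, int]]] = []
    active: list[list[tuple[int, int]]] = [
        [(n_scales - 1, int(p))] for p in ridge_points[n_scales - 1]]
    for k in range(n_scales - 1, 0, -1):
        tol = LINK_TOL_FACTOR * scales[k] * f
        below = ridge_points[k - 1]
        pairs = []
        for li, line in enumerate(active):
            pos = line[-1][1]
            d = np.abs(below - pos)
            for pi in np.flatnonzero(d <= tol):
                pairs.append((float(d[pi]), li, int(pi)))
        pairs.sort(key=lambda t: (t[0], t[1], t[2]))
        line_used = [False] * len(active)
        point_used = [False] * len(below)
        matches: dict[int, int] = {}
        for _, li, pi in pairs:
            if not line_used[li] and not point_used[pi]:
                line_used[li] = True
                point_used[pi] = True
                matches[li] = pi
        next_active = []
        for li, line in enumerate(active):
            if li in matches:
                line.append((k - 1, int(below[matches[li]])))
                next_active.append(line)
            else:
                finished.append(line)
        for pi, p in enumerate(below):
            if not point_used[pi]:
                next_active.append([(k - 1, int(p))])
        active = next_active
    finished.extend(active)

    lines = []
    for pts in finished:
        pts = pts[::-1]  # now ordered small scale -> large scale
        ks = np.array([k for k, _ in pts], dtype=int)
        ps = np.array([p for _, p in pts], dtype=int)
        lines.append(RidgeLine(ks, ps))
    return lines
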