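"""Choosing the ridge lines that correspond to heartbeats.

Lines that span the scalogram from the coarsest region (bottom scale
>= 0.244 s) to the finest (top scale <= 0.069 s) are accepted outright:
they mark the most persistent peaks.  Lines that reach the fine scales
but bottom out between 0.069 s and 0.244 s are candidates, swept from
the deepest-reaching down; a candidate joins the accepted set only if
it does not decrease the log-normal likelihood of the resulting
beat-to-beat intervals given the estimated heart-rate curve (an extra
spurious peak halves an interval and moves log RR away from log(1/hr),
while a genuinely missed beat split in two moves it closer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .heart_rate import HeartRateCurve, Spectrogram
from .scalogram_ridges import RidgeLine

BOTTOM_SCALE_S = 0.244  # full-height lines reach at least this scale
TOP_SCALE_S = 0.069     # ... and rise to at most this scale


def estimated_likelihood(rr_ms: np.ndarray, hrf: np.ndarray) -> float:
    """Average log-likelihood (up to scale) of intervals under log-normal RR.

    ``-(1/k) sum (log rr_i - log(1000/hrf_i))^2``; empty input scores 0
    by convention.
    """
    rr_ms = np.asarray(rr_ms, dtype=float)
    hrf = np.asarray(hrf, dtype=float)
    if rr_ms.size == 0:
        return 0.0
    expected = 1000.0 / hrf
    d = np.log(rr_ms) - np.log(expected)
    return float(-np.mean(d * d))


@dataclass
class RRSequence:
    """Accepted peak positions (samples) and the intervals between them."""

    peaks: np.ndarray            # sample indices, sorted ascending
    f: float

    @property
    def rr_ms(self) -> np.ndarray:
        return np.diff(self.peaks) / self.f * 1000.0


@dataclass
class CandidateSet:
    chosen: list[RidgeLine] = field(default_factory=list)
    candidates: list[RidgeLine] = field(default_factory=list)


def _classify(lines: list[RidgeLine], scales: np.ndarray) -> CandidateSet:
    chosen, candidates = [], []
    for line in lines:
        top_a = scales[line.top_scale_index]
        bottom_a = scales[line.bottom_scale_index]
        if top_a > TOP_SCALE_S:
            continue  # pure small-scale noise or never reaches fine scales
        if bottom_a >= BOTTOM_SCALE_S:
            chosen.append(line)
        elif bottom_a > TOP_SCALE_S:
            candidates.append(line)
    # deepest-reaching candidates first
    candidates.sort(key=lambda ln: -scales[ln.bottom_scale_index])
    return CandidateSet(chosen, candidates)


def _interval_hrf(peaks: np.ndarray, f: float, hr_curve: HeartRateCurve,
                  spec: Spectrogram, sample_offset: int = 0) -> np.ndarray:
    """Heart-rate value for each interval, read at the spectrogram
    column whose window centre is nearest the interval midpoint."""
    mids_s = (peaks[:-1] + peaks[1:]) / 2.0
    mids_s = (mids_s + sample_offset) / f
    return np.array([hr_curve.at_column(spec.column_for_time(t))
                     for t in mids_s])


def select_ridge_lines(lines: list[RidgeLine], scales: np.ndarray, f: float,
                       hr_curve: HeartRateCurve, spec: Spectrogram,
                       sample_offset: int = 0) -> list[RidgeLine]:
    """Greedy likelihood sweep of Algorithm-style candidate acceptance.

    ``sample_offset`` places chunk-local sample indices on the global
    time axis used by the spectrogram columns.
    """
    cset = _classify(lines, scales)
    chosen = list(cset.chosen)

    def score(curves: list[RidgeLine]) -> float:
        peaks = np.sort(np.array([c.top_position for c in curves], dtype=float))
        if peaks.size < 2:
            return 0.0
        rr = np.diff(peaks) / f * 1000.0
        hrf = _interval_hrf(peaks, f, hr_curve, spec, sample_offset)
        return estimated_likelihood(rr, hrf)

    current = score(chosen)
    for cand in cset.candidates:
        proposed = chosen + [cand]
        s = score(proposed)
        if s > current:
            chosen = proposed
            current = s
    return chosen


def peaks_from_lines(chosen: list[RidgeLine], f: float) -> RRSequence:
    """Peak positions = top points of the chosen lines, sorted in time."""
    peaks = np.sort(np.array([c.top_position for c in chosen], dtype=int))
    return RRSequence(peaks, f)


def lines_by_peak(chosen: list[RidgeLine]) -> list[RidgeLine]:
    """The chosen lines sorted by their top position (peak order)."""
    return sorted(chosen, key=lambda ln: ln.top_position)
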