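"""Time-domain heart-rate-variability summaries.

SDNN is the (population) standard deviation of the beat-to-beat
intervals; RMSSD is the root mean square of successive differences.
Intervals discarded by quality filtration are excluded, not
interpolated: a discarded gap breaks the chain of successive
differences, so RMSSD only pools differences between intervals that
were adjacent in the original detected sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class NotEnoughIntervalsError(ValueError):
    pass


def sdnn(rr_ms: np.ndarray) -> float:
    """Population standard deviation of the intervals, in ms."""
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 2:
        raise NotEnoughIntervalsError("SDNN needs at least 2 intervals")
    return float(np.std(rr))


def rmssd(rr_ms: np.ndarray) -> float:
    """Root mean square of successive differences (divisor n-1), in ms."""
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 2:
        raise NotEnoughIntervalsError("RMSSD needs at least 2 intervals")
    d = np.diff(rr)
    return float(np.sqrt(np.mean(d * d)))


def rmssd_with_gaps(rr_ms: np.ndarray, adjacency: np.ndarray) -> float:
    """RMSSD over differences of originally adjacent kept intervals.

    ``adjacency[i]`` is True when kept interval i+1 immediately
    followed kept interval i in the detected sequence (same chunk, no
    discarded interval between them).
    """
    rr = np.asarray(rr_ms, dtype=float)
    adjacency = np.asarray(adjacency, dtype=bool)
    d = np.diff(rr)[adjacency]
    if d.size == 0:
        raise NotEnoughIntervalsError("no adjacent interval pairs for RMSSD")
    return float(np.sqrt(np.mean(d * d)))


def discarded_ratio(n_discarded: int, n_total: int) -> float:
    """Fraction of detected intervals rejected by filtration; 0 when empty."""
    if n_discarded > n_total or n_discarded < 0:
        raise ValueError("0 <= n_discarded <= n_total required")
    if n_total == 0:
        return 0.0
    return n_discarded / n_total


@dataclass
class HRVSummary:
    sdnn_ms: float
    rmssd_ms: float
    discarded_ratio: float
    n_total: int
    n_kept: int

    @property
    def n_discarded(self) -> int:
        return self.n_total - self.n_kept

    def to_dict(self) -> dict:
        return {"sdnn_ms": self.sdnn_ms, "rmssd_ms": self.rmssd_ms,
                "discarded_ratio": self.discarded_ratio,
                "n_total": self.n_total, "n_kept": self.n_kept}
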