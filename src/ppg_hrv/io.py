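"""Readers and writers for recording files.

Two on-disk layouts are supported:

* the Welltory record layout — one recording per file with arrays
  ``Time`` (ms from start), ``R``, ``G``, ``B`` (per-frame mean colour
  intensities) and optionally ``RR`` (reference intervals in ms from a
  chest-strap device), stored either as JSON of arrays or as CSV with
  those column names;
* a generic single-channel CSV with a required ``time_ms,value``
  header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RawChannel

CHANNEL_NAMES = ("R", "G", "B")


def read_welltory(path: str | Path) -> tuple[dict[str, RawChannel], np.ndarray | None]:
    """Load a Welltory-layout record (JSON or CSV).

    Returns the colour channels present and the reference RR array in
    ms (or None).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        arrays = {k: np.asarray(v, dtype=float) for k, v in data.items()}
    else:
        frame = pd.read_csv(path)
        arrays = {c: frame[c].dropna().to_numpy(dtype=float)
                  for c in frame.columns}
    if "Time" not in arrays:
        raise ValueError(f"{path}: no 'Time' array in record")
    times = arrays["Time"]
    channels = {name: RawChannel(times, arrays[name])
                for name in CHANNEL_NAMES if name in arrays}
    if not channels:
        raise ValueError(f"{path}: no R/G/B channel found")
    rr = arrays.get("RR")
    return channels, rr


def read_generic_csv(path: str | Path) -> RawChannel:
    """Load a two-column ``time_ms,value`` CSV (header required)."""
    frame = pd.read_csv(path)
    missing = {"time_ms", "value"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return RawChannel(frame["time_ms"].to_numpy(dtype=float),
                      frame["value"].to_numpy(dtype=float))


def write_welltory_json(path: str | Path, times_ms: np.ndarray,
                        channels: dict[str, np.ndarray],
                        rr_ms: np.ndarray | None = None) -> None:
    record: dict[str, list] = {"Time": np.asarray(times_ms).tolist()}
    for name in CHANNEL_NAMES:
        if name in channels:
            record[name] = np.asarray(channels[name]).tolist()
    if rr_ms is not None:
        record["RR"] = np.asarray(rr_ms).tolist()
    Path(path).write_text(json.dumps(record))


def intervals_to_frame(result) -> pd.DataFrame:
    """Per-interval quality table (one row per detected interval)."""
    rows = [{"peak_time_ms": iv.peak_start / result.f * 1000.0,
             "rr_ms": iv.rr_ms, "q_sim": iv.q_sim, "q_cwt": iv.q_cwt,
             "q": iv.q, "kept": iv.kept, "outlier": iv.outlier}
            for iv in result.intervals]
    return pd.DataFrame(rows, columns=["peak_time_ms", "rr_ms", "q_sim",
                                       "q_cwt", "q", "kept", "outlier"])
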