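"""ΔF/F conversion, smoothing, z-scoring and calcium-transient detection.

ΔF/F = (F − F0)/F0 with F0 the median fluorescence over the whole trace.
Traces are smoothed with a two-frame median filter, z-scored over the whole
trace, and maximal runs of frames with z at or above a threshold of 3 are
reported as calcium transients (onset = first supra-threshold frame, peak =
frame of maximum z within the run).

Even-window median convention: a window of w frames is the causal median of
frames {t−w+1, …, t}; for w = 2 this is the average of the current and
previous frame, and the first w−1 frames use the shorter available window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

TRANSIENT_COLUMNS = [
    "roi_id",
    "compartment",
    "onset_time_s",
    "peak_time_s",
    "peak_z",
    "peak_dff",
    "wave_id",
]


@dataclass
class DffTrace:
    """A normalized fluorescence trace with its z-scored counterpart."""

    roi_id: str
    compartment: str
    dff: np.ndarray
    z: np.ndarray
    times_s: np.ndarray
    f0: float


def compute_dff(values: np.ndarray) -> tuple[np.ndarray, float]:
    """ΔF/F = (F − F0)/F0 with F0 = median(F).  Returns (dff, f0)."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("fluorescence trace contains non-finite values")
    f0 = float(np.median(values))
    if f0 == 0:
        raise ValueError("baseline F0 (trace median) is zero")
    if f0 < 0:
        raise ValueError("baseline F0 is negative; intensities must be non-negative")
    return (values - f0) / f0, f0


def smooth_dff(dff: np.ndarray, window: int = 2) -> np.ndarray:
    """Causal running median over ``window`` frames (length-preserving)."""
    dff = np.asarray(dff, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > dff.size:
        raise ValueError(f"window {window} exceeds trace length {dff.size}")
    if window == 1:
        return dff.copy()
    out = np.empty_like(dff)
    windows = np.lib.stride_tricks.sliding_window_view(dff, window)
    out[window - 1 :] = np.median(windows, axis=1)
    for t in range(window - 1):  # shorter leading windows
        out[t] = np.median(dff[: t + 1])
    return out


def zscore(x: np.ndarray, robust: bool = False) -> np.ndarray:
    """Whole-trace z-score; robust variant uses median/MAD (MAD scaled to SD)."""
    x = np.asarray(x, dtype=float)
    if robust:
        center = np.median(x)
        scale = 1.4826 * np.median(np.abs(x - center))
    else:
        center = x.mean()
        scale = x.std()
    if scale == 0:
        return np.zeros_like(x)
    return (x - center) / scale


def make_dff_trace(
    roi_id: str,
    compartment: str,
    values: np.ndarray,
    frame_interval_s: float,
    smooth_window: int = 2,
    robust_z: bool = False,
    t0_s: float = 0.0,
) -> DffTrace:
    """Raw fluorescence → smoothed ΔF/F with whole-trace z-scores."""
    dff, f0 = compute_dff(values)
    dff_s = smooth_dff(dff, smooth_window)
    z = zscore(dff_s, robust=robust_z)
    times = t0_s + np.arange(len(dff_s)) * frame_interval_s
    return DffTrace(
        roi_id=roi_id, compartment=compartment, dff=dff_s, z=z, times_s=times, f0=f0
    )


def detect_transients(
    trace: DffTrace, z_thresh: float = 3.0, min_duration_frames: int = 1
) -> pd.DataFrame:
    """Detect calcium transients as maximal supra-threshold runs of z.

    Each maximal run of consecutive frames with ``z >= z_thresh`` yields one
    transient; runs separated by at least one sub-threshold frame are distinct
    events.  ``wave_id`` is −1 (unassigned / spontaneous) until association.
    """
    z = trace.z
    if np.all(z == 0) and trace.dff.std() == 0:
        warnings.warn(f"flat trace for ROI {trace.roi_id}: no transients", stacklevel=2)
        return pd.DataFrame(columns=TRANSIENT_COLUMNS)
    above = z >= z_thresh
    if not above.any():
        return pd.DataFrame(columns=TRANSIENT_COLUMNS)
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(z)]
    rows = []
    for s, e in zip(starts, ends):
        if e - s < min_duration_frames:
            continue
        peak = s + int(np.argmax(z[s:e]))
        rows.append(
            {
                "roi_id": trace.roi_id,
                "compartment": trace.compartment,
                "onset_time_s": trace.times_s[s],
                "peak_time_s": trace.times_s[peak],
                "peak_z": z[peak],
                "peak_dff": trace.dff[peak],
                "wave_id": -1,
            }
        )
    return pd.DataFrame(rows, columns=TRANSIENT_COLUMNS)


def detect_all_transients(
    traces: pd.DataFrame,
    frame_interval_s: float,
    z_thresh: float = 3.0,
    smooth_window: int = 2,
    robust_z: bool = False,
) -> pd.DataFrame:
    """Run ΔF/F → smoothing → z-scoring → detection for every ROI trace.

    ``traces`` is the long-format output of
    :func:`gliawave.segmentation.extract_traces`.
    """
    tables = []
    for row in traces.itertuples(index=False):
        t = make_dff_trace(
            row.roi_id,
            row.compartment,
            row.values,
            frame_interval_s,
            smooth_window=smooth_window,
            robust_z=robust_z,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tables.append(detect_transients(t, z_thresh=z_thresh))
    tables = [t for t in tables if len(t)]
    if not tables:
        return pd.DataFrame(columns=TRANSIENT_COLUMNS)
    return pd.concat(tables, ignore_index=True)
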