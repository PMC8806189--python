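"""Retinal-wave detection from EPSC traces and wave-transient association.

A retinal wave registers in a voltage-clamped ganglion cell as a large,
negative-going compound EPSC.  Waves are detected as excursions of the
low-pass-filtered rectified current above a threshold; each wave is summarized
by its peak time, absolute peak magnitude (pA) and the interval to the
previous wave (IWI).

A calcium transient is wave-associated if its peak lies within 3 s of a
compound-EPSC peak (nearest wave wins; ties go to the earlier wave).  From the
associated table the module computes per-wave, per-compartment participation,
a chance baseline from randomly drawn times, the stalk-minus-process
intercompartment latency, and paired-condition fold-changes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import EphysTrace

WAVE_COLUMNS = ["wave_id", "peak_time_s", "magnitude_pA", "iwi_s"]


def detect_waves(
    ephys: EphysTrace,
    threshold_pA: float = 50.0,
    min_iwi_s: float = 5.0,
    min_width_s: float = 0.05,
    lowpass_hz: float = 2.0,
) -> pd.DataFrame:
    """Detect compound-EPSC wave events in a current trace.

    The trace is median-baseline-subtracted and rectified; a Butterworth
    low-pass (``lowpass_hz``) smooths the envelope; excursions above
    ``threshold_pA`` lasting at least ``min_width_s`` are events, and events
    whose peaks are closer than ``min_iwi_s`` are merged (keeping the larger
    peak).  Magnitude is the absolute peak of the baseline-subtracted current
    within the excursion.
    """
    if threshold_pA <= 0:
        raise ValueError("threshold_pA must be > 0")
    current = ephys.current_pA - np.median(ephys.current_pA)
    fs = ephys.sample_rate_hz
    env = np.abs(current)
    if lowpass_hz > 0 and lowpass_hz < fs / 2:
        sos = sps.butter(2, lowpass_hz, btype="low", fs=fs, output="sos")
        env = sps.sosfiltfilt(sos, env)
    above = env > threshold_pA
    if not above.any():
        return pd.DataFrame(columns=WAVE_COLUMNS)
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(env)]
    events = []
    for s, e in zip(starts, ends):
        if (e - s) / fs < min_width_s:
            continue
        peak = s + int(np.argmax(np.abs(current[s:e])))
        events.append((ephys.time_s[peak], float(np.abs(current[peak]))))
    # merge events closer than min_iwi_s, keeping the larger peak
    merged: list[tuple[float, float]] = []
    for t, m in events:
        if merged and t - merged[-1][0] < min_iwi_s:
            if m > merged[-1][1]:
                merged[-1] = (t, m)
        else:
            merged.append((t, m))
    rows = []
    prev_t = None
    for w, (t, m) in enumerate(merged):
        rows.append(
            {
                "wave_id": w,
                "peak_time_s": t,
                "magnitude_pA": m,
                "iwi_s": (t - prev_t) if prev_t is not None else np.nan,
            }
        )
        prev_t = t
    return pd.DataFrame(rows, columns=WAVE_COLUMNS)


def associate_transients(
    transients: pd.DataFrame, waves: pd.DataFrame, window_s: float = 3.0
) -> pd.DataFrame:
    """Assign each transient to its nearest wave within ``window_s``.

    A transient whose peak lies within ``window_s`` of the nearest wave peak
    gets that wave's id (ties toward the earlier wave); otherwise it is
    spontaneous (wave_id −1).  Returns a copy; the operation is idempotent.
    """
    out = transients.copy()
    if len(waves) == 0 or len(out) == 0:
        out["wave_id"] = -1
        return out
    wave_times = waves["peak_time_s"].to_numpy(dtype=float)
    wave_ids = waves["wave_id"].to_numpy()
    order = np.argsort(wave_times)
    wave_times = wave_times[order]
    wave_ids = wave_ids[order]
    t = out["peak_time_s"].to_numpy(dtype=float)
    right = np.searchsorted(wave_times, t)
    left = np.clip(right - 1, 0, len(wave_times) - 1)
    right = np.clip(right, 0, len(wave_times) - 1)
    d_left = np.abs(t - wave_times[left])
    d_right = np.abs(t - wave_times[right])
    # ties (equal distance) go to the earlier wave, i.e. the left neighbor
    use_left = d_left <= d_right
    nearest = np.where(use_left, left, right)
    dist = np.where(use_left, d_left, d_right)
    assigned = np.where(dist <= window_s, wave_ids[nearest], -1)
    out["wave_id"] = assigned
    return out


def participation(
    transients: pd.DataFrame, roi_table: pd.DataFrame, waves: pd.DataFrame
) -> pd.DataFrame:
    """Per-wave, per-compartment proportion of ROIs with ≥1 associated transient.

    ``roi_table`` needs columns roi_id, compartment and defines the
    denominator.  Compartments with zero ROIs get NaN.
    """
    n_by_comp = roi_table.groupby("compartment")["roi_id"].nunique()
    rows = []
    assoc = transients[transients["wave_id"] >= 0]
    responders = (
        assoc.groupby(["wave_id", "compartment"])["roi_id"].nunique()
        if len(assoc)
        else pd.Series(dtype=int)
    )
    for w in waves["wave_id"]:
        for comp in ("stalk", "process"):
            n = int(n_by_comp.get(comp, 0))
            if n == 0:
                prop = np.nan
            else:
                k = int(responders.get((w, comp), 0))
                prop = k / n
            rows.append({"wave_id": w, "compartment": comp, "proportion": prop})
    return pd.DataFrame(rows, columns=["wave_id", "compartment", "proportion"])


def chance_baseline(
    transients: pd.DataFrame,
    roi_table: pd.DataFrame,
    duration_s: float,
    n_times: int = 100,
    window_s: float = 3.0,
    seed: int = 0,
    compartment: str | None = None,
) -> float:
    """Proportion of ROIs with a transient peak within ±window of random times.

    Draws ``n_times`` uniform times in ``[window_s, duration_s − window_s]``
    and returns the mean over draws of the proportion of ROIs having at least
    one transient peak within ``window_s``.  This is the chance level against
    which wave participation is compared.
    """
    if n_times < 1:
        raise ValueError("n_times must be >= 1")
    if duration_s < 2 * window_s:
        raise ValueError("recording shorter than twice the association window")
    rois = roi_table
    tr = transients
    if compartment is not None:
        rois = rois[rois["compartment"] == compartment]
        tr = tr[tr["compartment"] == compartment]
    roi_ids = rois["roi_id"].unique()
    if len(roi_ids) == 0:
        return float("nan")
    peaks_by_roi = {rid: g["peak_time_s"].to_numpy(dtype=float) for rid, g in tr.groupby("roi_id")}
    rng = np.random.default_rng(seed)
    times = rng.uniform(window_s, duration_s - window_s, size=n_times)
    props = np.empty(n_times)
    for i, t in enumerate(times):
        hit = 0
        for rid in roi_ids:
            peaks = peaks_by_roi.get(rid)
            if peaks is not None and peaks.size and np.min(np.abs(peaks - t)) <= window_s:
                hit += 1
        props[i] = hit / len(roi_ids)
    return float(props.mean())


def intercompartment_latency(transients: pd.DataFrame, wave_id: int) -> pd.DataFrame:
    """Stalk-minus-process latency for one wave, per responding stalk.

    For each stalk ROI responding to the wave, latency = stalk transient peak
    time − median peak time of the wave's lateral-process transients
    (positive = stalk later).  Returns per-stalk rows; empty if either
    compartment has no response.
    """
    ev = transients[transients["wave_id"] == wave_id]
    stalks = ev[ev["compartment"] == "stalk"]
    procs = ev[ev["compartment"] == "process"]
    if len(stalks) == 0 or len(procs) == 0:
        return pd.DataFrame(columns=["wave_id", "roi_id", "latency_s"])
    proc_median = float(procs["peak_time_s"].median())
    return pd.DataFrame(
        {
            "wave_id": wave_id,
            "roi_id": stalks["roi_id"].to_numpy(),
            "latency_s": stalks["peak_time_s"].to_numpy(dtype=float) - proc_median,
        }
    )


def latency_table(transients: pd.DataFrame, waves: pd.DataFrame) -> pd.DataFrame:
    """Per-stalk latencies plus the per-wave median, for every wave.

    Returns columns wave_id, roi_id, latency_s where roi_id 'median' carries
    the per-wave aggregate.
    """
    tables = []
    for w in waves["wave_id"]:
        per_stalk = intercompartment_latency(transients, w)
        if len(per_stalk) == 0:
            continue
        tables.append(per_stalk)
        tables.append(
            pd.DataFrame(
                {
                    "wave_id": [w],
                    "roi_id": ["median"],
                    "latency_s": [float(per_stalk["latency_s"].median())],
                }
            )
        )
    if not tables:
        return pd.DataFrame(columns=["wave_id", "roi_id", "latency_s"])
    return pd.concat(tables, ignore_index=True)


def response_summary(
    transients: pd.DataFrame,
    roi_table: pd.DataFrame,
    waves: pd.DataFrame,
    fov: str = "fov0",
    condition: str = "ACSF",
) -> pd.DataFrame:
    """Long-format per-FOV summary: participation, amplitudes, latency.

    One row per (fov, condition, compartment, metric) with the FOV-level
    value: mean wave participation, mean peak z and ΔF/F amplitude of
    wave-associated transients, and the median per-wave intercompartment
    latency.
    """
    rows = []
    part = participation(transients, roi_table, waves)
    assoc = transients[transients["wave_id"] >= 0]
    for comp in ("stalk", "process"):
        p = part.loc[part["compartment"] == comp, "proportion"]
        rows.append(
            {
                "fov": fov,
                "condition": condition,
                "compartment": comp,
                "metric": "participation",
                "value": float(p.mean()) if p.notna().any() else np.nan,
            }
        )
        amp = assoc.loc[assoc["compartment"] == comp]
        rows.append(
            {
                "fov": fov,
                "condition": condition,
                "compartment": comp,
                "metric": "amplitude_z",
                "value": float(amp["peak_z"].mean()) if len(amp) else np.nan,
            }
        )
        rows.append(
            {
                "fov": fov,
                "condition": condition,
                "compartment": comp,
                "metric": "amplitude_dff",
                "value": float(amp["peak_dff"].mean()) if len(amp) else np.nan,
            }
        )
    lat = latency_table(transients, waves)
    lat_med = lat.loc[lat["roi_id"] == "median", "latency_s"]
    rows.append(
        {
            "fov": fov,
            "condition": condition,
            "compartment": "both",
            "metric": "latency_s",
            "value": float(lat_med.median()) if len(lat_med) else np.nan,
        }
    )
    return pd.DataFrame(rows, columns=["fov", "condition", "compartment", "metric", "value"])


def condition_fold_change(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
    metric: str = "participation",
) -> pd.DataFrame:
    """Per-FOV, per-compartment fold-change of a metric between conditions.

    Fold-change = (value in condition B) / (value in condition A) for each
    paired FOV.  A zero or missing A-value yields NaN with a warning.
    FOVs present in only one condition raise an error listing them.
    """
    a = summary_a[summary_a["metric"] == metric]
    b = summary_b[summary_b["metric"] == metric]
    fovs_a = set(a["fov"])
    fovs_b = set(b["fov"])
    if fovs_a != fovs_b:
        raise ValueError(f"unpaired FOV ids: {sorted(fovs_a ^ fovs_b)}")
    rows = []
    for fov in sorted(fovs_a):
        for comp in sorted(set(a["compartment"])):
            va = a.loc[(a["fov"] == fov) & (a["compartment"] == comp), "value"]
            vb = b.loc[(b["fov"] == fov) & (b["compartment"] == comp), "value"]
            if len(va) == 0 or len(vb) == 0:
                continue
            va = float(va.iloc[0])
            vb = float(vb.iloc[0])
            if not np.isfinite(va) or va == 0:
                warnings.warn(
                    f"zero/missing baseline {metric} for FOV {fov} ({comp})", stacklevel=2
                )
                fc = np.nan
            else:
                fc = vb / va
            rows.append(
                {"fov": fov, "compartment": comp, "metric": metric, "fold_change": fc}
            )
    return pd.DataFrame(rows, columns=["fov", "compartment", "metric", "fold_change"])
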