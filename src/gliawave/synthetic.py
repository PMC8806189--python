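"""Ground-truth synthetic data: calcium movies, EPSC traces, motility series.

The generator emulates a two-photon recording of GCaMP6f-expressing Müller glia
in a retinal whole mount during cholinergic retinal waves:

* Stalks appear as bright punctate discs (2–3 µm diameter) on a jittered
  hexagonal grid; the space between them carries diffuse lateral-process signal.
* Retinal waves are field-wide events.  For each wave, every stalk and every
  lateral-process unit independently participates with a compartment-specific
  probability; participating units receive a calcium transient whose peak ΔF/F
  is the compartment amplitude.  Stalk transients lag process transients by a
  configurable latency offset (positive = stalk later).
* Transients are double-exponential kernels normalized to unit peak, so the
  configured amplitude is exactly the true peak ΔF/F and the true peak time is
  known analytically.
* Noise is Gaussian read noise plus a signal-dependent (Poisson-like) term with
  variance proportional to the signal; both switch off exactly at zero.
* The paired voltage-clamp trace shows a negative-going compound EPSC at each
  wave time (inward current at −60 mV holding; magnitudes are reported as
  absolute values downstream).

Every output carries a :class:`GroundTruth` sidecar with the wave times,
per-(ROI, wave) participation flags, true event times and true compartments,
so each downstream stage has a parameter-recovery oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import EphysTrace, Movie

MOTILITY_CATEGORIES = (
    "extending",
    "retracting",
    "new",
    "lost",
    "ext_then_ret",
    "ret_then_ext",
    "stable",
)


@dataclass
class SimConfig:
    """Parameters of the synthetic recording.

    Defaults emulate a developing-retina FOV during the second postnatal week:
    a ~100 µm field imaged at 2 Hz, stalks 2.5 µm across on a semiregular grid,
    waves every ~40 s, high lateral-process and intermediate stalk wave
    participation, and a 0.5 s stalk-after-process latency.
    """

    field_size_um: tuple[float, float] = (100.0, 100.0)
    pixel_size_um: float = 0.5
    frame_rate_hz: float = 2.0
    duration_s: float = 300.0
    n_stalks: int = 49
    stalk_diameter_um: float = 2.5
    wave_rate_per_min: float = 1.5
    p_participate_stalk: float = 0.5
    p_participate_process: float = 0.9
    amp_stalk: float = 1.0
    amp_process: float = 0.8
    latency_offset_s: float = 0.5
    spont_rate_hz: float = 0.005
    spont_amp: float = 1.0
    kernel_rise_s: float = 0.5
    kernel_decay_s: float = 2.0
    noise_sigma: float = 10.0
    photon_scale: float = 0.5
    epsc_amp_pA: float = 300.0
    epsc_width_s: float = 1.0
    epsc_noise_pA: float = 5.0
    epsc_sample_rate_hz: float = 1000.0
    # rendering / layout internals
    process_unit_um: float = 10.0
    baseline_background: float = 300.0
    baseline_stalk: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_participate_stalk", "p_participate_process"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        positive = (
            "pixel_size_um",
            "frame_rate_hz",
            "duration_s",
            "stalk_diameter_um",
            "kernel_rise_s",
            "kernel_decay_s",
            "epsc_width_s",
            "epsc_sample_rate_hz",
            "process_unit_um",
        )
        for name in positive:
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        nonneg = (
            "wave_rate_per_min",
            "spont_rate_hz",
            "noise_sigma",
            "photon_scale",
            "epsc_amp_pA",
            "epsc_noise_pA",
            "amp_stalk",
            "amp_process",
            "spont_amp",
        )
        for name in nonneg:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_stalks < 1:
            raise ValueError("n_stalks must be >= 1")
        if self.kernel_rise_s >= self.kernel_decay_s:
            raise ValueError("kernel_rise_s must be < kernel_decay_s")
        if self.field_size_um[0] <= 0 or self.field_size_um[1] <= 0:
            raise ValueError("field_size_um extents must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["field_size_um"] = list(self.field_size_um)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "field_size_um" in d:
            d["field_size_um"] = tuple(d["field_size_um"])
        return cls(**d)


@dataclass
class GroundTruth:
    """True event structure of a synthetic recording.

    Attributes
    ----------
    wave_times_s : ndarray
        Times of the field-wide wave events.
    rois : DataFrame
        One row per true signal unit: roi_id, compartment ('stalk'/'process'),
        cx_um, cy_um (unit centroid).
    participation : DataFrame
        One row per (wave_id, roi_id): participates (bool), compartment.
    events : DataFrame
        One row per true calcium transient: roi_id, compartment, kind
        ('evoked'/'spontaneous'), wave_id (−1 for spontaneous), onset_s,
        peak_s, amp_dff.
    unit_labels : ndarray (Y, X) of int
        Pixel → roi_id map (stalk discs and process tiles).
    motility : DataFrame or None
        True per-process motility categories, for motility simulations.
    """

    wave_times_s: np.ndarray
    rois: pd.DataFrame
    participation: pd.DataFrame
    events: pd.DataFrame
    unit_labels: np.ndarray | None = None
    motility: pd.DataFrame | None = None
    config: SimConfig | None = None


def transient_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials calcium kernel, normalized to unit peak.

    ``k(t) = (exp(-t/decay) - exp(-t/rise)) / k_max`` for t ≥ 0, else 0.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    raw = np.exp(-tp / decay_s) - np.exp(-tp / rise_s)
    t_peak = kernel_peak_time(rise_s, decay_s)
    k_max = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    out[pos] = raw / k_max
    return out


def kernel_peak_time(rise_s: float, decay_s: float) -> float:
    """Time from kernel onset to its unit peak."""
    return rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)


# ---------------------------------------------------------------------------
# layout


def _hex_stalk_centers(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered hexagonal grid of stalk centers (µm), row-major."""
    lx, ly = config.field_size_um
    margin = config.stalk_diameter_um
    n = config.n_stalks
    # hexagonal packing density: spacing for n sites in the usable area
    ax, ay = lx - 2 * margin, ly - 2 * margin
    if ax <= 0 or ay <= 0:
        raise ValueError("field too small for the requested stalk diameter")
    spacing = np.sqrt(2.0 * ax * ay / (np.sqrt(3.0) * n))
    for _ in range(30):
        pts = []
        dy = spacing * np.sqrt(3.0) / 2.0
        row = 0
        y = margin
        while y <= ly - margin + 1e-9:
            x0 = margin + (spacing / 2.0 if row % 2 else 0.0)
            x = x0
            while x <= lx - margin + 1e-9:
                pts.append((x, y))
                x += spacing
            y += dy
            row += 1
        if len(pts) >= n:
            break
        spacing *= 0.95
    else:
        raise ValueError(
            f"cannot place {n} stalks of diameter {config.stalk_diameter_um} µm "
            f"in a {lx}×{ly} µm field"
        )
    if spacing < 1.5 * config.stalk_diameter_um:
        raise ValueError(
            f"stalk packing infeasible: spacing {spacing:.2f} µm < 1.5× diameter "
            f"for n_stalks={n}"
        )
    centers = np.asarray(pts[:n], dtype=float)
    jitter = rng.uniform(-0.25, 0.25, size=centers.shape) * spacing
    centers = centers + jitter
    centers[:, 0] = np.clip(centers[:, 0], margin, lx - margin)
    centers[:, 1] = np.clip(centers[:, 1], margin, ly - margin)
    return centers


def _unit_label_image(config: SimConfig, centers_um: np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
    """Label pixels with true-unit ids: stalk discs 1..n, process tiles after."""
    px = config.pixel_size_um
    ny = int(round(config.field_size_um[1] / px))
    nx = int(round(config.field_size_um[0] / px))
    yy, xx = np.mgrid[0:ny, 0:nx]
    # pixel centers in µm
    xum = (xx + 0.5) * px
    yum = (yy + 0.5) * px
    labels = np.zeros((ny, nx), dtype=np.int32)
    radius = config.stalk_diameter_um / 2.0
    rois = []
    for i, (cx, cy) in enumerate(centers_um, start=1):
        mask = (xum - cx) ** 2 + (yum - cy) ** 2 <= radius**2
        labels[mask] = i
        rois.append({"roi_id": i, "compartment": "stalk", "cx_um": cx, "cy_um": cy})
    # process tiles over the interstitial space
    tile = config.process_unit_um
    tix = np.minimum((xum / tile).astype(int), int(np.ceil(config.field_size_um[0] / tile)) - 1)
    tiy = np.minimum((yum / tile).astype(int), int(np.ceil(config.field_size_um[1] / tile)) - 1)
    ntx = int(np.ceil(config.field_size_um[0] / tile))
    tile_idx = tiy * ntx + tix
    interstitial = labels == 0
    next_id = len(centers_um) + 1
    for t in np.unique(tile_idx[interstitial]):
        mask = interstitial & (tile_idx == t)
        labels[mask] = next_id
        rois.append(
            {
                "roi_id": next_id,
                "compartment": "process",
                "cx_um": float(xum[mask].mean()),
                "cy_um": float(yum[mask].mean()),
            }
        )
        next_id += 1
    return labels, pd.DataFrame(rois)


def draw_wave_times(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Quasi-regular wave times: IWIs uniform in ±30% of the mean interval."""
    if config.wave_rate_per_min == 0:
        return np.asarray([], dtype=float)
    mean_iwi = 60.0 / config.wave_rate_per_min
    margin = 3.0 * config.kernel_decay_s
    times = []
    t = margin + rng.uniform(0.0, mean_iwi)
    while t < config.duration_s - margin:
        times.append(t)
        t += mean_iwi * rng.uniform(0.7, 1.3)
    return np.asarray(times, dtype=float)


# ---------------------------------------------------------------------------
# movie simulation


def simulate_movie(config: SimConfig) -> tuple[Movie, GroundTruth]:
    """Render a synthetic wave-responsive movie and its ground truth.

    Stalk evoked transients peak at ``wave_time + latency_offset_s``; process
    evoked transients peak at ``wave_time``.  Pixel intensity is
    ``baseline × (1 + ΔF/F_true)`` plus read noise and signal-dependent noise.
    """
    rng = np.random.default_rng([config.seed, 0])
    centers = _hex_stalk_centers(config, rng)
    labels, rois = _unit_label_image(config, centers)
    wave_times = draw_wave_times(config, rng)

    n_units = int(rois["roi_id"].max()) if len(rois) else 0
    compartment = dict(zip(rois["roi_id"], rois["compartment"]))

    part_rows = []
    events = []
    t_peak_offset = kernel_peak_time(config.kernel_rise_s, config.kernel_decay_s)
    for w, wt in enumerate(wave_times):
        for rid in rois["roi_id"]:
            comp = compartment[rid]
            p = config.p_participate_stalk if comp == "stalk" else config.p_participate_process
            participates = bool(rng.random() < p)
            part_rows.append(
                {"wave_id": w, "roi_id": rid, "compartment": comp, "participates": participates}
            )
            if participates:
                peak = wt + (config.latency_offset_s if comp == "stalk" else 0.0)
                amp = config.amp_stalk if comp == "stalk" else config.amp_process
                events.append(
                    {
                        "roi_id": rid,
                        "compartment": comp,
                        "kind": "evoked",
                        "wave_id": w,
                        "onset_s": peak - t_peak_offset,
                        "peak_s": peak,
                        "amp_dff": amp,
                    }
                )
    # spontaneous events: homogeneous Poisson per unit
    if config.spont_rate_hz > 0:
        for rid in rois["roi_id"]:
            n_spont = rng.poisson(config.spont_rate_hz * config.duration_s)
            for peak in np.sort(rng.uniform(0.0, config.duration_s, size=n_spont)):
                events.append(
                    {
                        "roi_id": rid,
                        "compartment": compartment[rid],
                        "kind": "spontaneous",
                        "wave_id": -1,
                        "onset_s": peak - t_peak_offset,
                        "peak_s": peak,
                        "amp_dff": config.spont_amp,
                    }
                )
    events_df = pd.DataFrame(
        events,
        columns=["roi_id", "compartment", "kind", "wave_id", "onset_s", "peak_s", "amp_dff"],
    )

    # per-unit ΔF/F traces on the frame grid
    n_frames = int(np.floor(config.duration_s * config.frame_rate_hz))
    frame_times = np.arange(n_frames) / config.frame_rate_hz
    dff_units = np.zeros((n_units + 1, n_frames))  # row 0 unused (background label 0)
    support = 8.0 * config.kernel_decay_s
    dt = 1.0 / config.frame_rate_hz
    for ev in events_df.itertuples(index=False):
        i0 = max(0, int(np.ceil(ev.onset_s / dt)))
        i1 = min(n_frames, int(np.ceil((ev.onset_s + support) / dt)))
        if i0 >= i1:
            continue
        tt = frame_times[i0:i1] - ev.onset_s
        dff_units[int(ev.roi_id), i0:i1] += ev.amp_dff * transient_kernel(
            tt, config.kernel_rise_s, config.kernel_decay_s
        )

    # baseline image: bright stalk discs on diffuse process signal
    baseline = np.full(labels.shape, config.baseline_background, dtype=float)
    baseline[(labels >= 1) & (labels <= len(centers))] = config.baseline_stalk

    frames = np.empty((n_frames,) + labels.shape, dtype=np.float32)
    for t in range(n_frames):
        frame = baseline * (1.0 + dff_units[labels, t])
        if config.noise_sigma > 0:
            frame = frame + rng.normal(0.0, config.noise_sigma, size=frame.shape)
        if config.photon_scale > 0:
            frame = frame + np.sqrt(config.photon_scale * np.maximum(frame, 0.0)) * (
                rng.standard_normal(frame.shape)
            )
        frames[t] = frame

    movie = Movie(
        frames=frames,
        frame_interval_s=1.0 / config.frame_rate_hz,
        pixel_size_um=config.pixel_size_um,
    )
    truth = GroundTruth(
        wave_times_s=wave_times,
        rois=rois,
        participation=pd.DataFrame(
            part_rows, columns=["wave_id", "roi_id", "compartment", "participates"]
        ),
        events=events_df,
        unit_labels=labels,
        config=config,
    )
    return movie, truth


# ---------------------------------------------------------------------------
# EPSC trace simulation


def simulate_epsc_trace(config: SimConfig, wave_times: np.ndarray | list[float]) -> EphysTrace:
    """Voltage-clamp current trace with a compound EPSC at each wave time.

    Each wave contributes a negative-going Gaussian deflection of peak
    magnitude ``epsc_amp_pA`` and FWHM ``epsc_width_s`` centered at the wave
    time, on a zero baseline with Gaussian noise.
    """
    wave_times = np.asarray(wave_times, dtype=float)
    if wave_times.size and (wave_times.min() < 0 or wave_times.max() > config.duration_s):
        raise ValueError("wave_times must lie within [0, duration_s]")
    if wave_times.size >= 2 and np.any(np.diff(np.sort(wave_times)) < config.epsc_width_s):
        warnings.warn("compound EPSCs closer than epsc_width_s overlap", stacklevel=2)
    rng = np.random.default_rng([config.seed, 1])
    fs = config.epsc_sample_rate_hz
    if fs < 10.0 * config.frame_rate_hz:
        raise ValueError("epsc_sample_rate_hz must be at least 10× the movie frame rate")
    n = int(np.floor(config.duration_s * fs)) + 1
    t = np.arange(n) / fs
    current = np.zeros(n)
    sigma = config.epsc_width_s / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM → SD
    for wt in wave_times:
        lo = np.searchsorted(t, wt - 6 * sigma)
        hi = np.searchsorted(t, wt + 6 * sigma)
        current[lo:hi] -= config.epsc_amp_pA * np.exp(-0.5 * ((t[lo:hi] - wt) / sigma) ** 2)
    if config.epsc_noise_pA > 0:
        current += rng.normal(0.0, config.epsc_noise_pA, size=n)
    return EphysTrace(time_s=t, current_pA=current)


# ---------------------------------------------------------------------------
# motility simulation


def _category_counts(n: int, category_mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n processes to categories."""
    unknown = set(category_mix) - set(MOTILITY_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown motility categories: {sorted(unknown)}")
    total = sum(category_mix.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"category_mix must sum to 1, got {total}")
    exact = {c: n * category_mix[c] for c in category_mix}
    counts = {c: int(np.floor(v)) for c, v in exact.items()}
    rem = n - sum(counts.values())
    order = sorted(exact, key=lambda c: exact[c] - np.floor(exact[c]), reverse=True)
    for c in order[:rem]:
        counts[c] += 1
    return counts


def simulate_motility_series(
    n_processes: int,
    n_timepoints: int = 6,
    category_mix: dict[str, float] | None = None,
    seed: int = 0,
    step_um: float = 1.5,
    noise_sigma_um: float = 0.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-process length trajectories with known motility categories.

    The default six timepoints emulate a 10-min volumetric series sampled every
    2 min.  ``step_um`` is the per-interval length change of motile processes
    (well above the 0.5 µm motion threshold used downstream).  Absent
    timepoints ('new' before sprouting, 'lost' after elimination) are NaN.

    Returns a long-format DataFrame (process_id, timepoint_index, length_um)
    and a GroundTruth whose ``motility`` table holds the true categories.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    if category_mix is None:
        category_mix = {"stable": 1.0}
    rng = np.random.default_rng([seed, 2])
    counts = _category_counts(n_processes, category_mix)
    rows = []
    truth = []
    pid = 0
    m = n_timepoints
    for cat, cnt in counts.items():
        for _ in range(cnt):
            base = rng.uniform(4.0, 10.0)
            steps = step_um * rng.uniform(1.0, 1.5, size=m - 1)
            lengths = np.full(m, np.nan)
            if cat == "stable":
                lengths[:] = base
            elif cat == "extending":
                lengths = base + np.concatenate([[0.0], np.cumsum(steps)])
            elif cat == "retracting":
                start = base + steps.sum()
                lengths = start - np.concatenate([[0.0], np.cumsum(steps)])
            elif cat == "new":
                k = int(rng.integers(1, m - 1)) if m > 2 else 1
                lengths[k:] = base + np.concatenate([[0.0], np.cumsum(steps[: m - k - 1])])
            elif cat == "lost":
                k = int(rng.integers(1, m - 1)) if m > 2 else 1
                lengths[:k] = base + steps.sum() - np.concatenate([[0.0], np.cumsum(steps[: k - 1])])
            elif cat == "ext_then_ret":
                if m < 3:
                    raise ValueError("two-phase categories need n_timepoints >= 3")
                j = int(rng.integers(1, m - 1))
                up = base + np.concatenate([[0.0], np.cumsum(steps[:j])])
                down = up[-1] - np.cumsum(steps[j:])
                lengths = np.concatenate([up, down])
            elif cat == "ret_then_ext":
                if m < 3:
                    raise ValueError("two-phase categories need n_timepoints >= 3")
                j = int(rng.integers(1, m - 1))
                start = base + steps[:j].sum()
                down = start - np.concatenate([[0.0], np.cumsum(steps[:j])])
                up = down[-1] + np.cumsum(steps[j:])
                lengths = np.concatenate([down, up])
            present = ~np.isnan(lengths)
            if noise_sigma_um > 0:
                lengths[present] = lengths[present] + rng.normal(
                    0.0, noise_sigma_um, size=present.sum()
                )
            lengths[present] = np.maximum(lengths[present], 0.1)
            for k in range(m):
                rows.append(
                    {
                        "process_id": pid,
                        "timepoint_index": k,
                        "length_um": lengths[k],
                    }
                )
            truth.append({"process_id": pid, "category": cat})
            pid += 1
    lengths_df = pd.DataFrame(rows, columns=["process_id", "timepoint_index", "length_um"])
    gt = GroundTruth(
        wave_times_s=np.asarray([]),
        rois=pd.DataFrame(columns=["roi_id", "compartment", "cx_um", "cy_um"]),
        participation=pd.DataFrame(columns=["wave_id", "roi_id", "compartment", "participates"]),
        events=pd.DataFrame(
            columns=["roi_id", "compartment", "kind", "wave_id", "onset_s", "peak_s", "amp_dff"]
        ),
        motility=pd.DataFrame(truth, columns=["process_id", "category"]),
    )
    return lengths_df, gt


# ---------------------------------------------------------------------------
# ground-truth persistence


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    """Write ground-truth tables as CSVs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"wave_id": np.arange(len(truth.wave_times_s)), "time_s": truth.wave_times_s}).to_csv(
        out / "wave_times.csv", index=False
    )
    truth.rois.to_csv(out / "rois.csv", index=False)
    truth.participation.to_csv(out / "participation.csv", index=False)
    truth.events.to_csv(out / "events.csv", index=False)
    if truth.motility is not None:
        truth.motility.to_csv(out / "motility.csv", index=False)
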