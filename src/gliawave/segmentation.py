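"""Stalk ROI segmentation and random lateral-process square placement.

Stalks appear in the time-averaged image as semiregularly spaced punctate
blobs 2–3 µm in diameter.  They are segmented by a blob-enhancing Laplacian
filter (negated Laplacian of Gaussian, σ matched to the stalk diameter),
binarized at a user-defined or Otsu-derived threshold, split with a
distance-transform watershed, and size-filtered to the expected diameter band.
Lateral-process ROIs are small squares placed uniformly at random in the
interstitial space, never overlapping a stalk pixel (they may overlap each
other).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .io import Movie


@dataclass
class ROISet:
    """Stalk label image plus square lateral-process ROIs.

    ``label_image`` holds positive integer stalk labels (0 = background).
    ``process_rois`` has columns roi_id, row, col, side_px (top-left pixel,
    half-open extent).  ROI ids are ``stalk_<label>`` and ``process_<k>``.
    """

    label_image: np.ndarray
    process_rois: pd.DataFrame
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if self.label_image.ndim != 2:
            raise ValueError("label_image must be 2-D")
        for r in self.process_rois.itertuples(index=False):
            if self.label_image[r.row : r.row + r.side_px, r.col : r.col + r.side_px].any():
                raise ValueError(f"process ROI {r.roi_id} overlaps a stalk pixel")

    @property
    def stalk_labels(self) -> np.ndarray:
        labs = np.unique(self.label_image)
        return labs[labs > 0]

    def stalk_table(self) -> pd.DataFrame:
        """Per-stalk centroid (pixels) and area."""
        rows = [
            {
                "roi_id": f"stalk_{p.label}",
                "label": p.label,
                "centroid_row": p.centroid[0],
                "centroid_col": p.centroid[1],
                "area_px": p.area,
                "equivalent_diameter_um": p.equivalent_diameter_area * self.pixel_size_um,
            }
            for p in regionprops(self.label_image)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "roi_id",
                "label",
                "centroid_row",
                "centroid_col",
                "area_px",
                "equivalent_diameter_um",
            ],
        )


def log_response(mean_image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Blob-enhancing (negated, scale-normalized) Laplacian-of-Gaussian response."""
    return -(sigma_px**2) * ndimage.gaussian_laplace(mean_image.astype(float), sigma_px)


def segment_stalks(
    mean_image: np.ndarray,
    pixel_size_um: float,
    threshold: float | None = None,
    min_diameter_um: float = 2.0,
    max_diameter_um: float = 3.0,
    stalk_diameter_um: float = 2.5,
    sigma_px: float | None = None,
) -> np.ndarray:
    """Segment stalk ROIs from a time-averaged image.

    Pipeline: blob-enhancing Laplacian filter → binarize at ``threshold``
    (Otsu on the filter response when None) → distance-transform watershed to
    split touching stalks → drop components whose equivalent diameter falls
    outside [min_diameter_um, max_diameter_um].

    Returns the int32 label image.
    """
    mean_image = np.asarray(mean_image, dtype=float)
    if not np.all(np.isfinite(mean_image)):
        raise ValueError("mean_image contains non-finite pixels")
    if np.ptp(mean_image) == 0:
        return np.zeros(mean_image.shape, dtype=np.int32)
    if sigma_px is None:
        sigma_px = stalk_diameter_um / pixel_size_um / (2.0 * np.sqrt(2.0))
    resp = log_response(mean_image, sigma_px)
    if threshold is None:
        threshold = float(threshold_otsu(resp))
    blob = resp > threshold
    if not blob.any():
        return np.zeros(mean_image.shape, dtype=np.int32)

    dist = ndimage.distance_transform_edt(blob)
    # half the minimum diameter: close enough to split discs whose centers sit
    # 0.7 diameters apart, far enough not to fragment a single disc
    min_sep_px = max(1, int(round(min_diameter_um / pixel_size_um / 2)))
    peaks = peak_local_max(
        dist, min_distance=min_sep_px, labels=blob, exclude_border=False
    )
    markers = np.zeros(blob.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers, _ = ndimage.label(blob)
    labels = watershed(-dist, markers, mask=blob)

    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    for p in regionprops(labels):
        eq_d = p.equivalent_diameter_area * pixel_size_um
        if min_diameter_um <= eq_d <= max_diameter_um:
            out[labels == p.label] = next_label
            next_label += 1
    return out


def apply_roi_edits(label_image: np.ndarray, edits: pd.DataFrame) -> np.ndarray:
    """Apply manual add/remove ROI edits from a table.

    ``edits`` columns: action ('remove' drops a label; 'add' paints a disc),
    label, row, col, radius_px.  Stand-in for the interactive adjustments an
    analyst would make by eye.
    """
    out = np.array(label_image, dtype=np.int32, copy=True)
    for e in edits.itertuples(index=False):
        if e.action == "remove":
            out[out == int(e.label)] = 0
        elif e.action == "add":
            yy, xx = np.mgrid[0 : out.shape[0], 0 : out.shape[1]]
            disc = (yy - e.row) ** 2 + (xx - e.col) ** 2 <= float(e.radius_px) ** 2
            out[disc] = int(e.label)
        else:
            raise ValueError(f"unknown ROI edit action: {e.action!r}")
    return out


def place_process_rois(
    label_image: np.ndarray,
    pixel_size_um: float,
    n_squares: int = 250,
    square_side_um: float = 2.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Place ``n_squares`` square process ROIs avoiding all stalk pixels.

    Positions are drawn uniformly (with replacement) over every top-left
    pixel whose square fits in the field and contains no stalk pixel.
    Squares may overlap each other.
    """
    if n_squares < 1:
        raise ValueError("n_squares must be >= 1")
    label_image = np.asarray(label_image)
    side = max(1, int(round(square_side_um / pixel_size_um)))
    ny, nx = label_image.shape
    if side > ny or side > nx:
        raise ValueError("square side exceeds field size")
    # sliding-window count of stalk pixels per candidate square
    stalk = (label_image > 0).astype(np.int64)
    csum = np.pad(stalk, ((1, 0), (1, 0))).cumsum(0).cumsum(1)
    win = (
        csum[side:, side:]
        - csum[:-side, side:]
        - csum[side:, :-side]
        + csum[:-side, :-side]
    )
    admissible = np.argwhere(win == 0)
    if len(admissible) == 0:
        raise ValueError(
            "no admissible square positions (field fully covered by stalk ROIs); "
            "achievable maximum is 0 squares"
        )
    rng = np.random.default_rng(seed)
    picks = admissible[rng.integers(0, len(admissible), size=n_squares)]
    return pd.DataFrame(
        {
            "roi_id": [f"process_{k}" for k in range(n_squares)],
            "row": picks[:, 0],
            "col": picks[:, 1],
            "side_px": side,
        }
    )


def extract_traces(movie: Movie, roiset: ROISet) -> pd.DataFrame:
    """Mean-intensity time series for every ROI.

    Returns a long-format DataFrame with one row per ROI: roi_id, compartment,
    and a ``values`` column holding the 1-D trace (length = movie frames).
    """
    if roiset.label_image.shape != movie.frames.shape[1:]:
        raise ValueError(
            f"ROI field shape {roiset.label_image.shape} does not match movie "
            f"frame shape {movie.frames.shape[1:]}"
        )
    frames = movie.frames
    T = frames.shape[0]
    flat = frames.reshape(T, -1)
    rows = []
    lab_flat = roiset.label_image.ravel()
    for lab in roiset.stalk_labels:
        idx = np.flatnonzero(lab_flat == lab)
        if idx.size == 0:
            raise ValueError(f"stalk ROI {lab} is empty")
        rows.append(
            {
                "roi_id": f"stalk_{lab}",
                "compartment": "stalk",
                "values": flat[:, idx].mean(axis=1).astype(float),
            }
        )
    for r in roiset.process_rois.itertuples(index=False):
        block = frames[:, r.row : r.row + r.side_px, r.col : r.col + r.side_px]
        if block.shape[1] == 0 or block.shape[2] == 0:
            raise ValueError(f"process ROI {r.roi_id} is empty")
        rows.append(
            {
                "roi_id": r.roi_id,
                "compartment": "process",
                "values": block.reshape(T, -1).mean(axis=1).astype(float),
            }
        )
    return pd.DataFrame(rows, columns=["roi_id", "compartment", "values"])


def traces_to_csv(traces: pd.DataFrame, frame_interval_s: float, path: str | Path) -> None:
    """Write traces as wide CSV: time_s column + one column per ROI."""
    T = len(traces["values"].iloc[0])
    out = pd.DataFrame({"time_s": np.arange(T) * frame_interval_s})
    for row in traces.itertuples(index=False):
        out[row.roi_id] = row.values
    comp = pd.DataFrame(
        {"roi_id": traces["roi_id"], "compartment": traces["compartment"]}
    )
    path = Path(path)
    out.to_csv(path, index=False)
    comp.to_csv(path.with_suffix(".compartments.csv"), index=False)


def traces_from_csv(path: str | Path) -> tuple[pd.DataFrame, float]:
    """Read traces written by :func:`traces_to_csv`; returns (traces, frame_interval_s)."""
    path = Path(path)
    wide = pd.read_csv(path)
    comp = pd.read_csv(path.with_suffix(".compartments.csv"))
    comp_map = dict(zip(comp["roi_id"], comp["compartment"]))
    t = wide["time_s"].to_numpy()
    interval = float(t[1] - t[0]) if len(t) > 1 else 1.0
    rows = [
        {"roi_id": c, "compartment": comp_map[c], "values": wide[c].to_numpy(dtype=float)}
        for c in wide.columns
        if c != "time_s"
    ]
    return pd.DataFrame(rows, columns=["roi_id", "compartment", "values"]), interval
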