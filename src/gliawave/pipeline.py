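"""End-to-end orchestration and ground-truth matching helpers.

``analyze_movie`` chains segmentation → trace extraction → transient
detection → wave detection → association into one result object, the same
sequence the CLI stages run file-by-file.  The matching helpers map measured
ROIs back onto the synthetic generator's true signal units, which is what
makes parameter-recovery evaluation (participation, latency, amplitudes)
possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.measure import regionprops

from .io import EphysTrace, Movie
from .segmentation import ROISet, extract_traces, place_process_rois, segment_stalks
from .signals import detect_all_transients
from .synthetic import GroundTruth
from .waves import associate_transients, detect_waves


@dataclass
class PipelineResult:
    """Everything the downstream summaries need from one FOV."""

    roiset: ROISet
    roi_table: pd.DataFrame  # roi_id, compartment
    traces: pd.DataFrame
    transients: pd.DataFrame  # wave-associated
    waves: pd.DataFrame


def analyze_movie(
    movie: Movie,
    ephys: EphysTrace,
    n_squares: int = 250,
    square_side_um: float = 2.5,
    roi_seed: int = 0,
    z_thresh: float = 3.0,
    window_s: float = 3.0,
    wave_threshold_pA: float = 50.0,
    min_iwi_s: float = 5.0,
) -> PipelineResult:
    """Run the full calcium pipeline on one paired (movie, EPSC) recording."""
    labels = segment_stalks(movie.mean_image(), movie.pixel_size_um)
    squares = place_process_rois(
        labels,
        movie.pixel_size_um,
        n_squares=n_squares,
        square_side_um=square_side_um,
        seed=roi_seed,
    )
    roiset = ROISet(labels, squares, movie.pixel_size_um)
    traces = extract_traces(movie, roiset)
    transients = detect_all_transients(traces, movie.frame_interval_s, z_thresh=z_thresh)
    waves = detect_waves(ephys, threshold_pA=wave_threshold_pA, min_iwi_s=min_iwi_s)
    transients = associate_transients(transients, waves, window_s=window_s)
    roi_table = pd.DataFrame(
        [{"roi_id": f"stalk_{l}", "compartment": "stalk"} for l in roiset.stalk_labels]
        + [{"roi_id": rid, "compartment": "process"} for rid in squares["roi_id"]]
    )
    return PipelineResult(
        roiset=roiset, roi_table=roi_table, traces=traces, transients=transients, waves=waves
    )


def match_stalks_to_truth(
    roiset: ROISet, truth: GroundTruth, max_dist_um: float = 1.5
) -> pd.DataFrame:
    """Match segmented stalk labels to true stalk centers by nearest centroid.

    Returns columns roi_id, true_roi_id (−1 when unmatched = false positive)
    and distance_um.
    """
    props = regionprops(roiset.label_image)
    true_stalks = truth.rois[truth.rois["compartment"] == "stalk"]
    centers = true_stalks[["cx_um", "cy_um"]].to_numpy(dtype=float)
    tree = cKDTree(centers)
    rows = []
    for p in props:
        cy, cx = p.centroid
        pos = np.array([(cx + 0.5) * roiset.pixel_size_um, (cy + 0.5) * roiset.pixel_size_um])
        d, i = tree.query(pos)
        matched = d <= max_dist_um
        rows.append(
            {
                "roi_id": f"stalk_{p.label}",
                "true_roi_id": int(true_stalks["roi_id"].iloc[i]) if matched else -1,
                "distance_um": float(d),
            }
        )
    return pd.DataFrame(rows, columns=["roi_id", "true_roi_id", "distance_um"])


def map_rois_to_truth(roiset: ROISet, truth: GroundTruth) -> pd.DataFrame:
    """Map every measured ROI to the true signal unit it samples.

    Stalk ROIs match the nearest true stalk center; process squares take the
    true unit underneath their center pixel (the unit holding the square's
    majority).  Returns columns roi_id, compartment, true_roi_id.
    """
    rows = list(match_stalks_to_truth(roiset, truth).itertuples(index=False))
    out = [
        {"roi_id": r.roi_id, "compartment": "stalk", "true_roi_id": r.true_roi_id}
        for r in rows
    ]
    labels = truth.unit_labels
    for r in roiset.process_rois.itertuples(index=False):
        cy = int(r.row + r.side_px // 2)
        cx = int(r.col + r.side_px // 2)
        out.append(
            {
                "roi_id": r.roi_id,
                "compartment": "process",
                "true_roi_id": int(labels[cy, cx]),
            }
        )
    return pd.DataFrame(out, columns=["roi_id", "compartment", "true_roi_id"])


def truth_participation_for_rois(
    roi_map: pd.DataFrame, truth: GroundTruth
) -> pd.DataFrame:
    """Realized ground-truth participation re-indexed to the measured ROIs.

    For each measured ROI and wave, the truth flag of the ROI's underlying
    unit.  Unmatched ROIs (true_roi_id −1) are dropped.
    """
    mapped = roi_map[roi_map["true_roi_id"] >= 0]
    part = truth.participation.rename(columns={"roi_id": "true_roi_id"})
    merged = mapped.merge(
        part[["wave_id", "true_roi_id", "participates"]], on="true_roi_id", how="inner"
    )
    return merged[["roi_id", "compartment", "wave_id", "participates"]]
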