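"""Skeleton morphometrics: tips, lengths, Sholl profiles, hull area, sublayers.

Skeletons are SWC trees with the radial stalk tagged type 2 and lateral
processes type 3.  Scalar metrics follow tracing conventions: tips are
process nodes with no children, branch points are process nodes with at least
two children, primary branches are process nodes whose parent lies on the
stalk, and total process length sums Euclidean parent-child distances over
process segments.

Sholl analysis counts ring crossings of the skeleton projected to the XY, XZ
or YZ plane, with 1 µm ring spacing.  The XY center is the registered stalk
position; the XZ/YZ center is the stalk end closest to the INL (smallest z in
this package's convention: z grows from the INL border toward the GCL).
Radii may be normalized to the IPL thickness and resampled onto a common
0–1 grid so cells with different IPL thicknesses are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .io import SWC_PROCESS, SWC_STALK, Skeleton

_PLANES = {"XY": (0, 1), "XZ": (0, 2), "YZ": (1, 2)}
SUBLAYERS = ("S1", "S2", "S3", "S4", "S5")


@dataclass
class MorphometryResult:
    """Scalar morphometrics of one traced cell."""

    n_tips: int
    total_length_um: float
    n_branch_points: int
    n_primary_branches: int
    convex_hull_area_um2: float


def skeleton_metrics(skel: Skeleton) -> MorphometryResult:
    """Tips, total process length, branch points, primary branches, hull area."""
    nodes = skel.nodes
    if not (nodes["node_type"] == SWC_STALK).any():
        raise ValueError("skeleton has no tagged stalk path (SWC type 2)")
    children = skel.children_of()
    ntype = dict(zip(nodes["node_id"].astype(int), nodes["node_type"].astype(int)))
    idx = {int(i): k for k, i in enumerate(nodes["node_id"])}
    xyz = skel.coords_um()

    n_tips = 0
    n_branch = 0
    n_primary = 0
    total_len = 0.0
    for nid, pid in zip(nodes["node_id"].astype(int), nodes["parent_id"].astype(int)):
        if ntype[nid] != SWC_PROCESS:
            continue
        if len(children[nid]) == 0:
            n_tips += 1
        if len(children[nid]) >= 2:
            n_branch += 1
        if pid != -1:
            if ntype[pid] == SWC_STALK:
                n_primary += 1
            total_len += float(np.linalg.norm(xyz[idx[nid]] - xyz[idx[pid]]))
    return MorphometryResult(
        n_tips=n_tips,
        total_length_um=total_len,
        n_branch_points=n_branch,
        n_primary_branches=n_primary,
        convex_hull_area_um2=convex_hull_area(skel),
    )


def _subdivided_points(
    segments: np.ndarray, axes: tuple[int, int], max_step_um: float = 0.1
) -> np.ndarray:
    """Projected points along all segments, subdivided to ≤ max_step_um."""
    pts = []
    for a, b in segments:
        n = max(1, int(np.ceil(np.linalg.norm(b - a) / max_step_um)))
        s = np.linspace(0.0, 1.0, n + 1)[:, None]
        pts.append((a[None, :] + s * (b - a)[None, :])[:, list(axes)])
    if not pts:
        return np.zeros((0, 2))
    return np.vstack(pts)


def register_stalk_xy(skel: Skeleton) -> np.ndarray:
    """Registered stalk XY position: mean XY of the stalk path (µm).

    Corrects for XY displacement of the stalk between GCL and INL by
    collapsing the stalk path to its mean lateral position.
    """
    stalk = skel.stalk_nodes()
    if len(stalk) == 0:
        raise ValueError("skeleton has no tagged stalk path (SWC type 2)")
    return stalk[["x", "y"]].to_numpy(dtype=float).mean(axis=0)


def sholl_center(skel: Skeleton, plane: str) -> np.ndarray:
    """Ring center for a projection plane.

    XY: registered stalk position.  XZ/YZ: the stalk end closest to the INL
    (minimum z), projected to the plane.
    """
    if plane == "XY":
        return register_stalk_xy(skel)
    stalk = skel.stalk_nodes()
    if len(stalk) == 0:
        raise ValueError("skeleton has no tagged stalk path (SWC type 2)")
    inl_end = stalk.loc[stalk["z"].idxmin(), ["x", "y", "z"]].to_numpy(dtype=float)
    ax = _PLANES[plane]
    return inl_end[list(ax)]


def sholl_profile(
    skel: Skeleton,
    plane: str = "XY",
    ring_spacing_um: float = 1.0,
    normalize_to_ipl: bool = False,
    ipl_thickness_um: float | None = None,
    max_radius_um: float | None = None,
) -> pd.DataFrame:
    """Ring-crossing counts of the projected skeleton at concentric radii.

    Only lateral-process segments are counted (the stalk defines the center).
    A segment crossing a ring twice counts twice; tangency counts zero.
    Returns columns ``radius_um``, ``intersections`` and, when normalizing,
    ``radius_norm`` = radius / IPL thickness.
    """
    if plane not in _PLANES:
        raise ValueError(f"plane must be one of {sorted(_PLANES)}")
    if normalize_to_ipl:
        if not ipl_thickness_um or ipl_thickness_um <= 0:
            raise ValueError("normalize_to_ipl requires a positive ipl_thickness_um")
    center = sholl_center(skel, plane)
    axes = _PLANES[plane]
    ntype = dict(zip(skel.nodes["node_id"].astype(int), skel.nodes["node_type"].astype(int)))
    idx = {int(i): k for k, i in enumerate(skel.nodes["node_id"])}
    xyz = skel.coords_um()
    segs = [
        (xyz[idx[int(pid)]], xyz[idx[int(nid)]])
        for nid, pid in zip(skel.nodes["node_id"], skel.nodes["parent_id"])
        if pid != -1 and ntype[int(nid)] == SWC_PROCESS
    ]
    # radial distance of sub-piece endpoints, pieces paired within segments only
    r_start: list[np.ndarray] = []
    r_end: list[np.ndarray] = []
    r_max = 0.0
    for a, b in segs:
        pts = _subdivided_points(np.asarray([(a, b)]), axes)
        r = np.linalg.norm(pts - center[None, :], axis=1)
        if r.size >= 2:
            r_start.append(r[:-1])
            r_end.append(r[1:])
        r_max = max(r_max, float(r.max()))
    ra = np.concatenate(r_start) if r_start else np.zeros(0)
    rb = np.concatenate(r_end) if r_end else np.zeros(0)
    if max_radius_um is None:
        max_radius_um = r_max + ring_spacing_um
    radii = np.arange(ring_spacing_um, max_radius_um + 1e-9, ring_spacing_um)
    counts = np.zeros(len(radii), dtype=int)
    for k, rho in enumerate(radii):
        # points exactly on the ring are treated as inside, so a path passing
        # through a ring point counts one crossing and tangency counts zero
        sa = np.where(ra > rho, 1, -1)
        sb = np.where(rb > rho, 1, -1)
        counts[k] = int(np.count_nonzero(sa != sb))
    out = pd.DataFrame({"radius_um": radii, "intersections": counts})
    if normalize_to_ipl:
        out["radius_norm"] = out["radius_um"] / ipl_thickness_um
    return out


def resample_normalized_sholl(
    profile: pd.DataFrame, grid_step: float = 0.01
) -> pd.DataFrame:
    """Linearly interpolate a normalized Sholl profile onto a common 0–1 grid."""
    if "radius_norm" not in profile.columns:
        raise ValueError("profile must carry a radius_norm column (normalize_to_ipl=True)")
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    x = np.r_[0.0, profile["radius_norm"].to_numpy(dtype=float)]
    y = np.r_[0.0, profile["intersections"].to_numpy(dtype=float)]
    vals = np.interp(grid, x, y, left=0.0, right=0.0)
    return pd.DataFrame({"radius_norm": grid, "intersections": vals})


def convex_hull_area(skel: Skeleton, max_step_um: float = 0.1) -> float:
    """Area (µm²) of the convex hull of the skeleton's XY maximum projection.

    Segments are subdivided to ≤ ``max_step_um`` before projection.
    Degenerate (collinear or near-empty) skeletons return 0 with a warning.
    """
    segs = skel.segments_um()
    if len(segs) == 0:
        pts = skel.coords_um()[:, :2]
    else:
        pts = _subdivided_points(segs, (0, 1), max_step_um)
    pts = np.unique(np.round(pts, 9), axis=0)
    if len(pts) < 3:
        warnings.warn("degenerate skeleton: convex hull undefined, area 0", stacklevel=2)
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        warnings.warn("collinear skeleton: convex hull degenerate, area 0", stacklevel=2)
        return 0.0
    return float(hull.volume)  # in 2-D, .volume is the enclosed area


def sublayer_distribution(
    tip_depths_um: np.ndarray, ipl_bounds_um: tuple[float, float]
) -> pd.Series:
    """Bin process-tip depths into the five IPL sublayers S1–S5.

    ``ipl_bounds_um`` = (INL border depth, GCL border depth); S1 abuts the
    INL.  Bins are half-open [edge, next) with the last bin closed; tips
    outside the IPL are dropped with a warning.
    """
    inl, gcl = ipl_bounds_um
    if not gcl > inl:
        raise ValueError(f"inverted IPL bounds: INL {inl} must be < GCL {gcl}")
    depths = np.asarray(tip_depths_um, dtype=float)
    inside = (depths >= inl) & (depths <= gcl)
    if np.any(~inside):
        warnings.warn(
            f"{int(np.count_nonzero(~inside))} tip(s) outside the IPL dropped", stacklevel=2
        )
        depths = depths[inside]
    frac = (depths - inl) / (gcl - inl)
    bins = np.minimum((frac * 5).astype(int), 4)  # last bin closed at the GCL border
    counts = np.bincount(bins, minlength=5)
    return pd.Series(counts, index=list(SUBLAYERS), name="n_tips")
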