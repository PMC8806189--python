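"""Shared data model and file I/O.

Conventions
-----------
* Pixel indices are 0-based; physical coordinates in µm are ``index * pixel_size_um``.
* The timestamp of frame ``k`` is ``t0_s + k * frame_interval_s`` (acquisition start
  of the frame).  Imaging and electrophysiology share one absolute clock; any
  alignment offset is applied upstream.
* SWC node types: 1 is reserved (soma), 2 tags the radial stalk path, 3 tags
  lateral processes.

Movies are stored as frame-major multi-page TIFF (16-bit) with a JSON sidecar
(``<movie>.json``) holding ``frame_interval_s``, ``pixel_size_um`` and ``t0_s``;
electrophysiology traces as two-column CSV (``time_s``, ``current_pA``);
skeletons as standard 7-column SWC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

SWC_STALK = 2
SWC_PROCESS = 3
_KNOWN_SWC_TYPES = frozenset({0, 1, SWC_STALK, SWC_PROCESS, 4, 5, 6, 7})

_SWC_COLUMNS = ["node_id", "node_type", "x", "y", "z", "radius", "parent_id"]


@dataclass
class Movie:
    """A registered single-channel fluorescence time series.

    Parameters
    ----------
    frames : ndarray, shape (T, Y, X)
        Intensity in arbitrary units, non-negative.
    frame_interval_s : float
        Seconds between successive frames.
    pixel_size_um : float
        Lateral pixel size in µm.
    t0_s : float
        Absolute time of the first frame, seconds.
    """

    frames: np.ndarray
    frame_interval_s: float
    pixel_size_um: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or min(self.frames.shape) < 1:
            raise ValueError(f"frames must be a T×Y×X array, got shape {self.frames.shape}")
        if not self.frame_interval_s > 0:
            raise ValueError(f"frame_interval_s must be > 0, got {self.frame_interval_s}")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def frame_times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_frames) * self.frame_interval_s

    def mean_image(self) -> np.ndarray:
        """Temporal average intensity projection."""
        return self.frames.mean(axis=0)


@dataclass
class EphysTrace:
    """A voltage-clamp current trace on the imaging clock.

    ``time_s`` must be strictly increasing and uniformly sampled
    (relative tolerance 1e-9 on the sample interval).
    """

    time_s: np.ndarray
    current_pA: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if self.time_s.shape != self.current_pA.shape or self.time_s.ndim != 1:
            raise ValueError("time_s and current_pA must be 1-D vectors of equal length")
        if self.time_s.size >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise ValueError(f"time_s must be strictly increasing (violation at sample {i + 1})")
            if np.ptp(dt) > 1e-9 * dt[0]:
                raise ValueError("time_s must be uniformly sampled")

    @property
    def sample_interval_s(self) -> float:
        if self.time_s.size < 2:
            raise ValueError("trace too short to define a sample interval")
        return float(self.time_s[1] - self.time_s[0])

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / self.sample_interval_s


@dataclass
class Skeleton:
    """A traced 3-D process tree with SWC semantics.

    ``nodes`` has columns node_id, node_type, x, y, z, radius, parent_id
    (coordinates in µm; parent_id −1 marks the root).  Exactly one root is
    required and parent pointers must form a tree.
    """

    nodes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        nodes = pd.DataFrame(self.nodes)
        missing = [c for c in _SWC_COLUMNS if c not in nodes.columns]
        if missing:
            raise ValueError(f"skeleton nodes missing columns: {missing}")
        self.nodes = nodes.reset_index(drop=True)
        _validate_skeleton(self.nodes)

    @property
    def root_id(self) -> int:
        return int(self.nodes.loc[self.nodes["parent_id"] == -1, "node_id"].iloc[0])

    def children_of(self) -> dict[int, list[int]]:
        """Map node_id -> list of child node_ids."""
        out: dict[int, list[int]] = {int(i): [] for i in self.nodes["node_id"]}
        for nid, pid in zip(self.nodes["node_id"], self.nodes["parent_id"]):
            if pid != -1:
                out[int(pid)].append(int(nid))
        return out

    def coords_um(self) -> np.ndarray:
        return self.nodes[["x", "y", "z"]].to_numpy(dtype=float)

    def segments_um(self) -> np.ndarray:
        """Parent-child segments as an (n, 2, 3) array of endpoints in µm."""
        idx = {int(i): k for k, i in enumerate(self.nodes["node_id"])}
        xyz = self.coords_um()
        segs = [
            (xyz[idx[int(pid)]], xyz[idx[int(nid)]])
            for nid, pid in zip(self.nodes["node_id"], self.nodes["parent_id"])
            if pid != -1
        ]
        return np.asarray(segs, dtype=float).reshape(-1, 2, 3)

    def stalk_nodes(self) -> pd.DataFrame:
        return self.nodes[self.nodes["node_type"] == SWC_STALK]


def _validate_skeleton(nodes: pd.DataFrame) -> None:
    ids = nodes["node_id"].to_numpy()
    if len(set(ids.tolist())) != len(ids):
        raise ValueError("duplicate node ids in skeleton")
    if not np.all(np.isfinite(nodes[["x", "y", "z"]].to_numpy(dtype=float))):
        bad = nodes.index[~np.isfinite(nodes[["x", "y", "z"]].to_numpy(dtype=float)).all(axis=1)]
        raise ValueError(f"non-finite coordinates at node rows {list(bad)}")
    unknown = set(int(t) for t in nodes["node_type"]) - _KNOWN_SWC_TYPES
    if unknown:
        raise ValueError(f"unknown SWC node types: {sorted(unknown)}")
    roots = nodes[nodes["parent_id"] == -1]
    if len(roots) != 1:
        raise ValueError(f"skeleton must have exactly one root, found {len(roots)}")
    id_set = set(int(i) for i in ids)
    parents = {int(n): int(p) for n, p in zip(nodes["node_id"], nodes["parent_id"])}
    for nid, pid in parents.items():
        if pid != -1 and pid not in id_set:
            raise ValueError(f"node {nid} references missing parent {pid}")
    # cycle check by walking to the root from every node
    for start in parents:
        seen = set()
        cur = start
        while cur != -1:
            if cur in seen:
                raise ValueError(f"cycle in parent pointers involving node {cur}")
            seen.add(cur)
            cur = parents[cur]


# ---------------------------------------------------------------------------
# movies


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write a movie as 16-bit multi-page TIFF plus a JSON metadata sidecar.

    Float frames are rounded and clipped to the uint16 range; integer frames
    already within range round-trip losslessly.
    """
    path = Path(path)
    frames = movie.frames
    if not np.issubdtype(frames.dtype, np.integer):
        frames = np.round(frames)
    frames = np.clip(frames, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {
        "frame_interval_s": movie.frame_interval_s,
        "pixel_size_um": movie.pixel_size_um,
        "t0_s": movie.t0_s,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_movie(path: str | Path) -> Movie:
    """Read a multi-page TIFF movie with its JSON metadata sidecar."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"movie metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("frame_interval_s", "pixel_size_um"):
        if key not in meta:
            raise ValueError(f"movie metadata missing required field '{key}'")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return Movie(
        frames=frames,
        frame_interval_s=float(meta["frame_interval_s"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        t0_s=float(meta.get("t0_s", 0.0)),
    )


# ---------------------------------------------------------------------------
# ephys traces


def write_ephys(trace: EphysTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "current_pA": trace.current_pA}).to_csv(
        path, index=False
    )


def read_ephys(path: str | Path) -> EphysTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "current_pA"):
        if col not in df.columns:
            raise ValueError(f"ephys CSV missing column '{col}'")
    return EphysTrace(df["time_s"].to_numpy(), df["current_pA"].to_numpy())


# ---------------------------------------------------------------------------
# SWC skeletons


def read_swc(path: str | Path) -> Skeleton:
    """Read a standard 7-column SWC file ('#' comments allowed)."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"{path}:{lineno}: expected 7 SWC columns, got {len(parts)}")
        rows.append(
            {
                "node_id": int(parts[0]),
                "node_type": int(parts[1]),
                "x": float(parts[2]),
                "y": float(parts[3]),
                "z": float(parts[4]),
                "radius": float(parts[5]),
                "parent_id": int(parts[6]),
            }
        )
    if not rows:
        raise ValueError(f"{path}: no SWC records")
    return Skeleton(pd.DataFrame(rows))


def write_swc(skel: Skeleton, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# node_id type x y z radius parent_id\n")
        for row in skel.nodes.itertuples(index=False):
            fh.write(
                f"{int(row.node_id)} {int(row.node_type)} {row.x:.6g} {row.y:.6g} "
                f"{row.z:.6g} {row.radius:.6g} {int(row.parent_id)}\n"
            )
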