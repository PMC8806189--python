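"""Classification of lateral-process length trajectories into motility classes.

Each lateral process is followed across volumetric timepoints (typically six,
2 min apart) as a length in µm, with NaN where the process is absent.  The
seven categories are: extending, retracting, new (sprouted during the
series), lost (eliminated), extension-then-retraction,
retraction-then-extension, and stable.

This scoring is traditionally done by eye on temporally color-coded
projections; here an explicit rule substitutes for the annotator: length
changes smaller than ``delta_um`` (default 0.5 µm, about half the 1 µm axial
step of the source volumes) are treated as no motion.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .synthetic import MOTILITY_CATEGORIES


def classify_motility(lengths_um: np.ndarray, delta_um: float = 0.5) -> str:
    """Assign one motility category to a length trajectory.

    Appearance (absent→present) anywhere makes the process 'new'; otherwise
    disappearance makes it 'lost'.  For continuously present processes the
    signed per-interval steps are thresholded at ``delta_um``; all-positive
    steps mean 'extending', all-negative 'retracting', a positive phase
    followed by a negative one 'ext_then_ret' (and vice versa), and no
    supra-threshold step 'stable'.  Multi-reversal patterns take the
    combination category of their first two phases.
    """
    lengths = np.asarray(lengths_um, dtype=float)
    if lengths.size < 2:
        raise ValueError("trajectory needs at least two timepoints")
    present = ~np.isnan(lengths)
    if not present.any():
        raise ValueError("all-absent trajectory cannot be classified")
    if np.any(~present[:-1] & present[1:]):
        return "new"
    if np.any(present[:-1] & ~present[1:]):
        return "lost"
    steps = np.diff(lengths)
    signs = np.sign(steps)
    signs[np.abs(steps) < delta_um] = 0
    nonzero = signs[signs != 0]
    if nonzero.size == 0:
        return "stable"
    if np.all(nonzero > 0):
        return "extending"
    if np.all(nonzero < 0):
        return "retracting"
    return "ext_then_ret" if nonzero[0] > 0 else "ret_then_ext"


def classify_table(
    lengths: pd.DataFrame,
    delta_um: float = 0.5,
    group_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Classify every process in a long-format length table.

    ``lengths`` columns: process_id, timepoint_index, length_um (NaN/empty
    where absent) plus optional grouping columns (cell_id, condition,
    sublayer) carried through to the output.
    """
    rows = []
    carried = [c for c in ("cell_id", "condition", "sublayer") if c in lengths.columns]
    carried += [c for c in group_cols if c in lengths.columns and c not in carried]
    for pid, g in lengths.groupby("process_id"):
        g = g.sort_values("timepoint_index")
        row = {"process_id": pid, "category": classify_motility(g["length_um"].to_numpy(), delta_um)}
        for c in carried:
            row[c] = g[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def motility_summary(
    records: pd.DataFrame, group_by: tuple[str, ...] = ()
) -> pd.DataFrame:
    """Per-group category counts and proportions, plus the motile aggregate.

    ``records`` needs a ``category`` column (from :func:`classify_table`).
    Proportions sum to 1 within each group; ``motile`` = 1 − stable.
    Empty groups are omitted with a warning.
    """
    group_by = tuple(c for c in group_by if c in records.columns)
    if group_by:
        grouped = list(records.groupby(list(group_by)))
    else:
        grouped = [(("all",), records)]
    rows = []
    for key, g in grouped:
        if len(g) == 0:
            warnings.warn(f"empty motility group {key} omitted", stacklevel=2)
            continue
        if not isinstance(key, tuple):
            key = (key,)
        n = len(g)
        counts = g["category"].value_counts()
        base = dict(zip(group_by, key)) if group_by else {}
        for cat in MOTILITY_CATEGORIES:
            k = int(counts.get(cat, 0))
            rows.append({**base, "category": cat, "count": k, "proportion": k / n})
        stable = int(counts.get("stable", 0))
        rows.append(
            {**base, "category": "motile", "count": n - stable, "proportion": (n - stable) / n}
        )
    return pd.DataFrame(rows)


def read_lengths_csv(path) -> pd.DataFrame:
    """Read a long-format process-length CSV (empty cells = absent)."""
    df = pd.read_csv(path)
    for col in ("process_id", "timepoint_index", "length_um"):
        if col not in df.columns:
            raise ValueError(f"length table missing column '{col}'")
    return df
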