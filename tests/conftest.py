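import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import gliawave as gw

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_cfg() -> gw.SimConfig:
    """Small noiseless field: every ROI participates in the single wave."""
    return gw.SimConfig(
        field_size_um=(40.0, 40.0),
        n_stalks=9,
        duration_s=60.0,
        wave_rate_per_min=1.0,
        p_participate_stalk=1.0,
        p_participate_process=1.0,
        spont_rate_hz=0.0,
        noise_sigma=0.0,
        photon_scale=0.0,
        epsc_noise_pA=0.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def clean_movie(clean_cfg):
    return gw.simulate_movie(clean_cfg)


@pytest.fixture(scope="session")
def example_skeleton() -> gw.Skeleton:
    """Vertical 10 µm stalk with three straight 5 µm lateral processes."""
    rows = [
        # stalk along z
        (1, 2, 0.0, 0.0, 0.0, 0.5, -1),
        (2, 2, 0.0, 0.0, 5.0, 0.5, 1),
        (3, 2, 0.0, 0.0, 10.0, 0.5, 2),
        # three unbranched 5 µm processes off stalk nodes
        (4, 3, 5.0, 0.0, 5.0, 0.3, 2),
        (5, 3, 0.0, 5.0, 5.0, 0.3, 2),
        (6, 3, -5.0, 0.0, 10.0, 0.3, 3),
    ]
    return gw.Skeleton(
        pd.DataFrame(
            rows, columns=["node_id", "node_type", "x", "y", "z", "radius", "parent_id"]
        )
    )


def star_skeleton(k: int, spoke_len: float = 5.0, plane: str = "XY") -> gw.Skeleton:
    """k straight process spokes radiating from a one-node stalk, in one plane.

    The spokes lie in the named projection plane so every projected spoke
    keeps its full length — the exact-count Sholl oracle.
    """
    axes = {"XY": (0, 1), "XZ": (0, 2), "YZ": (1, 2)}[plane]
    rows = [(1, 2, 0.0, 0.0, 0.0, 0.5, -1)]
    for i in range(k):
        ang = 2 * np.pi * i / k
        xyz = [0.0, 0.0, 0.0]
        xyz[axes[0]] = spoke_len * np.cos(ang)
        xyz[axes[1]] = spoke_len * np.sin(ang)
        rows.append((2 + i, 3, *xyz, 0.3, 1))
    return gw.Skeleton(
        pd.DataFrame(
            rows, columns=["node_id", "node_type", "x", "y", "z", "radius", "parent_id"]
        )
    )
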