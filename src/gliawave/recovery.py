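"""Parameter-recovery benchmarks: generator truth in, pipeline estimates out.

Each function builds a synthetic scenario with known ground truth, runs the
full pipeline (segmentation → traces → detection → wave association →
summaries) and returns the recovered quantity next to the truth it should
match.  These are the package's own verification workloads; the test suite
asserts on them and the acceptance script reports them.

Scenario scale: recovery fields are 60×60 µm with 16 stalks (a scaled-down
FOV that keeps full stalk/process geometry), imaged at 2 Hz with waves every
~40 s — the realistic inter-wave interval regime in which whole-trace
z-scoring behaves as intended.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pipeline import analyze_movie, map_rois_to_truth, match_stalks_to_truth, truth_participation_for_rois
from .synthetic import GroundTruth, SimConfig, simulate_epsc_trace, simulate_motility_series, simulate_movie
from .motility import classify_table
from .waves import chance_baseline, condition_fold_change, latency_table, participation, response_summary
from .stats import chisq_goodness_of_fit, wilcoxon_tests
from .synthetic import MOTILITY_CATEGORIES


def _recovery_config(seed: int, **overrides) -> SimConfig:
    base = dict(
        field_size_um=(60.0, 60.0),
        n_stalks=16,
        frame_rate_hz=2.0,
        wave_rate_per_min=1.5,
        spont_rate_hz=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def run_fov(config: SimConfig, roi_seed: int, n_squares: int = 250):
    """Simulate one FOV and run the full pipeline on it."""
    movie, truth = simulate_movie(config)
    ephys = simulate_epsc_trace(config, truth.wave_times_s)
    result = analyze_movie(movie, ephys, n_squares=n_squares, roi_seed=roi_seed)
    return movie, truth, result


def participation_recovery(
    seed: int,
    p_stalk: float = 0.5,
    p_process: float = 0.9,
    duration_s: float = 4150.0,
) -> dict:
    """Recover wave-participation probabilities from a ~100-wave recording.

    Returns per compartment: the pipeline estimate (mean over waves of the
    per-wave responding proportion), the realized ground-truth proportion for
    the same measured ROIs (each ROI inherits the truth flag of the unit it
    samples), and 3 SE of the estimate (SE of the mean over waves).
    """
    config = _recovery_config(
        seed, p_participate_stalk=p_stalk, p_participate_process=p_process,
        duration_s=duration_s,
    )
    _, truth, res = run_fov(config, roi_seed=seed + 1)
    part = participation(res.transients, res.roi_table, res.waves)
    roi_map = map_rois_to_truth(res.roiset, truth)
    truth_part = truth_participation_for_rois(roi_map, truth)
    out = {"n_waves": int(len(res.waves))}
    for comp in ("stalk", "process"):
        sub = part.loc[part["compartment"] == comp, "proportion"]
        t = truth_part[truth_part["compartment"] == comp]
        out[comp] = {
            "recovered": float(sub.mean()),
            "truth_realized": float(t.groupby("wave_id")["participates"].mean().mean()),
            "truth_parameter": p_stalk if comp == "stalk" else p_process,
            "se3": 3.0 * float(sub.std(ddof=1) / np.sqrt(len(sub))),
        }
    return out


def chance_baseline_poisson(
    seed: int,
    rate_hz: float = 0.01,
    duration_s: float = 500.0,
    n_rois: int = 40,
    n_seeds: int = 50,
    window_s: float = 3.0,
) -> dict:
    """Chance baseline under homogeneous-Poisson spontaneous transients.

    The closed form for the probability of at least one event within ±w of a
    random time is 1 − exp(−2wr); the measured baseline is averaged over
    ``n_seeds`` independent event realizations.
    """
    rng = np.random.default_rng(seed)
    rois = pd.DataFrame(
        {"roi_id": [f"r{i}" for i in range(n_rois)], "compartment": ["process"] * n_rois}
    )
    vals = []
    for _ in range(n_seeds):
        rows = []
        for rid in rois["roi_id"]:
            for t in rng.uniform(0, duration_s, size=rng.poisson(rate_hz * duration_s)):
                rows.append({"roi_id": rid, "compartment": "process", "peak_time_s": t})
        tr = pd.DataFrame(rows, columns=["roi_id", "compartment", "peak_time_s"])
        vals.append(
            chance_baseline(
                tr, rois, duration_s=duration_s, n_times=50, window_s=window_s,
                seed=int(rng.integers(1 << 31)),
            )
        )
    vals = np.asarray(vals)
    return {
        "measured": float(vals.mean()),
        "expected": float(1.0 - np.exp(-2.0 * window_s * rate_hz)),
        "se3": 3.0 * float(vals.std(ddof=1) / np.sqrt(len(vals))),
    }


def latency_recovery(
    seeds: range,
    latency_offset_s: float = 0.5,
    duration_s: float = 2100.0,
) -> dict:
    """Recover the stalk-after-process latency from ~50-wave recordings.

    Returns the per-seed pipeline medians of the per-wave median latency and
    the tolerance (one frame interval) within which recovery is judged.
    """
    medians = []
    n_waves = []
    frame_interval = None
    for seed in seeds:
        config = _recovery_config(
            seed, latency_offset_s=latency_offset_s, duration_s=duration_s,
            p_participate_stalk=0.6, p_participate_process=0.9,
        )
        movie, truth, res = run_fov(config, roi_seed=seed + 1)
        frame_interval = movie.frame_interval_s
        lat = latency_table(res.transients, res.waves)
        med = lat.loc[lat["roi_id"] == "median", "latency_s"]
        medians.append(float(med.median()))
        n_waves.append(int(len(res.waves)))
    return {
        "per_seed_median_s": medians,
        "median_s": float(np.median(medians)),
        "true_offset_s": latency_offset_s,
        "tolerance_s": frame_interval,
        "n_waves": n_waves,
    }


def fold_change_recovery(
    n_fovs: int = 6,
    seed: int = 0,
    amp_factor: float = 2.0,
    participation_factor: float = 0.5,
    duration_s: float = 1200.0,
) -> dict:
    """Recover condition fold-changes from paired synthetic FOVs.

    Condition B doubles the stalk transient amplitude and halves the stalk
    participation probability relative to condition A; the pipeline should
    recover per-FOV fold-changes of 2.0 (raw ΔF/F amplitude) and 0.5
    (participation) for the stalk compartment.
    """
    sums_a, sums_b = [], []
    for fov in range(n_fovs):
        common = dict(duration_s=duration_s)
        cfg_a = _recovery_config(seed + 10 * fov + 1, **common)
        cfg_b = _recovery_config(
            seed + 10 * fov + 2,
            amp_stalk=SimConfig().amp_stalk * amp_factor,
            p_participate_stalk=SimConfig().p_participate_stalk * participation_factor,
            **common,
        )
        for cfg, acc, cond in ((cfg_a, sums_a, "A"), (cfg_b, sums_b, "B")):
            _, _, res = run_fov(cfg, roi_seed=seed + fov)
            acc.append(
                response_summary(
                    res.transients, res.roi_table, res.waves, fov=f"fov{fov}", condition=cond
                )
            )
    sa, sb = pd.concat(sums_a), pd.concat(sums_b)
    out = {}
    for metric, target in (("amplitude_dff", amp_factor), ("participation", participation_factor)):
        fc = condition_fold_change(sa, sb, metric=metric)
        stalk = fc.loc[fc["compartment"] == "stalk", "fold_change"].to_numpy(dtype=float)
        out[metric] = {
            "recovered_mean": float(stalk.mean()),
            "target": target,
            "se3": 3.0 * float(stalk.std(ddof=1) / np.sqrt(len(stalk))),
            "per_fov": stalk.tolist(),
        }
    return out


def segmentation_recovery(n_seeds: int = 20, seed0: int = 0) -> dict:
    """Stalk recall and false positives on noiseless synthetic fields."""
    hits = total = fps = 0
    from .segmentation import ROISet, place_process_rois, segment_stalks

    for seed in range(seed0, seed0 + n_seeds):
        config = _recovery_config(
            seed, duration_s=10.0, wave_rate_per_min=0.0,
            noise_sigma=0.0, photon_scale=0.0,
        )
        movie, truth = simulate_movie(config)
        labels = segment_stalks(movie.mean_image(), config.pixel_size_um)
        squares = place_process_rois(labels, config.pixel_size_um, n_squares=5, seed=seed)
        match = match_stalks_to_truth(ROISet(labels, squares, config.pixel_size_um), truth)
        hits += int((match["true_roi_id"] >= 0).sum())
        fps += int((match["true_roi_id"] < 0).sum())
        total += config.n_stalks
    return {
        "recall": hits / total,
        "false_positives_per_field": fps / n_seeds,
        "n_fields": n_seeds,
    }


def motility_recovery(n_processes: int = 700, seed: int = 0) -> dict:
    """Label agreement of the motility classifier on noiseless trajectories."""
    mix = {c: 1.0 / len(MOTILITY_CATEGORIES) for c in MOTILITY_CATEGORIES}
    lengths, truth = simulate_motility_series(n_processes, 6, mix, seed=seed)
    records = classify_table(lengths, delta_um=0.5)
    merged = records.merge(truth.motility, on="process_id", suffixes=("_got", "_true"))
    return {
        "agreement": float((merged["category_got"] == merged["category_true"]).mean()),
        "n": int(len(merged)),
    }


def statistical_calibration(seed: int = 0, n_reps: int = 1000) -> dict:
    """Type-I error of the χ² goodness-of-fit and Wilcoxon tests under nulls."""
    rng = np.random.default_rng(seed)
    rej_chisq = sum(
        chisq_goodness_of_fit(rng.multinomial(100, [0.2] * 5)).p_value < 0.05
        for _ in range(n_reps)
    )
    rej_signed = sum(
        wilcoxon_tests(rng.normal(size=20), np.zeros(20), paired=True).p_value < 0.05
        for _ in range(n_reps)
    )
    rej_ranksum = sum(
        wilcoxon_tests(rng.normal(size=12), rng.normal(size=12), paired=False).p_value < 0.05
        for _ in range(n_reps)
    )
    se3 = 3.0 * float(np.sqrt(0.05 * 0.95 / n_reps))
    return {
        "chisq_gof_type1": rej_chisq / n_reps,
        "wilcoxon_signed_rank_type1": rej_signed / n_reps,
        "wilcoxon_rank_sum_type1": rej_ranksum / n_reps,
        "nominal": 0.05,
        "se3": se3,
        "n_reps": n_reps,
    }
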