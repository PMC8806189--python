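import numpy as np
import pandas as pd
import pytest

import gliawave as gw


def transient_table(times, compartments=None, roi_ids=None):
    times = np.asarray(times, dtype=float)
    n = len(times)
    return pd.DataFrame(
        {
            "roi_id": roi_ids if roi_ids is not None else [f"r{i}" for i in range(n)],
            "compartment": compartments if compartments is not None else ["stalk"] * n,
            "onset_time_s": times - 0.5,
            "peak_time_s": times,
            "peak_z": np.full(n, 4.0),
            "peak_dff": np.full(n, 1.0),
            "wave_id": np.full(n, -1),
        }
    )


def wave_table(times):
    times = np.asarray(times, dtype=float)
    iwi = np.r_[np.nan, np.diff(times)] if len(times) else np.array([])
    return pd.DataFrame(
        {
            "wave_id": np.arange(len(times)),
            "peak_time_s": times,
            "magnitude_pA": np.full(len(times), 100.0),
            "iwi_s": iwi,
        }
    )


class TestDetectWaves:
    def test_flat_trace_empty(self):
        trace = gw.EphysTrace(np.arange(1000) / 100.0, np.zeros(1000))
        assert len(gw.detect_waves(trace)) == 0

    def test_synthetic_waves_recovered_with_iwis(self, clean_cfg):
        cfg = gw.SimConfig(**{**clean_cfg.to_dict(), "duration_s": 100.0})
        trace = gw.simulate_epsc_trace(cfg, [10.0, 40.0, 75.0])
        table = gw.detect_waves(trace, threshold_pA=50.0)
        assert len(table) == 3
        np.testing.assert_allclose(table["peak_time_s"], [10, 40, 75], atol=0.1)
        np.testing.assert_allclose(table["iwi_s"].to_numpy()[1:], [30, 35], atol=0.2)
        assert table["magnitude_pA"].min() > 0
        assert np.isnan(table["iwi_s"].iloc[0])

    def test_close_deflections_merged(self, clean_cfg):
        cfg = gw.SimConfig(**{**clean_cfg.to_dict(), "duration_s": 40.0})
        with pytest.warns(UserWarning, match="overlap"):
            trace = gw.simulate_epsc_trace(cfg, [10.0, 10.5])
        table = gw.detect_waves(trace, threshold_pA=50.0, min_iwi_s=5.0)
        assert len(table) == 1

    def test_magnitude_is_absolute_peak(self, clean_cfg):
        trace = gw.simulate_epsc_trace(clean_cfg, [20.0])
        table = gw.detect_waves(trace, threshold_pA=50.0)
        assert table["magnitude_pA"].iloc[0] == pytest.approx(clean_cfg.epsc_amp_pA, rel=0.01)


class TestAssociateTransients:
    def test_within_window_associated(self):
        out = gw.associate_transients(transient_table([10.0]), wave_table([8.5]))
        assert out["wave_id"].iloc[0] == 0

    def test_outside_window_spontaneous(self):
        out = gw.associate_transients(transient_table([12.0]), wave_table([8.5]))
        assert out["wave_id"].iloc[0] == -1

    def test_empty_wave_table_all_spontaneous(self):
        out = gw.associate_transients(transient_table([5.0, 9.0]), wave_table([]))
        assert (out["wave_id"] == -1).all()

    def test_tie_goes_to_earlier_wave(self):
        out = gw.associate_transients(transient_table([10.0]), wave_table([8.0, 12.0]))
        assert out["wave_id"].iloc[0] == 0

    def test_idempotent(self):
        t = transient_table([4.0, 10.0, 30.0])
        w = wave_table([8.0, 29.0])
        once = gw.associate_transients(t, w)
        twice = gw.associate_transients(once, w)
        pd.testing.assert_frame_equal(once, twice)

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(123)
        waves = wave_table(np.sort(rng.uniform(0, 600, size=40)))
        wt = waves["peak_time_s"].to_numpy()
        t = rng.uniform(0, 600, size=2000)
        out = gw.associate_transients(transient_table(t), waves, window_s=3.0)
        for ti, got in zip(t, out["wave_id"]):
            d = np.abs(wt - ti)
            best = int(np.argmin(d))  # argmin takes the first = earlier wave on ties
            expected = best if d[best] <= 3.0 else -1
            assert got == expected


class TestParticipation:
    def _rois(self, n_stalk=2, n_proc=2):
        return pd.DataFrame(
            {
                "roi_id": [f"s{i}" for i in range(n_stalk)] + [f"p{i}" for i in range(n_proc)],
                "compartment": ["stalk"] * n_stalk + ["process"] * n_proc,
            }
        )

    def test_all_respond_gives_one(self):
        rois = self._rois()
        waves = wave_table([10.0])
        t = transient_table(
            [10.0] * 4,
            compartments=["stalk", "stalk", "process", "process"],
            roi_ids=["s0", "s1", "p0", "p1"],
        )
        assoc = gw.associate_transients(t, waves)
        part = gw.participation(assoc, rois, waves)
        assert (part["proportion"] == 1.0).all()

    def test_no_transients_gives_zero(self):
        part = gw.participation(transient_table([]), self._rois(), wave_table([10.0, 50.0]))
        assert (part["proportion"] == 0.0).all()

    def test_empty_compartment_gives_nan(self):
        rois = self._rois(n_stalk=2, n_proc=0)
        part = gw.participation(transient_table([]), rois, wave_table([10.0]))
        assert np.isnan(part.loc[part["compartment"] == "process", "proportion"]).all()

    def test_roi_counted_once_per_wave(self):
        rois = self._rois(n_stalk=1, n_proc=0)
        waves = wave_table([10.0])
        t = transient_table([9.0, 11.0], compartments=["stalk"] * 2, roi_ids=["s0", "s0"])
        assoc = gw.associate_transients(t, waves)
        part = gw.participation(assoc, rois, waves)
        assert part.loc[part["compartment"] == "stalk", "proportion"].iloc[0] == 1.0


class TestChanceBaseline:
    def test_no_transients_zero(self):
        rois = pd.DataFrame({"roi_id": ["a", "b"], "compartment": ["stalk", "stalk"]})
        assert gw.chance_baseline(transient_table([]), rois, duration_s=100.0, seed=0) == 0.0

    def test_saturated_rois_one(self):
        rois = pd.DataFrame({"roi_id": ["a"], "compartment": ["stalk"]})
        t = transient_table(np.arange(0.0, 100.0, 1.0), roi_ids=["a"] * 100)
        assert gw.chance_baseline(t, rois, duration_s=100.0, seed=0) == 1.0

    def test_short_recording_rejected(self):
        rois = pd.DataFrame({"roi_id": ["a"], "compartment": ["stalk"]})
        with pytest.raises(ValueError, match="shorter"):
            gw.chance_baseline(transient_table([]), rois, duration_s=4.0, window_s=3.0)

    def test_poisson_rate_matches_closed_form(self):
        # closed form: P(≥1 event within ±w) = 1 − exp(−2wr)
        r, w, duration = 0.01, 3.0, 500.0
        rng = np.random.default_rng(99)
        vals = []
        for _ in range(30):
            rows = []
            for roi in range(40):
                n = rng.poisson(r * duration)
                for t in rng.uniform(0, duration, size=n):
                    rows.append({"roi_id": f"r{roi}", "peak": t})
            t = transient_table(
                [x["peak"] for x in rows], roi_ids=[x["roi_id"] for x in rows]
            )
            rois = pd.DataFrame(
                {"roi_id": [f"r{i}" for i in range(40)], "compartment": ["process"] * 40}
            )
            vals.append(
                gw.chance_baseline(
                    t, rois, duration_s=duration, n_times=50, window_s=w,
                    seed=int(rng.integers(1 << 31)),
                )
            )
        expected = 1.0 - np.exp(-2 * w * r)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se + 1e-12


class TestLatency:
    def test_rule_application(self):
        t = transient_table(
            [5.2, 4.8, 5.0, 5.4],
            compartments=["stalk", "process", "process", "process"],
        )
        t["wave_id"] = 0
        out = gw.intercompartment_latency(t, 0)
        assert out["latency_s"].iloc[0] == pytest.approx(0.2)

    def test_zero_when_stalk_equals_process_median(self):
        t = transient_table([5.0, 4.0, 5.0, 6.0], compartments=["stalk"] + ["process"] * 3)
        t["wave_id"] = 0
        assert gw.intercompartment_latency(t, 0)["latency_s"].iloc[0] == 0.0

    def test_undefined_without_both_compartments(self):
        t = transient_table([5.0], compartments=["stalk"])
        t["wave_id"] = 0
        assert len(gw.intercompartment_latency(t, 0)) == 0

    def test_latency_table_emits_per_stalk_and_median_rows(self):
        t = transient_table(
            [5.0, 5.6, 4.9, 5.1],
            compartments=["stalk", "stalk", "process", "process"],
        )
        t["wave_id"] = 0
        out = gw.latency_table(t, wave_table([5.0]))
        assert set(out["roi_id"]) == {"r0", "r1", "median"}
        med = out.loc[out["roi_id"] == "median", "latency_s"].iloc[0]
        assert med == pytest.approx(0.3)


class TestFoldChange:
    def _summary(self, fov, condition, stalk_val, metric="participation"):
        return pd.DataFrame(
            [
                {"fov": fov, "condition": condition, "compartment": "stalk",
                 "metric": metric, "value": stalk_val},
            ]
        )

    def test_identical_conditions_give_one(self):
        a = self._summary("f0", "A", 0.6)
        b = self._summary("f0", "B", 0.6)
        fc = gw.condition_fold_change(a, b)
        assert fc["fold_change"].iloc[0] == 1.0

    def test_halved_proportion(self):
        fc = gw.condition_fold_change(self._summary("f0", "A", 0.6), self._summary("f0", "B", 0.3))
        assert fc["fold_change"].iloc[0] == pytest.approx(0.5)

    def test_zero_baseline_warns_nan(self):
        with pytest.warns(UserWarning, match="zero"):
            fc = gw.condition_fold_change(
                self._summary("f0", "A", 0.0), self._summary("f0", "B", 0.3)
            )
        assert np.isnan(fc["fold_change"].iloc[0])

    def test_unpaired_fovs_rejected(self):
        with pytest.raises(ValueError, match="f1"):
            gw.condition_fold_change(
                self._summary("f0", "A", 0.5), self._summary("f1", "B", 0.5)
            )
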