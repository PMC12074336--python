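"""Limb-flag extraction, event partitioning, exclusion rules, staging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plmdkit import capture, simulate
from plmdkit.detector import (
    DetectorConfig, DurationFIFO, MovementEvent, analyze_stream, bst_build,
    build_reference_bst, decision_fusion, extract_events, fusion_measurement,
    limb_flags, match_posture, window_key,
)
from plmdkit.simulate import PLMEpisodeSpec, SimConfig

from conftest import make_zero_noise_config


def brute_force_tlm(flags):
    """Independent TLM counter: one unit per second in which any limb moves."""
    return sum(1 for l, r in flags if l or r)


class TestFusionMeasurement:
    def test_identical_windows_zero(self):
        w = np.full((4, 6), 20000.0)
        assert fusion_measurement(w, w) == (0.0, 0.0)

    def test_left_dip_measured(self):
        a = np.full((4, 6), 20000.0)
        b = a.copy()
        b[:, 4] -= 1500
        assert fusion_measurement(a, b) == (1500.0, 0.0)

    def test_malformed_windows_rejected(self):
        with pytest.raises(ValueError):
            fusion_measurement(np.zeros((4, 5)), np.zeros((4, 5)))

    def test_noise_only_magnitudes_stay_sub_threshold(self):
        """sd 3 mm sensor noise keeps window-mean differences far below the
        default 100 mm threshold (a ~47 sigma margin)."""
        cfg = SimConfig(duration_s=600.0, noise_sd_mm=3.0, seed=13)
        frames, _ = simulate.simulate_session(cfg)
        assert limb_flags(frames).sum() == 0


class TestLimbFlags:
    def test_static_session_all_zero(self):
        cfg = make_zero_noise_config(duration_s=30.0)
        frames, _ = simulate.simulate_session(cfg)
        assert limb_flags(frames).sum() == 0

    def test_logic_levels_left_then_right(self):
        """Left limb moves first (LLL=1, LLR=0), later the right limb moves
        while the left is static (LLL=0, LLR=1)."""
        cfg = make_zero_noise_config(duration_s=40.0, episodes=[
            PLMEpisodeSpec("left", 5, 1, 1, 2, 150.0),
            PLMEpisodeSpec("right", 15, 1, 1, 2, 150.0),
        ])
        frames, _ = simulate.simulate_session(cfg)
        flags = limb_flags(frames)
        assert flags[5].tolist() == [1, 0]
        assert flags[15].tolist() == [0, 1]

    @pytest.mark.parametrize("limb,duration", [("left", 1), ("right", 3),
                                               ("both", 2)])
    def test_zero_noise_flags_equal_ground_truth(self, limb, duration):
        cfg = make_zero_noise_config(duration_s=80.0, episodes=[
            PLMEpisodeSpec(limb, 10, 4, duration, duration + 9, 150.0)])
        frames, truth = simulate.simulate_session(cfg)
        assert np.array_equal(limb_flags(frames), truth.flags)

    def test_threshold_monotonicity(self):
        cfg = SimConfig(duration_s=120.0, noise_sd_mm=40.0, seed=3,
                        episodes=(PLMEpisodeSpec("left", 10, 3, 1, 10, 150.0),))
        frames, _ = simulate.simulate_session(cfg)
        counts = [
            limb_flags(frames, DetectorConfig(movement_threshold=t)).sum()
            for t in (100.0, 500.0, 1000.0, 2000.0, 5000.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_too_short_stream_rejected(self):
        with pytest.raises(ValueError):
            limb_flags(np.full((4, 6), 20000.0))


class TestExtractEvents:
    def test_all_zero(self):
        events, tlm = extract_events(np.zeros((30, 2), dtype=int))
        assert events == [] and tlm == 0

    def test_run_lengths(self):
        flags = np.zeros((20, 2), dtype=int)
        flags[2:4, 0] = 1   # left, 2 units
        flags[7, 0] = 1     # left, 1 unit
        flags[10:13, 0] = 1  # left, 3 units
        events, tlm = extract_events(flags)
        assert [(e.limb, e.start_s, e.duration_units) for e in events] == [
            ("left", 2, 2), ("left", 7, 1), ("left", 10, 3)]
        assert tlm == 6

    def test_alternating_limbs_six_units(self):
        flags = np.zeros((14, 2), dtype=int)
        for s, col in [(1, 0), (3, 1), (5, 0), (7, 1), (9, 0), (11, 1)]:
            flags[s, col] = 1
        events, tlm = extract_events(flags)
        assert tlm == 6 and len(events) == 6

    def test_partial_overlap_splits_into_both_plus_residuals(self):
        flags = np.zeros((10, 2), dtype=int)
        flags[1:5, 0] = 1  # left seconds 1-4
        flags[3:6, 1] = 1  # right seconds 3-5
        events, tlm = extract_events(flags)
        assert [(e.limb, e.start_s, e.duration_units) for e in events] == [
            ("left", 1, 2), ("both", 3, 2), ("right", 5, 1)]
        assert tlm == 5

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=0, max_size=60))
    def test_tlm_matches_brute_force_counter(self, series):
        flags = np.array(series, dtype=int).reshape(-1, 2)
        _events, tlm = extract_events(flags)
        assert tlm == brute_force_tlm(series)
        # events partition the flagged seconds
        covered = sum(e.duration_units for e in _events)
        assert covered >= tlm  # both-limb seconds counted once in TLM
        assert all(e.duration_units >= 1 for e in _events)


class TestDurationFIFO:
    def test_capacity_and_overwrite_order(self):
        fifo = DurationFIFO(capacity=8)
        for d in range(1, 12):
            fifo.push(d)
            assert len(fifo) <= 8
        assert fifo.contents() == list(range(4, 12))


class TestFeatureBST:
    def test_single_pattern(self):
        bst = bst_build({5: "supine-static"})
        assert bst.lookup(5) == "supine-static" and bst.lookup(6) is None

    def test_twelve_patterns_sorted_in_order(self, trained_zero_noise_forest):
        baseline, _f = trained_zero_noise_forest
        bst = build_reference_bst(baseline)
        keys = bst.in_order_keys()
        assert len(keys) == 12 and keys == sorted(keys)

    def test_conflicting_duplicate_keys_rejected(self):
        with pytest.raises(ValueError, match="maps to both"):
            bst_build([(3, "supine-static"), (3, "prone-static")])

    def test_match_prefers_bst_then_forest(self, trained_zero_noise_forest,
                                           zero_noise_training):
        baseline, f = trained_zero_noise_forest
        cfg = zero_noise_training[0]
        frames, truth = simulate.simulate_session(simulate.with_seed(cfg, 5))
        bst = build_reference_bst(baseline)
        window = frames[:4]
        x = capture.build_feature_vector(window, baseline).values
        key = window_key(window, baseline, DetectorConfig())
        assert match_posture(bst, key, f, x) == truth.posture_per_second[0]
        # empty BST and absent keys both fall back to the forest
        empty = bst_build({})
        assert match_posture(empty, key, f, x) == f.predict(x)[0]


class TestDecisionFusion:
    def test_no_events(self):
        r = decision_fusion([], session_duration_s=600)
        assert r.status == "none" and r.stage == "not-applicable"
        assert r.tlm_units == 0

    def test_pose_change_excluded(self):
        ev = [MovementEvent("both", 300, 1)]
        r = decision_fusion(ev, posture_change_seconds=[300],
                            session_duration_s=600)
        assert r.status == "none"
        assert any("pose change" in note for note in r.exclusions)

    def test_constant_movement_excluded(self):
        r = decision_fusion([MovementEvent("both", 100, 120)],
                            session_duration_s=600)
        assert r.status == "none"
        assert any("constant movement" in note for note in r.exclusions)

    def test_left_series_confirmed(self):
        ev = [MovementEvent("left", 100 + 10 * k, 1) for k in range(8)]
        r = decision_fusion(ev, session_duration_s=600)
        assert r.status == "left" and r.tlm_units == 8
        assert r.stage == "middle"  # 48 events/hour
        assert r.duration_fifo == [1] * 8  # last 8 confirmed durations

    def test_sparse_events_not_a_series(self):
        ev = [MovementEvent("left", 200 * k + 10, 1) for k in range(4)]
        r = decision_fusion(ev, session_duration_s=900)  # gaps ~199 s > 90 s
        assert r.status == "none"

    def test_stage_bounds(self):
        def series(n, dur_s):
            return [MovementEvent("left", 10 + 20 * k, 1) for k in range(n)]

        assert decision_fusion(series(4, 3600), session_duration_s=3600
                               ).stage == "early"
        assert decision_fusion(series(30, 3600), session_duration_s=3600
                               ).stage == "middle"
        assert decision_fusion(series(60, 3600), session_duration_s=3600
                               ).stage == "high"

    def test_duration_fifo_keeps_last_capacity(self):
        ev = [MovementEvent("left", 10 * k + 5, 1 + k % 3) for k in range(12)]
        r = decision_fusion(ev, session_duration_s=600)
        assert len(r.duration_fifo) == 8
        assert r.duration_fifo == [1 + k % 3 for k in range(4, 12)]


class TestAnalyzeStream:
    def test_static_session_no_findings(self, trained_zero_noise_forest):
        baseline, f = trained_zero_noise_forest
        cfg = make_zero_noise_config(duration_s=40.0)
        frames, _ = simulate.simulate_session(cfg)
        r = analyze_stream(frames, baseline, f)
        assert r.status == "none" and r.tlm_units == 0
        assert r.report["left"] == r.report["right"] == r.report["both"] == 0
        assert r.posture_segments == [("supine-static", 0, 40)]

    def test_exp1_report_matches_injected_truth(self, trained_zero_noise_forest):
        baseline, f = trained_zero_noise_forest
        lib = simulate.scenario_library(seed=2, noise_sd_mm=0.0)
        frames, truth = simulate.simulate_session(lib["exp1"])
        bst = build_reference_bst(baseline)
        r = analyze_stream(frames, baseline, f, bst=bst)
        # injected: both 5x2 units, left 5x1, right 6x2
        assert r.report["both"] == 10
        assert r.report["left"] == 5
        assert r.report["right"] == 12
        assert r.status == "both"
        assert r.tlm_units == brute_force_tlm(truth.flags)

    def test_pose_change_preset_is_not_plmd(self, trained_zero_noise_forest):
        baseline, f = trained_zero_noise_forest
        lib = simulate.scenario_library(seed=6, noise_sd_mm=0.0)
        frames, _ = simulate.simulate_session(lib["pose_change"])
        bst = build_reference_bst(baseline)
        r = analyze_stream(frames, baseline, f, bst=bst)
        assert r.status == "none"
        assert r.report["posture_changes"] == 1
        assert r.events == []
        assert any("pose change" in n for n in r.exclusions)

    def test_short_stream_rejected(self, trained_zero_noise_forest):
        baseline, f = trained_zero_noise_forest
        with pytest.raises(ValueError):
            analyze_stream(np.full((2, 6), 20000.0), baseline, f)
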