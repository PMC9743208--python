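"""Helix traces, the groove-tracking/hopping classifier and its smoothing
rules, flip detection, and event statistics."""
import numpy as np
import pytest

from grooveslide.analysis import (
    EventRecord, HelixTrace, classify_1d_3d, detect_flips,
    event_statistics, fit_groove_map, segment_events, _smooth_labels,
)
from grooveslide.simulator import Trajectory
from grooveslide.synthetic import DNAGeometry, generate_ideal_bdna, generate_oracle_trace
from grooveslide.analysis import compute_helix_trace


def make_traj(coms, dt_ns=1.0):
    """Single-bead trajectory whose frames equal the given COM positions."""
    coms = np.asarray(coms, float).reshape(-1, 1, 3)
    return Trajectory(
        frames=coms, times_ns=np.arange(len(coms)) * dt_ns,
        frame_interval_ns=dt_ns, bead_indices=np.array([0]),
        box=None, seed=0, config={}, topology_hash="",
    )


class TestHelixTrace:
    def test_axis_projection_conventions(self):
        traj = make_traj([[0, 5, 12], [5, 0, 0], [-5, 0, 0]])
        trace = compute_helix_trace(traj, {"1": [0]})
        r = trace.regions["1"]
        assert r["Z"][0] == 12 and r["d"][0] == 5 and r["phi"][0] == 0
        assert r["phi"][1] == pytest.approx(np.pi / 2)   # x > 0
        assert r["phi"][2] == pytest.approx(-np.pi / 2)  # x < 0

    def test_on_axis_frame_flagged_undefined(self):
        traj = make_traj([[0, 0, 3]])
        trace = compute_helix_trace(traj, {"1": [0]})
        assert np.isnan(trace.regions["1"]["phi"][0])

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            compute_helix_trace(make_traj([[0, 1, 0]]), {"1": []})

    def test_groove_map_from_ideal_duplex(self):
        geom = DNAGeometry(n_bp=20)
        _, dna = generate_ideal_bdna(geom)
        gm = fit_groove_map(dna)
        assert gm.slope == pytest.approx(2 * np.pi / 33.2, rel=1e-6)
        assert abs(gm.phi0) < 1e-6


class TestOneDThreeD:
    @pytest.mark.parametrize("d,expected", [(33.0, "3D"), (31.0, "1D"),
                                            (32.0, "1D")])
    def test_cutoff_convention(self, d, expected):
        trace = HelixTrace(
            times_ns=np.arange(2.0),
            regions={"1": {"Z": np.zeros(2), "d": np.full(2, d),
                           "phi": np.zeros(2)}},
        )
        assert classify_1d_3d(trace)[0] == expected


class TestClassifier:
    def test_oracle_trace_recovered_exactly(self):
        plan = [
            {"type": "groove", "duration_ns": 400, "span_bp": 2},
            {"type": "hop", "duration_ns": 30, "span_bp": 10},
            {"type": "groove", "duration_ns": 300, "span_bp": -1},
            {"type": "threeD", "duration_ns": 100},
            {"type": "groove", "duration_ns": 250, "span_bp": 1},
            {"type": "hop", "duration_ns": 40, "span_bp": -8},
            {"type": "groove", "duration_ns": 350, "span_bp": 2},
        ]
        ot = generate_oracle_trace(plan, seed=4, noise_bp=0.3)
        events, labels = segment_events(ot.helix_trace())
        acc = np.mean(labels == ot.true_labels)
        assert acc >= 0.99
        kinds = [ev.type for ev in events]
        assert kinds.count("hop") == 2
        assert kinds.count("groove") == 4
        assert kinds.count("threeD") == 1

    def test_sub_bp_hop_merges_into_groove(self):
        plan = [
            {"type": "groove", "duration_ns": 100, "span_bp": 1},
            {"type": "hop", "duration_ns": 10, "span_bp": 0.9},
            {"type": "groove", "duration_ns": 100, "span_bp": 1},
        ]
        ot = generate_oracle_trace(plan, seed=1, noise_bp=0.2)
        events, labels = segment_events(ot.helix_trace())
        non3d = [ev for ev in events if ev.type != "threeD"]
        assert len(non3d) == 1
        assert non3d[0].type == "groove"

    def test_short_groove_relabeled_hop(self):
        plan = [
            {"type": "hop", "duration_ns": 20, "span_bp": 6},
            {"type": "groove", "duration_ns": 0.4, "span_bp": 0},
            {"type": "hop", "duration_ns": 20, "span_bp": 6},
        ]
        ot = generate_oracle_trace(plan, seed=2, noise_bp=0.1)
        events, labels = segment_events(ot.helix_trace())
        non3d = [ev for ev in events if ev.type != "threeD"]
        assert len(non3d) == 1
        assert non3d[0].type == "hop"

    def test_every_frame_gets_exactly_one_label(self):
        plan = [
            {"type": "threeD", "duration_ns": 50},
            {"type": "groove", "duration_ns": 200, "span_bp": 2},
            {"type": "hop", "duration_ns": 30, "span_bp": 5},
            {"type": "threeD", "duration_ns": 2},  # below the 5 ns 1D minimum
            {"type": "groove", "duration_ns": 100, "span_bp": 0},
        ]
        ot = generate_oracle_trace(plan, seed=0)
        _, labels = segment_events(ot.helix_trace())
        assert set(np.unique(labels)) <= {"3D", "groove", "hop"}
        assert len(labels) == ot.helix_trace().n_frames

    def test_smoothing_is_idempotent(self):
        plan = [
            {"type": "groove", "duration_ns": 100, "span_bp": 1},
            {"type": "hop", "duration_ns": 8, "span_bp": 0.8},
            {"type": "groove", "duration_ns": 0.4, "span_bp": 0},
            {"type": "hop", "duration_ns": 30, "span_bp": 7},
            {"type": "groove", "duration_ns": 150, "span_bp": 1},
        ]
        ot = generate_oracle_trace(plan, seed=5)
        trace = ot.helix_trace()
        _, labels = segment_events(trace)
        z = trace.regions["1"]["Z"]
        again = _smooth_labels(labels, z, trace.frame_dt_ns, 1.0, 0.5)
        assert np.array_equal(labels, again)

    def test_uncalibrated_trace_raises(self):
        trace = HelixTrace(
            times_ns=np.arange(10.0),
            regions={"1": {"Z": np.zeros(10), "d": np.full(10, 10.0),
                           "phi": np.zeros(10)}},
        )
        with pytest.raises(ValueError, match="groove_map"):
            segment_events(trace)


class TestFlips:
    def test_scripted_inversion_detected_once(self):
        plan = [
            {"type": "groove", "duration_ns": 200, "span_bp": 1},
            {"type": "flip"},
            {"type": "groove", "duration_ns": 200, "span_bp": 1},
        ]
        ot = generate_oracle_trace(plan, seed=0, n_regions=2)
        flips = detect_flips(ot.helix_trace())
        assert len(flips) == 1
        assert flips[0] == pytest.approx(ot.flip_times_us[0], abs=1e-3)

    def test_no_inversion_no_flip(self):
        ot = generate_oracle_trace(
            [{"type": "groove", "duration_ns": 300, "span_bp": 2}],
            seed=0, n_regions=2,
        )
        assert detect_flips(ot.helix_trace()) == []

    def test_single_frame_blip_debounced(self):
        t = np.arange(100.0)
        z1 = np.full(100, 10.0)
        z2 = np.zeros(100)
        z1[50] = -10.0  # one-frame order inversion = noise
        trace = HelixTrace(
            times_ns=t,
            regions={"1": {"Z": z1, "d": np.full(100, 10.0), "phi": np.zeros(100)},
                     "2": {"Z": z2, "d": np.full(100, 10.0), "phi": np.zeros(100)}},
        )
        assert detect_flips(trace, debounce_frames=10) == []

    def test_monomeric_trace_warns_and_returns_empty(self):
        trace = HelixTrace(
            times_ns=np.arange(10.0),
            regions={"1": {"Z": np.zeros(10), "d": np.full(10, 5.0),
                           "phi": np.zeros(10)}},
        )
        with pytest.warns(UserWarning, match="dimeric"):
            assert detect_flips(trace) == []


class TestEventStats:
    def test_hop_frequency_arithmetic(self):
        # 2 hops in 0.5 ms of 1D time -> 4 per ms
        events = [
            EventRecord("groove", 0.0, 400.0, 2.0),
            EventRecord("hop", 400.0, 420.0, 8.0),
            EventRecord("groove", 420.0, 480.0, 1.0),
            EventRecord("hop", 480.0, 500.0, -9.0),
        ]
        stats = event_statistics(events)
        assert stats.time_1d_us == pytest.approx(500.0)
        assert stats.hop_frequency_per_ms == pytest.approx(4.0)

    def test_long_hop_count(self):
        events = [EventRecord("hop", 10 * i, 10 * i + 5, s)
                  for i, s in enumerate([4.0, 6.0, 12.0])]
        stats = event_statistics(events)
        assert stats.long_hop_frequency_per_ms * stats.time_1d_us * 1e-3 \
            == pytest.approx(2.0)

    def test_empty_event_list_all_absent(self):
        with pytest.warns(UserWarning, match="frequency undefined"):
            stats = event_statistics([])
        assert stats.n_hop == 0 and stats.n_groove == 0
        assert stats.groove_duration_us is None
        assert stats.hop_frequency_per_ms is None

    def test_frequency_invariant_under_time_rescaling(self):
        events = [
            EventRecord("groove", 0.0, 100.0, 2.0),
            EventRecord("hop", 100.0, 110.0, 8.0),
        ]
        scaled = [EventRecord(ev.type, 3 * ev.start_us, 3 * ev.end_us, ev.span_bp)
                  for ev in events]
        s1 = event_statistics(events)
        s2 = event_statistics(scaled)
        assert s2.hop_frequency_per_ms == pytest.approx(s1.hop_frequency_per_ms / 3)
        # rescaling trace and total time together leaves the count per event
        # unchanged: k_hop * time_1d is invariant
        assert s1.hop_frequency_per_ms * s1.time_1d_us == pytest.approx(
            s2.hop_frequency_per_ms * s2.time_1d_us)
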