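"""Population event detection: forced examples, the brute-force oracle,
and planted-event recovery on synthetic recordings."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neodev.events import (
    PopulationEvent,
    classify_event,
    detect_events,
    population_mean_trace,
    score_participation,
    summarize_events,
)
from neodev.io import ValidationError
from neodev.normalize import dff_percentile
from neodev.simulate import SimConfig, simulate_recording

from brute_force import brute_force_detect
from conftest import boxcar_event_dff, make_dff


class TestPopulationMeanTrace:
    def test_two_cells_average(self):
        dff = make_dff([[0.0, 2.0], [2.0, 0.0]])
        np.testing.assert_array_equal(population_mean_trace(dff), [1.0, 1.0])

    def test_single_cell_is_identity(self):
        dff = make_dff([[0.5, 0.1, 0.9]])
        np.testing.assert_array_equal(population_mean_trace(dff), [0.5, 0.1, 0.9])


class TestClassify:
    @pytest.mark.parametrize(
        "p,cls",
        [(0.85, "H"), (0.50, "L"), (0.10, "unclassified"),
         (0.80, "L"), (0.20, "L"), (0.81, "H"), (0.19, "unclassified")],
    )
    def test_thresholds(self, p, cls):
        assert classify_event(p) == cls

    @given(p=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_partition_is_total(self, p):
        assert classify_event(p) in ("H", "L", "unclassified")


class TestParticipation:
    def test_constant_cell_never_participates(self):
        dff = make_dff([[1.0] * 10, [0.0] * 5 + [1.0] * 5])
        mask, frac = score_participation(dff, 5, 10)
        assert mask.tolist() == [False, True]
        assert frac == 0.5

    def test_planted_half_participation(self):
        dff = boxcar_event_dff(n_cells=10, participants=range(5))
        _, frac = score_participation(dff, 200, 260)
        assert frac == 0.5

    def test_empty_interval_rejected(self):
        with pytest.raises(ValidationError):
            score_participation(make_dff(np.zeros((2, 10))), 5, 5)


class TestDetectEvents:
    def test_flat_recording_has_no_events(self):
        dff = make_dff(np.ones((3, 400)))
        assert detect_events(dff, bin_s=6.0) == []

    def test_single_boxcar_recovered(self):
        dff = boxcar_event_dff(n_cells=8, onset=200, duration=60)
        events = detect_events(dff)
        assert len(events) == 1
        ev = events[0]
        assert ev.start_frame == 200 and ev.end_frame == 260
        assert 200 <= ev.peak_frame < 260
        assert ev.participation == 1.0
        assert ev.event_class == "H"
        assert not ev.truncated

    def test_two_separated_events(self):
        dff = make_dff(np.zeros((4, 3000)))
        dff.dff[:, 300:360] = 1.0
        dff.dff[:2, 1800:1860] = 1.0
        events = detect_events(dff)
        assert len(events) == 2
        assert events[0].peak_frame < events[1].peak_frame
        assert events[0].end_frame <= events[1].start_frame
        assert events[0].event_class == "H"
        assert events[1].event_class == "L"

    def test_bin_longer_than_recording_rejected(self):
        with pytest.raises(ValidationError):
            detect_events(make_dff(np.zeros((2, 30))), bin_s=6.0)

    def test_time_translation_equivariance(self):
        rng = np.random.default_rng(11)
        base = np.zeros((5, 2400))
        base[:, 600:660] = 1.0
        base += rng.normal(0, 0.01, base.shape)
        k = 90
        shifted = np.roll(base, k, axis=1)
        ev_a = detect_events(make_dff(base))
        ev_b = detect_events(make_dff(shifted))
        assert [e.peak_frame + k for e in ev_a] == [e.peak_frame for e in ev_b]
        assert [e.start_frame + k for e in ev_a] == [e.start_frame for e in ev_b]

    def test_event_straddling_bin_boundary_is_single_event(self):
        # 6 s bin = 180 frames; plant a transient across the 180-frame edge
        dff = boxcar_event_dff(n_cells=6, n_frames=1200, onset=160, duration=60)
        events = detect_events(dff)
        assert len(events) == 1
        assert events[0].start_frame == 160 and events[0].end_frame == 220


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_recordings(self, seed):
        rng = np.random.default_rng(seed)
        n_cells = int(rng.integers(2, 21))
        n_frames = int(rng.integers(400, 3001))
        mat = rng.normal(0, 0.05, size=(n_cells, n_frames))
        # plant a few transients so events exist
        for _ in range(int(rng.integers(0, 4))):
            onset = int(rng.integers(0, n_frames - 90))
            members = rng.random(n_cells) < rng.uniform(0.2, 1.0)
            mat[members, onset:onset + 60] += rng.uniform(0.3, 1.0)
        dff = make_dff(mat)
        got = detect_events(dff)
        expected = brute_force_detect(mat.tolist(), 30.0)
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert g.peak_frame == e["peak"]
            assert g.start_frame == e["start"]
            assert g.end_frame == e["end"]
            assert g.participation == pytest.approx(e["participation"], abs=1e-12)
            assert g.event_class == e["event_class"]


class TestRecovery:
    def test_planted_events_recovered_at_default_noise(self):
        cfg = SimConfig(seed=123)
        rec, truth = simulate_recording(cfg)
        dff = dff_percentile(rec)
        events = detect_events(dff)
        tol = int(0.5 * cfg.frame_rate)
        matched = 0
        for ev in truth.events:
            hits = [d for d in events if abs(d.peak_frame - ev["peak_frame"]) <= tol]
            if hits:
                matched += 1
                assert abs(hits[0].participation - ev["participation"]) <= 0.05
                assert hits[0].event_class == ev["event_class"]
        assert matched >= 0.9 * len(truth.events)
        assert len(events) - matched <= 0.1 * len(truth.events)


class TestSummaries:
    def _event(self, cls, amp, peak, start, end, fr=30.0):
        return PopulationEvent(
            peak_frame=peak, start_frame=start, end_frame=end,
            duration_s=(end - start) / fr, amplitude=amp, participation=0.9 if cls == "H" else 0.5,
            participant_mask=np.ones(4, bool), event_class=cls,
        )

    def test_frequency_per_minute(self):
        events = [self._event("H", 1.0, 100 * i + 10, 100 * i, 100 * i + 30) for i in range(3)]
        s = summarize_events(events, 600.0)
        assert s.frequency_per_min["H"] == pytest.approx(0.3)

    def test_empty_event_list(self):
        s = summarize_events([], 600.0)
        assert s.n_events == 0
        assert np.isnan(s.mean_amplitude["H"])
        assert s.frequency_per_min["L"] == 0.0

    def test_mean_amplitude(self):
        events = [self._event("L", a, 50 * i + 10, 50 * i, 50 * i + 30) for i, a in enumerate([1.0, 2.0, 3.0])]
        assert summarize_events(events, 60.0).mean_amplitude["L"] == pytest.approx(2.0)

    def test_truncated_excluded_from_duration_only(self):
        ev = self._event("H", 1.0, 5, 0, 30)
        ev.truncated = True
        s = summarize_events([ev], 60.0)
        assert s.n_h == 1
        assert np.isnan(s.mean_duration_s["H"])
        assert s.mean_amplitude["H"] == 1.0
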