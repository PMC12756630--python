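"""Linking, motion-mode decision, intensity traces, event calling."""

import numpy as np
import pytest

from exotrack.detection import ParticleSet
from exotrack.synthetic import (
    CircleSpec,
    EventSchedule,
    EventSpec,
    NoiseMix,
    SceneSpec,
    generate_time_lapse,
)
from exotrack.tracking import (
    EventParams,
    IntensityTrace,
    decide_motion_mode,
    detect_exocytosis,
    link_trajectories,
    summarize,
    trace_intensity,
)
from oracles import min_cost_matching


def frames_from(positions_per_frame):
    return [
        ParticleSet(t, np.array(pos).reshape(-1, 2), np.ones(len(pos)))
        for t, pos in enumerate(positions_per_frame)
    ]


class TestLinking:
    def test_single_stationary_particle_single_track(self):
        per_frame = frames_from([[(10, 10)]] * 10)
        tracks = link_trajectories(per_frame)
        assert len(tracks) == 1
        assert len(tracks[0]) == 10

    def test_no_identity_swap_beyond_gate(self):
        # two particles 20 px apart try to "swap": the swap would need a
        # 20 px jump, far beyond the 3 px gate, so each keeps its own track
        a, b = (10, 10), (10, 30)
        per_frame = frames_from([[a, b], [a, b], [a, b]])
        tracks = link_trajectories(per_frame)
        assert len(tracks) == 2
        for tr in tracks:
            assert len(set(tr.positions)) == 1  # never jumps

    def test_matches_exhaustive_min_cost_assignment(self, rng):
        # well-separated particles with sub-gate jitter: mutual-nearest
        # linking must agree with the optimal assignment
        params = EventParams()
        base = np.array([(10, 10), (10, 40), (40, 10), (40, 40)], float)
        for _ in range(20):
            prev = base + rng.integers(-2, 3, (4, 2))
            curr = prev + rng.integers(-1, 2, (4, 2))
            per_frame = frames_from([prev.tolist(), curr.tolist()])
            tracks = link_trajectories(per_frame, params)
            links = {
                tuple(tr.positions[0]): tuple(tr.positions[1])
                for tr in tracks if len(tr) == 2
            }
            oracle = {
                tuple(map(int, prev[i])): tuple(map(int, curr[j]))
                for i, j in min_cost_matching(prev, curr,
                                              params.max_link_distance)
            }
            assert links == oracle

    def test_track_ends_when_particle_vanishes(self):
        per_frame = frames_from([[(10, 10)], [(10, 10)], [], []])
        tracks = link_trajectories(per_frame)
        assert len(tracks) == 1
        assert tracks[0].frames == [0, 1]

    def test_every_detection_in_exactly_one_track(self, rng):
        per_frame = frames_from([
            rng.integers(0, 50, (int(rng.integers(0, 6)), 2)).tolist()
            for _ in range(8)
        ])
        tracks = link_trajectories(per_frame)
        n_detections = sum(len(ps) for ps in per_frame)
        assert sum(len(tr) for tr in tracks) == n_detections


class TestMotionMode:
    def test_stationary_particles_static_mode(self):
        tracks = link_trajectories(frames_from([[(5, 5), (20, 20)]] * 6))
        assert decide_motion_mode(tracks) == "static_first_frame"

    def test_supra_threshold_jitter_tracked_mode(self):
        pos = [[(10 + 5 * (t % 2), 10)] for t in range(6)]
        tracks = link_trajectories(
            frames_from(pos), EventParams(max_link_distance=6.0))
        assert decide_motion_mode(tracks, motion_threshold=1.0) == "tracked"

    def test_decision_matches_independent_median(self, rng):
        pos = rng.integers(10, 50, (5, 2)).astype(float)
        per_frame = []
        steps = []
        for t in range(6):
            if t:
                delta = rng.integers(-1, 2, (5, 2)).astype(float)
                steps.extend(np.hypot(delta[:, 0], delta[:, 1]))
                pos = pos + delta
            per_frame.append(pos.copy().tolist())
        tracks = link_trajectories(frames_from(per_frame),
                                   EventParams(max_link_distance=5.0))
        med = float(np.median(steps))
        expected = "static_first_frame" if med < 1.0 else "tracked"
        assert decide_motion_mode(tracks, motion_threshold=1.0) == expected

    def test_no_tracks_is_an_error(self):
        with pytest.raises(ValueError):
            decide_motion_mode([])


class TestTraceIntensity:
    def test_constant_stack_constant_trace(self):
        stack = np.full((5, 16, 16), 0.3)
        trace = trace_intensity(stack, (8, 8))
        assert np.allclose(trace.values, 0.3)

    def test_five_point_arithmetic(self):
        frame = np.zeros((7, 7))
        frame[3, 3] = 1.0
        for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            frame[3 + dy, 3 + dx] = 0.5
        trace = trace_intensity(frame[None], (3, 3))
        assert trace.values[0] == pytest.approx((1.0 + 4 * 0.5) / 5)

    def test_all_ones_stack_traces_one_everywhere(self):
        stack = np.ones((4, 10, 10))
        for anchor in [(5, 5), (0, 0), (9, 3)]:
            if 0 in anchor or 9 in anchor:
                with pytest.warns(UserWarning, match="border"):
                    trace = trace_intensity(stack, anchor)
            else:
                trace = trace_intensity(stack, anchor)
            assert np.all(trace.values == 1.0)

    def test_event_stack_trace_follows_schedule(self):
        spec = SceneSpec(
            shape=(48, 48), circles=(CircleSpec(24, 24, 4),),
            noise=NoiseMix(w1=0.05, w2=0.05, seed=3),
            foreground_level=0.6, background_level=0.05,
        )
        sched = EventSchedule((EventSpec(0, 0, 10, 15, 20, 1.7),))
        stack, _, _ = generate_time_lapse(spec, sched, 30)
        trace = trace_intensity(stack, (24, 24))
        raw_w = 0.9
        baseline = raw_w * 0.6
        peak = raw_w * (0.05 + 0.55 * 1.7)
        post = raw_w * 0.05
        assert trace.values[:10].mean() == pytest.approx(baseline, abs=0.08)
        assert trace.values[15] == pytest.approx(peak, abs=0.08)
        assert trace.values[21:].mean() == pytest.approx(post, abs=0.08)

    def test_anchor_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            trace_intensity(np.zeros((2, 8, 8)), (10, 3))


class TestDetectExocytosis:
    params = EventParams(baseline_window=5, persistence=3)

    def trace(self, values):
        return IntensityTrace(0, 0, np.asarray(values, dtype=float))

    def test_flat_trace_no_events(self):
        assert detect_exocytosis(self.trace([0.2] * 30), self.params) == []

    def test_constructed_rise_then_loss_called_once(self):
        # baseline 0.2 (frames 0-9), linear rise to 0.5 at frame 14,
        # abrupt drop to 0.02 from frame 17 onward
        v = [0.2] * 10 + list(np.linspace(0.2, 0.5, 5)) + [0.5, 0.5] \
            + [0.02] * 13
        events = detect_exocytosis(self.trace(v), self.params)
        assert len(events) == 1
        ev = events[0]
        # hand evaluation: baseline median 0.2; first frame over 1.4*0.2=0.28
        # is frame 12 (0.35); loss at frame 17 (< 0.05), peak at 14-16 (0.5)
        assert ev.onset_frame == 12
        assert ev.loss_frame == 17
        assert v[ev.peak_frame] == 0.5
        assert ev.peak_over_baseline == pytest.approx(2.5)

    def test_rise_without_loss_not_an_event(self):
        v = [0.2] * 10 + [0.5] * 20  # docked granule that never fuses
        assert detect_exocytosis(self.trace(v), self.params) == []

    def test_short_trace_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert detect_exocytosis(self.trace([0.2] * 6), self.params) == []

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EventParams(rise_factor=0.9)
        with pytest.raises(ValueError):
            EventParams(loss_factor=1.2)


class TestSummarize:
    def test_worked_example(self):
        mean, sem = summarize([1, 2, 3])
        assert mean == pytest.approx(2.0)
        assert sem == pytest.approx(1 / np.sqrt(3), abs=1e-3)

    def test_identical_values_zero_sem(self):
        assert summarize([4, 4, 4, 4]) == (4.0, 0.0)

    def test_single_value_error(self):
        with pytest.raises(ValueError):
            summarize([1])
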