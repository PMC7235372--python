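"""Tail-kinematics scoring: geometry oracles, segmentation, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfbehave import synth
from zfbehave import tail_kinematics as tk


def make_series(deflection, frame_rate=1000.0, tip_x=None, curvature=None):
    deflection = np.asarray(deflection, dtype=float)
    return tk.KinematicSeries(
        frame_rate=frame_rate,
        deflection=deflection,
        curvature=(np.zeros_like(deflection) if curvature is None
                   else np.asarray(curvature, float)),
        tip_x=(np.tan(np.radians(deflection)) if tip_x is None
               else np.asarray(tip_x, float)),
        body_axis=np.array([0.0, 1.0]),
    )


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def brute_force_smooth(x, wf, wp):
    """Independent double-loop box filter with shrinking symmetric windows."""
    nf, npnt = x.shape
    hf, hp = (wf - 1) // 2, (wp - 1) // 2
    tmp = np.empty_like(x)
    for i in range(nf):
        k = min(hf, i, nf - 1 - i)
        for j in range(npnt):
            tmp[i, j] = x[i - k:i + k + 1, j].mean()
    out = np.empty_like(x)
    for i in range(nf):
        for j in range(npnt):
            k = min(hp, j, npnt - 1 - j)
            out[i, j] = tmp[i, j - k:j + k + 1].mean()
    return out


class TestSmoothTrace:
    def test_constant_trace_unchanged(self):
        trace = tk.TailTrace(1000.0, np.full((40, 20), 2.5),
                             np.full((40, 20), -1.0))
        out = tk.smooth_trace(trace, tk.KinematicThresholds())
        assert np.allclose(out.x, 2.5) and np.allclose(out.y, -1.0)

    def test_interior_impulse_box_filter_arithmetic(self):
        A = 90.0
        x = np.zeros((31, 21))
        x[15, 10] = A
        trace = tk.TailTrace(1000.0, x, np.zeros_like(x))
        out = tk.smooth_trace(trace, tk.KinematicThresholds())
        assert out.x[15, 10] == pytest.approx(A / (15 * 3))

    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(size=(50, 20))
        y = rng.normal(size=(50, 20))
        trace = tk.TailTrace(1000.0, x, y)
        out = tk.smooth_trace(trace, tk.KinematicThresholds())
        assert np.allclose(out.x, brute_force_smooth(x, 15, 3), atol=1e-9)
        assert np.allclose(out.y, brute_force_smooth(y, 15, 3), atol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            tk.KinematicThresholds(smooth_frames=14)


# ---------------------------------------------------------------------------
# kinematic series
# ---------------------------------------------------------------------------

class TestComputeSeries:
    def test_collinear_points_zero_deflection_and_curvature(self):
        s = np.linspace(0, 1, 20)
        trace = tk.TailTrace(1000.0, np.zeros((5, 20)), np.tile(s, (5, 1)))
        series = tk.compute_series(trace, body_axis=(0.0, 1.0))
        assert np.allclose(series.deflection, 0.0)
        assert np.allclose(series.curvature, 0.0)

    def test_straight_chord_at_45_degrees(self):
        s = np.linspace(0, 1, 20)
        trace = tk.TailTrace(1000.0, np.tile(s, (3, 1)), np.tile(s, (3, 1)))
        series = tk.compute_series(trace, body_axis=(0.0, 1.0))
        assert np.allclose(np.abs(series.deflection), 45.0)
        assert np.allclose(series.curvature, 0.0, atol=1e-9)

    def test_arc_polyline_curvature_equals_turning_angle(self):
        # oracle: a polyline whose 18 joints each turn by 5 degrees has an
        # exterior-angle sum of exactly 90 degrees (points lie on a circle)
        n = 20
        turn = math.radians(90.0 / (n - 2))
        directions = math.radians(90.0) + np.arange(n - 1) * turn
        pts = np.vstack([[0.0, 0.0],
                         np.cumsum(np.stack([np.cos(directions),
                                             np.sin(directions)], axis=1),
                                   axis=0)])
        trace = tk.TailTrace(1000.0, np.tile(pts[:, 0], (3, 1)),
                             np.tile(pts[:, 1], (3, 1)))
        series = tk.compute_series(trace, body_axis=(0.0, 1.0))
        assert series.curvature[0] == pytest.approx(90.0, abs=1e-6)

    def test_coincident_points_contribute_zero_with_warning(self, caplog):
        s = np.linspace(0, 1, 20)
        y = np.tile(s, (3, 1))
        y[:, 5] = y[:, 4]  # duplicate point -> zero-length segment
        trace = tk.TailTrace(1000.0, np.zeros((3, 20)), y)
        with caplog.at_level("WARNING"):
            series = tk.compute_series(trace, body_axis=(0.0, 1.0))
        assert np.allclose(series.curvature, 0.0)
        assert any("coincident" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class TestSegmentBouts:
    def test_flat_series_no_bouts(self):
        series = make_series(np.zeros(1000))
        assert tk.segment_bouts(series, tk.KinematicThresholds()) == []

    def test_two_bouts_separated_by_long_rest(self):
        params = synth.TailSimParams(
            duration=2.0,
            bouts=[(0.1, 0.5, 20.0, 25.0), (1.1, 0.5, 20.0, 25.0)])
        trace, gt = synth.gen_tail_trace(params)
        t = tk.KinematicThresholds()
        series = tk.compute_series(tk.smooth_trace(trace, t),
                                   body_axis=(0.0, 1.0))
        bouts = tk.segment_bouts(series, t)
        assert len(bouts) == 2
        for (s, e), (_, row) in zip(bouts, gt.iterrows()):
            # smoothing plus the 3-degree gate trims edges by a few frames
            assert abs(s - row.start_frame) <= 15
            assert abs(e - row.end_frame) <= 15

    def test_short_gap_merges_to_one_bout(self):
        # hand-applied merge rule on a 30-frame toy series at 100 fps:
        # active 0-9, rest 10-12 (30 ms < 50 ms), active 13-29 -> one bout
        d = np.zeros(30)
        d[0:10] = 10.0
        d[13:30] = -10.0
        series = make_series(d, frame_rate=100.0)
        bouts = tk.segment_bouts(series, tk.KinematicThresholds())
        assert bouts == [(0, 30)]

    def test_long_gap_keeps_two_bouts(self):
        d = np.zeros(40)
        d[0:10] = 10.0
        d[25:40] = -10.0  # 150 ms gap at 100 fps
        series = make_series(d, frame_rate=100.0)
        bouts = tk.segment_bouts(series, tk.KinematicThresholds())
        assert bouts == [(0, 10), (25, 40)]


def snapped_sine(freq, n_frames, frame_rate=1000.0):
    """Sine deflection with exact zeros at the sampling points."""
    t = np.arange(n_frames) / frame_rate
    d = 20.0 * np.sin(2 * math.pi * freq * t)
    d[np.abs(d) < 1e-9] = 0.0
    return d


class TestSegmentHalfbeats:
    def test_pure_sine_half_beat_count_and_frequency(self):
        # 20 Hz over 0.5 s: zero crossings every 25 ms -> 20 half-beats
        d = np.concatenate([snapped_sine(20.0, 501), np.zeros(100)])
        series = make_series(d)
        hbs = tk.segment_halfbeats(series, (0, 500))
        assert len(hbs) == 20
        assert all(h.frequency == pytest.approx(20.0) for h in hbs)

    def test_10ms_half_period_gives_50_hz(self):
        d = np.concatenate([snapped_sine(50.0, 201), np.zeros(50)])
        series = make_series(d)
        hbs = tk.segment_halfbeats(series, (0, 200))
        assert all(h.frequency == pytest.approx(50.0) for h in hbs)
        assert all(h.period == pytest.approx(0.01) for h in hbs)

    def test_noisy_bout_count_matches_analytic_crossings(self):
        f, length = 24.0, 0.5
        params = synth.TailSimParams(duration=0.8,
                                     bouts=[(0.15, length, f, 25.0)],
                                     noise_sd=0.003, seed=21)
        trace, gt = synth.gen_tail_trace(params)
        t = tk.KinematicThresholds()
        series = tk.compute_series(tk.smooth_trace(trace, t),
                                   body_axis=(0.0, 1.0))
        bouts = tk.segment_bouts(series, t)
        assert len(bouts) == 1
        hbs = tk.segment_halfbeats(series, bouts[0], t)
        assert abs(len(hbs) - gt.loc[0, "halfbeat_count"]) <= 1

    def test_no_crossing_flags_single_halfbeat(self):
        d = np.full(100, 20.0)
        series = make_series(d)
        hbs = tk.segment_halfbeats(series, (10, 90))
        assert len(hbs) == 1
        assert hbs[0].incomplete

    def test_halfbeats_tile_without_overlap(self):
        params = synth.TailSimParams(duration=0.8,
                                     bouts=[(0.1, 0.6, 28.0, 20.0)],
                                     noise_sd=0.002, seed=3)
        trace, _ = synth.gen_tail_trace(params)
        t = tk.KinematicThresholds()
        series = tk.compute_series(tk.smooth_trace(trace, t),
                                   body_axis=(0.0, 1.0))
        (bout,) = tk.segment_bouts(series, t)
        hbs = tk.segment_halfbeats(series, bout, t)
        for a, b in zip(hbs[:-1], hbs[1:]):
            assert a.end_frame == b.start_frame

    def test_frequency_definition(self):
        # frequency = 1 / (2 * period) by construction
        d = np.concatenate([snapped_sine(40.0, 301), np.zeros(50)])
        hbs = tk.segment_halfbeats(make_series(d), (0, 300))
        for h in hbs:
            assert h.frequency == pytest.approx(1.0 / (2.0 * h.period))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _halfbeat(peak_deflection, frequency):
    period = 1.0 / (2.0 * frequency)
    return tk.HalfBeat(start_frame=0, end_frame=10, period=period,
                       frequency=frequency, peak_deflection=peak_deflection,
                       peak_curvature=0.0, trajectory=1.0, net_trajectory=1.0,
                       velocity=1.0 / period)


class TestClassifyHalfbeat:
    @pytest.mark.parametrize("deflection,frequency,response,speed", [
        (34.0, 59.0, "swim", "slow"),
        (36.0, 61.0, "escape", "fast"),
        (35.0, 60.0, "swim", "slow"),   # boundary -> lower class
        (35.0001, 60.0001, "escape", "fast"),
    ])
    def test_thresholds(self, deflection, frequency, response, speed):
        hb = tk.classify_halfbeat(_halfbeat(deflection, frequency),
                                  tk.KinematicThresholds())
        assert hb.response_class == response
        assert hb.speed_class == speed


# ---------------------------------------------------------------------------
# bout metrics
# ---------------------------------------------------------------------------

class TestBoutMetrics:
    def test_cumulative_and_mean_trajectory(self):
        hbs = []
        for traj in (1.0, 2.0, 3.0):
            hb = _halfbeat(20.0, 30.0)
            hb.trajectory = traj
            hbs.append(tk.classify_halfbeat(hb, tk.KinematicThresholds()))
        m = tk.bout_metrics(hbs, (0, 100), 1000.0)
        slow = m.per_class["slow"]
        assert slow.cumulative_trajectory == pytest.approx(6.0)
        assert slow.mean_trajectory == pytest.approx(2.0)
        assert slow.n_halfbeats == 3

    def test_single_halfbeat_variance_missing(self):
        hb = tk.classify_halfbeat(_halfbeat(20.0, 30.0),
                                  tk.KinematicThresholds())
        m = tk.bout_metrics([hb], (0, 100), 1000.0)
        assert m.per_class["slow"].period_variance is None

    def test_empty_class_counts_zero_metrics_missing(self):
        hb = tk.classify_halfbeat(_halfbeat(20.0, 30.0),
                                  tk.KinematicThresholds())
        m = tk.bout_metrics([hb], (0, 100), 1000.0)
        fast = m.per_class["fast"]
        assert fast.n_halfbeats == 0
        assert fast.cumulative_trajectory is None
        assert fast.mean_velocity is None

    def test_matches_brute_force_recomputation(self):
        params = synth.TailSimParams(duration=0.8,
                                     bouts=[(0.1, 0.5, 20.0, 25.0)],
                                     noise_sd=0.002, seed=13)
        trace, _ = synth.gen_tail_trace(params)
        metrics, halfbeats = tk.score_trace(trace)
        assert len(metrics) == 1
        hbs = [h for h in halfbeats[0] if h.speed_class == "slow"]
        got = metrics[0].per_class["slow"]
        # independent loop oracle
        total = 0.0
        velocities, periods, defl, curv = [], [], [], []
        for h in hbs:
            total += h.trajectory
            velocities.append(h.velocity)
            periods.append(h.period)
            defl.append(h.peak_deflection)
            curv.append(h.peak_curvature)
        assert got.cumulative_trajectory == pytest.approx(total, abs=1e-9)
        assert got.mean_trajectory == pytest.approx(total / len(hbs), abs=1e-9)
        assert got.mean_velocity == pytest.approx(np.mean(velocities), abs=1e-9)
        assert got.max_deflection == pytest.approx(max(defl), abs=1e-9)
        assert got.max_curvature == pytest.approx(max(curv), abs=1e-9)
        mean_p = sum(periods) / len(periods)
        var = sum((p - mean_p) ** 2 for p in periods) / (len(periods) - 1)
        assert got.period_variance == pytest.approx(var, abs=1e-12)


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------

def _score(trace, axis):
    t = tk.KinematicThresholds(body_axis=axis)
    metrics, halfbeats = tk.score_trace(trace, t)
    return metrics, halfbeats


class TestInvariances:
    @settings(max_examples=8, deadline=None)
    @given(angle=st.floats(-math.pi, math.pi, allow_nan=False))
    def test_rotation_equivariance(self, angle):
        params = synth.TailSimParams(duration=0.5,
                                     bouts=[(0.05, 0.4, 25.0, 20.0)],
                                     noise_sd=0.0, seed=2)
        trace, _ = synth.gen_tail_trace(params)
        m0, _ = _score(trace, (0.0, 1.0))
        c, s = math.cos(angle), math.sin(angle)
        rx = c * trace.x - s * trace.y
        ry = s * trace.x + c * trace.y
        rot = tk.TailTrace(trace.frame_rate, rx, ry)
        m1, _ = _score(rot, (-s, c))  # axis rotated with the data
        for a, b in zip(m0, m1):
            for cls in ("slow", "fast"):
                ca, cb = a.per_class[cls], b.per_class[cls]
                assert ca.n_halfbeats == cb.n_halfbeats
                if ca.cumulative_trajectory is not None:
                    assert ca.cumulative_trajectory == pytest.approx(
                        cb.cumulative_trajectory, abs=1e-6)
                    assert ca.max_deflection == pytest.approx(
                        cb.max_deflection, abs=1e-6)
                    assert ca.max_curvature == pytest.approx(
                        cb.max_curvature, abs=1e-6)

    @settings(max_examples=8, deadline=None)
    @given(k=st.floats(0.1, 10.0, allow_nan=False))
    def test_scale_equivariance(self, k):
        params = synth.TailSimParams(duration=0.5,
                                     bouts=[(0.05, 0.4, 25.0, 20.0)],
                                     noise_sd=0.0, seed=2)
        trace, _ = synth.gen_tail_trace(params)
        m0, _ = _score(trace, (0.0, 1.0))
        scaled = tk.TailTrace(trace.frame_rate, k * trace.x, k * trace.y)
        m1, _ = _score(scaled, (0.0, 1.0))
        for a, b in zip(m0, m1):
            for cls in ("slow", "fast"):
                ca, cb = a.per_class[cls], b.per_class[cls]
                assert ca.n_halfbeats == cb.n_halfbeats
                if ca.cumulative_trajectory is not None:
                    assert cb.cumulative_trajectory == pytest.approx(
                        k * ca.cumulative_trajectory, rel=1e-9)
                    assert cb.mean_velocity == pytest.approx(
                        k * ca.mean_velocity, rel=1e-9)
                    assert cb.max_deflection == pytest.approx(
                        ca.max_deflection, rel=1e-9)
                    assert cb.period_variance == pytest.approx(
                        ca.period_variance, rel=1e-9) \
                        if ca.period_variance is not None else True

    def test_parameter_recovery_noiseless(self, tail_trace):
        trace, gt = tail_trace
        metrics, halfbeats = tk.score_trace(trace)
        assert len(halfbeats) == 1
        assert len(halfbeats[0]) == gt.loc[0, "halfbeat_count"]
        freqs = [h.frequency for h in halfbeats[0]]
        assert np.median(freqs) == pytest.approx(20.0, abs=0.01)


class TestCsvDialects:
    def test_long_round_trip(self, tmp_path, tail_trace):
        trace, _ = tail_trace
        path = tmp_path / "tail.csv"
        trace.to_csv(path)
        back = tk.TailTrace.from_csv(path)
        assert back.frame_rate == pytest.approx(trace.frame_rate)
        assert np.allclose(back.x, trace.x) and np.allclose(back.y, trace.y)

    def test_wide_dialect(self, tmp_path, tail_trace):
        import pandas as pd
        trace, _ = tail_trace
        cols = {f"x{j}": trace.x[:, j] for j in range(trace.n_points)}
        cols.update({f"y{j}": trace.y[:, j] for j in range(trace.n_points)})
        path = tmp_path / "wide.csv"
        pd.DataFrame(cols).to_csv(path, index=False)
        back = tk.TailTrace.from_csv(path, frame_rate=1000.0, dialect="wide")
        assert np.allclose(back.x, trace.x) and np.allclose(back.y, trace.y)

    def test_wide_dialect_needs_frame_rate(self, tmp_path):
        import pandas as pd
        path = tmp_path / "wide.csv"
        pd.DataFrame({"x0": [0.0], "y0": [0.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="frame_rate"):
            tk.TailTrace.from_csv(path, dialect="wide")
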