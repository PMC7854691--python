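"""Split computation, speed corridors and the split CSV format."""

import numpy as np
import pytest

from trackpace import SplitSeries, SpeedCorridor, compute_splits, build_corridor
from trackpace.splits import read_splits, write_splits, piecewise_linear_time
from trackpace.racetime import parse_race_time, format_race_time, finish_gap


class FakeTraj:
    """Minimal trajectory stand-in: s/v arrays only (synthetic)."""

    def __init__(self, s, v):
        self.s = np.asarray(s, float)
        self.v = np.asarray(v, float)
        self.final_time = piecewise_linear_time(self.s, self.v, s[0], s[-1])


class TestComputeSplits:
    def test_constant_speed_gives_equal_splits(self):
        s = np.linspace(0, 1000, 51)
        traj = FakeTraj(s, np.full_like(s, 5.0))
        series = compute_splits(traj, 100.0)
        np.testing.assert_allclose(series.times, 20.0, rtol=1e-12)
        np.testing.assert_allclose(series.mean_speeds, 5.0, rtol=1e-12)

    def test_linear_speed_matches_log_integral(self):
        # v rises linearly 4 -> 6 m/s over 100 m: T = 50 ln(3/2)
        s = np.linspace(0, 100, 11)
        traj = FakeTraj(s, 4.0 + 0.02 * s)
        series = compute_splits(traj, 100.0)
        assert series.times[0] == pytest.approx(50 * np.log(1.5), rel=1e-9)

    def test_splits_sum_to_final_time(self):
        rng = np.random.default_rng(0)
        s = np.linspace(0, 2000, 101)
        v = 5.0 + 0.5 * np.sin(s / 150.0) + 0.05 * rng.standard_normal(len(s))
        traj = FakeTraj(s, v)
        series = compute_splits(traj, 100.0)
        assert series.final_time == pytest.approx(traj.final_time, rel=1e-9)

    def test_piecewise_constant_speed_is_exact(self):
        s = np.array([0.0, 100.0, 100.0 + 1e-9, 200.0])
        # grid aligned with the jump: each split integrates a constant
        traj = FakeTraj(np.array([0, 50, 100, 150, 200.0]),
                        np.array([4.0, 4.0, 4.0, 8.0, 8.0]))
        series = compute_splits(traj, 100.0)
        assert series.times[0] == pytest.approx(25.0, rel=1e-9)

    def test_grid_coarser_than_segment_rejected(self):
        traj = FakeTraj([0.0, 150.0, 300.0], [5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="coarser"):
            compute_splits(traj, 100.0)

    def test_additivity_of_time_integral(self):
        s = np.linspace(0, 400, 21)
        v = 5.0 + s / 400.0
        whole = piecewise_linear_time(s, v, 0.0, 400.0)
        parts = sum(
            piecewise_linear_time(s, v, a, a + 50.0) for a in np.arange(0, 400, 50.0)
        )
        assert parts == pytest.approx(whole, rel=1e-12)


class TestCorridor:
    def _series(self, speeds):
        speeds = np.asarray(speeds, float)
        return SplitSeries(
            times=100.0 / speeds, segment_length=100.0,
            race_distance=100.0 * len(speeds),
        )

    def test_constant_profile_bounds(self):
        obs = self._series(np.full(100, 6.0))
        corr = build_corridor(obs, tight_windows=())
        lo, hi = corr.bounds_at(5_000.0)
        assert lo == pytest.approx(5.7)
        assert hi == pytest.approx(6.3)

    def test_tight_window_overrides(self):
        obs = self._series(np.full(100, 6.0))
        corr = build_corridor(obs, tight_windows=((4000.0, 6000.0),), delta_tight=0.1)
        lo_in, hi_in = corr.bounds_at(5_000.0)
        lo_out, hi_out = corr.bounds_at(2_000.0)
        assert (lo_in, hi_in) == (pytest.approx(5.9), pytest.approx(6.1))
        assert (lo_out, hi_out) == (pytest.approx(5.7), pytest.approx(6.3))

    def test_moving_average_interior(self):
        obs = self._series([5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        corr = build_corridor(obs, smooth_window=3, tight_windows=())
        # interior centreline is the 3-term mean of the neighbours
        centre = 0.5 * (corr.v_lo[2] + corr.v_hi[2])
        assert centre == pytest.approx((6.0 + 7.0 + 8.0) / 3)

    def test_equal_deltas_make_windows_irrelevant(self):
        obs = self._series(6.0 + 0.1 * np.sin(np.arange(100)))
        a = build_corridor(obs, delta_wide=0.3, delta_tight=0.3,
                           tight_windows=((4000.0, 6000.0),))
        b = build_corridor(obs, delta_wide=0.3, tight_windows=())
        np.testing.assert_allclose(a.v_lo, b.v_lo)
        np.testing.assert_allclose(a.v_hi, b.v_hi)

    def test_overlapping_windows_rejected(self):
        obs = self._series(np.full(100, 6.0))
        with pytest.raises(ValueError, match="overlap"):
            build_corridor(obs, tight_windows=((0.0, 300.0), (200.0, 500.0)))

    def test_widened_preserves_tight_windows(self):
        obs = self._series(np.full(100, 6.0))
        corr = build_corridor(obs, tight_windows=((4000.0, 6000.0),))
        wide = corr.widened(0.15, keep_tight_below=0.4)
        assert wide.bounds_at(5_000.0) == corr.bounds_at(5_000.0)
        assert wide.bounds_at(2_000.0)[0] == pytest.approx(5.7 - 0.15)

    def test_corridor_csv(self, tmp_path):
        obs = self._series(np.full(100, 6.0))
        corr = build_corridor(obs)
        path = tmp_path / "corr.csv"
        corr.write_csv(path)
        assert path.read_text().startswith("start_m,end_m,v_lo,v_hi")


class TestSplitsIO:
    def _series(self):
        rng = np.random.default_rng(3)
        return SplitSeries(times=16.0 + 0.1 * rng.standard_normal(100))

    def test_roundtrip_lossless(self, tmp_path):
        series = self._series()
        path = tmp_path / "splits.csv"
        write_splits(series, path)
        back = read_splits(path)
        np.testing.assert_allclose(back.times, series.times, atol=1e-9)
        assert back.segment_length == series.segment_length

    def test_zero_time_row_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "segment_index,distance_end_m,time_s,mean_speed_mps\n"
            "1,100,16.0,6.25\n2,200,0.0,0.0\n"
        )
        with pytest.raises(ValueError, match="row 3"):
            read_splits(path)

    def test_wrong_row_count_for_10k(self, tmp_path):
        series = SplitSeries(times=np.full(99, 16.0), race_distance=9_900.0)
        path = tmp_path / "short.csv"
        write_splits(series, path)
        with pytest.raises(ValueError, match="expected 100"):
            read_splits(path, expected_distance=10_000.0)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("segment_index,distance_end_m\n1,100\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_splits(path)

    def test_non_monotone_distance_named(self, tmp_path):
        path = tmp_path / "mono.csv"
        path.write_text(
            "segment_index,distance_end_m,time_s,mean_speed_mps\n"
            "1,100,16.0,6.25\n2,90,16.0,6.25\n"
        )
        with pytest.raises(ValueError, match="row 3"):
            read_splits(path)

    def test_speed_disagreement_warns(self, tmp_path):
        path = tmp_path / "warn.csv"
        path.write_text(
            "segment_index,distance_end_m,time_s,mean_speed_mps\n"
            "1,100,16.0,9.99\n"
        )
        with pytest.warns(UserWarning, match="disagrees"):
            read_splits(path)


class TestRaceClock:
    def test_winner_vs_sixth_gap(self):
        # published finish times of the two modelled athletes
        assert finish_gap("26:49.51", "26:57.77") == pytest.approx(8.26)

    @pytest.mark.parametrize(
        "text, seconds",
        [("26:49.51", 1609.51), ("0:59.99", 59.99), ("1:00:00.00", 3600.0)],
    )
    def test_parse(self, text, seconds):
        assert parse_race_time(text) == pytest.approx(seconds)

    def test_format_roundtrip(self):
        for t in (1609.51, 1617.77, 59.99):
            assert parse_race_time(format_race_time(t)) == pytest.approx(t, abs=5e-3)

    def test_bad_input(self):
        with pytest.raises(ValueError):
            parse_race_time("abc")
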