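"""The minimum-time solver: transcription, constraints, and the ODE oracle."""

import numpy as np
import pytest

from trackpace import (
    DEFAULT_TRACK,
    SolverOptions,
    SpeedCorridor,
    TrackGeometry,
    Trajectory,
    default_winner,
    solve_race,
    verify_trajectory,
    CorridorInfeasibleError,
)
from trackpace.ocp import estimate_final_time


def bend_free_track(distance=2_000.0):
    """Effectively straight track: enormous bend radius kills the cap."""
    return TrackGeometry(bend_radius=1e6, race_distance=distance)


class TestPinnedCorridor:
    def test_constant_speed_corridor_gives_distance_over_speed(self):
        track = bend_free_track(2_000.0)
        p = default_winner().with_field("e0", 5_000.0)  # ample energy
        bp = np.arange(0.0, 2_001.0, 100.0)
        corr = SpeedCorridor(bp, np.full(20, 6.0), np.full(20, 6.0))
        opts = SolverOptions(n_nodes=100, v_init=6.0, launch_window_m=0.5,
                             launch_refine_m=0.0, end_refine_m=0.0)
        traj = solve_race(p, track, corr, opts)
        assert traj.converged
        assert traj.final_time == pytest.approx(2_000.0 / 6.0, rel=1e-3)

    def test_pinned_dynamics_reintegrate_exactly(self):
        track = bend_free_track(2_000.0)
        p = default_winner().with_field("e0", 5_000.0)
        bp = np.arange(0.0, 2_001.0, 100.0)
        corr = SpeedCorridor(bp, np.full(20, 6.0), np.full(20, 6.0))
        opts = SolverOptions(n_nodes=100, v_init=6.0, launch_window_m=0.5,
                             launch_refine_m=0.0, end_refine_m=0.0)
        traj = solve_race(p, track, corr, opts)
        report = verify_trajectory(traj, p, track)
        assert report.max_speed_dev < 1e-9


class TestGridRefinement:
    def test_bend_free_solution_is_grid_converged(self):
        track = bend_free_track(1_600.0)
        p = default_winner()
        coarse = solve_race(p, track, None, SolverOptions(n_nodes=80, end_refine_m=0.0))
        fine = solve_race(p, track, None, SolverOptions(n_nodes=320, end_refine_m=0.0))
        assert coarse.converged and fine.converged
        assert coarse.final_time == pytest.approx(fine.final_time, rel=2e-3)


class TestFullRace:
    def test_anaerobic_reserve_exhausted_at_finish(self, free_race, winner):
        assert free_race.e[-1] <= 0.02 * winner.e0
        assert free_race.e[-1] >= -0.02 * winner.e0

    def test_final_time_in_world_class_range(self, free_race):
        assert 1_500.0 <= free_race.final_time <= 1_700.0

    def test_time_is_quadrature_of_inverse_speed(self, free_race):
        from trackpace.splits import piecewise_linear_time
        t = piecewise_linear_time(free_race.s, free_race.v, 0.0, 10_000.0)
        assert free_race.final_time == pytest.approx(t, rel=1e-6)

    def test_trajectory_respects_path_constraints(self, free_race, winner):
        tol = 0.02
        assert np.all(free_race.v >= 0.5 - tol)
        assert np.all(free_race.e >= -0.02 * winner.e0)
        assert np.all(free_race.f >= -tol)
        # bend cap as the model states it: interval force against the
        # interval-midpoint speed and curvature
        v_mid = 0.5 * (free_race.v[:-1] + free_race.v[1:])
        s_mid = 0.5 * (free_race.s[:-1] + free_race.s[1:])
        kap_mid = DEFAULT_TRACK.curvature_at(s_mid)
        cap = free_race.f[:-1] ** 2 + v_mid**4 * kap_mid**2
        assert np.all(cap <= winner.f_M**2 + 0.05)

    def test_cruise_laps_run_bends_slower_than_straights(self, free_race):
        for lap in range(4, 10):
            m = (free_race.s >= lap * 400.0) & (free_race.s < (lap + 1) * 400.0)
            v_bend = free_race.v[m & (free_race.curvature > 0)].mean()
            v_straight = free_race.v[m & (free_race.curvature == 0)].mean()
            assert v_bend < v_straight, f"lap {lap + 1}"

    def test_monotone_energy_response(self, winner, fast_opts):
        times = []
        for factor in (0.90, 0.95, 1.0):
            p = winner.with_field("e0", factor * winner.e0)
            traj = solve_race(p, DEFAULT_TRACK, None, fast_opts)
            assert traj.converged
            times.append(traj.final_time)
        assert times[0] >= times[1] >= times[2]

    def test_monotone_economy_response(self, winner, fast_opts):
        base = solve_race(winner, DEFAULT_TRACK, None, fast_opts).final_time
        worse = solve_race(
            winner.with_field("tau", 0.95 * winner.tau), DEFAULT_TRACK, None, fast_opts
        ).final_time
        better = solve_race(
            winner.with_field("f_M", 1.05 * winner.f_M), DEFAULT_TRACK, None, fast_opts
        ).final_time
        assert worse > base
        assert better <= base + 0.1


class TestOracle:
    def test_forward_reintegration_matches(self, free_race, winner):
        report = verify_trajectory(free_race, winner)
        assert report.ok
        assert report.max_speed_dev < 1e-2
        assert report.energy_residual < 0.01 * winner.e0

    def test_corrupted_force_flags_violation(self, free_race, winner):
        bad = Trajectory(**{**free_race.__dict__})
        bad.f = free_race.f * 1.1
        report = verify_trajectory(bad, winner)
        assert not report.ok
        assert report.max_speed_dev > 0.1


class TestFailures:
    def test_contradictory_corridor_raises(self):
        bp = np.arange(0.0, 10_001.0, 100.0)
        corr = SpeedCorridor(bp, np.full(100, 9.0), np.full(100, 9.5))
        with pytest.raises(CorridorInfeasibleError):
            solve_race(default_winner(), DEFAULT_TRACK, corr,
                       SolverOptions(n_nodes=100))

    def test_energy_impossible_corridor_reports_infeasible(self, fast_opts):
        p = default_winner()
        bp = np.arange(0.0, 10_001.0, 100.0)
        # demands ~7 m/s throughout: far beyond the anaerobic budget
        corr = SpeedCorridor(bp, np.full(100, 7.0), np.full(100, 7.4))
        traj = solve_race(p, DEFAULT_TRACK, corr, fast_opts)
        assert traj.solve_status == "infeasible"
        assert not traj.converged

    def test_options_validated(self):
        with pytest.raises(ValueError):
            SolverOptions(n_nodes=10)
        with pytest.raises(ValueError):
            SolverOptions(nlp_tol=0.0)


class TestTrajectoryIO:
    def test_csv_roundtrip(self, free_race, tmp_path):
        path = tmp_path / "traj.csv"
        free_race.write_csv(path)
        back = Trajectory.read_csv(path)
        np.testing.assert_allclose(back.v, free_race.v, rtol=1e-6)
        np.testing.assert_allclose(back.f, free_race.f, rtol=1e-6)
        assert back.final_time == pytest.approx(free_race.final_time, rel=1e-6)


class TestEstimate:
    def test_quasi_steady_estimate_is_close_and_cheap(self, winner, std_opts, free_race):
        est = estimate_final_time(winner, DEFAULT_TRACK, std_opts)
        assert est == pytest.approx(free_race.final_time, rel=0.02)
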