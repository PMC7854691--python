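"""Counterfactual experiments: perturb one parameter and re-run the race.

The canonical experiments are a 5% reduction of the anaerobic capacity
``e0`` (which removes the ability to speed up at the end of the race)
and a reduction of ``tau`` modelling a costlier runner (at steady state
the per-distance cost of speed ``v`` is ``v/tau``, so smaller ``tau``
means worse running economy), which damps the speed variation between
bends and straights.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ocp import SolverOptions, Trajectory, solve_race
from .runner import RunnerParams
from .splits import SpeedCorridor, compute_splits
from .track import TrackGeometry, DEFAULT_TRACK

__all__ = ["perturb_params", "compare_scenarios", "ScenarioReport", "bend_straight_amplitude"]

log = logging.getLogger(__name__)

PERTURBABLE = ("e0", "f_M", "tau", "u_plus", "u_minus", "sigma_max")


def perturb_params(params: RunnerParams, fld: str, factor: float) -> RunnerParams:
    """Copy of ``params`` with one field scaled by ``factor`` (re-validated)."""
    if fld not in PERTURBABLE:
        raise ValueError(f"field must be one of {PERTURBABLE}, got {fld!r}")
    if factor <= 0:
        raise ValueError("factor must be positive")
    current = params.to_dict()[fld]
    return params.with_field(fld, current * factor)


def endspurt_summary(traj: Trajectory, window_m: float = 400.0) -> float:
    """Mean speed over the final ``window_m`` minus the race mean (m/s)."""
    race_mean = traj.s[-1] / traj.final_time
    m = traj.s >= traj.s[-1] - window_m
    return float(traj.v[m].mean() - race_mean)


def bend_straight_amplitude(traj: Trajectory, lap_length: float = 400.0):
    """Per-lap mean straight-speed minus bend-speed; returns (mean, std)."""
    diffs = []
    n_laps = int(round(traj.s[-1] / lap_length))
    for lap in range(n_laps):
        m = (traj.s >= lap * lap_length) & (traj.s < (lap + 1) * lap_length)
        on_bend = m & (traj.curvature > 0)
        on_straight = m & (traj.curvature == 0)
        if on_bend.any() and on_straight.any():
            diffs.append(traj.v[on_straight].mean() - traj.v[on_bend].mean())
    diffs = np.asarray(diffs)
    return float(diffs.mean()), float(diffs.std())


@dataclass
class ScenarioReport:
    """Comparison of a base race and a perturbed variant."""

    t_base: float
    t_variant: float
    delta_t: float
    split_speed_diff: np.ndarray  # base minus variant, per 100-m segment
    endspurt_base: float
    endspurt_variant: float
    amplitude_base: tuple
    amplitude_variant: tuple
    corridor_widened: bool
    base_status: str
    variant_status: str

    def to_json(self, path) -> None:
        d = {
            "t_base": self.t_base,
            "t_variant": self.t_variant,
            "delta_t": self.delta_t,
            "split_speed_diff": [float(x) for x in self.split_speed_diff],
            "endspurt_base": self.endspurt_base,
            "endspurt_variant": self.endspurt_variant,
            "amplitude_base": list(self.amplitude_base),
            "amplitude_variant": list(self.amplitude_variant),
            "corridor_widened": self.corridor_widened,
            "base_status": self.base_status,
            "variant_status": self.variant_status,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)
            fh.write("\n")

    def write_split_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["segment_index", "speed_diff_mps"])
            for k, d in enumerate(self.split_speed_diff, start=1):
                w.writerow([k, f"{d:.6f}"])


def compare_scenarios(
    base: RunnerParams,
    variant: RunnerParams,
    track: TrackGeometry = DEFAULT_TRACK,
    corridor: Optional[SpeedCorridor] = None,
    options: Optional[SolverOptions] = None,
    widen_extra: float = 0.15,
    keep_tight_below: float = 0.4,
) -> ScenarioReport:
    """Solve both runners and summarize the strategic consequences.

    Both are solved under the same corridor.  If the variant cannot
    follow it, the wide sections of the corridor are relaxed by
    ``widen_extra`` m/s on each side (strategic windows narrower than
    ``keep_tight_below`` m/s are preserved) and the fallback is flagged
    in the report.
    """
    options = options or SolverOptions()
    traj_b = solve_race(base, track, corridor, options)
    traj_v = solve_race(variant, track, corridor, options)
    widened = False
    if not traj_v.converged and corridor is not None:
        log.warning(
            "variant infeasible under base corridor (%s); widening wide bounds "
            "by %.2f m/s", traj_v.solve_status, widen_extra,
        )
        widened = True
        corridor_w = corridor.widened(widen_extra, keep_tight_below=keep_tight_below)
        traj_v = solve_race(variant, track, corridor_w, options)
    if not (traj_b.converged and traj_v.converged):
        raise RuntimeError(
            f"scenario solves did not converge: base={traj_b.solve_status}, "
            f"variant={traj_v.solve_status}"
        )
    splits_b = compute_splits(traj_b)
    splits_v = compute_splits(traj_v)
    return ScenarioReport(
        t_base=traj_b.final_time,
        t_variant=traj_v.final_time,
        delta_t=traj_v.final_time - traj_b.final_time,
        split_speed_diff=splits_b.mean_speeds - splits_v.mean_speeds,
        endspurt_base=endspurt_summary(traj_b),
        endspurt_variant=endspurt_summary(traj_v),
        amplitude_base=bend_straight_amplitude(traj_b),
        amplitude_variant=bend_straight_amplitude(traj_v),
        corridor_widened=widened,
        base_status=traj_b.solve_status,
        variant_status=traj_v.solve_status,
    )
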