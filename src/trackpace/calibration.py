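"""Identification of runner parameters from an observed split series.

The forward map is a full optimal-control solve: given a candidate
parameter vector the race is re-optimized inside the tactical corridor
and the simulated 100-m mean speeds are compared with the observed ones.
Calibration minimizes that discrepancy (RMSE in m/s by default) with a
bounded derivative-free search.  The sigma-curve shape fractions
(``phi_ramp``, ``phi_final``, ``sigma_rest``) are held fixed during the
search to curb non-identifiability; the free fields are ``e0``, ``f_M``,
``tau``, ``u_plus``, ``u_minus``, ``sigma_max`` and ``sigma_final``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .ocp import SolverOptions, solve_race
from .runner import RunnerParams
from .splits import SpeedCorridor, SplitSeries, build_corridor, compute_splits
from .track import TrackGeometry, DEFAULT_TRACK

__all__ = ["FitResult", "fit_error", "calibrate", "FREE_FIELDS"]

log = logging.getLogger(__name__)

FREE_FIELDS: Tuple[str, ...] = (
    "e0",
    "f_M",
    "tau",
    "u_plus",
    "u_minus",
    "sigma_max",
    "sigma_final",
)


def _residuals(
    params: RunnerParams,
    observed: SplitSeries,
    track: TrackGeometry,
    corridor: SpeedCorridor,
    options: SolverOptions,
    metric: str,
    x0: Optional[np.ndarray] = None,
):
    try:
        traj = solve_race(params, track, corridor, options, x0=x0)
    except ValueError as exc:
        log.warning("fit_error: solve raised %s", exc)
        return None, None
    if not traj.converged:
        log.warning("fit_error: solve status %s", traj.solve_status)
        return None, None
    sim = compute_splits(traj, observed.segment_length)
    if metric == "speed":
        return sim.mean_speeds - observed.mean_speeds, traj
    if metric == "time":
        return sim.times - observed.times, traj
    raise ValueError(f"unknown metric {metric!r}")


def fit_error(
    params: RunnerParams,
    observed: SplitSeries,
    track: TrackGeometry = DEFAULT_TRACK,
    corridor: Optional[SpeedCorridor] = None,
    options: Optional[SolverOptions] = None,
    metric: str = "speed",
) -> float:
    """RMSE between simulated and observed per-segment mean speeds (m/s).

    Solves the race for ``params`` inside ``corridor`` (rebuilt from the
    observed series when not supplied), computes the simulated splits and
    returns the RMSE; infeasible or failed solves return ``+inf`` with
    the reason logged.  Deterministic for identical inputs.
    """
    corridor = corridor if corridor is not None else build_corridor(observed)
    options = options or SolverOptions()
    res, _ = _residuals(params, observed, track, corridor, options, metric)
    if res is None:
        return float("inf")
    return float(np.sqrt(np.mean(res**2)))


@dataclass
class FitResult:
    """Outcome of a calibration run."""

    params: RunnerParams
    rmse: float
    residuals: np.ndarray
    n_solves: int
    converged: bool
    history: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "rmse": self.rmse,
            "residuals": [float(r) for r in self.residuals],
            "n_solves": self.n_solves,
            "converged": self.converged,
            "history": [float(h) for h in self.history],
        }


DEFAULT_FREE_FIELDS: Tuple[str, ...] = ("e0", "f_M", "tau")


def calibrate(
    observed: SplitSeries,
    init: RunnerParams,
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    budget: int = 200,
    options: Optional[SolverOptions] = None,
    track: TrackGeometry = DEFAULT_TRACK,
    corridor: Optional[SpeedCorridor] = None,
    metric: str = "speed",
    free_fields: Sequence[str] = DEFAULT_FREE_FIELDS,
    n_stages: int = 2,
) -> FitResult:
    """Bounded derivative-free minimization of :func:`fit_error`.

    By default only ``(e0, f_M, tau)`` are varied: from a single race's
    100-m splits the aerobic-curve levels and the force-rate limits are
    structurally near-unidentifiable (they influence the observable
    splits almost solely through the total work available in the
    unconstrained race phases, which ``e0`` already parametrizes), and
    freeing them lets the search wander along compensation valleys.  Any
    subset of :data:`FREE_FIELDS` can be requested instead.

    ``bounds`` maps field names to (low, high) in natural units; fields
    without an entry default to ``[0.6, 1.6]`` times the initial value.
    ``budget`` caps the number of race solves.  The search is a bounded
    Nelder-Mead simplex on parameters scaled by their initial values
    (vertices offset 5% per coordinate), run in ``n_stages`` stages with
    a fresh full-size simplex at the incumbent between stages — the
    restart re-expands the collapsed simplex and lets it walk down the
    narrow (e0, tau) compensation valley.  Deterministic given the same
    inputs; the best iterate is returned even if the budget runs out.
    """
    if budget < 1:
        raise ValueError("budget must be at least 1")
    corridor = corridor if corridor is not None else build_corridor(observed)
    options = options or SolverOptions()
    bounds = dict(bounds or {})
    fields = list(free_fields)
    for name in fields:
        if name not in FREE_FIELDS:
            raise ValueError(f"{name!r} is not a calibratable field")

    init_d = init.to_dict()
    init_vals = np.array([init_d[f] for f in fields])
    lo = np.array([bounds.get(f, (0.6 * init_d[f], None))[0] for f in fields])
    hi = np.array([bounds.get(f, (None, 1.6 * init_d[f]))[-1] for f in fields])
    if np.any(init_vals < lo) or np.any(init_vals > hi):
        raise ValueError("init must lie within bounds")

    def build(x_scaled: np.ndarray) -> Optional[RunnerParams]:
        p = init
        try:
            for name, val in zip(fields, x_scaled * init_vals):
                p = p.with_field(name, float(val))
            return p
        except ValueError as exc:
            log.debug("calibrate: invalid parameter combination: %s", exc)
            return None

    state = {"n": 0, "best": (float("inf"), None), "history": [], "x0": None}

    def objective(x_scaled: np.ndarray) -> float:
        if state["n"] >= budget:
            # budget exhausted: return a flat large value so the optimizer
            # winds down without triggering further race solves
            return state["best"][0] + 1.0
        state["n"] += 1
        p = build(x_scaled)
        if p is None:
            return float("inf")
        # warm-start from the incumbent's speed profile: the evaluation
        # order is deterministic, so the whole search stays reproducible
        res, traj = _residuals(
            p, observed, track, corridor, options, metric, x0=state["x0"]
        )
        rmse = float("inf") if res is None else float(np.sqrt(np.mean(res**2)))
        if rmse < state["best"][0]:
            state["best"] = (rmse, p)
            state["x0"] = traj.v[1:]
        state["history"].append(state["best"][0])
        return rmse

    n_stages = max(1, min(n_stages, budget // 20)) or 1
    x = np.ones(len(fields))
    nm_bounds = list(zip(lo / init_vals, hi / init_vals))
    res = None
    for _ in range(n_stages):
        simplex = np.vstack(
            [x] + [x + 0.05 * np.eye(len(fields))[i] for i in range(len(fields))]
        )
        res = minimize(
            objective,
            x,
            method="Nelder-Mead",
            bounds=nm_bounds,
            options={
                "maxfev": max(1, budget // n_stages),
                "initial_simplex": np.clip(simplex, *np.transpose(nm_bounds)),
                "xatol": 1e-5,
                "fatol": 1e-8,
                "adaptive": True,
            },
        )
        if state["best"][1] is not None:
            x = np.array(
                [state["best"][1].to_dict()[f] for f in fields]
            ) / init_vals
        if state["n"] >= budget:
            break

    best_rmse, best_params = state["best"]
    if best_params is None:
        best_params, best_rmse = init, float("inf")
    residuals, _ = _residuals(best_params, observed, track, corridor, options, metric)
    if residuals is None:
        residuals = np.full(len(observed), np.nan)
    converged = bool(res is not None and res.success and np.isfinite(best_rmse))
    log.info(
        "calibrate: %d solves, best rmse %.4g, converged=%s",
        state["n"], best_rmse, converged,
    )
    return FitResult(
        params=best_params,
        rmse=float(best_rmse),
        residuals=residuals,
        n_solves=state["n"],
        converged=converged,
        history=state["history"],
    )
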