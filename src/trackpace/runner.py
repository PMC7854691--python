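"""Physiology of the runner: parameters, aerobic power curve, equations of motion.

The runner is a point mass moving along the track.  Three coupled state
variables describe the race at distance ``s``: the speed ``v``, the
propulsive force per unit mass ``f`` (the control-driven forward force,
N/kg), and the remaining anaerobic energy per unit mass ``e`` (J/kg, the
mechanical equivalent of the maximal accumulated oxygen deficit).  In time
the dynamics are::

    dv/dt = f - v / tau            (Newton, with linear friction)
    df/dt = u,  u in [-u_minus, u_plus]   (motor control: bounded force rate)
    de/dt = sigma(e) - f * v       (energy balance)

``sigma(e)`` is the aerobic power available to the runner, modelled as a
function of the remaining anaerobic reserve, which proxies race phase: it
ramps up from a resting value at the start (oxygen-uptake kinetics),
plateaus through the bulk of the race and drops near exhaustion.

On the bends part of the force budget is consumed by the centripetal
acceleration ``v^2 / R``; the propulsive force is limited by::

    f^2 + v^4 / R^2 <= f_M^2

so that at a given bend speed less forward force is available than on a
straight.  ``f_M * tau`` is the maximal (sprint) speed of the runner.

All powers here are mechanical (work done by the propulsive force).
Oxygen-uptake figures quoted in mL/kg/min convert to *metabolic* W/kg via
an energy equivalent of 20.9 J per mL of O2; only a fraction of that
(the gross efficiency of running, on the order of one third once elastic
return is counted) appears as mechanical power, which is why the default
``sigma_max`` is far below the ~25 W/kg metabolic figure implied by
running at 85% of an 85 mL/kg/min VO2max.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "SigmaProfile",
    "RunnerParams",
    "sigma_of_e",
    "vo2_to_power",
    "dynamics_rhs",
    "bend_force_cap",
    "max_speed",
    "default_winner",
]

#: J of metabolic energy released per mL of O2 consumed.
O2_ENERGY_EQUIVALENT = 20.9


def vo2_to_power(vo2: float, energy_equivalent: float = O2_ENERGY_EQUIVALENT) -> float:
    """Convert an oxygen uptake (mL O2/kg/min) to metabolic power (W/kg)."""
    if vo2 < 0:
        raise ValueError("vo2 must be non-negative")
    if energy_equivalent <= 0:
        raise ValueError("energy_equivalent must be positive")
    return vo2 * energy_equivalent / 60.0


@dataclass(frozen=True)
class SigmaProfile:
    """Aerobic power (W/kg) as a piecewise-linear function of remaining energy.

    Reading the race forward in time, ``e`` *decreases* from ``e0``: the
    curve rises from ``sigma_rest`` at ``e = e0`` to ``sigma_max`` at
    ``e = phi_ramp * e0`` (start kinetics), stays at ``sigma_max`` down to
    ``e = phi_final * e0``, then falls linearly to ``sigma_final`` at
    ``e = 0`` (near-exhaustion decline).
    """

    sigma_max: float
    sigma_rest: float
    sigma_final: float
    phi_ramp: float = 0.9
    phi_final: float = 0.2

    def __post_init__(self) -> None:
        if not (0 <= self.sigma_rest <= self.sigma_max):
            raise ValueError("need 0 <= sigma_rest <= sigma_max")
        if not (0 <= self.sigma_final <= self.sigma_max):
            raise ValueError("need 0 <= sigma_final <= sigma_max")
        if not (0 < self.phi_final < self.phi_ramp < 1):
            raise ValueError("need 0 < phi_final < phi_ramp < 1")

    def __call__(self, e, e0: float):
        return sigma_of_e(e, e0, self)

    def breakpoints(self, e0: float) -> Tuple[np.ndarray, np.ndarray]:
        xp = np.array([0.0, self.phi_final * e0, self.phi_ramp * e0, e0])
        fp = np.array([self.sigma_final, self.sigma_max, self.sigma_max, self.sigma_rest])
        return xp, fp


def sigma_of_e(e, e0: float, profile: SigmaProfile):
    """Evaluate the aerobic power curve at remaining energy ``e`` in [0, e0]."""
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr < -1e-9) or np.any(e_arr > e0 * (1 + 1e-12) + 1e-9):
        raise ValueError("e outside [0, e0]")
    xp, fp = profile.breakpoints(e0)
    out = np.interp(e_arr, xp, fp)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RunnerParams:
    """Physiological parameter vector of one athlete.

    Attributes
    ----------
    e0
        Total anaerobic energy per mass (J/kg) — the mechanical equivalent
        of the maximal accumulated oxygen deficit.
    f_M
        Maximal propulsive force per mass (N/kg).
    tau
        Global friction coefficient (s); lumps every speed-proportional
        loss.  The per-distance steady cost of speed ``v`` is ``v / tau``,
        so a *smaller* tau means a costlier (less economical) runner.
    u_plus, u_minus
        Maximal increase / decrease rate of the propulsive force
        (N/kg/s); ``u_minus`` is stored positive.
    sigma
        Aerobic power curve, see :class:`SigmaProfile`.
    """

    e0: float
    f_M: float
    tau: float
    u_plus: float
    u_minus: float
    sigma: SigmaProfile

    def __post_init__(self) -> None:
        for name in ("e0", "f_M", "tau", "u_plus", "u_minus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        vmax = self.f_M * self.tau
        if not (2.0 <= vmax <= 15.0):
            raise ValueError(
                f"f_M * tau = {vmax:.3f} m/s outside the plausible human "
                "maximal-speed window [2, 15]"
            )

    # -- convenience -------------------------------------------------------

    @property
    def max_speed(self) -> float:
        """Maximal speed ``f_M * tau`` (m/s)."""
        return self.f_M * self.tau

    def sigma_at(self, e):
        return sigma_of_e(e, self.e0, self.sigma)

    def with_field(self, name: str, value: float) -> "RunnerParams":
        """Copy with one top-level or sigma field replaced (re-validated)."""
        if name in ("sigma_max", "sigma_rest", "sigma_final", "phi_ramp", "phi_final"):
            return replace(self, sigma=replace(self.sigma, **{name: value}))
        return replace(self, **{name: value})

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "e0": self.e0,
            "f_M": self.f_M,
            "tau": self.tau,
            "u_plus": self.u_plus,
            "u_minus": self.u_minus,
            "sigma_max": self.sigma.sigma_max,
            "sigma_rest": self.sigma.sigma_rest,
            "sigma_final": self.sigma.sigma_final,
            "phi_ramp": self.sigma.phi_ramp,
            "phi_final": self.sigma.phi_final,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunnerParams":
        d = dict(d)
        sigma_keys = ("sigma_max", "sigma_rest", "sigma_final", "phi_ramp", "phi_final")
        try:
            sigma = SigmaProfile(**{k: d.pop(k) for k in sigma_keys if k in d})
            return cls(sigma=sigma, **d)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid runner parameters: {exc}") from exc

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunnerParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def max_speed(params: RunnerParams) -> float:
    """Maximal speed of the runner, ``f_M * tau`` (m/s)."""
    return params.f_M * params.tau


def dynamics_rhs(
    v: float, f: float, e: float, u: float, params: RunnerParams
) -> Tuple[float, float, float]:
    """Time-domain right-hand side ``(dv/dt, df/dt, de/dt)``."""
    sigma = params.sigma_at(np.clip(e, 0.0, params.e0))
    return (f - v / params.tau, u, sigma - f * v)


def bend_force_cap(v, R, f_M: float):
    """Maximal propulsive force available at speed ``v`` on radius ``R``.

    ``sqrt(max(0, f_M^2 - v^4 / R^2))``; an infinite radius (straight)
    leaves the full budget ``f_M``.  Accepts scalars or arrays.
    """
    if f_M <= 0:
        raise ValueError("f_M must be positive")
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("v must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        centripetal_sq = np.where(np.isinf(R), 0.0, v**4 / np.asarray(R, float) ** 2)
    cap = np.sqrt(np.maximum(0.0, f_M**2 - centripetal_sq))
    return float(cap) if cap.ndim == 0 else cap


def default_winner() -> RunnerParams:
    """Winner-like default parameter set (tuning anchors, not measurements).

    Chosen so that the unconstrained optimal 10,000 m is in the 26-27 min
    range of a world-class championship final, with a plateau cruising
    speed near ``sqrt(sigma_max * tau)`` ~ 6.2 m/s, a sprint ceiling
    ``f_M * tau`` ~ 7.7 m/s, and a bend force cap that starts to bite at
    cruising speed so that bends are run slightly slower than straights.
    """
    sigma_max = 8.54
    return RunnerParams(
        e0=600.0,
        f_M=1.76,
        tau=4.5,
        u_plus=0.2,
        u_minus=0.2,
        sigma=SigmaProfile(
            sigma_max=sigma_max,
            sigma_rest=0.3 * sigma_max,
            sigma_final=0.8 * sigma_max,
            phi_ramp=0.9,
            phi_final=0.2,
        ),
    )
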