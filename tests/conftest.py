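"""Shared fixtures: expensive race solves are session-scoped and reused.

Every converged trajectory produced here is registered in
``solved_races`` so the oracle-equivalence test can re-integrate each
one independently.
"""

import numpy as np
import pytest

from trackpace import (
    DEFAULT_TRACK,
    SolverOptions,
    default_winner,
    solve_race,
)
from trackpace.synth import generate_race


@pytest.fixture(scope="session")
def winner():
    return default_winner()


@pytest.fixture(scope="session")
def fast_opts():
    """Coarse but adequate grid for the many-solve tests (40 m spacing)."""
    return SolverOptions(n_nodes=250, end_spacing_m=12.0, max_iter=100)


@pytest.fixture(scope="session")
def std_opts():
    return SolverOptions(n_nodes=500)


@pytest.fixture(scope="session")
def solved_races():
    """Registry name -> (trajectory, params) filled by the fixtures below."""
    return {}


@pytest.fixture(scope="session")
def free_race(winner, std_opts, solved_races):
    """Unconstrained optimal 10,000 m at the standard grid."""
    traj = solve_race(winner, DEFAULT_TRACK, None, std_opts)
    assert traj.converged, traj.message
    solved_races["free_10k"] = (traj, winner)
    return traj


@pytest.fixture(scope="session")
def synthetic_race(winner, fast_opts):
    """Zero-noise championship-style synthetic race with its truth record."""
    observed, truth = generate_race(
        winner, "championship_surge", DEFAULT_TRACK, fast_opts,
        noise_sd=0.0, seed=1,
    )
    return observed, truth


@pytest.fixture(scope="session")
def corridor_race(winner, fast_opts, synthetic_race, solved_races):
    """The winner re-solved inside the synthetic race's tactical corridor."""
    _, truth = synthetic_race
    traj = solve_race(winner, DEFAULT_TRACK, truth.corridor, fast_opts)
    assert traj.converged, traj.message
    solved_races["corridor_10k"] = (traj, winner)
    return traj


@pytest.fixture(scope="session")
def reduced_energy_race(winner, fast_opts, synthetic_race, solved_races):
    """The -5% anaerobic-energy variant under the same corridor."""
    _, truth = synthetic_race
    variant = winner.with_field("e0", 0.95 * winner.e0)
    traj = solve_race(variant, DEFAULT_TRACK, truth.corridor, fast_opts)
    assert traj.converged, traj.message
    solved_races["reduced_e0_10k"] = (traj, variant)
    return traj
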