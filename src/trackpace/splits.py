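"""Split series and tactical speed corridors.

The observable a pacing model is fitted to is the series of 100-m split
times ``T_k`` (equivalently mean speeds ``v_k = 100 / T_k``).  This module
converts solved trajectories to split series by exact quadrature of
``1/v`` assuming the speed is piecewise linear in distance between grid
nodes, builds piecewise-constant speed corridors (tactical lower/upper
speed bounds) around an observed profile, and reads/writes the split CSV
format.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "SplitSeries",
    "SpeedCorridor",
    "compute_splits",
    "build_corridor",
    "read_splits",
    "write_splits",
    "piecewise_linear_time",
]


def _interval_time(length: float, v1: float, v2: float) -> float:
    """Exact travel time over ``length`` with speed linear from v1 to v2."""
    if length == 0.0:
        return 0.0
    dv = v2 - v1
    if abs(dv) < 1e-10 * v1:
        return 2.0 * length / (v1 + v2)
    return length * np.log1p(dv / v1) / dv


def piecewise_linear_time(s: np.ndarray, v: np.ndarray, a: float, b: float) -> float:
    """Travel time from ``a`` to ``b`` for a speed profile piecewise linear in s.

    Grid-exact: sub-interval boundaries are interpolated, so the result is
    additive over adjacent ranges to machine precision and exact for
    profiles that really are piecewise linear (including constant).
    """
    if not (s[0] - 1e-9 <= a <= b <= s[-1] + 1e-9):
        raise ValueError("integration range outside the trajectory grid")
    i = int(np.searchsorted(s, a, side="right")) - 1
    i = max(0, min(i, len(s) - 2))
    total = 0.0
    lo = a
    while lo < b - 1e-12:
        hi = min(b, s[i + 1])
        # speeds at lo, hi by linear interpolation within [s_i, s_{i+1}]
        w_lo = (lo - s[i]) / (s[i + 1] - s[i])
        w_hi = (hi - s[i]) / (s[i + 1] - s[i])
        v_lo = v[i] + w_lo * (v[i + 1] - v[i])
        v_hi = v[i] + w_hi * (v[i + 1] - v[i])
        total += _interval_time(hi - lo, v_lo, v_hi)
        lo = hi
        i += 1
    return total


@dataclass(frozen=True)
class SplitSeries:
    """Per-segment times of a race cut into fixed-length splits.

    ``times[k]`` is the time for the k-th ``segment_length``-metre segment;
    ``mean_speeds[k] = segment_length / times[k]``.
    """

    times: np.ndarray
    segment_length: float = 100.0
    race_distance: float = 10_000.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        n_expected = self.race_distance / self.segment_length
        if abs(n_expected - round(n_expected)) > 1e-9:
            raise ValueError("segment_length must divide race_distance")
        if len(times) != round(n_expected):
            raise ValueError(
                f"expected {round(n_expected)} segments, got {len(times)}"
            )
        if np.any(times <= 0):
            raise ValueError("split times must be strictly positive")

    @property
    def mean_speeds(self) -> np.ndarray:
        return self.segment_length / self.times

    @property
    def final_time(self) -> float:
        return float(self.times.sum())

    @property
    def distance_ends(self) -> np.ndarray:
        return self.segment_length * np.arange(1, len(self.times) + 1)

    def __len__(self) -> int:
        return len(self.times)


def compute_splits(traj, segment_length: float = 100.0) -> SplitSeries:
    """Cut a trajectory into fixed-length splits by quadrature of ``1/v``.

    ``traj`` needs ``s`` and ``v`` arrays covering the race.  The time for
    each segment is the exact integral of ``1/v`` with ``v`` piecewise
    linear between grid nodes, so the splits sum to the trajectory's final
    time to machine precision.
    """
    s = np.asarray(traj.s, float)
    v = np.asarray(traj.v, float)
    D = float(s[-1])
    n = D / segment_length
    if abs(n - round(n)) > 1e-9:
        raise ValueError("segment_length must divide the race distance")
    n = round(n)
    if np.min(np.diff(s)) > segment_length:
        raise ValueError("trajectory grid is coarser than the split length")
    times = np.array(
        [
            piecewise_linear_time(s, v, k * segment_length, (k + 1) * segment_length)
            for k in range(n)
        ]
    )
    return SplitSeries(times=times, segment_length=segment_length, race_distance=D)


# ---------------------------------------------------------------------------
# Speed corridors


@dataclass(frozen=True)
class SpeedCorridor:
    """Piecewise-constant speed bounds vs distance.

    ``breakpoints`` has K+1 edges covering the race; on
    ``[breakpoints[i], breakpoints[i+1])`` the speed must stay within
    ``[v_lo[i], v_hi[i]]``.
    """

    breakpoints: np.ndarray
    v_lo: np.ndarray
    v_hi: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, float)
        lo = np.asarray(self.v_lo, float)
        hi = np.asarray(self.v_hi, float)
        for name, arr in (("breakpoints", bp), ("v_lo", lo), ("v_hi", hi)):
            object.__setattr__(self, name, arr)
        if len(bp) != len(lo) + 1 or len(lo) != len(hi):
            raise ValueError("need len(breakpoints) == len(v_lo) + 1 == len(v_hi) + 1")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(lo > hi):
            raise ValueError("v_lo must not exceed v_hi")

    @property
    def race_distance(self) -> float:
        return float(self.breakpoints[-1])

    def bounds_at(self, s):
        """(lo, hi) at distance(s) ``s``; the last interval is closed."""
        s = np.asarray(s, float)
        idx = np.clip(
            np.searchsorted(self.breakpoints, s, side="right") - 1,
            0,
            len(self.v_lo) - 1,
        )
        lo, hi = self.v_lo[idx], self.v_hi[idx]
        if lo.ndim == 0:
            return float(lo), float(hi)
        return lo, hi

    def widened(self, extra: float, keep_tight_below: float | None = None) -> "SpeedCorridor":
        """Relax bounds by ``extra`` m/s; intervals whose width is below
        ``keep_tight_below`` (strategic windows) are left untouched."""
        width = self.v_hi - self.v_lo
        relax = np.ones_like(width, dtype=bool)
        if keep_tight_below is not None:
            relax = width >= keep_tight_below
        lo = np.where(relax, self.v_lo - extra, self.v_lo)
        hi = np.where(relax, self.v_hi + extra, self.v_hi)
        return SpeedCorridor(self.breakpoints.copy(), np.maximum(lo, 0.1), hi)

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["start_m", "end_m", "v_lo", "v_hi"])
            for i in range(len(self.v_lo)):
                w.writerow(
                    [
                        f"{self.breakpoints[i]:.3f}",
                        f"{self.breakpoints[i + 1]:.3f}",
                        f"{self.v_lo[i]:.6f}",
                        f"{self.v_hi[i]:.6f}",
                    ]
                )


def _moving_average_truncated(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; the window is truncated at the edges."""
    n = len(x)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + (window - 2 * half))
        out[i] = x[lo:hi].mean()
    return out


def build_corridor(
    observed: SplitSeries,
    smooth_window: int = 4,
    delta_wide: float = 0.3,
    tight_windows: Sequence[Tuple[float, float]] = ((0.0, 200.0), (4000.0, 6000.0)),
    delta_tight: float = 0.1,
) -> SpeedCorridor:
    """Corridor around the smoothed observed speed profile.

    The centreline is a centred ``smooth_window``-segment moving average of
    the observed mean speeds (truncated at the edges); bounds are
    centreline +/- ``delta_wide``, tightened to +/- ``delta_tight`` inside
    the strategic ``tight_windows``.
    """
    if len(observed) < smooth_window:
        raise ValueError("observed series shorter than the smoothing window")
    wins = sorted((float(a), float(b)) for a, b in tight_windows)
    for (a1, b1), (a2, b2) in zip(wins, wins[1:]):
        if b1 > a2:
            raise ValueError(f"tight windows ({a1},{b1}) and ({a2},{b2}) overlap")
    centre = _moving_average_truncated(observed.mean_speeds, smooth_window)
    L = observed.segment_length
    bp = np.concatenate([[0.0], observed.distance_ends])
    delta = np.full(len(observed), delta_wide)
    mids = bp[:-1] + L / 2
    for a, b in wins:
        delta[(mids > a) & (mids < b)] = delta_tight
    return SpeedCorridor(bp, centre - delta, centre + delta)


# ---------------------------------------------------------------------------
# CSV I/O

_HEADER = ["segment_index", "distance_end_m", "time_s", "mean_speed_mps"]


def write_splits(series: SplitSeries, path) -> None:
    """Write the split CSV (``segment_index,distance_end_m,time_s,mean_speed_mps``)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_HEADER)
        for k, (d, t, v) in enumerate(
            zip(series.distance_ends, series.times, series.mean_speeds), start=1
        ):
            w.writerow([k, f"{d:.3f}", f"{t:.9f}", f"{v:.9f}"])


def read_splits(path, expected_distance: float | None = None) -> SplitSeries:
    """Read a split CSV; validates monotone distances and positive times.

    If ``expected_distance`` is given, the file must cover exactly that
    distance (e.g. 100 rows of 100 m for a 10,000 m race).  The stored
    mean speed is recomputed from the time; a disagreement above 0.1%
    triggers a warning.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(_HEADER[:3]).issubset(reader.fieldnames):
            raise ValueError(
                f"missing columns: expected at least {_HEADER[:3]}, got {reader.fieldnames}"
            )
        dist, times, speeds = [], [], []
        for row_no, row in enumerate(reader, start=2):
            try:
                d = float(row["distance_end_m"])
                t = float(row["time_s"])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"row {row_no}: unparseable number") from exc
            if t <= 0:
                raise ValueError(f"row {row_no}: non-positive time_s {t}")
            if dist and d <= dist[-1]:
                raise ValueError(f"row {row_no}: non-monotone distance_end_m {d}")
            dist.append(d)
            times.append(t)
            if row.get("mean_speed_mps"):
                speeds.append((row_no, float(row["mean_speed_mps"])))
    if not dist:
        raise ValueError("empty split file")
    seg = dist[0]
    widths = np.diff([0.0] + dist)
    if np.max(np.abs(widths - seg)) > 1e-6:
        raise ValueError("segments are not of uniform length")
    if expected_distance is not None:
        n_expected = round(expected_distance / seg)
        if len(dist) != n_expected:
            raise ValueError(
                f"expected {n_expected} rows covering {expected_distance} m, "
                f"got {len(dist)}"
            )
    series = SplitSeries(
        times=np.array(times), segment_length=seg, race_distance=dist[-1]
    )
    for (row_no, v_stored), v_calc in zip(speeds, series.mean_speeds):
        if abs(v_stored - v_calc) > 1e-3 * v_calc:
            warnings.warn(
                f"row {row_no}: stored mean speed {v_stored} disagrees with "
                f"recomputed {v_calc:.6f} by more than 0.1%",
                stacklevel=2,
            )
    return series
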