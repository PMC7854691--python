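"""Geometry of the standard 400 m athletics track.

A standard outdoor track is built from two 84 m straights joined by two
half-circle bends; on the measurement line of lane one the bends are 116 m
long, giving a 400 m lap.  A 10,000 m race covers 25 laps and starts on a
bend, so the race alternates 50 bends and 50 straights.  For the pacing
model the only geometric quantity that matters is the curvature of the
running line as a function of distance from the start: zero on the
straights and ``1 / bend_radius`` on the bends.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterator, List, Tuple

import numpy as np

__all__ = ["TrackGeometry", "Segment", "DEFAULT_TRACK"]

BEND = "bend"
STRAIGHT = "straight"


@dataclass(frozen=True)
class Segment:
    """One bend or straight: half-open interval ``[start, end)`` in metres."""

    start: float
    end: float
    kind: str

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class TrackGeometry:
    """Curvature-vs-distance description of a standard 400 m track.

    Parameters
    ----------
    lap_length
        Length of one lap on the measurement line (m).
    straight_length
        Length of each straight (m).
    bend_length
        Length of each half-circle bend as measured on the lap line (m).
    bend_radius
        Radius used for the curvature on the bends (m).  Following common
        championship-track practice the nominal kerb radius 36.5 m is used
        even though the lap line is offset 0.30 m outward; the two printed
        values (116 m bends, radius 36.5 m) are therefore slightly
        inconsistent (pi * 36.5 = 114.7 m) and are both kept as-is.
    race_distance
        Total race distance (m); 10,000 m is 25 laps.
    start_segment
        Whether distance 0 falls on a bend or a straight.  Championship
        10,000 m races start on the first bend.
    """

    lap_length: float = 400.0
    straight_length: float = 84.0
    bend_length: float = 116.0
    bend_radius: float = 36.5
    race_distance: float = 10_000.0
    start_segment: str = BEND

    def __post_init__(self) -> None:
        if abs(2 * (self.straight_length + self.bend_length) - self.lap_length) > 1e-9:
            raise ValueError(
                "2*(straight_length + bend_length) must equal lap_length; got "
                f"2*({self.straight_length} + {self.bend_length}) != {self.lap_length}"
            )
        if self.bend_radius <= 0:
            raise ValueError("bend_radius must be positive")
        if self.race_distance <= 0:
            raise ValueError("race_distance must be positive")
        if self.start_segment not in (BEND, STRAIGHT):
            raise ValueError(f"start_segment must be '{BEND}' or '{STRAIGHT}'")

    # -- curvature ---------------------------------------------------------

    def curvature_at(self, s):
        """Curvature (1/m) of the running line at distance ``s`` from the start.

        ``s`` may be a scalar or an array; values are reduced modulo the lap
        length.  Segments are half-open, so exactly at a boundary the
        curvature of the *next* segment applies.
        """
        s = np.asarray(s, dtype=float)
        if np.any(s < 0) or np.any(s > self.race_distance):
            raise ValueError("distance outside [0, race_distance]")
        sl = np.mod(s, self.lap_length)
        b, st = self.bend_length, self.straight_length
        if self.start_segment == BEND:
            on_bend = (sl < b) | ((sl >= b + st) & (sl < 2 * b + st))
        else:
            on_bend = ((sl >= st) & (sl < st + b)) | (sl >= 2 * st + b)
        kappa = np.where(on_bend, 1.0 / self.bend_radius, 0.0)
        return float(kappa) if kappa.ndim == 0 else kappa

    # -- segmentation ------------------------------------------------------

    def _lap_pattern(self) -> List[Tuple[float, str]]:
        if self.start_segment == BEND:
            kinds = [BEND, STRAIGHT, BEND, STRAIGHT]
        else:
            kinds = [STRAIGHT, BEND, STRAIGHT, BEND]
        lengths = [
            self.bend_length if k == BEND else self.straight_length for k in kinds
        ]
        return list(zip(lengths, kinds))

    def segment_boundaries(self) -> List[Segment]:
        """Ordered, contiguous cover of ``[0, race_distance]`` by segments."""
        out: List[Segment] = []
        s = 0.0
        pattern = self._lap_pattern()
        i = 0
        while s < self.race_distance - 1e-9:
            length, kind = pattern[i % 4]
            i += 1
            if length <= 0:
                continue
            end = min(s + length, self.race_distance)
            out.append(Segment(s, end, kind))
            s = end
        return out

    def total_distance_by_type(self, kind: str) -> float:
        """Total metres of the requested segment type over the race."""
        if kind not in (BEND, STRAIGHT):
            raise ValueError(f"kind must be '{BEND}' or '{STRAIGHT}'")
        return sum(seg.length for seg in self.segment_boundaries() if seg.kind == kind)

    # -- export ------------------------------------------------------------

    def write_segments_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["start_m", "end_m", "type"])
            for seg in self.segment_boundaries():
                w.writerow([f"{seg.start:.3f}", f"{seg.end:.3f}", seg.kind])

    @classmethod
    def from_dict(cls, d: dict) -> "TrackGeometry":
        return cls(**d)


DEFAULT_TRACK = TrackGeometry()
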