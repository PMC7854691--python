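"""Small helpers for race clock times in ``min:s`` notation (e.g. ``26:49.51``)."""

from __future__ import annotations

__all__ = ["parse_race_time", "format_race_time", "finish_gap"]


def parse_race_time(text: str) -> float:
    """Parse ``"M:SS.ss"`` (or ``"H:MM:SS.ss"``) into seconds."""
    parts = text.strip().split(":")
    if not 1 <= len(parts) <= 3 or any(p == "" for p in parts):
        raise ValueError(f"cannot parse race time {text!r}")
    try:
        values = [float(p) for p in parts]
    except ValueError as exc:
        raise ValueError(f"cannot parse race time {text!r}") from exc
    seconds = 0.0
    for v in values:
        seconds = seconds * 60.0 + v
    return seconds


def format_race_time(seconds: float) -> str:
    """Format seconds as ``M:SS.ss`` (round-trips with :func:`parse_race_time`)."""
    if seconds < 0:
        raise ValueError("negative race time")
    minutes, rem = divmod(round(seconds, 2), 60.0)
    return f"{int(minutes)}:{rem:05.2f}"


def finish_gap(time_a: str | float, time_b: str | float) -> float:
    """Finish-time gap ``b - a`` in seconds; accepts clock strings or seconds."""
    a = parse_race_time(time_a) if isinstance(time_a, str) else float(time_a)
    b = parse_race_time(time_b) if isinstance(time_b, str) else float(time_b)
    return round(b - a, 6)
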