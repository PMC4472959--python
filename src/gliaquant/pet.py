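"""Small-animal PET: frame schedules, SUV, time-activity curves.

The standardized uptake value normalizes a tissue radioactivity
concentration by injected dose and body weight,

    SUV = (tissue concentration / injected dose) x body weight,

with the usual 1 g/mL tissue-density convention so the result is
dimensionless.  A time-activity curve (TAC) holds one SUV per acquisition
frame; windowed averages weight frames by their exact temporal overlap
with the window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "parse_schedule",
    "suv",
    "windowed_mean_suv",
    "peak_suv",
    "value_at",
    "blockade_comparison",
]

#: The dynamic acquisition used throughout: 30 min as
#: 20 s x 3, 30 s x 2, 1 min x 2, 2 min x 3, 5 min x 4.
DEFAULT_SCHEDULE_TEXT = "20x3,30x2,60x2,120x3,300x4"


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous acquisition frames: (start_s, duration_s) pairs from 0."""

    frames: tuple[tuple[float, float], ...]

    def __init__(self, frames) -> None:
        frames = tuple((float(s), float(d)) for s, d in frames)
        if not frames:
            raise ValueError("empty schedule")
        t = 0.0
        for start, dur in frames:
            if dur <= 0:
                raise ValueError("frame durations must be positive")
            if abs(start - t) > 1e-9:
                raise ValueError(f"frames not contiguous at t={t} s")
            t = start + dur
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def total_duration_s(self) -> float:
        start, dur = self.frames[-1]
        return start + dur

    @property
    def starts_s(self) -> np.ndarray:
        return np.array([s for s, _ in self.frames])

    @property
    def durations_s(self) -> np.ndarray:
        return np.array([d for _, d in self.frames])

    @property
    def midpoints_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s / 2

    def frame_index_at(self, t_s: float) -> int:
        """Frame whose interval contains t; a boundary t belongs to the
        earlier frame."""
        if t_s < 0 or t_s > self.total_duration_s:
            raise ValueError(f"t={t_s} s outside schedule span")
        for i, (start, dur) in enumerate(self.frames):
            if start < t_s <= start + dur:
                return i
        return 0  # t == 0


_TOKEN = re.compile(
    r"^\s*(\d+(?:\.\d+)?)\s*(s|sec|secs|second|seconds|m|min|mins|minute|minutes)?"
    r"\s*x\s*(\d+)\s*$"
)


def parse_schedule(text: str) -> FrameSchedule:
    """Parse a frame-schedule string into a FrameSchedule.

    Accepts the compact form ``"20x3,30x2,60x2,120x3,300x4"`` (seconds)
    and the unit-annotated form ``"20 sec x 3, 30 sec x 2, 1 min x 2,
    2 min x 3, 5 min x 4"``.
    """
    frames: list[tuple[float, float]] = []
    t = 0.0
    for token in text.split(","):
        m = _TOKEN.match(token)
        if not m:
            raise ValueError(f"cannot parse schedule token {token!r}")
        dur = float(m.group(1))
        unit = m.group(2) or "s"
        if unit.startswith("m"):
            dur *= 60
        count = int(m.group(3))
        if dur <= 0 or count <= 0:
            raise ValueError(f"nonpositive duration or count in {token!r}")
        for _ in range(count):
            frames.append((t, dur))
            t += dur
    return FrameSchedule(frames)


@dataclass
class TimeActivityCurve:
    """Frame-wise SUV for one region, subject and condition."""

    schedule: FrameSchedule
    frame_values: np.ndarray
    injected_dose: float = float("nan")
    body_weight_g: float = float("nan")
    region: str = "whole brain"
    condition: str = "baseline"   # "baseline" | "blockade"

    def __post_init__(self) -> None:
        self.frame_values = np.asarray(self.frame_values, dtype=float)
        if self.frame_values.shape != (self.schedule.n_frames,):
            raise ValueError("frame_values length does not match schedule")
        if np.any(self.frame_values < 0):
            raise ValueError("SUV values must be non-negative")


def suv(concentration: float, injected_dose: float, body_weight_g: float,
        concentration_unit: str = "kBq/mL", dose_unit: str = "kBq") -> float:
    """SUV = (concentration / injected dose) x body weight.

    ``concentration`` is activity per mL of tissue and ``injected_dose``
    total activity; both must be expressed in the same activity unit
    (checked via the unit strings).  Body weight is grams; with the
    1 g/mL tissue-density convention the result is dimensionless.
    """
    if injected_dose <= 0 or body_weight_g <= 0:
        raise ValueError("dose and body weight must be positive")
    if not concentration_unit.startswith(dose_unit):
        raise ValueError(
            f"activity unit mismatch: {concentration_unit!r} vs {dose_unit!r}"
        )
    return (concentration / injected_dose) * body_weight_g


def windowed_mean_suv(tac: TimeActivityCurve, t0_s: float, t1_s: float) -> float:
    """Duration-weighted mean SUV over [t0, t1].

    Each frame contributes with weight equal to its exact temporal overlap
    with the window; over the full span this reduces to the
    duration-weighted mean of all frames.
    """
    if t1_s <= t0_s:
        raise ValueError("window end must exceed start")
    if t0_s < 0 or t1_s > tac.schedule.total_duration_s:
        raise ValueError("window outside schedule span")
    starts = tac.schedule.starts_s
    ends = starts + tac.schedule.durations_s
    overlap = np.clip(np.minimum(ends, t1_s) - np.maximum(starts, t0_s), 0, None)
    return float(np.sum(overlap * tac.frame_values) / np.sum(overlap))


def peak_suv(tac: TimeActivityCurve) -> tuple[float, tuple[float, float]]:
    """Maximum frame SUV and its (start_s, end_s) interval."""
    i = int(np.argmax(tac.frame_values))
    start, dur = tac.schedule.frames[i]
    return float(tac.frame_values[i]), (start, start + dur)


def value_at(tac: TimeActivityCurve, t_min: float) -> float:
    """SUV of the frame containing time t (minutes); boundary times belong
    to the earlier frame."""
    i = tac.schedule.frame_index_at(t_min * 60.0)
    return float(tac.frame_values[i])


def blockade_comparison(
    baseline: TimeActivityCurve,
    blockade: TimeActivityCurve,
    window_s: tuple[float, float] = (120.0, 600.0),
) -> tuple[float, float, float]:
    """Windowed mean SUV under baseline and receptor blockade, plus the
    fold reduction (baseline / blockade)."""
    if baseline.schedule != blockade.schedule:
        raise ValueError("baseline and blockade schedules differ")
    b = windowed_mean_suv(baseline, *window_s)
    k = windowed_mean_suv(blockade, *window_s)
    if k == 0:
        raise ValueError("blockade windowed mean is zero; fold undefined")
    return b, k, b / k
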