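"""Synthetic time-activity curves.

A TacSpec defines a continuous "true" SUV curve by piecewise-linear
interpolation through control points (with value 0 at t = 0).  Sampling on
a frame schedule replaces the continuous curve by duration-weighted frame
means, optionally with additive Gaussian frame noise; a blockade condition
scales the whole curve by ``blockade_scale`` before sampling, emulating
receptor occupancy by a pre-injected ligand.

Should a schedule extend beyond the last control point, the tail is
extrapolated by the terminal mono-exponential through the last two control
points (never negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..pet import FrameSchedule, TimeActivityCurve

__all__ = ["TacSpec", "generate_tac", "true_curve_value", "frame_means"]


@dataclass
class TacSpec:
    """Ground-truth kinetics and subject metadata for TAC generation."""

    control_points: list[tuple[float, float]]   # (time_min, SUV_true)
    injected_dose: float = 0.125    # mCi, bolus
    body_weight_g: float = 30.0
    noise_sd: float = 0.0           # SUV units, per frame
    n_subjects: int = 1
    blockade_scale: float = 1.0     # multiplicative, in (0, 1]

    def __post_init__(self) -> None:
        pts = [(float(t), float(v)) for t, v in self.control_points]
        if pts and pts[0][0] > 0:
            pts = [(0.0, 0.0)] + pts
        times = [t for t, _ in pts]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("control times must be strictly increasing")
        if any(v < 0 for _, v in pts):
            raise ValueError("SUV control values must be non-negative")
        if not 0 < self.blockade_scale <= 1:
            raise ValueError("blockade_scale must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        self.control_points = pts

    def scaled(self, factor: float) -> "TacSpec":
        return TacSpec(
            [(t, v * factor) for t, v in self.control_points],
            injected_dose=self.injected_dose, body_weight_g=self.body_weight_g,
            noise_sd=self.noise_sd, n_subjects=self.n_subjects,
            blockade_scale=self.blockade_scale,
        )


def true_curve_value(spec: TacSpec, t_min: np.ndarray) -> np.ndarray:
    """Evaluate the continuous true curve at times in minutes."""
    t = np.asarray(t_min, dtype=float)
    times = np.array([p[0] for p in spec.control_points])
    vals = np.array([p[1] for p in spec.control_points])
    out = np.interp(t, times, vals)
    beyond = t > times[-1]
    if np.any(beyond):
        t1, v1 = times[-1], vals[-1]
        t0, v0 = times[-2], vals[-2]
        if v1 > 0 and v0 > v1:
            k = np.log(v0 / v1) / (t1 - t0)      # terminal decay constant
            out[beyond] = v1 * np.exp(-k * (t[beyond] - t1))
        else:
            out[beyond] = max(v1, 0.0)
    return np.clip(out, 0.0, None)


def frame_means(spec: TacSpec, schedule: FrameSchedule,
                n_sub: int = 512) -> np.ndarray:
    """Duration-weighted mean of the true curve over each frame."""
    out = np.empty(schedule.n_frames)
    for i, (start_s, dur_s) in enumerate(schedule.frames):
        t = np.linspace(start_s / 60.0, (start_s + dur_s) / 60.0, n_sub + 1)
        out[i] = np.trapezoid(true_curve_value(spec, t), t) / (dur_s / 60.0)
    return out


def generate_tac(
    spec: TacSpec,
    schedule: FrameSchedule,
    seed: int,
    condition: str = "baseline",
    region: str = "whole brain",
) -> list[TimeActivityCurve]:
    """Sample ``spec.n_subjects`` noisy TACs on a frame schedule.

    ``condition="blockade"`` scales the true curve by
    ``spec.blockade_scale`` before sampling, so with zero noise every
    blockade frame is exactly that fraction of its baseline counterpart.
    """
    if condition not in ("baseline", "blockade"):
        raise ValueError(f"unknown condition {condition!r}")
    base = frame_means(spec, schedule)
    if condition == "blockade":
        base = base * spec.blockade_scale
    rng = np.random.default_rng(seed)
    tacs = []
    for _ in range(spec.n_subjects):
        noisy = base + rng.normal(0.0, spec.noise_sd, size=base.shape) \
            if spec.noise_sd > 0 else base.copy()
        tacs.append(TimeActivityCurve(
            schedule=schedule, frame_values=np.clip(noisy, 0.0, None),
            injected_dose=spec.injected_dose, body_weight_g=spec.body_weight_g,
            region=region, condition=condition,
        ))
    return tacs
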