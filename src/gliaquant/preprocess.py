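"""Illumination correction and intensity normalization.

All quantification starts from background-subtracted planes: a rolling-ball
background estimate (grayscale opening with a ball structuring element) is
removed from each channel of each z-slice, emulating the standard
subtract-background step of fluorescence image analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.restoration import rolling_ball

__all__ = ["subtract_background", "subtract_background_stack", "normalize_to_max"]


def subtract_background(plane: np.ndarray, ball_radius_px: float = 50) -> np.ndarray:
    """Remove smooth background from a single 2-D plane.

    The background is estimated by rolling a ball of the given radius under
    the intensity surface; features narrower than the ball survive, smooth
    illumination gradients do not.  The result is clipped at zero and is
    everywhere <= the input.

    A radius at least as large as the image cannot roll anywhere: the
    background then degenerates to the global minimum (with a warning).
    """
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ValueError("expected a 2-D plane")
    if ball_radius_px < 1:
        raise ValueError("ball_radius_px must be >= 1")
    if ball_radius_px >= max(plane.shape):
        warnings.warn(
            "rolling-ball radius exceeds image size; using global minimum "
            "as background",
            stacklevel=2,
        )
        background = np.full_like(plane, plane.min())
    else:
        background = rolling_ball(plane, radius=ball_radius_px)
    return np.clip(plane - background, 0, None)


def subtract_background_stack(stack, ball_radius_px: float = 50):
    """Apply :func:`subtract_background` per channel, per z-slice."""
    from .io_formats import ChannelStack

    out = np.empty_like(stack.intensities)
    for c in range(stack.n_channels):
        for z in range(stack.n_z):
            out[c, z] = subtract_background(stack.intensities[c, z], ball_radius_px)
    return ChannelStack(out, list(stack.channel_names),
                        stack.pixels_per_um, stack.z_step_um)


def normalize_to_max(values) -> np.ndarray:
    """Rescale so the maximum maps to exactly 100 (percent of channel max).

    NaNs (e.g. empty profile bins) are ignored when locating the maximum
    and propagate unchanged.
    """
    arr = np.asarray(values, dtype=float)
    peak = np.nanmax(arr) if arr.size else 0.0
    if not peak > 0:
        raise ValueError("normalization undefined: maximum is not positive")
    return arr / peak * 100.0    # divide first: arr/peak <= 1, cannot overflow
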