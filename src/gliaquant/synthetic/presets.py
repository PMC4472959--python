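"""Packaged default parameter sets.

These are the study conditions the synthetic tests run under: TAC control
points calibrated so the frame-sampled whole-brain curve reproduces the
reference kinetics (peak ~2.30 SUV in the 40-60 s frame, ~0.67 SUV at
10 min, ~0.22 SUV at 20 min, and the baseline/blockade pair with 2-10 min
windowed means of 1.8 and 0.65), plus the default image-phantom fields for
the engulfment-synapse offset, plaque core-radius and shared-fluorochrome
analyses.
"""

from __future__ import annotations

import numpy as np

from ..pet import DEFAULT_SCHEDULE_TEXT, parse_schedule
from .phantoms import (
    AstrocyteSpec,
    MicrogliaSpec,
    NeuronSpec,
    PhantomSpec,
    PlaqueSpec,
    S3PhantomSpec,
)
from .tac import TacSpec

__all__ = [
    "default_schedule",
    "ad_baseline",
    "ntg_baseline",
    "blockade_pair",
    "engulfment_default",
    "plaque_default",
    "s3_default",
]


def default_schedule():
    """The 30-min dynamic schedule: 20 s x3, 30 s x2, 1 min x2, 2 min x3,
    5 min x4."""
    return parse_schedule(DEFAULT_SCHEDULE_TEXT)


# Whole-brain bolus kinetics of the amyloid-bearing group.  Sampled from a
# calibrated bolus-shaped biexponential; piecewise-linear interpolation
# through these points, frame-averaged on the default schedule, lands the
# peak frame at 2.29 SUV (40-60 s), the 8-10 min frame at 0.67 SUV and the
# 18-23 min frame at 0.22 SUV.
_AD_BASELINE_POINTS = [
    (0.0, 0.0), (0.25, 1.7508), (0.5, 2.2412), (0.75, 2.3169), (1.0, 2.2603),
    (1.25, 2.1652), (1.5, 2.0627), (2.0, 1.8684), (2.5, 1.6976), (3.0, 1.549),
    (4.0, 1.3058), (5.0, 1.1174), (6.0, 0.9687), (7.0, 0.8489), (8.0, 0.7506),
    (9.0, 0.6684), (10.0, 0.5987), (12.0, 0.4863), (14.0, 0.3993),
    (16.0, 0.33), (18.0, 0.2738), (20.0, 0.2276), (23.0, 0.1729),
    (26.0, 0.1315), (30.0, 0.0914),
]

# The blockade-study baseline animal showed higher uptake than the group
# mean: its curve is the group curve scaled so the 2-10 min windowed mean
# is 1.8 SUV; the blocked animal retains 0.65/1.8 of it.
_BLOCKADE_WINDOW_S = (120.0, 600.0)
_BLOCKADE_BASELINE_TARGET = 1.8
_BLOCKADE_SCALE = 0.65 / 1.8


def ad_baseline(noise_sd: float = 0.0, n_subjects: int = 3) -> TacSpec:
    """Whole-brain baseline TAC of the amyloid-bearing group."""
    return TacSpec(list(_AD_BASELINE_POINTS), noise_sd=noise_sd,
                   n_subjects=n_subjects)


def ntg_baseline(noise_sd: float = 0.0, n_subjects: int = 3) -> TacSpec:
    """Control (non-transgenic) whole-brain TAC: ~33% lower uptake over
    the 2-10 min window."""
    return ad_baseline(noise_sd, n_subjects).scaled(0.67)


def blockade_pair(noise_sd: float = 0.0) -> TacSpec:
    """Baseline/blockade TacSpec for the receptor-specificity experiment.

    Generate the baseline condition as-is and the blockade condition with
    ``condition="blockade"``; with zero noise the 2-10 min windowed means
    are 1.8 and 0.65 SUV (a 2.77-fold reduction).
    """
    from ..pet import TimeActivityCurve, windowed_mean_suv
    from .tac import frame_means

    base = TacSpec(list(_AD_BASELINE_POINTS), noise_sd=noise_sd, n_subjects=1,
                   blockade_scale=_BLOCKADE_SCALE)
    sched = default_schedule()
    tac = TimeActivityCurve(sched, frame_means(base, sched))
    w = windowed_mean_suv(tac, *_BLOCKADE_WINDOW_S)
    return base.scaled(_BLOCKADE_BASELINE_TARGET / w)


def engulfment_default(cb2_offset_um: float = 1.5) -> PhantomSpec:
    """One plaque plus one microglia forming an engulfment synapse.

    The microglial body sits due east of the plaque so the body-to-plaque
    axis is the horizontal midline; the planted CB2-to-CD68 separation at
    the synapse equals ``cb2_offset_um``.
    """
    plaque = PlaqueSpec(center_um=(14.0, 18.0), core_radius_um=8.0)
    mg = MicrogliaSpec(body_center_um=(34.0, 18.0), target_plaque=0,
                       cb2_offset_um=cb2_offset_um)
    return PhantomSpec(
        field_size_px=(400, 533),      # 36 x 48 um at 11.1 px/um
        n_z=3,
        plaques=[plaque],
        microglia=[mg],
        background={"DAPI": 4.0, "CB2": 6.0, "CD68": 4.0, "NeuN": 4.0},
        genotype="AD",
    )


def plaque_default(core_radius_um: float = 7.0) -> PhantomSpec:
    """A single plaque ringed by four engulfing microglia.

    The four plate endings leave a CB2-dark core with a halo covering
    two-thirds of the perimeter, the geometry the radial-profile
    core-radius estimator assumes.
    """
    center = (20.0, 20.0)
    plaque = PlaqueSpec(center_um=center, core_radius_um=core_radius_um)
    mgs = []
    for k in range(4):
        ang = np.pi / 4 + k * np.pi / 2
        bx = center[0] + 18.0 * np.cos(ang)
        by = center[1] + 18.0 * np.sin(ang)
        mgs.append(MicrogliaSpec(body_center_um=(bx, by), target_plaque=0))
    return PhantomSpec(
        field_size_px=(444, 444),      # 40 x 40 um
        n_z=6,
        plaques=[plaque],
        microglia=mgs,
        background={"DAPI": 4.0, "CB2": 6.0, "CD68": 4.0, "NeuN": 4.0},
        genotype="AD",
    )


def s3_default(p_neuron: float = 0.009, p_gfap: float = 0.049) -> S3PhantomSpec:
    """Shared-fluorochrome discrimination field with the default planted
    error rates (0.9% neuron overlap, 4.9% unconfirmed mGFAP)."""
    return S3PhantomSpec(p_neuron=p_neuron, p_gfap=p_gfap)
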