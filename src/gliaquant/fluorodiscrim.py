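"""Error rates of discriminating neurons from astroglia on a shared
fluorochrome.

When only four laser lines are available, NeuN (neurons) and mouse-GFAP
(astrocytes) may have to share one fluorochrome/channel; the two cell types
are then separated by morphology.  The error of that separation is
quantified with a second, independently-labeled astroglial stain
(rabbit-GFAP on its own channel):

* neuron-overlap error — the fraction of total neuronal area (hand-drawn
  outlines on the shared channel) that carries rbGFAP signal, i.e.
  astroglial signal that would have been misread as neuronal;
* unconfirmed-mGFAP error — the fraction of mGFAP-positive area on the
  shared channel with no rbGFAP counterpart, i.e. signal called astroglial
  that the independent stain does not confirm.

Signal masks come from Gaussian blur followed by IsoData binarization, so
both rates are invariant to global intensity scaling.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_formats import RoiPolygon, rasterize_roi
from .masks import threshold_isodata

__all__ = [
    "rbgfap_mask",
    "neuron_overlap_error",
    "gfap_unconfirmed_error",
    "mgfap_mask_from_shared_channel",
]


def rbgfap_mask(channel: np.ndarray, blur_sigma_px: float = 1.0) -> np.ndarray:
    """Binarize an rbGFAP plane: Gaussian blur then IsoData threshold."""
    blurred = gaussian_filter(np.asarray(channel, dtype=float), blur_sigma_px)
    _, mask = threshold_isodata(blurred, marker="rbGFAP")
    return mask.values


def neuron_overlap_error(
    rbgfap_channel: np.ndarray,
    neuron_outlines: list[RoiPolygon],
    blur_sigma_px: float = 1.0,
) -> float:
    """Percent of total neuronal area overlapped by rbGFAP signal."""
    if not neuron_outlines:
        raise ValueError("need at least one neuron outline")
    plane = np.asarray(rbgfap_channel, dtype=float)
    neuron_mask = np.zeros(plane.shape, dtype=bool)
    for roi in neuron_outlines:
        neuron_mask |= rasterize_roi(roi, plane.shape)
    if not neuron_mask.any():
        raise ValueError("neuron outlines rasterize to an empty mask")
    glial = rbgfap_mask(plane, blur_sigma_px)
    return 100.0 * float((glial & neuron_mask).sum()) / float(neuron_mask.sum())


def gfap_unconfirmed_error(mgfap_mask: np.ndarray, rbgfap: np.ndarray) -> float:
    """Percent of mGFAP area not confirmed by the rbGFAP mask."""
    m = np.asarray(mgfap_mask, dtype=bool)
    r = np.asarray(rbgfap, dtype=bool)
    if m.shape != r.shape:
        raise ValueError("mask shapes differ")
    total = m.sum()
    if total == 0:
        raise ValueError("empty mGFAP mask")
    return 100.0 * float((m & ~r).sum()) / float(total)


def mgfap_mask_from_shared_channel(
    shared_channel: np.ndarray,
    neuron_outlines: list[RoiPolygon],
    blur_sigma_px: float = 1.0,
    outline_pad_px: int = 2,
) -> np.ndarray:
    """mGFAP mask on the dual NeuN+mGFAP channel.

    The hand-drawn neuron outlines are subtracted first (outline
    transfer), then the remaining signal is blurred and IsoData-binarized.
    The subtracted outlines are padded by ``outline_pad_px`` so the blur
    skirt of bright NeuN somata is not misread as astroglial signal.
    """
    from scipy.ndimage import binary_dilation

    plane = np.asarray(shared_channel, dtype=float)
    neuron_mask = np.zeros(plane.shape, dtype=bool)
    for roi in neuron_outlines:
        neuron_mask |= rasterize_roi(roi, plane.shape)
    if outline_pad_px > 0:
        neuron_mask = binary_dilation(neuron_mask, iterations=outline_pad_px)
    blurred = gaussian_filter(plane, blur_sigma_px)
    _, mask = threshold_isodata(blurred, marker="mGFAP")
    return mask.values & ~neuron_mask
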