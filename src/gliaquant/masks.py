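"""Marker masks, autofluorescence exclusion, and voxel-surface thresholds.

Marker-positive regions are produced by automatic intensity thresholds
(IsoData / iterative intermeans by default), autofluorescent perinuclear
granules are flagged on the DAPI channel and excluded from ROIs before
density measurement, and voxel surfaces for 3-D rendering-style analyses
use an "upper third of the intensity distribution" percentile rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "BinaryMask",
    "threshold_isodata",
    "threshold_upper_third",
    "autofluorescence_mask",
    "marker_partition",
]

# Partition priority when marker masks overlap (highest first).
PARTITION_PRIORITY = ("CD68", "GFAP", "NeuN")


@dataclass
class BinaryMask:
    """A boolean region with provenance.

    ``values`` matches the z-y-x (or y-x) shape of the channel it was
    derived from; provenance records which marker and threshold produced it.
    """

    values: np.ndarray
    marker: str
    method: str
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)

    @property
    def area_px(self) -> int:
        return int(self.values.sum())

    def __and__(self, other):
        return self.values & np.asarray(other, dtype=bool)

    def __array__(self, dtype=None, copy=None):
        return self.values.astype(dtype) if dtype is not None else self.values


def isodata_threshold_value(values: np.ndarray, nbins: int = 256) -> float:
    """Iterative-intermeans (IsoData) threshold of an intensity sample.

    Iterates t <- (mean below t + mean above t) / 2 from the global mean on
    an ``nbins``-bin histogram until the fixed point is reached.  The fixed
    point satisfies t = (mu_low + mu_high)/2 to within one bin width.
    """
    flat = np.asarray(values, dtype=float).ravel()
    lo, hi = float(flat.min()), float(flat.max())
    if not hi > lo:
        raise ValueError("IsoData threshold undefined on a constant input")
    counts, edges = np.histogram(flat, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    csum = np.cumsum(counts)
    cmass = np.cumsum(counts * centers)
    total_n, total_m = csum[-1], cmass[-1]

    def intermeans(t: float) -> float:
        # means of the two classes split at t (bin-center resolution)
        k = int(np.searchsorted(centers, t, side="right"))
        n_lo = csum[k - 1] if k > 0 else 0
        if n_lo == 0 or n_lo == total_n:
            # one class empty: nudge toward the middle
            return 0.5 * (lo + hi)
        m_lo = cmass[k - 1] if k > 0 else 0.0
        mu_lo = m_lo / n_lo
        mu_hi = (total_m - m_lo) / (total_n - n_lo)
        return 0.5 * (mu_lo + mu_hi)

    bin_width = edges[1] - edges[0]
    t = float(flat.mean())
    for _ in range(500):
        t_new = intermeans(t)
        if abs(t_new - t) < 0.5 * bin_width:
            t = t_new
            break
        t = t_new
    return float(t)


def threshold_isodata(plane: np.ndarray, nbins: int = 256,
                      marker: str = "") -> tuple[float, BinaryMask]:
    """IsoData threshold of a plane; mask = strictly-above pixels."""
    t = isodata_threshold_value(plane, nbins=nbins)
    mask = np.asarray(plane, dtype=float) > t
    return t, BinaryMask(mask, marker=marker, method="isodata", threshold=t)


def threshold_upper_third(stack_values: np.ndarray, candidate_mask=None,
                          marker: str = "") -> BinaryMask:
    """Voxels in the upper third of the intensity distribution.

    The threshold is the 66.67th percentile of the candidate voxels (the
    whole array, or ``candidate_mask`` if given); the mask keeps voxels
    strictly above it, i.e. ~1/3 of candidates on continuous data.
    """
    arr = np.asarray(stack_values, dtype=float)
    sample = arr[np.asarray(candidate_mask, dtype=bool)] if candidate_mask is not None else arr
    if sample.size == 0 or np.ptp(sample) == 0:
        raise ValueError("upper-third threshold undefined on constant input")
    t = float(np.percentile(sample, 100 * 2 / 3))
    mask = arr > t
    if candidate_mask is not None:
        mask &= np.asarray(candidate_mask, dtype=bool)
    return BinaryMask(mask, marker=marker, method="upper_third", threshold=t)


def autofluorescence_mask(
    dapi: np.ndarray,
    nuclei_mask: np.ndarray,
    pixels_per_um: float,
    min_area_um2: float = 0.2,
    max_area_um2: float = 8.0,
    threshold: float | None = None,
) -> BinaryMask:
    """Flag autofluorescent cytoplasmic granules on the DAPI channel.

    Granules (lipofuscin-like aggregates that bleed across channels) are
    DAPI-bright connected components *outside* nuclei / plaque cores, with
    per-slice area inside [min_area_um2, max_area_um2].  The returned mask
    is meant to be subtracted from ROIs before density measurement.

    Operates per z-slice on 2-D or 3-D input; an empty mask is a valid
    result.
    """
    dapi = np.asarray(dapi, dtype=float)
    nuclei = np.asarray(nuclei_mask, dtype=bool)
    if dapi.shape != nuclei.shape:
        raise ValueError("DAPI and nuclei mask shapes differ")
    squeeze = dapi.ndim == 2
    if squeeze:
        dapi, nuclei = dapi[None], nuclei[None]

    lo_px = min_area_um2 * pixels_per_um**2
    hi_px = max_area_um2 * pixels_per_um**2
    out = np.zeros(dapi.shape, dtype=bool)
    for z in range(dapi.shape[0]):
        plane = dapi[z]
        t = isodata_threshold_value(plane) if threshold is None else threshold
        bright = plane > t
        labels, n = ndimage.label(bright)
        if n == 0:
            continue
        idx = np.arange(1, n + 1)
        areas = ndimage.sum_labels(np.ones_like(plane), labels, idx)
        touches_nucleus = ndimage.sum_labels(nuclei[z].astype(float), labels, idx) > 0
        keep = (areas >= lo_px) & (areas <= hi_px) & ~touches_nucleus
        out[z] = np.isin(labels, idx[keep])
    if squeeze:
        out = out[0]
    return BinaryMask(out, marker="granule", method="isodata+area",
                      threshold=threshold)


def marker_partition(marker_masks: dict[str, np.ndarray]) -> np.ndarray:
    """Partition every voxel into one marker class or background.

    Returns an integer label array of the shared mask shape: 0 background,
    then one label per marker.  Voxels claimed by several markers go to the
    highest-priority one (CD68 > GFAP > NeuN; unknown markers follow, in
    dict order).  The classes always cover each voxel exactly once.
    """
    if not marker_masks:
        raise ValueError("need at least one marker mask")
    masks = {k: np.asarray(v, dtype=bool) for k, v in marker_masks.items()}
    shapes = {m.shape for m in masks.values()}
    if len(shapes) != 1:
        raise ValueError(f"marker masks have differing shapes: {shapes}")
    ordered = [m for m in PARTITION_PRIORITY if m in masks]
    ordered += [m for m in masks if m not in ordered]
    labels = np.zeros(next(iter(shapes)), dtype=np.int32)
    # paint lowest priority first so higher priority overwrites
    for i, name in reversed(list(enumerate(ordered, start=1))):
        labels[masks[name]] = i
    return labels


def partition_class_names(marker_masks: dict[str, np.ndarray]) -> list[str]:
    """Label meanings for :func:`marker_partition`: index 0 is background."""
    ordered = [m for m in PARTITION_PRIORITY if m in marker_masks]
    ordered += [m for m in marker_masks if m not in ordered]
    return ["background"] + ordered
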