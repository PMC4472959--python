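"""Integrated-intensity densities in marker-defined regions.

"Density" is integrated intensity per unit area: the sum of pixel values of
a measured channel (typically CB2) over a region, divided by the region's
area, after removing autofluorescence-excluded pixels.  Densities are
computed per z-slice and averaged across the slices of a stack; batch
tables aggregate image-level records into genotype x marker summaries with
SEM over images (fields), mirroring how replicate fields rather than
animals are the unit of sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["DensityRecord", "roi_density", "marker_density_table"]


@dataclass
class DensityRecord:
    image_id: str
    genotype: str          # "NTG" | "AD"
    marker: str            # "NeuN" | "CD68" | "GFAP" | "background" | ...
    region_class: str      # "positive" | "negative" | "background"
    density: float         # intensity a.u. per px^2
    area_px2: float
    excluded_area_px2: float = 0.0
    pixels_per_um: float | None = None

    @property
    def density_per_um2(self) -> float | None:
        if self.pixels_per_um is None:
            return None
        return self.density * self.pixels_per_um**2


def roi_density(
    channel: np.ndarray,
    region_mask: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
    *,
    image_id: str = "",
    genotype: str = "",
    marker: str = "",
    region_class: str = "positive",
    pixels_per_um: float | None = None,
) -> DensityRecord:
    """Density of one channel over (region minus exclusions).

    For a z-stack the per-slice densities are averaged (slices with empty
    effective region are skipped); for a 2-D plane the density is computed
    directly.  Raises if the effective region is empty everywhere.
    """
    chan = np.asarray(channel, dtype=float)
    region = np.asarray(region_mask, dtype=bool)
    if chan.shape != region.shape:
        raise ValueError("channel and region mask shapes differ")
    effective = region if exclusion_mask is None else region & ~np.asarray(
        exclusion_mask, dtype=bool)
    excluded = int(region.sum() - effective.sum())

    planes = [(chan, effective)] if chan.ndim == 2 else [
        (chan[z], effective[z]) for z in range(chan.shape[0])
    ]
    per_slice = [p[m].sum() / m.sum() for p, m in planes if m.any()]
    if not per_slice:
        raise ValueError("effective region is empty")
    return DensityRecord(
        image_id=image_id, genotype=genotype, marker=marker,
        region_class=region_class, density=float(np.mean(per_slice)),
        area_px2=float(region.sum()), excluded_area_px2=float(excluded),
        pixels_per_um=pixels_per_um,
    )


def marker_density_table(records: list[DensityRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble per-image density records into a table plus group summaries.

    Returns ``(table, summary)`` where ``table`` has one row per record and
    ``summary`` holds mean +/- SEM per (genotype, marker, region_class),
    with n = number of contributing images.
    """
    if not records:
        raise ValueError("no density records")
    table = pd.DataFrame([asdict(r) for r in records])
    grouped = table.groupby(["genotype", "marker", "region_class"])["density"]
    summary = grouped.agg(
        mean="mean",
        sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
        n="count",
    ).reset_index()
    return table, summary


def density_records_from_partition(
    measure_channel: np.ndarray,
    partition_labels: np.ndarray,
    class_names: list[str],
    exclusion_mask: np.ndarray | None = None,
    *,
    image_id: str = "",
    genotype: str = "",
    pixels_per_um: float | None = None,
) -> list[DensityRecord]:
    """One DensityRecord per partition class (background included).

    Classes absent from the image are skipped.
    """
    out = []
    for i, name in enumerate(class_names):
        region = partition_labels == i
        if not region.any():
            continue
        out.append(roi_density(
            measure_channel, region, exclusion_mask,
            image_id=image_id, genotype=genotype, marker=name,
            region_class="background" if name == "background" else "positive",
            pixels_per_um=pixels_per_um,
        ))
    return out
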