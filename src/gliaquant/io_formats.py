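"""Reading and writing the formats the pipeline touches.

Image stacks are multi-page TIFF with channel-z-y-x axes and physical pixel
scale carried in the TIFF metadata.  Regions of interest are polygons stored
as JSON sidecars; time-activity curves and density tables are plain CSV.

Coordinate convention: polygon vertices are expressed in pixel units where
integer coordinates lie on pixel corners, i.e. the pixel at array index
(row r, column c) occupies the square [c, c+1) x [r, r+1) and has its
center at (c + 0.5, r + 0.5).  Rasterization tests pixel centers for
containment.  Physical distances are always reported in micrometers via
``pixels_per_um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile
from shapely.geometry import Point, Polygon

__all__ = [
    "ChannelStack",
    "RoiPolygon",
    "read_stack",
    "write_stack",
    "read_rois",
    "write_rois",
    "rasterize_roi",
    "read_tac_table",
    "write_tac_table",
]

DEFAULT_PIXELS_PER_UM = 11.1


@dataclass
class ChannelStack:
    """A multi-channel z-stack with physical scale.

    Parameters
    ----------
    intensities : ndarray, shape (channel, z, y, x)
        Non-negative fluorescence intensities (arbitrary units).
    channel_names : list of str
        One name per channel (e.g. ``["DAPI", "CB2", "CD68", "NeuN"]``).
    pixels_per_um : float
        Lateral sampling; 11.1 px/um matches the confocal fields the
        pipeline was designed around.
    z_step_um : float
        Axial slice spacing.
    """

    intensities: np.ndarray
    channel_names: list[str]
    pixels_per_um: float = DEFAULT_PIXELS_PER_UM
    z_step_um: float = 0.31

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim == 2:  # single plane -> 1 channel, 1 slice
            arr = arr[None, None]
        elif arr.ndim == 3:  # interpret as (z, y, x), single channel
            arr = arr[None]
        if arr.ndim != 4:
            raise ValueError(f"expected 2-4 dims (channel-z-y-x), got {arr.ndim}")
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")
        if len(self.channel_names) != arr.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {arr.shape[0]} channels"
            )
        if not self.pixels_per_um > 0:
            raise ValueError("pixels_per_um must be positive")
        self.intensities = arr

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_z(self) -> int:
        return self.intensities.shape[1]

    @property
    def plane_shape(self) -> tuple[int, int]:
        return self.intensities.shape[2:]

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) array for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}")
        return self.intensities[idx]

    def um_to_px(self, um: float) -> float:
        return um * self.pixels_per_um

    def px_to_um(self, px: float) -> float:
        return px / self.pixels_per_um


def write_stack(stack: ChannelStack, path) -> None:
    meta = {
        "axes": "CZYX",
        "channel_names": list(stack.channel_names),
        "pixels_per_um": float(stack.pixels_per_um),
        "z_step_um": float(stack.z_step_um),
    }
    tifffile.imwrite(path, stack.intensities.astype(np.float32),
                     photometric="minisblack", metadata=meta)


def read_stack(path, pixels_per_um: float | None = None,
               z_step_um: float | None = None) -> ChannelStack:
    """Read a tagged-image stack written by :func:`write_stack`.

    Plain TIFFs without scale metadata are accepted only when
    ``pixels_per_um`` is supplied explicitly; y-x or z-y-x files are
    promoted to 4-D.
    """
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[None]
    names = meta.get("channel_names")
    if names is None:
        names = [f"ch{i}" for i in range(arr.shape[0])]
    scale = pixels_per_um if pixels_per_um is not None else meta.get("pixels_per_um")
    if scale is None:
        raise ValueError(
            f"{path}: no pixel-scale metadata; pass pixels_per_um explicitly"
        )
    zstep = z_step_um if z_step_um is not None else meta.get("z_step_um", 0.31)
    return ChannelStack(arr, list(names), float(scale), float(zstep))


@dataclass
class RoiPolygon:
    """A hand-drawn polygonal region on one z-slice.

    Vertices are (x, y) pairs in the corner-based pixel coordinate system
    described in the module docstring.
    """

    vertices: list[tuple[float, float]]
    label: str = "roi"
    z: int = 0
    _poly: Polygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError(f"invalid (self-intersecting?) polygon: {self.label}")
        if poly.area <= 0:
            raise ValueError("polygon has zero area")
        self._poly = poly

    @property
    def area(self) -> float:
        """Analytic area in px^2."""
        return self._poly.area

    def contains_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        from shapely import contains_xy

        return contains_xy(self._poly, x, y)


def write_rois(rois: list[RoiPolygon], path) -> None:
    payload = [
        {"label": r.label, "z": r.z, "vertices": [list(map(float, v)) for v in r.vertices]}
        for r in rois
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_rois(path) -> list[RoiPolygon]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        RoiPolygon([tuple(v) for v in item["vertices"]],
                   label=item.get("label", "roi"), z=int(item.get("z", 0)))
        for item in payload
    ]


def rasterize_roi(roi: RoiPolygon, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon to a boolean mask by pixel-center containment.

    A pixel (r, c) is set when its center (c + 0.5, r + 0.5) lies strictly
    inside the polygon.  For convex polygons of area >= 25 px^2 the mask
    area tracks the analytic area to within ~2 px^2.
    """
    ny, nx = shape
    minx, miny, maxx, maxy = roi._poly.bounds
    c0, c1 = max(int(np.floor(minx)) - 1, 0), min(int(np.ceil(maxx)) + 1, nx)
    r0, r1 = max(int(np.floor(miny)) - 1, 0), min(int(np.ceil(maxy)) + 1, ny)
    mask = np.zeros(shape, dtype=bool)
    if c1 <= c0 or r1 <= r0:
        return mask
    cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    inside = roi.contains_points(cc + 0.5, rr + 0.5)
    mask[r0:r1, c0:c1] = inside
    return mask


# ---------------------------------------------------------------------------
# TAC tables: CSV with '#'-prefixed header metadata then frame rows.

def write_tac_table(tac, path) -> None:
    """Write a TimeActivityCurve (see :mod:`gliaquant.pet`) as CSV."""
    with open(path, "w") as fh:
        fh.write(f"# injected_dose={tac.injected_dose}\n")
        fh.write(f"# body_weight_g={tac.body_weight_g}\n")
        fh.write(f"# region={tac.region}\n")
        fh.write(f"# condition={tac.condition}\n")
        fh.write("frame_start_s,frame_duration_s,value\n")
        for (start, dur), v in zip(tac.schedule.frames, tac.frame_values):
            fh.write(f"{start:g},{dur:g},{v:.6g}\n")


def read_tac_table(path):
    from .pet import FrameSchedule, TimeActivityCurve

    meta: dict[str, str] = {}
    rows: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            elif line[0].isdigit():
                start, dur, val = (float(x) for x in line.split(","))
                rows.append((start, dur, val))
    schedule = FrameSchedule([(s, d) for s, d, _ in rows])
    return TimeActivityCurve(
        schedule=schedule,
        frame_values=np.array([v for _, _, v in rows]),
        injected_dose=float(meta.get("injected_dose", "nan")),
        body_weight_g=float(meta.get("body_weight_g", "nan")),
        region=meta.get("region", "whole brain"),
        condition=meta.get("condition", "baseline"),
    )
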