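"""Immunofluorescence image phantoms with planted ground truth.

Geometry is specified in micrometers and converted to pixels only at
rasterization (pixel centers at half-integer pixel coordinates).  Each
object class is rendered into its own per-channel component image; the
components are individually Gaussian-smoothed (sigma = ``blur_sigma_px``,
emulating optical blur and giving sub-pixel peak localization something to
estimate) and summed into the noiseless stack, so the noiseless phantom is
exactly the sum of its per-class components.  Noise is Poisson on the
signal plus additive Gaussian read noise, drawn from a seeded generator;
object geometry never depends on the seed, so two seeds differ only in
their noise realization.

Radial structure of the engulfment synapse (per microglia targeting a
plaque of core radius R): the DAPI-dense core ends at R; the CB2 halo
band sits just outside it; the CD68 plate (the plate-like process ending
hugging the core) is centered ``cb2_offset_um`` farther out, so the
planted CB2-to-CD68 peak separation equals the membrane offset delta.  At
the cell body the CB2 membrane ring lies delta outward of the CD68
cytoplasm edge.  Endings carry brighter signal than the cytoplasm
(``plate_boost``/``halo_boost``), matching the robust staining of process
endings this geometry emulates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from ..io_formats import ChannelStack, RoiPolygon

__all__ = [
    "PlaqueSpec", "MicrogliaSpec", "NeuronSpec", "AstrocyteSpec",
    "PhantomSpec", "S3PhantomSpec", "GroundTruth",
    "generate_if_phantom", "generate_s3_phantom", "write_ground_truth",
]

GOLDEN_ANGLE = np.pi * (3 - np.sqrt(5))


# ---------------------------------------------------------------------------
# Object specs (all geometry in um)

@dataclass
class PlaqueSpec:
    center_um: tuple[float, float]          # (x, y)
    core_radius_um: float                   # dense-core radius
    dapi_amplitude: float = 150.0           # DAPI-positive core


@dataclass
class MicrogliaSpec:
    body_center_um: tuple[float, float]
    body_radius_um: float = 5.0
    nucleus_radius_um: float = 2.0
    target_plaque: int | None = None        # index into PhantomSpec.plaques
    cd68_amplitude: float = 150.0           # lysosomal cytoplasm + process
    cb2_cyto_amplitude: float = 60.0        # diffuse cytoplasmic CB2
    cb2_ring_amplitude: float = 110.0       # membrane ring at body
    cb2_offset_um: float = 1.5              # delta: ring offset outward of
                                            # CD68 edge; also halo-to-plate
                                            # separation at the synapse
    cb2_ring_width_um: float = 0.6
    halo_boost: float = 1.5                 # ending CB2 vs ring amplitude
    plate_boost: float = 1.4                # plate CD68 vs cytoplasm
    process_width_um: float = 1.0
    plate_thickness_um: float = 0.7
    plate_halfangle_deg: float = 30.0
    cb2_gap_um: float = 0.4                 # core edge to halo band
    cb2_halo_width_um: float = 0.7


@dataclass
class NeuronSpec:
    center_um: tuple[float, float]
    radius_um: float = 5.0
    nucleus_radius_um: float = 2.5
    neun_amplitude: float = 150.0
    cb2_amplitude: float = 70.0             # cytoplasmic CB2
    dapi_amplitude: float = 120.0
    granule_count: int = 0
    granule_radius_um: float = 0.6
    granule_amplitude: float = 200.0        # added to ALL channels


@dataclass
class AstrocyteSpec:
    center_um: tuple[float, float]
    n_branches: int = 5
    branch_length_um: float = 9.0
    branch_width_um: float = 0.55
    gfap_amplitude: float = 150.0
    cb2_amplitude: float = 25.0
    phase_deg: float = 0.0                  # rotates the branch fan


@dataclass
class PhantomSpec:
    """A confocal field: objects, optics, noise, genotype."""

    field_size_px: tuple[int, int]          # (ny, nx)
    n_z: int = 1
    z_step_um: float = 0.31
    pixels_per_um: float = 11.1
    channel_plan: tuple[str, ...] = ("DAPI", "CB2", "CD68", "NeuN")
    plaques: list[PlaqueSpec] = dc_field(default_factory=list)
    microglia: list[MicrogliaSpec] = dc_field(default_factory=list)
    neurons: list[NeuronSpec] = dc_field(default_factory=list)
    astrocytes: list[AstrocyteSpec] = dc_field(default_factory=list)
    background: dict[str, float] = dc_field(default_factory=dict)
    core_suppression: float = 0.9           # non-DAPI background removed in core
    poisson_scale: float = 1.0              # 0 disables shot noise
    gaussian_sd: float = 2.0                # read noise, intensity units
    blur_sigma_px: float = 1.0              # 0 disables optical blur
    genotype: str = "AD"
    core_radius_bounds: tuple[float, float] = (7.0, 15.0)

    def validate(self) -> None:
        if self.pixels_per_um <= 0:
            raise ValueError("pixels_per_um must be positive")
        if self.genotype == "AD" and not self.plaques:
            raise ValueError("AD phantom must contain at least one plaque")
        if self.genotype == "NTG" and self.plaques:
            raise ValueError("NTG phantom must contain no plaques")
        lo, hi = self.core_radius_bounds
        for p in self.plaques:
            if not lo <= p.core_radius_um <= hi:
                raise ValueError(
                    f"core radius {p.core_radius_um} um outside [{lo}, {hi}]")
            if p.dapi_amplitude < 0:
                raise ValueError("amplitudes must be non-negative")
        for i, p in enumerate(self.plaques):
            for q in self.plaques[i + 1:]:
                d = np.hypot(p.center_um[0] - q.center_um[0],
                             p.center_um[1] - q.center_um[1])
                if d < p.core_radius_um + q.core_radius_um + 1.0:
                    raise ValueError("plaque cores overlap/merge: invalid geometry")
        if any(v < 0 for v in self.background.values()):
            raise ValueError("background levels must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    label_masks: dict[str, np.ndarray]          # (z, y, x) bool, exclusive
    noiseless: np.ndarray                       # (c, z, y, x)
    components: dict[str, np.ndarray]           # class -> (c, z, y, x)
    plaque_centers_px: list[tuple[float, float]] = dc_field(default_factory=list)
    plaque_core_radii_um: list[float] = dc_field(default_factory=list)
    microglia_body_centers_px: list[tuple[float, float]] = dc_field(default_factory=list)
    cb2_offset_um: float | None = None
    overlap_fractions: dict[str, float] | None = None
    neuron_outlines: list[RoiPolygon] = dc_field(default_factory=list)


# ---------------------------------------------------------------------------
# Rasterization primitives (um geometry -> boolean pixel masks)

class _Raster:
    def __init__(self, shape_px: tuple[int, int], pixels_per_um: float):
        ny, nx = shape_px
        yy, xx = np.mgrid[0:ny, 0:nx]
        self.x_um = (xx + 0.5) / pixels_per_um
        self.y_um = (yy + 0.5) / pixels_per_um
        self.shape = (ny, nx)
        self.ppum = pixels_per_um

    def disk(self, cx, cy, r):
        return (self.x_um - cx) ** 2 + (self.y_um - cy) ** 2 <= r ** 2

    def annulus(self, cx, cy, r0, r1):
        d2 = (self.x_um - cx) ** 2 + (self.y_um - cy) ** 2
        return (d2 > r0 ** 2) & (d2 <= r1 ** 2)

    def arc_band(self, cx, cy, r0, r1, phi, halfangle):
        band = self.annulus(cx, cy, r0, r1)
        ang = np.arctan2(self.y_um - cy, self.x_um - cx)
        dphi = np.angle(np.exp(1j * (ang - phi)))
        return band & (np.abs(dphi) <= halfangle)

    def segment(self, p0, p1, width):
        """Band of half-width width/2 around the segment p0-p1 (um)."""
        x0, y0 = p0
        x1, y1 = p1
        dx, dy = x1 - x0, y1 - y0
        L2 = dx * dx + dy * dy
        if L2 == 0:
            return self.disk(x0, y0, width / 2)
        t = ((self.x_um - x0) * dx + (self.y_um - y0) * dy) / L2
        t = np.clip(t, 0.0, 1.0)
        px, py = x0 + t * dx, y0 + t * dy
        return (self.x_um - px) ** 2 + (self.y_um - py) ** 2 <= (width / 2) ** 2


def _granule_positions(neuron: NeuronSpec) -> list[tuple[float, float]]:
    """Deterministic perinuclear granule placement (golden-angle fan)."""
    cx, cy = neuron.center_um
    r_mid = 0.5 * (neuron.nucleus_radius_um + neuron.radius_um)
    out = []
    for i in range(neuron.granule_count):
        ang = 0.7 + i * GOLDEN_ANGLE
        rad = r_mid + 0.25 * neuron.granule_radius_um * ((i % 3) - 1)
        out.append((cx + rad * np.cos(ang), cy + rad * np.sin(ang)))
    return out


# ---------------------------------------------------------------------------

def generate_if_phantom(spec: PhantomSpec, seed: int) -> tuple[ChannelStack, GroundTruth]:
    """Render a multi-channel confocal field phantom.

    Returns the noisy stack and the planted ground truth.  Identical
    (spec, seed) pairs reproduce bit-identical output; changing only the
    seed changes only the noise realization.
    """
    spec.validate()
    ny, nx = spec.field_size_px
    chans = list(spec.channel_plan)
    nc, nz = len(chans), spec.n_z
    ras = _Raster((ny, nx), spec.pixels_per_um)
    z_rel = (np.arange(nz) - (nz - 1) / 2) * spec.z_step_um  # um from stack center

    def blank():
        return np.zeros((nc, nz, ny, nx))

    comps: dict[str, np.ndarray] = {}

    def add(comp: str, channel: str, z: int, img: np.ndarray, amplitude: float):
        if channel not in chans or amplitude == 0:
            return
        comps.setdefault(comp, blank())[chans.index(channel), z] += amplitude * img

    # label masks (2-D per slice, stacked later); painted with priority
    label_stacks: dict[str, list[np.ndarray]] = {
        k: [] for k in ("plaque_core", "microglia_cytoplasm", "cb2_ring",
                        "neuron", "granule", "astrocyte")
    }

    core_masks_by_z: list[np.ndarray] = []
    for zi, z in enumerate(z_rel):
        core_mask = np.zeros((ny, nx), dtype=bool)
        mg_mask = np.zeros((ny, nx), dtype=bool)
        ring_mask = np.zeros((ny, nx), dtype=bool)
        neuron_mask = np.zeros((ny, nx), dtype=bool)
        granule_mask = np.zeros((ny, nx), dtype=bool)
        astro_mask = np.zeros((ny, nx), dtype=bool)

        # plaques: dense cores are spheres -> slice disks
        for p in spec.plaques:
            if abs(z) >= p.core_radius_um:
                continue
            r_slice = np.sqrt(p.core_radius_um ** 2 - z ** 2)
            disk = ras.disk(*p.center_um, r_slice)
            add("plaque_core", "DAPI", zi, disk.astype(float), p.dapi_amplitude)
            core_mask |= disk

        # microglia: body + process + engulfment ending (extruded in z)
        for m in spec.microglia:
            bx, by = m.body_center_um
            body = ras.annulus(bx, by, m.nucleus_radius_um, m.body_radius_um)
            add("microglia_cytoplasm", "CD68", zi, body.astype(float),
                m.cd68_amplitude)
            add("microglia_cytoplasm", "CB2", zi, body.astype(float),
                m.cb2_cyto_amplitude)
            nucleus = ras.disk(bx, by, m.nucleus_radius_um)
            add("microglia_cytoplasm", "DAPI", zi, nucleus.astype(float), 100.0)
            ring = ras.annulus(
                bx, by,
                m.body_radius_um + m.cb2_offset_um - m.cb2_ring_width_um / 2,
                m.body_radius_um + m.cb2_offset_um + m.cb2_ring_width_um / 2)
            add("cb2_ring", "CB2", zi, ring.astype(float), m.cb2_ring_amplitude)
            mg_mask |= body | nucleus
            ring_mask |= ring

            if m.target_plaque is not None:
                plq = spec.plaques[m.target_plaque]
                px_, py_ = plq.center_um
                R = plq.core_radius_um
                phi = np.arctan2(by - py_, bx - px_)
                half = np.deg2rad(m.plate_halfangle_deg)
                r_halo0 = R + m.cb2_gap_um
                r_halo1 = r_halo0 + m.cb2_halo_width_um
                r_halo_c = 0.5 * (r_halo0 + r_halo1)
                r_plate_c = r_halo_c + m.cb2_offset_um
                halo = ras.arc_band(px_, py_, r_halo0, r_halo1, phi, half)
                plate = ras.arc_band(px_, py_, r_plate_c - m.plate_thickness_um / 2,
                                     r_plate_c + m.plate_thickness_um / 2, phi, half)
                add("microglia_cytoplasm", "CB2", zi, halo.astype(float),
                    m.cb2_ring_amplitude * m.halo_boost)
                add("microglia_cytoplasm", "CD68", zi, plate.astype(float),
                    m.cd68_amplitude * m.plate_boost)
                u = np.array([np.cos(phi), np.sin(phi)])
                # start beyond the plate so the stroke's rounded end cap
                # only touches it (keeps the plate profile a clean bump)
                start = np.array([px_, py_]) + u * (
                    r_plate_c + m.plate_thickness_um / 2 + m.process_width_um / 2)
                stop = np.array([bx, by]) - u * (
                    m.body_radius_um + m.process_width_um / 2)
                proc = ras.segment(start, stop, m.process_width_um)
                add("microglia_cytoplasm", "CD68", zi, proc.astype(float),
                    m.cd68_amplitude)
                mg_mask |= halo | plate | proc
                ring_mask |= halo

        # neurons: NeuN soma, DAPI nucleus, cytoplasmic CB2, granules
        for n in spec.neurons:
            cx, cy = n.center_um
            soma = ras.disk(cx, cy, n.radius_um)
            cyto = ras.annulus(cx, cy, n.nucleus_radius_um, n.radius_um)
            nucleus = ras.disk(cx, cy, n.nucleus_radius_um)
            add("neuron", "NeuN", zi, soma.astype(float), n.neun_amplitude)
            add("neuron", "CB2", zi, cyto.astype(float), n.cb2_amplitude)
            add("neuron", "DAPI", zi, nucleus.astype(float), n.dapi_amplitude)
            neuron_mask |= soma
            for gx, gy in _granule_positions(n):
                g = ras.disk(gx, gy, n.granule_radius_um)
                for ch in chans:       # autofluorescence bleeds everywhere
                    add("granule", ch, zi, g.astype(float), n.granule_amplitude)
                granule_mask |= g

        # astrocytes: star-like GFAP skeleton with faint CB2
        for a in spec.astrocytes:
            cx, cy = a.center_um
            for b in range(a.n_branches):
                ang = np.deg2rad(a.phase_deg) + 2 * np.pi * b / a.n_branches
                tip = (cx + a.branch_length_um * np.cos(ang),
                       cy + a.branch_length_um * np.sin(ang))
                stroke = ras.segment((cx, cy), tip, a.branch_width_um)
                add("astrocyte", "GFAP", zi, stroke.astype(float), a.gfap_amplitude)
                add("astrocyte", "CB2", zi, stroke.astype(float), a.cb2_amplitude)
                astro_mask |= stroke

        # background neuropil, displaced inside dense cores (non-DAPI)
        for ch, level in spec.background.items():
            if ch not in chans or level == 0:
                continue
            img = np.full((ny, nx), float(level))
            if ch != "DAPI":
                img[core_mask] *= (1.0 - spec.core_suppression)
            comps.setdefault("background", blank())[chans.index(ch), zi] += img

        core_masks_by_z.append(core_mask)
        label_stacks["plaque_core"].append(core_mask)
        label_stacks["microglia_cytoplasm"].append(mg_mask)
        label_stacks["cb2_ring"].append(ring_mask)
        label_stacks["neuron"].append(neuron_mask)
        label_stacks["granule"].append(granule_mask)
        label_stacks["astrocyte"].append(astro_mask)

    # optical blur per component (background kept sharp only if blur off)
    if spec.blur_sigma_px > 0:
        for name, arr in comps.items():
            comps[name] = gaussian_filter(
                arr, sigma=(0, 0, spec.blur_sigma_px, spec.blur_sigma_px))

    noiseless = np.zeros((nc, nz, ny, nx))
    for arr in comps.values():
        noiseless += arr

    # exclusive label masks, highest priority first
    priority = ["granule", "plaque_core", "cb2_ring", "microglia_cytoplasm",
                "neuron", "astrocyte"]
    taken = np.zeros((nz, ny, nx), dtype=bool)
    label_masks: dict[str, np.ndarray] = {}
    for name in priority:
        m = np.stack(label_stacks[name]) & ~taken
        label_masks[name] = m
        taken |= m
    label_masks["background"] = ~taken

    rng = np.random.default_rng(seed)
    noisy = noiseless.copy()
    if spec.poisson_scale > 0:
        noisy = rng.poisson(noiseless * spec.poisson_scale) / spec.poisson_scale
    if spec.gaussian_sd > 0:
        noisy = noisy + rng.normal(0.0, spec.gaussian_sd, size=noisy.shape)
    noisy = np.clip(noisy, 0.0, None)

    stack = ChannelStack(noisy, chans, spec.pixels_per_um, spec.z_step_um)
    ppum = spec.pixels_per_um
    gt = GroundTruth(
        label_masks=label_masks,
        noiseless=noiseless,
        components=comps,
        plaque_centers_px=[(p.center_um[0] * ppum, p.center_um[1] * ppum)
                           for p in spec.plaques],
        plaque_core_radii_um=[p.core_radius_um for p in spec.plaques],
        microglia_body_centers_px=[(m.body_center_um[0] * ppum,
                                    m.body_center_um[1] * ppum)
                                   for m in spec.microglia],
        cb2_offset_um=(spec.microglia[0].cb2_offset_um if spec.microglia else None),
        neuron_outlines=[_circle_roi(n, ppum) for n in spec.neurons],
    )
    return stack, gt


def _circle_roi(neuron, ppum: float, n_vertices: int = 24,
                label: str = "neuron") -> RoiPolygon:
    cx, cy = neuron.center_um
    r = neuron.radius_um
    ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    verts = [((cx + r * np.cos(a)) * ppum, (cy + r * np.sin(a)) * ppum)
             for a in ang]
    return RoiPolygon(verts, label=label)


# ---------------------------------------------------------------------------
# Shared-fluorochrome (NeuN + mGFAP) discrimination phantoms

@dataclass
class S3PhantomSpec:
    """Phantom for the neuron/astroglia shared-fluorochrome error analysis.

    The red channel carries NeuN somata and mouse-GFAP skeletons through a
    single fluorochrome; the green channel carries rabbit-GFAP, which
    confirms the astroglial skeletons except for a planted fraction
    ``p_gfap`` of the mGFAP area, and additionally covers a planted
    fraction ``p_neuron`` of the total neuronal area (astroglial signal
    overlapping neurons).  Ground truth records the realized fractions.
    """

    field_size_px: tuple[int, int] = (512, 512)
    pixels_per_um: float = 11.1
    n_neurons: int = 5
    neuron_radius_um: float = 4.0
    n_astrocytes: int = 8
    n_branches: int = 5
    branch_length_um: float = 8.0
    branch_width_um: float = 0.55
    p_neuron: float = 0.009
    p_gfap: float = 0.049
    neun_amplitude: float = 150.0
    mgfap_amplitude: float = 150.0
    rbgfap_amplitude: float = 150.0
    dapi_amplitude: float = 120.0
    background: float = 5.0
    poisson_scale: float = 1.0
    gaussian_sd: float = 2.0
    blur_sigma_px: float = 1.0
    layout_seed: int = 202                  # geometry; independent of noise seed

    def validate(self) -> None:
        for name in ("p_neuron", "p_gfap"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.pixels_per_um <= 0:
            raise ValueError("pixels_per_um must be positive")


def _ordered_segment_pixels(ras: _Raster, p0, p1, width) -> np.ndarray:
    """Flat indices of a stroke's pixels, ordered along the stroke."""
    band = ras.segment(p0, p1, width)
    idx = np.flatnonzero(band)
    if idx.size == 0:
        return idx
    ys, xs = np.unravel_index(idx, ras.shape)
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    L2 = dx * dx + dy * dy
    t = ((xs + 0.5) / ras.ppum - p0[0]) * dx + ((ys + 0.5) / ras.ppum - p0[1]) * dy
    return idx[np.argsort(t / max(L2, 1e-12), kind="stable")]


def generate_s3_phantom(spec: S3PhantomSpec, seed: int) -> tuple[ChannelStack, GroundTruth]:
    """Render a shared-fluorochrome discrimination phantom.

    Channels: DAPI (nuclei), rbGFAP (green), and the shared NeuN+mGFAP
    red channel.  Identical (spec, seed) pairs are bit-identical; the
    object layout depends only on the spec.
    """
    spec.validate()
    ny, nx = spec.field_size_px
    ppum = spec.pixels_per_um
    ras = _Raster((ny, nx), ppum)
    geo = np.random.default_rng(spec.layout_seed)
    fw, fh = nx / ppum, ny / ppum          # field size in um

    # --- place neurons (non-overlapping) and astrocyte somata
    margin = spec.neuron_radius_um + 1.0
    neuron_centers: list[tuple[float, float]] = []
    while len(neuron_centers) < spec.n_neurons:
        c = (geo.uniform(margin, fw - margin), geo.uniform(margin, fh - margin))
        if all(np.hypot(c[0] - o[0], c[1] - o[1]) > 2.2 * spec.neuron_radius_um
               for o in neuron_centers):
            neuron_centers.append(c)

    neuron_mask = np.zeros((ny, nx), dtype=bool)
    outlines = []
    for cx, cy in neuron_centers:
        n = NeuronSpec((cx, cy), radius_um=spec.neuron_radius_um)
        roi = _circle_roi(n, ppum)
        outlines.append(roi)
        neuron_mask |= ras.disk(cx, cy, spec.neuron_radius_um)

    # keep-out zone around neurons so blur cannot bleed across
    keepout_um = 4.0 / ppum + spec.branch_width_um

    def far_from_neurons(p) -> bool:
        return all(np.hypot(p[0] - c[0], p[1] - c[1])
                   > spec.neuron_radius_um + keepout_um + 0.5
                   for c in neuron_centers)

    # --- astrocyte skeletons: confirmed branches + unconfirmed candidates
    confirmed = np.zeros((ny, nx), dtype=bool)
    candidate_order: list[np.ndarray] = []   # unconfirmed-stroke pixel lists
    somata = []
    attempts = 0
    while len(somata) < spec.n_astrocytes and attempts < 10000:
        attempts += 1
        c = (geo.uniform(2, fw - 2), geo.uniform(2, fh - 2))
        if far_from_neurons(c) and all(
                np.hypot(c[0] - o[0], c[1] - o[1]) > spec.branch_length_um
                for o in somata):
            somata.append(c)
    for cx, cy in somata:
        phase = geo.uniform(0, 2 * np.pi)
        for b in range(spec.n_branches):
            ang = phase + 2 * np.pi * b / spec.n_branches
            tip = (cx + spec.branch_length_um * np.cos(ang),
                   cy + spec.branch_length_um * np.sin(ang))
            if not far_from_neurons(tip):
                continue
            confirmed |= ras.segment((cx, cy), tip, spec.branch_width_um)
        # unconfirmed candidate: a detached distal stub, well clear of the
        # confirmed branches so the dilated rbGFAP support cannot reach it
        stub_ang = phase + np.pi / spec.n_branches
        base = (cx + (spec.branch_length_um + 1.5) * np.cos(stub_ang),
                cy + (spec.branch_length_um + 1.5) * np.sin(stub_ang))
        tip = (base[0] + 7.0 * np.cos(stub_ang), base[1] + 7.0 * np.sin(stub_ang))
        if far_from_neurons(base) and far_from_neurons(tip):
            candidate_order.append(
                _ordered_segment_pixels(ras, base, tip, spec.branch_width_um))

    confirmed &= ~neuron_mask
    # candidates must stay clear of the confirmed skeleton (and neurons):
    # unconfirmed pixels within the dilation reach would erode the rbGFAP
    # coverage of confirmed pixels and inflate the realized fraction
    forbidden = binary_dilation(confirmed, iterations=5) | neuron_mask
    cand_flat: list[int] = []
    seen: set[int] = set(np.flatnonzero(forbidden))
    for arr in candidate_order:
        for i in arr:
            if int(i) not in seen:
                cand_flat.append(int(i))
                seen.add(int(i))

    c_area = int(confirmed.sum())
    k_gfap = int(round(c_area * spec.p_gfap / (1 - spec.p_gfap))) \
        if spec.p_gfap < 1 else len(cand_flat)
    k_gfap = min(k_gfap, len(cand_flat))
    unconfirmed = np.zeros(ny * nx, dtype=bool)
    unconfirmed[cand_flat[:k_gfap]] = True
    unconfirmed = unconfirmed.reshape(ny, nx)
    if spec.p_gfap >= 1:                   # nothing confirmed at all
        unconfirmed |= confirmed
        confirmed = np.zeros_like(confirmed)

    mgfap = confirmed | unconfirmed

    # --- rbGFAP support: confirmed skeleton, slightly dilated, plus the
    #     planted overlap patches inside neurons
    rb_support = binary_dilation(confirmed, iterations=2)
    rb_support &= ~neuron_mask
    rb_support &= ~binary_dilation(unconfirmed, iterations=2)

    n_area = int(neuron_mask.sum())
    k_neuron = int(round(spec.p_neuron * n_area))
    overlap = np.zeros((ny, nx), dtype=bool)
    if k_neuron > 0:
        # compact disks growing from neuron centers, well inside outlines
        yy, xx = np.mgrid[0:ny, 0:nx]
        remaining = k_neuron
        for cx, cy in neuron_centers:
            if remaining <= 0:
                break
            inner = ras.disk(cx, cy, spec.neuron_radius_um - 0.7)
            idx = np.flatnonzero(inner & ~overlap)
            d2 = ((xx.ravel()[idx] + 0.5) / ppum - cx) ** 2 + \
                 ((yy.ravel()[idx] + 0.5) / ppum - cy) ** 2
            take = idx[np.argsort(d2, kind="stable")][:remaining]
            flat = overlap.reshape(-1)
            flat[take] = True
            remaining -= take.size
    rb_support |= overlap

    realized = {
        "p_neuron": (overlap & neuron_mask).sum() / n_area if n_area else 0.0,
        "p_gfap": (mgfap & ~rb_support).sum() / mgfap.sum() if mgfap.any() else 0.0,
    }

    # --- render channels
    chans = ["DAPI", "rbGFAP", "NeuN+mGFAP"]
    noiseless = np.zeros((3, 1, ny, nx))
    comps = {
        "neuron": np.zeros_like(noiseless),
        "mgfap": np.zeros_like(noiseless),
        "rbgfap": np.zeros_like(noiseless),
        "nuclei": np.zeros_like(noiseless),
        "background": np.full_like(noiseless, spec.background),
    }
    comps["neuron"][2, 0][neuron_mask] = spec.neun_amplitude
    comps["mgfap"][2, 0][mgfap] = spec.mgfap_amplitude
    comps["rbgfap"][1, 0][rb_support] = spec.rbgfap_amplitude
    for cx, cy in neuron_centers:
        comps["nuclei"][0, 0][ras.disk(cx, cy, spec.neuron_radius_um * 0.55)] = \
            spec.dapi_amplitude
    if spec.blur_sigma_px > 0:
        for name in ("neuron", "mgfap", "rbgfap", "nuclei"):
            comps[name] = gaussian_filter(
                comps[name], sigma=(0, 0, spec.blur_sigma_px, spec.blur_sigma_px))
    for arr in comps.values():
        noiseless += arr

    rng = np.random.default_rng(seed)
    noisy = noiseless.copy()
    if spec.poisson_scale > 0:
        noisy = rng.poisson(noiseless * spec.poisson_scale) / spec.poisson_scale
    if spec.gaussian_sd > 0:
        noisy = noisy + rng.normal(0.0, spec.gaussian_sd, size=noisy.shape)
    noisy = np.clip(noisy, 0.0, None)

    stack = ChannelStack(noisy, chans, ppum, z_step_um=1.0)
    gt = GroundTruth(
        label_masks={
            "neuron": neuron_mask[None],
            "mgfap_confirmed": (confirmed & ~unconfirmed)[None],
            "mgfap_unconfirmed": unconfirmed[None],
            "rbgfap": rb_support[None],
            "neuron_overlap": overlap[None],
        },
        noiseless=noiseless,
        components=comps,
        overlap_fractions={
            "p_neuron": float(realized["p_neuron"]),
            "p_gfap": float(realized["p_gfap"]),
            "p_neuron_planted": spec.p_neuron,
            "p_gfap_planted": spec.p_gfap,
        },
        neuron_outlines=outlines,
    )
    return stack, gt


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Write the scalar/geometry part of a GroundTruth as a JSON sidecar."""
    payload = {
        "plaque_centers_px": [list(map(float, c)) for c in gt.plaque_centers_px],
        "plaque_core_radii_um": list(map(float, gt.plaque_core_radii_um)),
        "microglia_body_centers_px": [list(map(float, c))
                                      for c in gt.microglia_body_centers_px],
        "cb2_offset_um": gt.cb2_offset_um,
        "overlap_fractions": gt.overlap_fractions,
        "label_classes": sorted(gt.label_masks),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
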