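"""Synthetic cross-sections with known ground truth.

The generator emulates the radial anatomy of a plant organ undergoing
secondary growth: a central xylem disc of large, radially oriented cells
(with a fiber-rich outer annulus), a thin cambial ring of small orthoradial
cells, and a phloem zone of orthoradial parenchyma with compact bundle
clusters (phloem poles) spaced at a constant arc interval along the
cambium.  Cells are produced as anisotropically weighted Voronoi regions of
jittered polar lattices, so every cell is wall-separated and recoverable by
watershed segmentation.  Intensities follow bright-field toluidine-blue
appearance: dark walls on bright lumina, 8-bit, with clipped Gaussian noise.

Everything is deterministic for a fixed spec and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology, segmentation

from .classify import CellClass
from .imaging import LabelMap, SectionImage

LUMEN_INTENSITY = 200
WALL_INTENSITY = 60
OUTSIDE_INTENSITY = 225


@dataclass
class ZoneParams:
    """Cell geometry of one concentric zone.

    mean_area_um2 : target cell area in square micrometres
    elongation : major/minor aspect ratio of the anisotropic metric (>= 1)
    orientation : 'radial', 'orthoradial' or 'mixed'
    """

    mean_area_um2: float
    elongation: float = 1.0
    orientation: str = "mixed"

    def __post_init__(self) -> None:
        if self.mean_area_um2 <= 0:
            raise ValueError("mean_area_um2 must be positive")
        if self.elongation < 1.0:
            raise ValueError("elongation is major/minor and must be >= 1")
        if self.orientation not in ("radial", "orthoradial", "mixed"):
            raise ValueError(f"unknown orientation mode {self.orientation!r}")


def _default_zones() -> dict:
    return {
        "xylem_vessel": ZoneParams(850.0, elongation=2.2, orientation="radial"),
        "xylem_fiber": ZoneParams(450.0, elongation=2.0, orientation="radial"),
        "cambium": ZoneParams(160.0, elongation=2.5, orientation="orthoradial"),
        "phloem": ZoneParams(1100.0, elongation=1.8, orientation="orthoradial"),
        "bundle": ZoneParams(130.0, elongation=1.3, orientation="mixed"),
    }


@dataclass
class SectionSpec:
    """Parameters of one synthetic cross-section.

    Zone radii are physical (micrometres) and must be strictly nested:
    0 < xylem_outer < cambium_outer < phloem_outer.  Phloem poles are
    positioned either by explicit count (``n_pole``) or by a constant arc
    spacing along the pole ring (``pole_arc_spacing``, default 140 um).
    """

    zone_radii: Mapping[str, float] = field(
        default_factory=lambda: {"xylem_outer": 220.0, "cambium_outer": 245.0,
                                 "phloem_outer": 490.0})
    pixel_size: float = 0.35
    cell_size_params: Mapping[str, ZoneParams] = field(default_factory=_default_zones)
    n_pole: int | None = None
    pole_arc_spacing: float | None = 140.0
    pole_radius_um: float = 16.0
    pole_offset_um: float = 12.0
    wall_width: int = 5
    noise: float = 6.0
    jitter: float = 0.22
    vessel_fraction: float = 0.62
    seed: int = 0
    center: tuple[float, float] | None = None
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        r = self.zone_radii
        if not (0 < r["xylem_outer"] < r["cambium_outer"] < r["phloem_outer"]):
            raise ValueError(
                "zone radii must satisfy 0 < xylem_outer < cambium_outer "
                "< phloem_outer")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.pole_arc_spacing is not None and self.pole_arc_spacing <= 0:
            raise ValueError("pole_arc_spacing must be positive when given")

    def resolved_shape(self) -> tuple[int, int]:
        if self.image_shape is not None:
            return tuple(self.image_shape)
        side = int(np.ceil(2.08 * self.zone_radii["phloem_outer"] / self.pixel_size))
        return (side, side)

    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return tuple(self.center)
        h, w = self.resolved_shape()
        return ((w - 1) / 2.0, (h - 1) / 2.0)

    def n_poles(self) -> int:
        if self.n_pole is not None:
            return int(self.n_pole)
        if self.pole_arc_spacing is None:
            return 0
        r_pole = self.zone_radii["cambium_outer"] + self.pole_offset_um
        return int(np.floor(2 * np.pi * r_pole / self.pole_arc_spacing))


@dataclass
class GroundTruth:
    """Known per-cell identity and geometry of a synthetic section.

    ``cell_geometry`` maps cell id to (centroid_xy_px, major_axis_vector,
    area_um2); the major-axis vector is the unit orientation the cell was
    constructed with.
    """

    label_map: LabelMap
    cell_classes: dict[int, CellClass]
    cell_geometry: dict[int, tuple[tuple[float, float], tuple[float, float], float]]

    @property
    def n_cells(self) -> int:
        return len(self.cell_classes)


# ---------------------------------------------------------------------------
# Seed placement
# ---------------------------------------------------------------------------

def _annulus_lattice(rng, r0, r1, zone: ZoneParams, pixel_size, jitter):
    """Jittered polar lattice of seed points in an annulus (radii in um).

    Returns arrays (radius_um, angle_rad).  Lattice spacing follows the
    zone's target area and elongation so the resulting Voronoi cells have
    roughly the requested size and aspect.
    """
    area = zone.mean_area_um2
    if zone.orientation == "radial":
        dr = np.sqrt(area * zone.elongation)
        da = area / dr
    elif zone.orientation == "orthoradial":
        da = np.sqrt(area * zone.elongation)
        dr = area / da
    else:
        dr = da = np.sqrt(area)
    n_rings = max(1, int(round((r1 - r0) / dr)))
    dr_eff = (r1 - r0) / n_rings
    radii, angles = [], []
    for i in range(n_rings):
        r = r0 + (i + 0.5) * dr_eff
        n_c = max(3, int(round(2 * np.pi * r / da)))
        phase = rng.uniform(0, 1)
        ang = 2 * np.pi * (np.arange(n_c) + phase) / n_c
        ang = ang + rng.normal(0, jitter * da / max(r, 1e-9), n_c)
        rr = r + rng.normal(0, jitter * dr_eff, n_c)
        rr = np.clip(rr, r0 + 0.12 * dr_eff, r1 - 0.12 * dr_eff)
        radii.append(rr)
        angles.append(ang % (2 * np.pi))
    return np.concatenate(radii), np.concatenate(angles)


def _pole_cluster(rng, cx, cy, radius_um, zone: ZoneParams, jitter):
    """Fermat-spiral packing of small bundle cells inside a pole disc."""
    n = max(3, int(round(np.pi * radius_um ** 2 / zone.mean_area_um2)))
    k = np.arange(n) + 0.5
    r = radius_um * np.sqrt(k / n) * 0.92
    golden = np.pi * (3 - np.sqrt(5))
    th = k * golden + rng.uniform(0, 2 * np.pi)
    x = cx + r * np.cos(th) + rng.normal(0, jitter * np.sqrt(zone.mean_area_um2), n)
    y = cy + r * np.sin(th) + rng.normal(0, jitter * np.sqrt(zone.mean_area_um2), n)
    return x, y


def _place_seeds(spec: SectionSpec, rng):
    """All cell seeds: positions (um, section-centred), class, orientation,
    and anisotropic-metric axes (a, b in px along/across the major axis)."""
    zr = spec.zone_radii
    zones = spec.cell_size_params
    xs, ys, cls, phis, aa, bb = [], [], [], [], [], []

    def metric(zone: ZoneParams):
        s = np.sqrt(zone.mean_area_um2) / spec.pixel_size  # px
        return s * np.sqrt(zone.elongation), s / np.sqrt(zone.elongation)

    def orientation_angle(theta, zone: ZoneParams):
        if zone.orientation == "radial":
            return theta
        if zone.orientation == "orthoradial":
            return theta + np.pi / 2
        return rng.uniform(0, np.pi, np.shape(theta))

    def add(r, th, zone_key, klass):
        zone = zones[zone_key]
        a, b = metric(zone)
        x, y = r * np.cos(th), r * np.sin(th)
        phi = orientation_angle(th, zone)
        xs.append(np.atleast_1d(x)); ys.append(np.atleast_1d(y))
        phis.append(np.atleast_1d(phi) * np.ones(np.size(x)))
        cls.extend([klass] * np.size(x))
        aa.append(np.full(np.size(x), a)); bb.append(np.full(np.size(x), b))

    # xylem: inner vessel/parenchyma annulus, outer fiber annulus
    r_split = spec.vessel_fraction * zr["xylem_outer"]
    r, th = _annulus_lattice(rng, 0.0, r_split, zones["xylem_vessel"],
                             spec.pixel_size, spec.jitter)
    add(r, th, "xylem_vessel", CellClass.XYLEM_VESSEL_PARENCHYMA)
    r, th = _annulus_lattice(rng, r_split, zr["xylem_outer"], zones["xylem_fiber"],
                             spec.pixel_size, spec.jitter)
    add(r, th, "xylem_fiber", CellClass.XYLEM_FIBER)

    # cambium ring
    r, th = _annulus_lattice(rng, zr["xylem_outer"], zr["cambium_outer"],
                             zones["cambium"], spec.pixel_size, spec.jitter)
    add(r, th, "cambium", CellClass.CAMBIUM)

    # phloem parenchyma
    r, th = _annulus_lattice(rng, zr["cambium_outer"], zr["phloem_outer"],
                             zones["phloem"], spec.pixel_size, spec.jitter)
    x_par, y_par = r * np.cos(th), r * np.sin(th)

    # phloem poles: equally arc-spaced bundle clusters just outside the cambium
    n_pole = spec.n_poles()
    keep = np.ones(len(x_par), dtype=bool)
    pole_xy = []
    if n_pole > 0:
        r_pole = zr["cambium_outer"] + spec.pole_offset_um
        phase = rng.uniform(0, 2 * np.pi)
        pole_angles = phase + 2 * np.pi * np.arange(n_pole) / n_pole
        for pa in pole_angles:
            px_, py_ = r_pole * np.cos(pa), r_pole * np.sin(pa)
            pole_xy.append((px_, py_))
            d2 = (x_par - px_) ** 2 + (y_par - py_) ** 2
            keep &= d2 > (1.25 * spec.pole_radius_um) ** 2
    x_par, y_par = x_par[keep], y_par[keep]
    th_par = np.arctan2(y_par, x_par)
    zone = zones["phloem"]
    a, b = metric(zone)
    xs.append(x_par); ys.append(y_par)
    phis.append(orientation_angle(th_par, zone) * np.ones(len(x_par)))
    cls.extend([CellClass.PHLOEM_PARENCHYMA] * len(x_par))
    aa.append(np.full(len(x_par), a)); bb.append(np.full(len(x_par), b))

    for (px_, py_) in pole_xy:
        bx, by = _pole_cluster(rng, px_, py_, spec.pole_radius_um,
                               zones["bundle"], spec.jitter)
        th_b = np.arctan2(by, bx)
        zone = zones["bundle"]
        a, b = metric(zone)
        xs.append(bx); ys.append(by)
        phis.append(orientation_angle(th_b, zone) * np.ones(len(bx)))
        cls.extend([CellClass.PHLOEM_BUNDLE] * len(bx))
        aa.append(np.full(len(bx), a)); bb.append(np.full(len(bx), b))

    return (np.concatenate(xs), np.concatenate(ys), np.array(cls, dtype=object),
            np.concatenate(phis), np.concatenate(aa), np.concatenate(bb))


# ---------------------------------------------------------------------------
# Tessellation and rendering
# ---------------------------------------------------------------------------

def _assign_voronoi(shape, cx, cy, seeds_px, phis, aa, bb):
    """Anisotropically weighted Voronoi assignment of pixels to seeds.

    Each seed carries its own metric d^2 = (u/a)^2 + (v/b)^2 with (u, v) the
    pixel offset rotated into the seed's orientation frame; scaling (a, b)
    with the zone's cell size makes boundaries respect the intended size
    contrast between zones.  Computed per seed on a local window.
    """
    h, w = shape
    best = np.full(shape, np.inf, dtype=np.float32)
    lab = np.zeros(shape, dtype=np.int32)
    sx, sy = seeds_px
    for i in range(len(sx)):
        a, b = aa[i], bb[i]
        half = int(np.ceil(1.35 * a))
        x0, x1 = max(0, int(sx[i]) - half), min(w, int(sx[i]) + half + 1)
        y0, y1 = max(0, int(sy[i]) - half), min(h, int(sy[i]) + half + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1, dtype=np.float32) - sx[i]
        ys = np.arange(y0, y1, dtype=np.float32) - sy[i]
        X, Y = np.meshgrid(xs, ys)
        c, s = np.cos(phis[i]), np.sin(phis[i])
        u = X * c + Y * s
        v = -X * s + Y * c
        d2 = (u / a) ** 2 + (v / b) ** 2
        win_best = best[y0:y1, x0:x1]
        upd = d2 < win_best
        win_best[upd] = d2[upd]
        lab[y0:y1, x0:x1][upd] = i + 1
    return lab


def generate_section(spec: SectionSpec):
    """Render a synthetic cross-section.

    Returns ``(image, ground_truth, masks)`` where ``masks`` holds binary
    ``section`` and ``xylem`` discs.  Identical spec and seed give identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.resolved_shape()
    cx, cy = spec.resolved_center()
    px = spec.pixel_size

    x_um, y_um, classes, phis, aa, bb = _place_seeds(spec, rng)
    sx = cx + x_um / px
    sy = cy + y_um / px

    lab = _assign_voronoi(shape, cx, cy, (sx, sy), phis, aa, bb)

    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    r_px = np.hypot(xx - cx, yy - cy)
    section_mask = r_px <= spec.zone_radii["phloem_outer"] / px
    xylem_mask = r_px <= spec.zone_radii["xylem_outer"] / px
    lab[~section_mask] = 0

    # fill any unassigned pixels inside the section with the nearest seed
    holes = section_mask & (lab == 0)
    if holes.any():
        _, (iy, ix) = ndi.distance_transform_edt(lab == 0, return_indices=True)
        lab[holes] = lab[iy[holes], ix[holes]]

    # wall network: inter-cell boundaries plus the section rim, thickened
    # isotropically (Euclidean distance to the interface) so diagonal walls
    # are as robust to binary morphology as axis-aligned ones
    interface = segmentation.find_boundaries(lab, mode="thick")
    interface |= section_mask & ~ndi.binary_erosion(
        section_mask, structure=morphology.disk(2))
    extra = max(0.0, (spec.wall_width - 1) / 2.0)
    if extra > 0:
        wall = ndi.distance_transform_edt(~interface) <= extra
    else:
        wall = interface

    truth_labels = lab.copy()
    truth_labels[wall] = 0

    # drop slivers and compact ids
    counts = np.bincount(truth_labels.ravel())
    small = np.flatnonzero(counts < 20)
    small = small[small > 0]
    if small.size:
        truth_labels[np.isin(truth_labels, small)] = 0
    label_map = LabelMap(truth_labels, pixel_size=px).compacted()

    # map compacted ids back to seed attributes
    old_of_new = {}
    ids_old = np.unique(truth_labels)
    ids_old = ids_old[ids_old > 0]
    for new, old in enumerate(ids_old, start=1):
        old_of_new[new] = int(old)

    cell_classes: dict[int, CellClass] = {}
    cell_geometry: dict[int, tuple] = {}
    lbl = label_map.labels
    objs = ndi.find_objects(lbl)
    areas = np.bincount(lbl.ravel())
    for new, old in old_of_new.items():
        seed_idx = old - 1
        sl = objs[new - 1]
        sub = lbl[sl] == new
        ys_c, xs_c = np.nonzero(sub)
        cxc = xs_c.mean() + sl[1].start
        cyc = ys_c.mean() + sl[0].start
        phi = float(phis[seed_idx])
        cell_classes[new] = classes[seed_idx]
        cell_geometry[new] = ((float(cxc), float(cyc)),
                              (float(np.cos(phi)), float(np.sin(phi))),
                              float(areas[new]) * px ** 2)

    image = np.full(shape, OUTSIDE_INTENSITY, dtype=np.float64)
    image[section_mask] = LUMEN_INTENSITY
    image[wall] = WALL_INTENSITY  # rim walls keep full thickness outside too
    if spec.noise > 0:
        image += rng.normal(0, spec.noise, shape)
    image = np.clip(image, 0, 255).astype(np.uint8)

    section = SectionImage(image, pixel_size=px, center=(cx, cy))
    truth = GroundTruth(label_map, cell_classes, cell_geometry)
    return section, truth, {"section": section_mask, "xylem": xylem_mask}


# ---------------------------------------------------------------------------
# Reporter-stained ring images (phloem-pole analysis input)
# ---------------------------------------------------------------------------

def generate_gus_ring(spec: SectionSpec, focus_intensity: float = 120.0,
                      background_sd: float = 0.0,
                      focus_sigma_um: float = 6.0) -> SectionImage:
    """Emulate a reporter-stained section: dark foci on a ring.

    Foci sit on the circle of radius ``cambium_outer + pole_offset_um``,
    equally arc-spaced (count from ``n_pole`` or from ``pole_arc_spacing``),
    as Gaussian intensity dips of depth ``focus_intensity`` and width
    ``focus_sigma_um`` on a bright background with additive Gaussian noise
    of the stated sd.
    """
    r_pole_um = spec.zone_radii["cambium_outer"] + spec.pole_offset_um
    if r_pole_um <= 0:
        raise ValueError("pole ring radius must be positive")
    n_pole = spec.n_poles()
    if n_pole <= 0:
        raise ValueError("pole count or arc spacing must be given")
    rng = np.random.default_rng(spec.seed)
    shape = spec.resolved_shape()
    cx, cy = spec.resolved_center()
    px = spec.pixel_size
    r_pole = r_pole_um / px
    sigma = focus_sigma_um / px

    image = np.full(shape, float(LUMEN_INTENSITY))
    phase = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for k in range(n_pole):
        ang = phase + 2 * np.pi * k / n_pole
        fx, fy = cx + r_pole * np.cos(ang), cy + r_pole * np.sin(ang)
        d2 = (xx - fx) ** 2 + (yy - fy) ** 2
        image -= focus_intensity * np.exp(-d2 / (2 * sigma ** 2))
    if background_sd > 0:
        image += rng.normal(0, background_sd, shape)
    image = np.clip(image, 0, 255).astype(np.uint8)
    return SectionImage(image, pixel_size=px, center=(cx, cy))


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

def tile_image(image: SectionImage, grid: tuple[int, int] | None = None,
               tile_px: int = 1024):
    """Cut an image into a row-major grid of square tiles.

    The grid must cover the image; the bottom/right margin is padded with
    zeros when the tile size does not divide the frame.  Returns
    ``(tiles, manifest)`` such that :func:`quanthisto.imaging.stitch_tiles`
    restores the original image bit-exactly.
    """
    if tile_px <= 0:
        raise ValueError("tile_px must be positive")
    h, w = image.pixels.shape
    need = (int(np.ceil(h / tile_px)), int(np.ceil(w / tile_px)))
    if grid is None:
        grid = need
    rows, cols = int(grid[0]), int(grid[1])
    if rows < need[0] or cols < need[1]:
        raise ValueError(f"grid {grid} does not cover image of shape {(h, w)}")
    padded = np.zeros((rows * tile_px, cols * tile_px), dtype=image.pixels.dtype)
    padded[:h, :w] = image.pixels
    tiles = [padded[r * tile_px:(r + 1) * tile_px, c * tile_px:(c + 1) * tile_px].copy()
             for r in range(rows) for c in range(cols)]
    manifest = {"rows": rows, "cols": cols, "tile_px": tile_px,
                "order": "row-major", "original_shape": [h, w],
                "pixel_size": image.pixel_size}
    return tiles, manifest


def write_manifest(manifest: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(manifest), fh, indent=2)
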