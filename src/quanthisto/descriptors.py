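"""Per-cell morphometric descriptors.

Each segmented cell is characterized by a 16-component vector: 10 geometric
features (area, perimeter, ellipse axes from the second-order central image
moments, eccentricity, orientation, and boundary-radius statistics) and 6
positional features (centroid, polar coordinates relative to the section
center, and the incline angle).

The incline angle is the key positional descriptor for radial tissues: with
``x`` the cell's major-axis vector and ``r`` the radius vector from the
section center to the cell centroid,

    theta = | arccos( x.r / (|x| |r|) ) - pi/2 |

so theta = 0 is a perfectly orthoradial (tangential/periclinal) cell and
theta = pi/2 a perfectly radial (anticlinal) one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

from .imaging import LabelMap

#: fixed column order of the 16 descriptors (units in parentheses):
#: geometric features first, positional features last.
FEATURE_NAMES = [
    "area",               # um^2
    "perimeter",          # um
    "major_axis",         # um
    "minor_axis",         # um
    "eccentricity",       # [0, 1]
    "orientation",        # rad, in [-pi/2, pi/2)
    "radius_mean",        # um, centroid->boundary
    "radius_sd",          # um
    "radius_min",         # um
    "radius_max",         # um
    "centroid_x",         # px
    "centroid_y",         # px
    "polar_radius",       # um
    "polar_radius_norm",  # [0, ~1.2]
    "polar_angle",        # rad, [0, 2pi)
    "incline",            # rad, [0, pi/2]
]

GEOMETRIC_FEATURES = FEATURE_NAMES[:10]
POSITIONAL_FEATURES = FEATURE_NAMES[10:]


# ---------------------------------------------------------------------------
# Moment-based ellipse fit
# ---------------------------------------------------------------------------

def ellipse_from_moments(labels: LabelMap, cell_id: int):
    """Fit an ellipse to a cell from its second-order central moments.

    The eigendecomposition of the 2x2 covariance matrix of pixel
    coordinates gives the ellipse with matching moments; axis lengths are
    ``4 * sqrt(eigenvalue)`` (full axes, px) and the orientation is the
    angle of the leading eigenvector in [-pi/2, pi/2), measured from the
    +x axis in (x, y) image coordinates (y down).

    Returns ``(major_axis, minor_axis, orientation, eccentricity,
    (cx, cy), degenerate)``; single-pixel or collinear cells are flagged
    degenerate with minor_axis 0 and eccentricity 1.
    """
    mask = labels.labels == cell_id
    if not mask.any():
        raise KeyError(f"cell id {cell_id} not present in label map")
    ys, xs = np.nonzero(mask)
    return _ellipse_from_coords(xs, ys)


def _ellipse_from_coords(xs: np.ndarray, ys: np.ndarray):
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    n = len(xs)
    # central second moments with the 1/12 pixel-variance correction is not
    # applied: moments are of the pixel-center point set, as in EBImage
    mu20 = (dx * dx).sum() / n
    mu02 = (dy * dy).sum() / n
    mu11 = (dx * dy).sum() / n
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lead = evecs[:, 1]
    major = 4.0 * np.sqrt(max(evals[1], 0.0))
    minor = 4.0 * np.sqrt(max(evals[0], 0.0))
    degenerate = minor <= 0
    orientation = np.arctan2(lead[1], lead[0])
    if orientation >= np.pi / 2:
        orientation -= np.pi
    elif orientation < -np.pi / 2:
        orientation += np.pi
    ecc = 1.0 if degenerate else float(np.sqrt(1.0 - (minor / major) ** 2))
    return (float(major), float(minor), float(orientation), ecc,
            (float(cx), float(cy)), bool(degenerate))


def shape_stats(labels: LabelMap, cell_id: int, pixel_size: float | None = None):
    """Area, perimeter and boundary-radius statistics of one cell (um).

    Area is the pixel count scaled by ``pixel_size**2``; the perimeter is
    the traced contour length (8-connected chain, as in
    :func:`skimage.measure.perimeter`); boundary radii are the distances
    from the centroid to each boundary pixel (a pixel of the cell with a
    non-cell 4-neighbor).
    """
    px = labels.pixel_size if pixel_size is None else pixel_size
    mask = labels.labels == cell_id
    if not mask.any():
        raise KeyError(f"cell id {cell_id} not present in label map")
    return _shape_stats_mask(mask, px)


def _shape_stats_mask(mask: np.ndarray, px: float):
    area = float(mask.sum()) * px ** 2
    perimeter = float(measure.perimeter(mask, neighborhood=4)) * px
    boundary = mask & ~ndi.binary_erosion(mask)
    ys, xs = np.nonzero(mask)
    cx, cy = xs.mean(), ys.mean()
    bys, bxs = np.nonzero(boundary)
    radii = np.hypot(bxs - cx, bys - cy) * px
    return (area, perimeter, float(radii.mean()), float(radii.std()),
            float(radii.min()), float(radii.max()))


# ---------------------------------------------------------------------------
# Polar position and incline
# ---------------------------------------------------------------------------

def polar_position(centroid, center, section_mean_radius: float,
                   pixel_size: float = 1.0):
    """Polar coordinates of a centroid about the section center.

    Radius is Euclidean distance in um; the normalized radius divides by
    the section's mean radius (0.0 at the center, 1.0 at the average
    distance of the outermost cells); the angle is counter-clockwise from
    +x in [0, 2pi).
    """
    if center is None:
        raise ValueError("section center is not set")
    if not section_mean_radius > 0:
        raise ValueError("section_mean_radius must be positive")
    dx = centroid[0] - center[0]
    dy = centroid[1] - center[1]
    radius = float(np.hypot(dx, dy)) * pixel_size
    angle = float(np.arctan2(dy, dx)) % (2 * np.pi)
    return radius, radius / section_mean_radius, angle


def incline_angle(x, r) -> float:
    """Deviation of the major axis from the local radius, in [0, pi/2].

    ``theta = |arccos(x.r / (|x||r|)) - pi/2|``: 0 for orthoradial
    (tangential) orientation, pi/2 for radial.  Invariant to rescaling and
    to flipping the sign of either vector.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    nx, nr = np.linalg.norm(x), np.linalg.norm(r)
    if nx == 0 or nr == 0:
        raise ValueError("incline angle requires non-zero vectors")
    c = np.clip(np.dot(x, r) / (nx * nr), -1.0, 1.0)
    return float(abs(np.arccos(c) - np.pi / 2))


def section_mean_radius(labels: LabelMap, center,
                        outer_fraction: float = 0.05) -> float:
    """Mean centroid distance (um) of the outermost cells from the center.

    The outermost cells are the ``outer_fraction`` (default 5%) of cells
    with the largest centroid distance; their average distance defines the
    radius at which the normalized polar radius equals 1.0.
    """
    if center is None:
        raise ValueError("section center is not set")
    lbl = labels.labels
    ids = labels.cell_ids
    if ids.size == 0:
        raise ValueError("empty label map")
    cents = ndi.center_of_mass(np.ones_like(lbl), lbl, ids)
    cents = np.asarray(cents)  # (n, 2) as (row, col)
    d = np.hypot(cents[:, 1] - center[0], cents[:, 0] - center[1])
    k = max(1, int(np.ceil(outer_fraction * len(d))))
    outer = np.sort(d)[-k:]
    return float(outer.mean()) * labels.pixel_size


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

def build_feature_table(labels: LabelMap, center,
                        pixel_size: float | None = None,
                        mean_radius_um: float | None = None) -> pd.DataFrame:
    """One row per cell with the 16 descriptors, ordered by cell id.

    ``mean_radius_um`` overrides the normalization radius (otherwise
    computed from the outermost cells of this label map).  An empty label
    map yields an empty table with the full header.
    """
    if center is None:
        raise ValueError("section center is not set")
    px = labels.pixel_size if pixel_size is None else pixel_size
    ids = labels.cell_ids
    cols = ["cell_id"] + FEATURE_NAMES
    if ids.size == 0:
        return pd.DataFrame(columns=cols)
    if mean_radius_um is None:
        mean_radius_um = section_mean_radius(labels, center)

    lbl = labels.labels
    rows = []
    for cell_id, sl in zip(ids, _objects_for(lbl, ids)):
        sub = lbl[sl] == cell_id
        ys, xs = np.nonzero(sub)
        xs = xs + sl[1].start
        ys = ys + sl[0].start
        major, minor, orient, ecc, (cx, cy), degen = _ellipse_from_coords(xs, ys)
        pad = np.pad(sub, 1)  # crop-local stats; padding isolates the border
        area, perim, rmean, rsd, rmin, rmax = _shape_stats_mask(pad, px)
        pradius, pnorm, pangle = polar_position((cx, cy), center,
                                                mean_radius_um, px)
        rvec = (cx - center[0], cy - center[1])
        if degen or (rvec[0] == 0 and rvec[1] == 0):
            theta = np.nan
        else:
            xvec = (np.cos(orient), np.sin(orient))
            theta = incline_angle(xvec, rvec)
        rows.append([int(cell_id), area, perim, major * px, minor * px, ecc,
                     orient, rmean, rsd, rmin, rmax, cx, cy,
                     pradius, pnorm, pangle, theta])
    return pd.DataFrame(rows, columns=cols)


def _objects_for(lbl: np.ndarray, ids: np.ndarray):
    objs = ndi.find_objects(lbl, max_label=int(ids.max()))
    return [objs[i - 1] for i in ids]


def write_feature_table(table: pd.DataFrame, path) -> None:
    """CSV serialization with a stable header; reads back losslessly."""
    table.to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
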