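"""Incline-angle organization across the radial axis.

As secondary growth refines the tissue, cell orientations organize into a
radial (xylem) population and an orthoradial (cambium/phloem) population;
the pooled incline distribution then turns bimodal.  This module provides
the statistics used to quantify that process: Hartigans' dip test for
bimodality (bootstrap p-values), lowess trends of incline against
normalized radial position, per-class radial profiles, cell counts within
fixed pixel radii of the center, and boundary-corrected kernel densities
for violin plots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from ._dip import dip_pvalue_bootstrap, dip_statistic

__all__ = [
    "dip_statistic", "dip_test", "lowess_trend", "radial_class_profile",
    "count_within_radius", "incline_density",
]


def dip_test(values, n_boot: int = 2000, seed: int = 0):
    """Hartigans' dip test of unimodality.

    The dip is the sup-norm distance from the empirical CDF to the closest
    unimodal CDF; the p-value is estimated by ``n_boot`` bootstrap samples
    from the uniform null (the least favourable unimodal distribution).
    Small p rejects unimodality.  Constant samples give dip 0, p 1.
    Requires at least 10 values.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[~np.isnan(v)]
    if v.size < 10:
        raise ValueError("dip test needs at least 10 values")
    return dip_pvalue_bootstrap(v, n_boot=n_boot, seed=seed)


def lowess_trend(radius_norm, incline, frac: float = 0.3,
                 n_grid: int = 200, it: int = 3):
    """Locally weighted linear regression of incline on radial position.

    Runs lowess with ``it`` robustifying iterations and evaluates the fit
    on an ``n_grid``-point grid spanning [0, 1] by linear interpolation
    (endpoints extend the nearest fitted value).  Returns a DataFrame with
    columns ``radius_norm`` and ``incline``.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    r = np.asarray(radius_norm, dtype=float).ravel()
    y = np.asarray(incline, dtype=float).ravel()
    ok = ~(np.isnan(r) | np.isnan(y))
    r, y = r[ok], y[ok]
    if r.size < 20:
        raise ValueError("lowess trend needs at least 20 points")
    fitted = sm_lowess(y, r, frac=frac, it=it, return_sorted=True)
    grid = np.linspace(0.0, 1.0, n_grid)
    curve = np.interp(grid, fitted[:, 0], fitted[:, 1])
    return pd.DataFrame({"radius_norm": grid, "incline": curve})


def radial_class_profile(table: pd.DataFrame,
                         class_column: str = "class") -> pd.DataFrame:
    """Per-class incline quartiles at the class's mean radial position.

    For every class present: the incline quartiles (linear, type-7
    interpolation), whisker bounds and outliers by the 1.5 IQR rule, and
    the mean normalized radius (the box position along the radial axis).
    Absent classes are simply omitted.
    """
    if class_column not in table:
        raise ValueError(f"table lacks a {class_column!r} column")
    rows = []
    for cls, grp in table.groupby(class_column, observed=True):
        inc = grp["incline"].dropna().to_numpy()
        if inc.size == 0:
            continue
        q1, q2, q3 = np.percentile(inc, [25, 50, 75])  # type-7 linear
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        outliers = inc[(inc < lo) | (inc > hi)]
        rows.append({
            "class": cls,
            "n": int(inc.size),
            "incline_q1": q1, "incline_median": q2, "incline_q3": q3,
            "whisker_low": float(inc[inc >= lo].min()),
            "whisker_high": float(inc[inc <= hi].max()),
            "n_outliers": int(outliers.size),
            "mean_radius_norm": float(grp["polar_radius_norm"].mean()),
        })
    return pd.DataFrame(rows)


def count_within_radius(table: pd.DataFrame, radii_px,
                        center=None) -> pd.Series:
    """Number of cells with centroid within each pixel radius of the center.

    ``center`` defaults to (0, 0) offsets already encoded if the table
    carries ``polar_radius`` in um; pass the section center (x, y) to
    compute pixel distances from ``centroid_x/centroid_y`` instead.
    Counts are non-decreasing in the radius.
    """
    radii = np.asarray(radii_px, dtype=float).ravel()
    if (radii < 0).any():
        raise ValueError("radii must be non-negative")
    if center is not None:
        d = np.hypot(table["centroid_x"].to_numpy() - center[0],
                     table["centroid_y"].to_numpy() - center[1])
    else:
        if "polar_radius_px" in table:
            d = table["polar_radius_px"].to_numpy()
        else:
            raise ValueError("pass center=(x, y) or provide polar_radius_px")
    return pd.Series([int((d <= r).sum()) for r in radii], index=radii,
                     name="n_cells")


def incline_density(values, grid=None, bandwidth=None) -> pd.DataFrame:
    """Gaussian kernel density of incline angles on [0, pi/2].

    The kernel mass leaking past the boundaries is reflected back
    (boundary-corrected KDE), so the density integrates to 1 on the
    support.  ``bandwidth`` follows scipy's Scott rule by default.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[~np.isnan(v)]
    if v.size < 10:
        raise ValueError("density estimate needs at least 10 values")
    lo, hi = 0.0, np.pi / 2
    if grid is None:
        grid = np.linspace(lo, hi, 256)
    grid = np.asarray(grid, dtype=float)
    if v.std() <= 1e-12 * max(1.0, abs(v.mean())):  # point mass: spike
        dens = np.zeros_like(grid)
        i = np.argmin(np.abs(grid - v[0]))
        dens[i] = 1.0
        dens /= np.trapezoid(dens, grid)
        return pd.DataFrame({"incline": grid, "density": dens})
    kde = stats.gaussian_kde(v, bw_method=bandwidth)
    dens = kde(grid) + kde(2 * lo - grid) + kde(2 * hi - grid)
    dens /= np.trapezoid(dens, grid)
    return pd.DataFrame({"incline": grid, "density": dens})
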