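"""Rugosity: surface-area / planar-area ratios from DEMs and profiles.

Surface area uses a dual-diagonal triangulation: each cell quad is split
along both diagonals and the two triangulated areas are averaged, which
removes the diagonal-orientation bias of a single triangulation.  Slope
correction divides out the secant of the best-fit plane's tilt.  Heightmaps
are 2.5D: overhangs and interstitial spaces cannot be represented, so
rugosity computed here is always that of the draped surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .grids import HeightMap, Profile1D, coarsen

__all__ = [
    "RugosityResult",
    "RichnessModelFit",
    "surface_rugosity",
    "profile_rugosity",
    "slope_corrected_rugosity",
    "multiresolution_rugosity",
    "area_decoupled_regression",
    "triangulated_area",
]


@dataclass
class RugosityResult:
    r_value: float
    surface_measure: float  # area (2D) or contour length (1D)
    planar_measure: float  # planar area (2D) or linear extent (1D)
    grain: float
    slope_corrected: bool = False
    method: str = "triangulated_2d"  # or "chain_1d"


@dataclass
class RichnessModelFit:
    """Coefficients of log S = a log A + b log R + c."""

    a: float
    b: float
    c: float
    se_a: float
    se_b: float
    se_c: float
    n_observations: int
    collinear: bool = False


def _require_no_holes(hmap: HeightMap) -> None:
    if hmap.has_nodata:
        raise ValueError("nodata holes inside the analysis window are not supported")


def triangulated_area(hmap: HeightMap) -> float:
    """Dual-diagonal triangulated surface area of the height grid."""
    _require_no_holes(hmap)
    z = hmap.heights
    c = hmap.cell_size
    z00 = z[:-1, :-1]
    z01 = z[:-1, 1:]
    z10 = z[1:, :-1]
    z11 = z[1:, 1:]

    def tri(za, zb, zc, dxb, dyb, dxc, dyc):
        # cross product of (dxb, dyb, zb-za) x (dxc, dyc, zc-za)
        ux = dyb * (zc - za) - (zb - za) * dyc
        uy = (zb - za) * dxc - dxb * (zc - za)
        uz = dxb * dyc - dyb * dxc
        return 0.5 * np.sqrt(ux**2 + uy**2 + uz**2)

    # triangulation 1: diagonal 00-11
    a1 = tri(z00, z10, z11, 0.0, c, c, c) + tri(z00, z11, z01, c, c, c, 0.0)
    # triangulation 2: diagonal 10-01
    a2 = tri(z00, z10, z01, 0.0, c, c, 0.0) + tri(z11, z10, z01, 0.0, -c, -c, 0.0)
    return float((a1.sum() + a2.sum()) / 2.0)


def surface_rugosity(hmap: HeightMap) -> RugosityResult:
    """Rugosity R = triangulated surface area / planar area (R >= 1)."""
    nr, nc = hmap.shape
    area = triangulated_area(hmap)
    planar = (nr - 1) * (nc - 1) * hmap.cell_size**2
    return RugosityResult(
        r_value=area / planar,
        surface_measure=area,
        planar_measure=planar,
        grain=hmap.cell_size,
    )


def profile_rugosity(profile: Profile1D) -> RugosityResult:
    """Chain-style rugosity of a 1D profile: contour length / linear extent."""
    dz = np.diff(profile.heights)
    contour = float(np.sqrt(profile.spacing**2 + dz**2).sum())
    extent = profile.extent
    return RugosityResult(
        r_value=contour / extent,
        surface_measure=contour,
        planar_measure=extent,
        grain=profile.spacing,
        method="chain_1d",
    )


def fit_plane(hmap: HeightMap) -> tuple[float, float, float]:
    """Least-squares plane z = gx*x + gy*y + z0 through the cell centres."""
    _require_no_holes(hmap)
    nr, nc = hmap.shape
    y, x = np.mgrid[0:nr, 0:nc] * hmap.cell_size
    design = np.column_stack([x.ravel(), y.ravel(), np.ones(nr * nc)])
    coef, _, rank, _ = np.linalg.lstsq(design, hmap.heights.ravel(), rcond=None)
    if rank < 3:
        raise ValueError("degenerate plane fit: collinear support")
    return float(coef[0]), float(coef[1]), float(coef[2])


def slope_corrected_rugosity(hmap: HeightMap) -> RugosityResult:
    """Rugosity with the large-scale tilt of the window divided out.

    The planar denominator becomes the window area projected onto the
    plane of best fit (window area times the secant of the plane's tilt),
    so a perfectly inclined plane has corrected rugosity 1.
    """
    gx, gy, _ = fit_plane(hmap)
    secant = float(np.sqrt(1.0 + gx**2 + gy**2))
    base = surface_rugosity(hmap)
    planar = base.planar_measure * secant
    return RugosityResult(
        r_value=base.surface_measure / planar,
        surface_measure=base.surface_measure,
        planar_measure=planar,
        grain=hmap.cell_size,
        slope_corrected=True,
    )


def multiresolution_rugosity(
    hmap: HeightMap, grains: list[int], method: str = "mean"
) -> list[RugosityResult]:
    """Rugosity after block-aggregating the map at each coarsening factor.

    Coarsening uses block means by default (``method="subsample"`` is
    available for comparison).  Results are ordered by grain.
    """
    results = []
    for factor in sorted(grains):
        cm = coarsen(hmap, factor, method=method)
        results.append(surface_rugosity(cm))
    return results


def area_decoupled_regression(
    richness: np.ndarray | list,
    areas: np.ndarray | list,
    rugosities: np.ndarray | list,
    cond_threshold: float = 1e8,
) -> RichnessModelFit:
    """OLS of log S on (log A, log R): the area-decoupled richness model.

    Including area as a covariate separates rugosity's contribution from
    the species-area effect.  Near-collinear predictors (including the
    degenerate all-R-equal case) are flagged, not silently dropped.
    """
    s = np.asarray(richness, dtype=float)
    a = np.asarray(areas, dtype=float)
    r = np.asarray(rugosities, dtype=float)
    if not (s.size == a.size == r.size):
        raise ValueError("richness, areas and rugosities must have equal length")
    if s.size < 5:
        raise ValueError("need at least 5 observations")
    if np.any(s <= 0) or np.any(a <= 0) or np.any(r <= 0):
        raise ValueError("all inputs must be strictly positive")
    log_s = np.log(s)
    design = sm.add_constant(np.column_stack([np.log(a), np.log(r)]), has_constant="add")
    collinear = bool(np.linalg.cond(design) > cond_threshold)
    fit = sm.OLS(log_s, design).fit()
    params = fit.params
    bse = fit.bse
    return RichnessModelFit(
        a=float(params[1]),
        b=float(params[2]),
        c=float(params[0]),
        se_a=float(bse[1]),
        se_b=float(bse[2]),
        se_c=float(bse[0]),
        n_observations=int(s.size),
        collinear=collinear,
    )
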