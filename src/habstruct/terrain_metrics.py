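"""Height range, terrain ruggedness, slope/aspect and vector dispersion."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import HeightMap

__all__ = [
    "TerrainSummary",
    "height_range",
    "terrain_ruggedness_index",
    "slope_aspect",
    "facet_normals",
    "dispersion_from_normals",
    "vector_dispersion",
    "terrain_summary",
]

_NEIGHBOUR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class TerrainSummary:
    height_range: float
    tri: float
    mean_slope: float  # degrees
    vector_dispersion: float
    grain: float


def height_range(hmap: HeightMap) -> float:
    """Range (max - min) of valid surface heights."""
    vals = hmap.valid_heights
    if vals.size == 0:
        raise ValueError("all cells are nodata")
    return float(vals.max() - vals.min())


def terrain_ruggedness_index(hmap: HeightMap) -> float:
    """Riley terrain ruggedness: per focal cell the RMS height difference
    to its 8 neighbours, averaged over all interior focal cells."""
    if hmap.has_nodata:
        raise ValueError("TRI requires a map without nodata holes")
    z = hmap.heights
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("TRI needs at least a 3x3 grid")
    focal = z[1:-1, 1:-1]
    sq = np.zeros_like(focal)
    for dr, dc in _NEIGHBOUR_OFFSETS:
        nb = z[1 + dr : z.shape[0] - 1 + dr, 1 + dc : z.shape[1] - 1 + dc]
        sq += (nb - focal) ** 2
    return float(np.sqrt(sq / 8.0).mean())


def slope_aspect(hmap: HeightMap) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell slope and aspect in degrees.

    Gradients use central differences in the interior (one-sided at the
    borders) scaled by cell size.  Aspect is the downslope compass
    direction (0 = north = decreasing row index, 90 = east); it is NaN
    wherever the gradient vanishes.
    """
    if hmap.has_nodata:
        raise ValueError("slope/aspect require a map without nodata holes")
    z = hmap.heights
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("slope/aspect need at least a 3x3 grid")
    g_row, g_col = np.gradient(z, hmap.cell_size)
    slope = np.degrees(np.arctan(np.hypot(g_row, g_col)))
    east = -g_col  # downslope components
    north = g_row  # row index increases southward
    aspect = np.degrees(np.arctan2(east, north)) % 360.0
    aspect[(g_row == 0) & (g_col == 0)] = np.nan
    return slope, aspect


def facet_normals(hmap: HeightMap) -> np.ndarray:
    """Upward unit normals of all triangular facets, (N, 3).

    Uses the same dual-diagonal triangulation as surface rugosity: four
    triangles per cell quad (two per diagonal split).
    """
    if hmap.has_nodata:
        raise ValueError("facet normals require a map without nodata holes")
    z = hmap.heights
    c = hmap.cell_size
    z00 = z[:-1, :-1]
    z01 = z[:-1, 1:]
    z10 = z[1:, :-1]
    z11 = z[1:, 1:]

    def normal(za, zb, zc, dxb, dyb, dxc, dyc):
        ux = dyb * (zc - za) - (zb - za) * dyc
        uy = (zb - za) * dxc - dxb * (zc - za)
        uz = np.full_like(za, dxb * dyc - dyb * dxc)
        n = np.stack([ux, uy, uz], axis=-1)
        # orient upward
        flip = n[..., 2] < 0
        n[flip] *= -1.0
        norms = np.linalg.norm(n, axis=-1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("degenerate facet with zero area")
        return (n / norms).reshape(-1, 3)

    tris = [
        normal(z00, z10, z11, 0.0, c, c, c),
        normal(z00, z11, z01, c, c, c, 0.0),
        normal(z00, z10, z01, 0.0, c, c, 0.0),
        normal(z11, z01, z10, 0.0, -c, -c, 0.0),
    ]
    return np.concatenate(tris, axis=0)


def dispersion_from_normals(normals: np.ndarray, convention: str = "resultant") -> float:
    """Vector dispersion of a set of unit normals.

    ``"resultant"`` (default): ``1 - R_bar`` with ``R_bar`` the mean
    resultant length |sum n| / N — 0 for identical normals, approaching 1
    for fully scattered ones.  ``"fisher"``: the spherical-statistics
    variant ``(N - |sum n|) / (N - 1)``.
    """
    normals = np.asarray(normals, dtype=float)
    n = normals.shape[0]
    resultant = float(np.linalg.norm(normals.sum(axis=0)))
    if convention == "resultant":
        return 1.0 - resultant / n
    if convention == "fisher":
        return (n - resultant) / (n - 1)
    raise ValueError(f"unknown dispersion convention {convention!r}")


def vector_dispersion(hmap: HeightMap, convention: str = "resultant") -> float:
    """Dispersion of triangulated facet normals; 0 for any plane."""
    return dispersion_from_normals(facet_normals(hmap), convention)


def terrain_summary(hmap: HeightMap) -> TerrainSummary:
    slope, _ = slope_aspect(hmap)
    return TerrainSummary(
        height_range=height_range(hmap),
        tri=terrain_ruggedness_index(hmap),
        mean_slope=float(slope[1:-1, 1:-1].mean()),
        vector_dispersion=vector_dispersion(hmap),
        grain=hmap.cell_size,
    )
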