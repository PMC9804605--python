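"""Core grid containers: heightmaps, 1D profiles and binary rasters.

Grid convention (used throughout the package): arrays are row-major with
the origin at the top-left corner; cell centres sit at
``(row + 0.5, col + 0.5) * cell_size``.  Scales (box sizes, grains,
oscillation windows) are expressed in cells on all public interfaces;
physical lengths are recovered by multiplying with ``cell_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HeightMap", "Profile1D", "BinaryMap", "coarsen", "coarsen_profile"]


@dataclass
class HeightMap:
    """Rectangular grid of elevations with a physical cell size.

    Parameters
    ----------
    heights : ndarray of shape (nrows, ncols)
        Elevation values in length units.
    cell_size : float
        Physical edge length of one cell (same length units as heights).
    nodata_mask : ndarray of bool, optional
        True marks an *invalid* cell. None means all cells are valid.
    """

    heights: np.ndarray
    cell_size: float = 1.0
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is not None:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.heights.shape:
                raise ValueError("nodata_mask shape must match heights")
        valid = self.valid_mask
        if min(self.heights.shape) < 2 or valid.sum() < 4:
            raise ValueError("a HeightMap needs at least 2x2 valid cells")
        if not np.all(np.isfinite(self.heights[valid])):
            raise ValueError("valid heights must be finite")

    @property
    def valid_mask(self) -> np.ndarray:
        if self.nodata_mask is None:
            return np.ones(self.heights.shape, dtype=bool)
        return ~self.nodata_mask

    @property
    def has_nodata(self) -> bool:
        return self.nodata_mask is not None and bool(self.nodata_mask.any())

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def valid_heights(self) -> np.ndarray:
        return self.heights[self.valid_mask]


@dataclass
class Profile1D:
    """1D elevation profile with a fixed horizontal sample spacing."""

    heights: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float).ravel()
        if self.heights.size < 2:
            raise ValueError("a Profile1D needs at least 2 samples")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")

    @property
    def n(self) -> int:
        return self.heights.size

    @property
    def extent(self) -> float:
        """Horizontal span covered by the profile."""
        return self.spacing * (self.n - 1)

    @property
    def distances(self) -> np.ndarray:
        return np.arange(self.n) * self.spacing


@dataclass
class BinaryMap:
    """Rectangular 0/1 grid marking membership of a (putatively fractal) set.

    An empty map (no 1-cells) is representable — level-set boundaries of
    uniform maps are legitimately empty — but operations that require a
    non-empty foreground raise on it.  ``is_empty`` is the flag.
    """

    cells: np.ndarray
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if self.cells.ndim != 2:
            raise ValueError("cells must be a 2D array")
        bad = np.setdiff1d(np.unique(self.cells), [0, 1])
        if bad.size:
            raise ValueError(f"cells must contain only 0/1; found values {bad.tolist()}")
        self.cells = self.cells.astype(np.uint8)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    @property
    def is_empty(self) -> bool:
        return not bool(self.cells.any())

    @property
    def foreground_fraction(self) -> float:
        return float(self.cells.mean())


def _block_reduce(a: np.ndarray, factor: int, op) -> np.ndarray:
    nr = a.shape[0] // factor
    nc = a.shape[1] // factor
    trimmed = a[: nr * factor, : nc * factor]
    return op(trimmed.reshape(nr, factor, nc, factor), axis=(1, 3))


def coarsen(hmap: HeightMap, factor: int, method: str = "mean") -> HeightMap:
    """Coarsen a heightmap by an integer factor.

    ``method="mean"`` aggregates blocks by their mean (DEM-resampling
    style); ``method="subsample"`` keeps every ``factor``-th cell (exposed
    for comparison only — it aliases high-frequency relief).  The grid is
    trimmed to the largest multiple of ``factor`` first.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return hmap
    if min(hmap.shape) // factor < 2:
        raise ValueError(f"factor {factor} leaves fewer than 2x2 cells")
    if hmap.has_nodata:
        raise ValueError("cannot coarsen a map with nodata holes")
    if method == "mean":
        z = _block_reduce(hmap.heights, factor, np.mean)
    elif method == "subsample":
        nr = hmap.shape[0] // factor
        nc = hmap.shape[1] // factor
        z = hmap.heights[: nr * factor : factor, : nc * factor : factor]
    else:
        raise ValueError(f"unknown coarsening method {method!r}")
    return HeightMap(z, cell_size=hmap.cell_size * factor)


def coarsen_profile(profile: Profile1D, factor: int) -> Profile1D:
    """Block-mean coarsening of a 1D profile by an integer factor."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return profile
    n = profile.n // factor
    if n < 2:
        raise ValueError(f"factor {factor} leaves fewer than 2 samples")
    z = profile.heights[: n * factor].reshape(n, factor).mean(axis=1)
    return Profile1D(z, spacing=profile.spacing * factor)
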