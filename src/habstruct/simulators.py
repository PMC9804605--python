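"""Synthetic surfaces, profiles and binary sets of known fractal dimension.

Two fractional-Brownian-motion generators are provided: recursive midpoint
displacement (diamond-square) and Fourier synthesis of a Gaussian random
field.  For a Hurst exponent ``H`` in (0, 1) the generated surface has true
fractal dimension ``3 - H``; the boundary of its median excursion set (and
any fBm *curve*) has dimension ``2 - H``.  Analytic fixtures (planes,
sawtooths, hemispheres) supply exact oracles for the geometric metrics.

Reproducibility: each generator takes an integer seed and is a pure
function of its parameters.  Replicated studies derive child seeds
deterministically via :func:`child_seed`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grids import BinaryMap, HeightMap, Profile1D

__all__ = [
    "SimParams",
    "child_seed",
    "midpoint_displacement",
    "midpoint_displacement_profile",
    "spectral_fbm_surface",
    "binarize",
    "level_set_boundary",
    "koch_curve_raster",
    "analytic_fixture",
    "sawtooth_profile",
    "inclined_profile",
    "weierstrass_profile",
]

_MAX_GRID_CELLS = 2**28  # ~16385^2; larger grids refuse to allocate


@dataclass(frozen=True)
class SimParams:
    """Parameters of an fBm simulation.

    hurst: Hurst exponent H, 0 < H < 1.
    level: recursion depth; grids have side 2**level + 1.
    rms_amplitude: standard deviation of the first-level displacement.
    seed: integer RNG seed.
    """

    hurst: float
    level: int
    rms_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ValueError("hurst must lie strictly in (0, 1)")
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if self.rms_amplitude < 0:
            raise ValueError("rms_amplitude must be >= 0")

    @property
    def side(self) -> int:
        return 2**self.level + 1


def child_seed(root_seed: int, *key: int) -> int:
    """Deterministic child seed for a replicate identified by ``key``.

    Uses :class:`numpy.random.SeedSequence` with ``key`` as spawn key, so a
    replicate is reproducible in isolation and independent of the order in
    which replicates run.
    """
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def midpoint_displacement(params: SimParams, cell_size: float = 1.0) -> HeightMap:
    """Diamond-square fractional Brownian surface of side ``2**level + 1``.

    Corners start at 0; both the diamond and the square pass of each
    recursion level add Gaussian displacements whose standard deviation is
    multiplied by ``2**(-hurst)`` per halving of the lateral scale.
    """
    n = params.side
    if n * n > _MAX_GRID_CELLS:
        raise MemoryError(
            f"requested grid {n}x{n} ({n * n} cells) exceeds the allocation limit"
        )
    rng = np.random.default_rng(params.seed)
    z = np.zeros((n, n))
    sigma = params.rms_amplitude
    step = n - 1
    decay = 2.0 ** (-params.hurst)
    while step > 1:
        half = step // 2
        sigma *= decay
        # diamond pass: square centres get the mean of their 4 corners
        c = (
            z[0:-1:step, 0:-1:step]
            + z[step::step, 0:-1:step]
            + z[0:-1:step, step::step]
            + z[step::step, step::step]
        ) / 4.0
        z[half::step, half::step] = c + rng.normal(0.0, sigma, c.shape) if sigma > 0 else c
        # square pass: edge midpoints get the mean of their (up to 4)
        # cardinal neighbours at distance `half`; out-of-grid neighbours
        # are dropped via NaN-padding
        zp = np.pad(z, half, constant_values=np.nan)
        for rows, cols in (
            (np.arange(half, n, step), np.arange(0, n, step)),
            (np.arange(0, n, step), np.arange(half, n, step)),
        ):
            up = zp[np.ix_(rows, cols + half)]
            down = zp[np.ix_(rows + 2 * half, cols + half)]
            left = zp[np.ix_(rows + half, cols)]
            right = zp[np.ix_(rows + half, cols + 2 * half)]
            with np.errstate(invalid="ignore"):
                m = np.nanmean(np.stack([up, down, left, right]), axis=0)
            noise = rng.normal(0.0, sigma, m.shape) if sigma > 0 else 0.0
            z[np.ix_(rows, cols)] = m + noise
        step = half
    return HeightMap(z, cell_size=cell_size)


def midpoint_displacement_profile(params: SimParams, spacing: float = 1.0) -> Profile1D:
    """1D midpoint-displacement fBm profile of length ``2**level + 1``."""
    n = params.side
    rng = np.random.default_rng(params.seed)
    z = np.zeros(n)
    sigma = params.rms_amplitude
    step = n - 1
    decay = 2.0 ** (-params.hurst)
    while step > 1:
        half = step // 2
        sigma *= decay
        mids = (z[0:-1:step] + z[step::step]) / 2.0
        noise = rng.normal(0.0, sigma, mids.shape) if sigma > 0 else 0.0
        z[half::step] = mids + noise
        step = half
    return Profile1D(z, spacing=spacing)


def spectral_fbm_surface(
    params: SimParams, size: int | None = None, cell_size: float = 1.0
) -> HeightMap:
    """Gaussian random field surface by Fourier synthesis.

    The radially averaged power spectrum follows a power law with exponent
    ``-(2H + 2)``, the spectral signature of a 2D fBm surface.  The output
    is zero-mean with standard deviation ``rms_amplitude``.
    """
    if size is None:
        size = params.side
    if size < 3:
        raise ValueError("size must be >= 3")
    if size * size > _MAX_GRID_CELLS:
        raise MemoryError(f"requested grid {size}x{size} exceeds the allocation limit")
    rng = np.random.default_rng(params.seed)
    fx = np.fft.fftfreq(size)
    f = np.hypot(fx[:, None], fx[None, :])
    with np.errstate(divide="ignore"):
        amp = np.where(f > 0, f ** -(params.hurst + 1.0), 0.0)
    spectrum = amp * (rng.standard_normal((size, size)) + 1j * rng.standard_normal((size, size)))
    z = np.fft.ifft2(spectrum).real
    z -= z.mean()
    sd = z.std()
    if sd > 0 and params.rms_amplitude > 0:
        z *= params.rms_amplitude / sd
    else:
        z = np.zeros_like(z)
    return HeightMap(z, cell_size=cell_size)


def binarize(hmap: HeightMap, rule: str | float = "median") -> BinaryMap:
    """Threshold a heightmap into a BinaryMap (1 where height >= threshold).

    ``rule`` is ``"median"``, ``"mean"`` or a fixed numeric threshold.
    With the median rule the two classes differ in count by at most one
    row-length of cells.
    """
    valid = hmap.valid_mask
    if not valid.any():
        raise ValueError("cannot binarize an all-nodata map")
    vals = hmap.heights[valid]
    if rule == "median":
        threshold = float(np.median(vals))
    elif rule == "mean":
        threshold = float(vals.mean())
    elif isinstance(rule, (int, float)):
        threshold = float(rule)
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    cells = (hmap.heights >= threshold) & valid
    return BinaryMap(cells.astype(np.uint8), cell_size=hmap.cell_size)


def level_set_boundary(bmap: BinaryMap) -> BinaryMap:
    """Boundary of a binary set: 1-cells with a 4-neighbour of class 0.

    For a median-thresholded fBm surface this excursion-set boundary is the
    object with fractal dimension ``2 - H``.  A uniform input yields an
    empty boundary (allowed; check ``result.is_empty``).
    """
    c = bmap.cells.astype(bool)
    opposite = np.zeros_like(c)
    opposite[1:, :] |= c[1:, :] & ~c[:-1, :]
    opposite[:-1, :] |= c[:-1, :] & ~c[1:, :]
    opposite[:, 1:] |= c[:, 1:] & ~c[:, :-1]
    opposite[:, :-1] |= c[:, :-1] & ~c[:, 1:]
    return BinaryMap(opposite.astype(np.uint8), cell_size=bmap.cell_size)


def _koch_segments(iterations: int) -> np.ndarray:
    """Vertices of the Koch curve from (0,0) to (1,0), bumping upward."""
    pts = np.array([[0.0, 0.0], [1.0, 0.0]])
    rot = np.array(
        [[math.cos(math.pi / 3), -math.sin(math.pi / 3)],
         [math.sin(math.pi / 3), math.cos(math.pi / 3)]]
    )
    for _ in range(iterations):
        p = pts[:-1]
        q = pts[1:]
        v = (q - p) / 3.0
        a = p + v
        b = p + 2.0 * v
        peak = a + v @ rot.T
        new = np.empty((p.shape[0] * 4 + 1, 2))
        new[0:-1:4] = p
        new[1::4] = a
        new[2::4] = peak
        new[3::4] = b
        new[-1] = pts[-1]
        pts = new
    return pts


def koch_curve_raster(
    iterations: int, raster_size: int, cell_size: float = 1.0, margin: int = 0
) -> BinaryMap:
    """Rasterize an iterated Koch curve (4**iterations segments) onto a grid.

    Every cell the ideal polyline passes through is set (no anti-aliasing,
    so box counts are threshold-free).  The curve spans ``raster_size``
    columns; rows cover its vertical span.  ``margin`` adds that many empty
    cells on every side — when box-counting with random origins, a margin
    at least as large as the biggest box keeps edge-straddling (excluded)
    boxes free of foreground, so no part of the curve is ever dropped.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    min_size = 2 * 3**iterations
    if raster_size < min_size:
        raise ValueError(
            f"raster_size {raster_size} too coarse for {iterations} iterations; "
            f"need at least {min_size} so the smallest segment spans >= 2 cells"
        )
    pts = _koch_segments(iterations)
    scale = raster_size - 1
    xy = pts * scale
    height = int(np.ceil(xy[:, 1].max())) + 1
    cells = np.zeros((height, raster_size), dtype=np.uint8)
    p = xy[:-1]
    q = xy[1:]
    seg_len = np.hypot(*(q - p).T)
    # dense supersampling: >=4 samples per cell traversed guarantees every
    # crossed cell is hit for these shallow-sloped segments
    n_samples = np.maximum(2, np.ceil(seg_len * 4).astype(int))
    for (x0, y0), (x1, y1), ns in zip(p, q, n_samples):
        t = np.linspace(0.0, 1.0, ns)
        cols = np.clip(np.rint(x0 + t * (x1 - x0)).astype(int), 0, raster_size - 1)
        rows = np.clip(np.rint(y0 + t * (y1 - y0)).astype(int), 0, height - 1)
        cells[rows, cols] = 1
    if margin:
        cells = np.pad(cells, margin)
    # flip so the curve baseline is at the bottom row (image convention)
    return BinaryMap(cells[::-1], cell_size=cell_size)


def analytic_fixture(
    kind: str,
    size: int = 65,
    cell_size: float = 1.0,
    *,
    angle: float = 30.0,
    amplitude: float = 1.0,
    period: float = 8.0,
    value: float = 0.0,
) -> HeightMap:
    """Closed-form oracle surfaces for rugosity / terrain-metric tests.

    kind: ``flat`` (constant ``value``), ``inclined_plane`` (tilt ``angle``
    degrees along columns), ``sawtooth`` (triangle wave along columns with
    ``amplitude`` and ``period`` in length units) or ``hemisphere``
    (radius spanning the grid).  Heights are exact at cell centres.
    """
    if size < 2:
        raise ValueError("size must be >= 2")
    x = np.arange(size) * cell_size
    if kind == "flat":
        z = np.full((size, size), float(value))
    elif kind == "inclined_plane":
        if not 0.0 <= angle < 90.0:
            raise ValueError("inclined_plane angle must be in [0, 90) degrees")
        z = np.tile(np.tan(np.radians(angle)) * x, (size, 1))
    elif kind == "sawtooth":
        if amplitude < 0 or period <= 0:
            raise ValueError("sawtooth needs amplitude >= 0 and period > 0")
        phase = np.mod(x, period) / period
        tri = 1.0 - np.abs(2.0 * phase - 1.0)  # triangle wave in [0, 1]
        z = np.tile(amplitude * tri, (size, 1))
    elif kind == "hemisphere":
        radius = (size - 1) * cell_size / 2.0
        cx = (size - 1) * cell_size / 2.0
        d2 = (x[None, :] - cx) ** 2 + (x[:, None] - cx) ** 2
        z = np.sqrt(np.maximum(0.0, radius**2 - d2))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return HeightMap(z, cell_size=cell_size)


def sawtooth_profile(
    amplitude: float, period_samples: int, n_periods: int = 8, spacing: float = 1.0
) -> Profile1D:
    """Triangle-wave profile; contour length per period is
    ``2 * sqrt((p/2)**2 + amplitude**2)`` with ``p = period_samples * spacing``."""
    if period_samples < 2 or period_samples % 2:
        raise ValueError("period_samples must be an even integer >= 2")
    half = period_samples // 2
    up = np.linspace(0.0, amplitude, half + 1)
    one = np.concatenate([up[:-1], up[::-1][:-1]])
    z = np.concatenate([np.tile(one, n_periods), [0.0]])
    return Profile1D(z, spacing=spacing)


def inclined_profile(angle: float, n: int = 65, spacing: float = 1.0) -> Profile1D:
    """Straight line at ``angle`` degrees; rugosity oracle 1/cos(angle)."""
    if not 0.0 <= angle < 90.0:
        raise ValueError("angle must be in [0, 90) degrees")
    z = np.tan(np.radians(angle)) * np.arange(n) * spacing
    return Profile1D(z, spacing=spacing)


def weierstrass_profile(
    hurst: float,
    n: int = 1025,
    spacing: float = 1.0,
    n_terms: int = 30,
    b: float = 1.5,
    seed: int = 0,
) -> Profile1D:
    # Optional fixture only: truncated random-phase cosine series
    # sum_k b^(-k*hurst) * cos(b^k * t + phi_k). Excluded from acceptance.
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, n_terms)
    t = np.linspace(0.0, 2.0 * np.pi, n)
    k = np.arange(n_terms)
    z = np.sum(b ** (-k[:, None] * hurst) * np.cos(b ** k[:, None] * t[None, :] + phases[:, None]), axis=0)
    return Profile1D(z, spacing=spacing)
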