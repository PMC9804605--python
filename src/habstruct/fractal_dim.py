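"""Fractal dimension estimation: box-counting and the variation method.

Box-counting regresses ``log N(eps)`` on ``log eps`` over a chosen scale
window; the estimate is minus the slope.  Known biases of the naive
protocol (full scale range, fixed origin) are mitigated by averaging over
random grid origins, excluding boxes that straddle the map edge, and
restricting the fit to an intermediate scale window
(:func:`intermediate_scale_rule`).  The naive protocol is retained
deliberately so bias studies can contrast the two.

The variation method measures the mean height oscillation (windowed
max - min) at a set of window half-widths; for an fBm surface the
oscillation scales as ``eps**H`` so the dimension is
``embed_dim - slope``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .grids import BinaryMap, HeightMap, Profile1D

__all__ = [
    "ScalingCurve",
    "DimensionEstimate",
    "FractalityReport",
    "dyadic_epsilons",
    "box_count",
    "fit_dimension",
    "intermediate_scale_rule",
    "variation_curve",
    "variation_dimension",
    "assess_fractality",
]


@dataclass
class ScalingCurve:
    """(scale, statistic) pairs from a box-counting or oscillation sweep."""

    epsilons: np.ndarray
    statistics: np.ndarray
    statistic_kind: str  # "box_count" | "oscillation"
    n_origins: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.epsilons = np.asarray(self.epsilons, dtype=float)
        self.statistics = np.asarray(self.statistics, dtype=float)
        if self.epsilons.size != self.statistics.size:
            raise ValueError("epsilons and statistics must have equal length")
        if self.epsilons.size and np.any(np.diff(self.epsilons) <= 0):
            raise ValueError("epsilons must be strictly increasing")
        if self.statistic_kind not in ("box_count", "oscillation"):
            raise ValueError(f"unknown statistic_kind {self.statistic_kind!r}")

    def subset(self, eps_min: float, eps_max: float) -> "ScalingCurve":
        sel = (self.epsilons >= eps_min) & (self.epsilons <= eps_max)
        return ScalingCurve(
            self.epsilons[sel], self.statistics[sel], self.statistic_kind,
            n_origins=self.n_origins, seed=self.seed,
        )


@dataclass
class DimensionEstimate:
    """Fitted fractal dimension with provenance and fit diagnostics."""

    d_hat: float
    intercept: float
    std_error: float
    scale_range: tuple[float, float]
    r_squared: float
    diagnostics: dict = field(default_factory=dict)
    method: str = "box_naive"
    embed_dim: int = 2

    def __post_init__(self) -> None:
        if self.scale_range[0] >= self.scale_range[1]:
            raise ValueError("scale_range must satisfy eps_min < eps_max")


@dataclass
class FractalityReport:
    orders_of_magnitude: float
    piecewise_fits: tuple[DimensionEstimate, DimensionEstimate]
    d_difference: float
    sufficient_range: bool


def dyadic_epsilons(side: int, eps_min: int = 2, eps_max: int | None = None) -> np.ndarray:
    """Powers of two from ``eps_min`` up to ``eps_max`` (default side // 2)."""
    if eps_max is None:
        eps_max = side // 2
    eps = 2 ** np.arange(int(math.floor(math.log2(eps_min))), int(math.log2(eps_max)) + 1)
    eps = eps[(eps >= eps_min) & (eps <= eps_max)]
    if eps.size == 0:
        raise ValueError("no dyadic scales in the requested range")
    return eps.astype(int)


def _count_boxes(cells: np.ndarray, eps: int, origin: tuple[int, int]) -> int:
    """Occupied-box count for one grid origin; edge-straddling boxes excluded."""
    orow, ocol = origin
    nbr = (cells.shape[0] - orow) // eps
    nbc = (cells.shape[1] - ocol) // eps
    if nbr < 1 or nbc < 1:
        raise ValueError(f"box size {eps} with origin {origin} leaves no complete box")
    sub = cells[orow : orow + nbr * eps, ocol : ocol + nbc * eps]
    occupied = sub.reshape(nbr, eps, nbc, eps).any(axis=(1, 3))
    return int(occupied.sum())


def box_count(
    bmap: BinaryMap,
    epsilons: np.ndarray | list | None = None,
    n_origins: int = 1,
    seed: int = 0,
    random_origins: bool = True,
) -> ScalingCurve:
    """Box-count a binary map at each scale, averaging over grid origins.

    Origins are drawn uniformly from ``[0, eps)^2``; with
    ``random_origins=False`` the single origin (0, 0) is used (the naive
    protocol).  Only boxes lying entirely inside the map are counted.
    """
    if bmap.is_empty:
        raise ValueError("box_count requires a non-empty foreground")
    side = min(bmap.shape)
    if epsilons is None:
        epsilons = dyadic_epsilons(side)
    epsilons = np.asarray(epsilons, dtype=int)
    if np.any(epsilons < 1) or np.any(epsilons > side // 2):
        raise ValueError("every box size must satisfy 1 <= eps <= half the shorter side")
    if n_origins < 1:
        raise ValueError("n_origins must be >= 1")
    rng = np.random.default_rng(seed)
    cells = bmap.cells.astype(bool)
    means = np.empty(epsilons.size)
    for i, eps in enumerate(epsilons):
        if random_origins:
            origins = rng.integers(0, eps, size=(n_origins, 2))
        else:
            origins = np.zeros((n_origins, 2), dtype=int)
        counts = [_count_boxes(cells, int(eps), (int(r), int(c))) for r, c in origins]
        means[i] = float(np.mean(counts))
    if np.any(means < 1):
        raise ValueError("a box grid missed the foreground entirely; map too sparse")
    return ScalingCurve(epsilons, means, "box_count", n_origins=n_origins, seed=seed)


def _regression_diagnostics(log_eps: np.ndarray, resid: np.ndarray, alpha: float) -> dict:
    """Boolean flags for linearity, homoskedasticity and residual normality."""
    flags = {"nonlinearity": False, "heteroskedasticity": False, "non_normal_residuals": False}
    n = resid.size
    if n >= 4:
        # quadratic-term t-test on the residuals
        x = log_eps - log_eps.mean()
        design = np.column_stack([np.ones(n), x, x**2])
        coef, res_ss, rank, _ = np.linalg.lstsq(design, resid, rcond=None)
        dof = n - 3
        if dof > 0 and res_ss.size:
            mse = float(res_ss[0]) / dof
            cov = mse * np.linalg.inv(design.T @ design)
            se = math.sqrt(max(cov[2, 2], 1e-300))
            t = coef[2] / se
            p = 2.0 * stats.t.sf(abs(t), dof)
            flags["nonlinearity"] = bool(p < alpha)
        # Breusch-Pagan-type score: regress squared residuals on log eps
        r2 = resid**2
        if np.var(r2) > 0:
            slope_res = stats.linregress(log_eps, r2)
            flags["heteroskedasticity"] = bool(slope_res.pvalue < alpha)
    if n >= 3 and np.ptp(resid) > 0:
        try:
            flags["non_normal_residuals"] = bool(stats.shapiro(resid).pvalue < alpha)
        except ValueError:
            pass
    return flags


def fit_dimension(
    curve: ScalingCurve,
    scale_range: tuple[float, float] | None = None,
    embed_dim: int = 2,
    method: str | None = None,
    alpha: float = 0.05,
) -> DimensionEstimate:
    """OLS fit of ``log(statistic)`` on ``log(eps)`` over ``scale_range``.

    For box counts ``d_hat = -slope``; for oscillation curves
    ``d_hat = embed_dim - slope``.  Unweighted OLS is used deliberately;
    assumption violations are reported as diagnostic flags, not silently
    corrected.
    """
    if scale_range is None:
        scale_range = (float(curve.epsilons[0]), float(curve.epsilons[-1]))
    sub = curve.subset(*scale_range)
    if sub.epsilons.size < 3:
        raise ValueError(
            f"need >= 3 scales inside {scale_range}; found {sub.epsilons.size}"
        )
    if np.any(sub.statistics <= 0):
        raise ValueError("zero statistic inside the fit range; dimension undefined")
    log_eps = np.log(sub.epsilons)
    log_stat = np.log(sub.statistics)
    res = stats.linregress(log_eps, log_stat)
    if curve.statistic_kind == "box_count":
        d_hat = -res.slope
        default_method = "box_naive"
    else:
        d_hat = embed_dim - res.slope
        default_method = "variation_naive"
    resid = log_stat - (res.intercept + res.slope * log_eps)
    r_squared = float(res.rvalue**2) if np.ptp(log_stat) > 0 else 1.0
    return DimensionEstimate(
        d_hat=float(d_hat),
        intercept=float(res.intercept),
        std_error=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        scale_range=(float(sub.epsilons[0]), float(sub.epsilons[-1])),
        r_squared=r_squared,
        diagnostics=_regression_diagnostics(log_eps, resid, alpha),
        method=method or default_method,
        embed_dim=embed_dim,
    )


def intermediate_scale_rule(map_side: int) -> tuple[int, int]:
    """Intermediate box-size window, proportional to the map side.

    Returns ``(round(side/128), round(side/32))`` — the 32-128 cell window
    for a side of 4097, rescaled — with both bounds clamped to >= 2 cells.
    Raises if fewer than 3 dyadic scales fit inside the window.
    """
    if map_side < 64:
        raise ValueError("map_side must be >= 64")
    lo = max(2, round(map_side / 128))
    hi = max(2, round(map_side / 32))
    n_dyadic = sum(1 for k in range(0, 64) if lo <= 2**k <= hi)
    if n_dyadic < 3:
        raise ValueError(
            f"intermediate window ({lo}, {hi}) admits {n_dyadic} dyadic scales; "
            "use a larger map (side >= ~256)"
        )
    return lo, hi


def _oscillation_mean(z: np.ndarray, eps: int) -> float:
    """Mean of (max - min) over square windows of half-width eps,
    truncated at the array edges."""
    size = 2 * eps + 1
    if z.ndim == 1:
        hi = ndimage.maximum_filter1d(z, size, mode="constant", cval=-np.inf)
        lo = ndimage.minimum_filter1d(z, size, mode="constant", cval=np.inf)
    else:
        hi = ndimage.maximum_filter(z, size=size, mode="constant", cval=-np.inf)
        lo = ndimage.minimum_filter(z, size=size, mode="constant", cval=np.inf)
    return float((hi - lo).mean())


def variation_curve(
    obj: HeightMap | Profile1D, epsilons: np.ndarray | list | None = None
) -> ScalingCurve:
    """Mean-oscillation V(eps) sweep over window half-widths in cells."""
    if isinstance(obj, HeightMap):
        if obj.has_nodata:
            raise ValueError("variation method requires a map without nodata holes")
        z = obj.heights
        side = min(z.shape)
    else:
        z = obj.heights
        side = z.size
    if epsilons is None:
        epsilons = dyadic_epsilons(side, eps_min=1, eps_max=max(2, side // 8))
    epsilons = np.asarray(epsilons, dtype=int)
    if np.any(epsilons < 1):
        raise ValueError("oscillation windows must be >= 1 cell")
    v = np.array([_oscillation_mean(z, int(e)) for e in epsilons])
    return ScalingCurve(epsilons, v, "oscillation")


def variation_dimension(
    obj: HeightMap | Profile1D,
    epsilons: np.ndarray | list | None = None,
    scale_range: tuple[float, float] | None = None,
    embed_dim: int | None = None,
    method: str | None = None,
) -> DimensionEstimate:
    """Variation-method dimension: ``embed_dim - slope`` of log V vs log eps.

    ``embed_dim`` defaults to 3 for surfaces and 2 for profiles.  A flat
    input (zero oscillation at every scale) has no defined dimension and
    raises.
    """
    if embed_dim is None:
        embed_dim = 3 if isinstance(obj, HeightMap) else 2
    curve = variation_curve(obj, epsilons)
    if np.all(curve.statistics == 0):
        raise ValueError("flat input: oscillation is zero at every scale, dimension undefined")
    return fit_dimension(curve, scale_range=scale_range, embed_dim=embed_dim, method=method)


def assess_fractality(curve: ScalingCurve, split: float, embed_dim: int = 2) -> FractalityReport:
    """Piecewise fits below/above ``split`` plus the 2-3 decade range check."""
    eps = curve.epsilons
    if not (eps[0] < split < eps[-1]):
        raise ValueError(f"split {split} lies outside the measured range [{eps[0]}, {eps[-1]}]")
    low = curve.subset(eps[0], split)
    high_start = float(eps[eps > split][0]) if np.any(eps > split) else split
    high = curve.subset(high_start, eps[-1])
    if low.epsilons.size < 3 or high.epsilons.size < 3:
        raise ValueError("need >= 3 entries on each side of the split")
    fit_low = fit_dimension(low, embed_dim=embed_dim)
    fit_high = fit_dimension(high, embed_dim=embed_dim)
    orders = float(np.log10(eps[-1] / eps[0]))
    return FractalityReport(
        orders_of_magnitude=orders,
        piecewise_fits=(fit_low, fit_high),
        d_difference=abs(fit_low.d_hat - fit_high.d_hat),
        sufficient_range=bool(orders >= 2.0),
    )
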