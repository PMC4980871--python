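"""Correlation-integral machinery: C(r), the multiscale dimension D(r), and
a Grassberger-Procaccia-style slope fit.

C(r) is the empirical CDF of pairwise distances; the multiscale function
D(r) = d log C / d log r gives the apparent dimension at each length scale
and is the main diagnostic for noise, boundary and curvature effects.  The
r -> 0 limit of D(r) is the classical correlation dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .metrics import DistanceSet
from .shapes import analytic_hypersphere_density

__all__ = [
    "ScalingProfile",
    "correlation_sum",
    "scaling_dimension",
    "gp_dimension",
    "analytic_hypersphere_Dr",
    "default_r_grid",
]


@dataclass
class ScalingProfile:
    """r grid with the correlation sum C(r) and local slope D(r)."""

    r_grid: np.ndarray
    C_values: np.ndarray
    D_values: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.C_values = np.asarray(self.C_values, dtype=float)
        if np.any(np.diff(self.r_grid) <= 0):
            raise ValueError("r_grid must be strictly increasing")
        if np.any(self.C_values < 0) or np.any(self.C_values > 1):
            raise ValueError("C values must lie in [0, 1]")


def default_r_grid(dist: DistanceSet, n_grid: int = 200) -> np.ndarray:
    """Log-spaced grid between the 0.1th-percentile and maximum distance.

    Exact-zero distances (duplicate points) are excluded from the
    percentile so the log grid stays finite.
    """
    vals = dist.values[dist.values > 0]
    if len(vals) == 0:
        raise ValueError("all distances are zero")
    lo = np.quantile(vals, 1e-3)
    hi = vals.max()
    if lo >= hi:
        lo = hi / 10
    return np.geomspace(lo, hi, n_grid)


def correlation_sum(dist: DistanceSet, r_grid: np.ndarray | None = None,
                    n_grid: int = 200) -> ScalingProfile:
    """Correlation sum C(r) = (# pairs with d <= r) / (# pairs).

    The normalization over distinct pairs i < j matches the classical
    2/(N(N-1)) prefactor.  Computed by sorting the condensed distances once
    and bisecting, so arbitrary grids are cheap.
    """
    if dist.n_points < 2:
        raise ValueError("need at least 2 points")
    if r_grid is None:
        r_grid = default_r_grid(dist, n_grid)
    else:
        r_grid = np.asarray(r_grid, dtype=float)
        if r_grid.size == 0:
            raise ValueError("empty r grid")
        if np.any(r_grid <= 0) or np.any(np.diff(r_grid) <= 0):
            raise ValueError("r_grid must be positive and strictly increasing")
    sorted_d = np.sort(dist.values)
    counts = np.searchsorted(sorted_d, r_grid, side="right")
    C = counts / len(sorted_d)
    n_zero = int(np.searchsorted(sorted_d, 0.0, side="right"))
    return ScalingProfile(r_grid, C,
                          meta={"metric_tag": dist.metric_tag,
                                "n_points": dist.n_points,
                                "n_zero_distances": n_zero})


def scaling_dimension(profile: ScalingProfile, smooth_window: int = 5,
                      ) -> ScalingProfile:
    """Fill D(r) = d log C / d log r by centered finite differences.

    Grid points with C = 0 are excluded from the differentiation (their
    D value is NaN).  The raw slope is smoothed with a centered moving
    average of ``smooth_window`` grid points; negative smoothed slopes
    (possible only through smoothing artifacts, since C is nondecreasing)
    are clipped to 0 and counted in ``meta``.
    """
    pos = profile.C_values > 0
    if pos.sum() < 10:
        raise ValueError("need >= 10 grid points with C > 0")
    lr = np.log(profile.r_grid[pos])
    lC = np.log(profile.C_values[pos])
    slope = np.gradient(lC, lr)
    if smooth_window > 1:
        w = min(smooth_window, len(slope))
        kernel = np.ones(w) / w
        sm = np.convolve(slope, kernel, mode="same")
        # renormalize the edges where the kernel hangs off the array
        norm = np.convolve(np.ones_like(slope), kernel, mode="same")
        slope = sm / norm
    n_clipped = int((slope < 0).sum())
    slope = np.maximum(slope, 0.0)
    D = np.full_like(profile.C_values, np.nan)
    D[pos] = slope
    meta = dict(profile.meta)
    meta.update(smooth_window=smooth_window, n_clipped_slopes=n_clipped)
    return ScalingProfile(profile.r_grid, profile.C_values, D, meta)


def gp_dimension(profile: ScalingProfile, r_range: tuple | None = None,
                 min_pairs_per_bin: int = 10) -> dict:
    """Ordinary least-squares slope of log C vs log r over a linear region.

    If ``r_range`` is not given, the fit runs over the smallest decade of r
    whose grid bins are all populated by at least ``min_pairs_per_bin``
    pairs.  The linear-region choice is a heuristic -- the fit diagnostics
    (r^2, residuals, range used) are always returned so it can be audited
    or overridden.
    """
    n_pairs_total = None
    if "n_points" in profile.meta:
        n = profile.meta["n_points"]
        n_pairs_total = n * (n - 1) // 2
    pos = profile.C_values > 0
    r, C = profile.r_grid[pos], profile.C_values[pos]
    if r_range is None:
        if n_pairs_total is not None:
            bin_pairs = np.diff(np.concatenate([[0], C * n_pairs_total]))
            ok = bin_pairs >= min_pairs_per_bin
        else:
            ok = np.ones_like(r, dtype=bool)
        start_candidates = np.flatnonzero(ok)
        if len(start_candidates) == 0:
            raise ValueError("no well-populated region found")
        r_lo = r[start_candidates[0]]
        r_range = (r_lo, min(10 * r_lo, r[-1]))
    mask = (r >= r_range[0]) & (r <= r_range[1])
    if mask.sum() < 5:
        raise ValueError(f"fewer than 5 grid points in range {r_range}")
    x, y = np.log(r[mask]), np.log(C[mask])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return {"slope": float(slope), "intercept": float(intercept),
            "r_squared": float(r2), "r_range": (float(r_range[0]),
                                                float(r_range[1])),
            "n_points_fit": int(mask.sum()),
            "max_abs_residual": float(np.abs(resid).max())}


def analytic_hypersphere_Dr(D: float, r_grid: np.ndarray) -> ScalingProfile:
    """Exact multiscale dimension of the D-hypersphere geodesic metric.

    D(r) = r p(r) / C(r) with p proportional to sin^(D-1); C by adaptive
    quadrature.  D(r) -> D as r -> 0 and decays to 0 at r = pi.
    """
    r = np.asarray(r_grid, dtype=float)
    if np.any(r <= 0) or np.any(r > np.pi + 1e-12):
        raise ValueError("r_grid must lie in (0, pi]")
    p = analytic_hypersphere_density(D, r)
    C = np.array([quad(lambda t: analytic_hypersphere_density(D, t), 0.0, ri,
                       limit=200)[0] for ri in np.minimum(r, np.pi)])
    Dr = r * p / C
    return ScalingProfile(r, np.clip(C, 0.0, 1.0), Dr,
                          meta={"analytic": True, "dim": D})
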