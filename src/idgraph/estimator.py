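"""Intrinsic-dimension estimation from the pairwise-distance density p(r).

The estimator characterizes p(r) around its maximum, where the empirical
density is insensitive to the sampling fluctuations that plague short
distances (the curse of dimensionality):

* ``gaussian_left_fit`` -- a quadratic fit of log p(r) vs r over the window
  [r_MAX - c*s, r_MAX] (s = standard deviation of the distance sample)
  yields the curvature a = -1/(2 sigma^2) of the best-approximating
  Gaussian and the dimensionless ratio R = r_MAX / sigma, which grows
  monotonically with the intrinsic dimension.
* ``fit_d`` -- after rescaling distances by pi/(2 r_MAX), the left flank of
  p(r) is matched by least squares against the geodesic-distance density of
  the D-dimensional unit hypersphere, C sin^(D-1)(x), with D continuous.
* ``rmsd_scan`` -- the same comparison over integer D; the global minimum
  of RMSD(D) is the integer estimate D_min.
* ``analytic_R_of_D`` / ``invert_R`` -- the deterministic R <-> D relation
  obtained by applying the identical finite-window fit to the analytic
  hypersphere density.

All estimates are invariant under a global rescaling of the distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize_scalar

from .metrics import DistanceSet
from .shapes import PointCloud, analytic_hypersphere_density

__all__ = [
    "DEFAULT_WINDOW_MULT",
    "DistanceDensity",
    "GaussianLeftFit",
    "IDEstimate",
    "estimate_density",
    "gaussian_left_fit",
    "hypersphere_model",
    "fit_d",
    "rmsd_scan",
    "analytic_R_of_D",
    "invert_R",
    "estimate_id",
]

#: Width of the left-side fit window in units of the sample standard
#: deviation.  Calibrated once, deterministically, so that the analytic
#: R(D) relation reproduces its reference values at D = 2 and D = 10
#: (see docs/methods.md); not a free parameter of the method.
DEFAULT_WINDOW_MULT = 2.1

_D_BOUNDS = (1.0, 100.0)


class FitError(RuntimeError):
    """Raised when a density or curvature fit is ill-posed."""


@dataclass
class DistanceDensity:
    """Histogram density of pairwise distances with its key summaries.

    ``r_max_pos`` is the center of the maximal bin after a 3-bin moving
    average (ties broken toward small r); ``spread_s`` is the standard
    deviation of the full distance sample.  ``plateau`` flags a density so
    flat that the maximum location is not meaningful.
    """

    bin_centers: np.ndarray
    p_values: np.ndarray
    counts: np.ndarray
    bin_width: float
    r_max_pos: float
    spread_s: float
    n_pairs: int
    metric_tag: str = "user"
    plateau: bool = False

    def integral(self) -> float:
        return float(self.p_values.sum() * self.bin_width)


@dataclass
class GaussianLeftFit:
    """Result of the quadratic fit of log p(r) on the left of the maximum."""

    sigma: float
    ratio_R: float
    curvature_a: float
    window: tuple
    n_bins_fit: int


@dataclass
class IDEstimate:
    """Full structured report of one intrinsic-dimension estimation."""

    sigma: float
    curvature_a: float
    ratio_R: float
    d_fit: float
    d_fit_residual: float
    d_min: int
    rmsd_curve: dict
    d_from_R: Optional[float]
    r_max: float
    spread_s: float
    n_pairs: int
    settings: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def estimate_density(dist: DistanceSet, bins: int | None = None,
                     ) -> DistanceDensity:
    """Histogram density of a distance set.

    Default bin count is ``min(200, ceil(sqrt(n_pairs)))`` equal-width
    bins; integer-valued (Hamming) distances get unit-width bins centered
    on the integers instead, so the discreteness never aliases.
    """
    vals = dist.values
    if len(vals) < 2:
        raise ValueError("need at least 2 pairwise distances")
    if len(vals) < 100:
        warnings.warn(f"only {len(vals)} pairwise distances; the density "
                      "estimate will be noisy", stacklevel=2)
    if np.ptp(vals) == 0:
        raise FitError("all pairwise distances are identical; "
                       "density is degenerate")
    integer_metric = dist.metric_tag == "hamming" or (
        bins is None and np.all(vals == np.round(vals)) and np.ptp(vals) < 1e4)
    if integer_metric and bins is None:
        lo, hi = int(vals.min()), int(vals.max())
        edges = np.arange(lo - 0.5, hi + 1.5)
    else:
        n_bins = bins if bins is not None else min(
            200, int(np.ceil(np.sqrt(len(vals)))))
        edges = np.linspace(vals.min(), vals.max(), n_bins + 1)
    counts, edges = np.histogram(vals, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = float(edges[1] - edges[0])
    p = counts / (counts.sum() * width)
    smoothed = _moving_average(counts.astype(float), 3)
    peak = smoothed.max()
    r_max = float(centers[int(np.argmax(smoothed))])
    # a maximum is "ill-defined" when most bins sit within counting noise
    # (Poisson ~ sqrt(peak)) of the top -- i.e. the density is a plateau
    near_peak = smoothed >= peak - 4.0 * np.sqrt(peak + 1.0)
    plateau = bool(near_peak.mean() > 0.5)
    return DistanceDensity(centers, p, counts, width, r_max,
                           float(vals.std()), len(vals),
                           metric_tag=dist.metric_tag, plateau=plateau)


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1 or len(x) < w:
        return x
    kernel = np.ones(w)
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    return np.convolve(x, kernel, mode="same") / norm


def gaussian_left_fit(density: DistanceDensity,
                      window_mult: float = DEFAULT_WINDOW_MULT,
                      ) -> GaussianLeftFit:
    """Quadratic fit of log p(r) vs r over [r_MAX - window_mult*s, r_MAX].

    The fit is weighted by the bin counts, so well-populated bins near the
    maximum dominate.  The quadratic coefficient a must be negative
    (concave log-density); then sigma = sqrt(-1/(2a)) and R = r_MAX/sigma.
    """
    lo = density.r_max_pos - window_mult * density.spread_s
    mask = ((density.bin_centers >= lo)
            & (density.bin_centers <= density.r_max_pos)
            & (density.p_values > 0))
    if mask.sum() < 5:
        raise FitError(f"only {int(mask.sum())} populated bins in the fit "
                       f"window [{lo:.4g}, {density.r_max_pos:.4g}]; "
                       "need >= 5")
    r = density.bin_centers[mask]
    log_p = np.log(density.p_values[mask])
    w = density.counts[mask].astype(float)
    a, b, c = np.polyfit(r, log_p, 2, w=w)
    if a >= 0:
        raise FitError(f"non-concave quadratic fit (a = {a:.4g}); the "
                       "density has no Gaussian-like left flank in the "
                       f"window [{lo:.4g}, {density.r_max_pos:.4g}] "
                       f"({int(mask.sum())} bins)")
    sigma = float(np.sqrt(-1.0 / (2.0 * a)))
    return GaussianLeftFit(sigma, density.r_max_pos / sigma, float(a),
                           (float(lo), float(density.r_max_pos)),
                           int(mask.sum()))


def hypersphere_model(x_grid: np.ndarray, D: float,
                      bin_width: float | None = None) -> np.ndarray:
    """Hypersphere-density model sin^(D-1)(x) renormalized over the grid.

    ``x_grid`` is the rescaled distance x = r * pi / (2 r_MAX), restricted
    to (0, pi].  With ``bin_width`` the renormalization treats the grid as
    histogram bin centers (sum * width = 1); otherwise trapezoidal.
    """
    if D <= 0:
        raise ValueError(f"D must be > 0, got {D}")
    x = np.asarray(x_grid, dtype=float)
    if np.any(x <= 0) or np.any(x > np.pi + 1e-12):
        raise ValueError("x_grid must lie in (0, pi]")
    vals = np.sin(np.minimum(x, np.pi)) ** (D - 1.0)
    if bin_width is not None:
        norm = vals.sum() * bin_width
    else:
        norm = np.trapezoid(vals, x)
    if norm <= 0:
        raise FitError(f"model density vanishes on the window for D={D}")
    return vals / norm


def _left_window(density: DistanceDensity):
    mask = ((density.bin_centers <= density.r_max_pos)
            & (density.p_values > 0))
    if mask.sum() < 3:
        raise FitError("fewer than 3 populated bins left of the maximum")
    x = density.bin_centers[mask] * np.pi / (2.0 * density.r_max_pos)
    width = density.bin_width * np.pi / (2.0 * density.r_max_pos)
    emp = density.p_values[mask]
    emp = emp / (emp.sum() * width)
    return x, width, emp


def _model_sse(x, width, emp, D) -> float:
    mod = hypersphere_model(x, D, bin_width=width)
    return float(np.sum((emp - mod) ** 2))


def fit_d(density: DistanceDensity) -> tuple:
    """Continuous least-squares dimension from the hypersphere model.

    Both the empirical density (bins with center <= r_MAX) and the model
    are renormalized to unit mass over that left window, which removes the
    dependence on the geometry-specific right tail.  The optimizer runs a
    coarse scan over integer D followed by a bounded refinement, making the
    result deterministic even when the residual is flat at large D.

    Returns ``(d_fit, residual, flag)`` where ``flag`` marks an optimizer
    pinned at the bounds.
    """
    x, width, emp = _left_window(density)
    grid = np.arange(1, int(_D_BOUNDS[1]) + 1, dtype=float)
    sse = np.array([_model_sse(x, width, emp, D) for D in grid])
    best = grid[int(np.argmin(sse))]
    lo = max(_D_BOUNDS[0], best - 2.0)
    hi = min(_D_BOUNDS[1], best + 2.0)
    res = minimize_scalar(lambda D: _model_sse(x, width, emp, D),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-5})
    d_fit = float(res.x)
    flag = None
    if d_fit <= _D_BOUNDS[0] + 1e-3 or d_fit >= _D_BOUNDS[1] - 1e-3:
        flag = "d_fit_at_bounds"
    return d_fit, float(res.fun), flag


def rmsd_scan(density: DistanceDensity, d_range: tuple = (1, 30)) -> tuple:
    """RMSD between the empirical and model densities over integer D.

    Same window and normalization as :func:`fit_d`.  Returns
    ``(d_min, curve)`` with ``curve = {"d": [...], "rmsd": [...]}``; ties
    are broken toward the smallest D.
    """
    lo, hi = int(d_range[0]), int(d_range[1])
    if not (1 <= lo < hi <= 100) or hi - lo + 1 < 3:
        raise ValueError(f"d_range must span >= 3 integers inside [1, 100], "
                         f"got {d_range}")
    x, width, emp = _left_window(density)
    ds = np.arange(lo, hi + 1)
    rmsd = np.array([np.sqrt(_model_sse(x, width, emp, D) / len(x))
                     for D in ds])
    d_min = int(ds[int(np.argmin(rmsd))])
    return d_min, {"d": ds.tolist(), "rmsd": rmsd.tolist()}


# --------------------------------------------------------------------------
# deterministic R <-> D relation on the analytic hypersphere density
# --------------------------------------------------------------------------

def analytic_R_of_D(D: float, window_mult: float = DEFAULT_WINDOW_MULT,
                    grid_size: int = 4001) -> float:
    """Ratio R = r_MAX/sigma for the exact sin^(D-1) geodesic density.

    The identical finite-window quadratic fit used on empirical histograms
    is applied to the analytic density tabulated on a fine grid over
    [0, pi], with the density values playing the role of the bin-count
    weights.  Grid-converged: doubling ``grid_size`` moves R by < 1e-3.
    """
    if D <= 1:
        raise ValueError("analytic_R_of_D requires D > 1 (the D = 1 "
                         "density is flat and has no curvature)")
    r = np.linspace(0.0, np.pi, grid_size)
    p = analytic_hypersphere_density(D, r)
    mean = np.trapezoid(r * p, r)
    s = np.sqrt(np.trapezoid((r - mean) ** 2 * p, r))
    r_max = r[int(np.argmax(p))]
    mask = (r >= r_max - window_mult * s) & (r <= r_max) & (p > 0)
    a, _, _ = np.polyfit(r[mask], np.log(p[mask]), 2, w=p[mask])
    if a >= 0:  # pragma: no cover - concave for all D >= 2
        raise FitError(f"non-concave analytic fit at D={D}")
    sigma = np.sqrt(-1.0 / (2.0 * a))
    return float(r_max / sigma)


_INVERT_TABLE: dict = {}


def _inversion_spline(window_mult: float) -> PchipInterpolator:
    key = round(window_mult, 6)
    if key not in _INVERT_TABLE:
        ds = np.concatenate([np.arange(1.1, 2.0, 0.1),
                             np.arange(2.0, 12.01, 0.25),
                             np.arange(12.5, 50.01, 0.5)])
        rs = np.array([analytic_R_of_D(d, window_mult) for d in ds])
        if np.any(np.diff(rs) <= 0):  # pragma: no cover
            raise FitError("analytic R(D) table is not monotone")
        _INVERT_TABLE[key] = PchipInterpolator(rs, ds)
    return _INVERT_TABLE[key]


def invert_R(R: float, window_mult: float = DEFAULT_WINDOW_MULT) -> float:
    """Dimension implied by a measured ratio R, by monotone interpolation
    of the precomputed analytic R(D) table over D in [1.1, 50]."""
    spline = _inversion_spline(window_mult)
    lo, hi = spline.x[0], spline.x[-1]
    if not lo <= R <= hi:
        raise ValueError(f"R = {R:.4g} outside the tabulated range "
                         f"[{lo:.4g}, {hi:.4g}] (D in [1.1, 50])")
    return float(spline(R))


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def estimate_id(data, metric: str = "euclidean", k: int | None = None,
                use_graph: bool | None = None,
                sources: int | None = None,
                window_mult: float = DEFAULT_WINDOW_MULT,
                bins: int | None = None,
                d_range: tuple = (1, 30),
                seed: int = 0) -> IDEstimate:
    """Run the full pipeline: distances -> (graph geodesics) -> p(r) -> ID.

    Parameters
    ----------
    data:
        :class:`PointCloud` (or plain ``N x M`` array), a precomputed
        :class:`DistanceSet`, or an MSA object with ``sequences`` (metric
        ``"hamming"``).
    metric:
        ``"euclidean"``, ``"hamming"`` or ``"precomputed"``; ignored when
        the input type already determines it.
    k:
        Neighbors for the graph-geodesic step.  Graph mode is on whenever
        ``k`` is given unless ``use_graph=False`` forces input-space
        distances (appropriate for flat convex supports).
    sources:
        Optional number of shortest-path source points to subsample (the
        density needs no specific pairs); drawn uniformly with ``seed``.
    window_mult, bins, d_range:
        Forwarded to the density and fit stages.
    """
    from . import geodesics as geo
    from . import metrics as met

    flags: list = []
    settings = {"metric": metric, "k": k, "window_mult": window_mult,
                "bins": bins, "d_range": list(d_range), "seed": seed}

    cloud = None
    if isinstance(data, DistanceSet):
        dist = data
    elif hasattr(data, "sequences"):
        dist = met.hamming_distances(data)
    else:
        cloud = data if isinstance(data, PointCloud) else PointCloud(np.asarray(data))
        if metric == "hamming":
            raise ValueError("hamming metric requires an MSA input")
        dist = None

    if use_graph is None:
        use_graph = k is not None
    if use_graph:
        if k is None:
            raise ValueError("graph mode requires k")
        if cloud is not None and dist is None:
            graph = geo.knn_graph_from_points(cloud, k)
        else:
            graph = geo.build_knn_graph(dist, k)
        if not graph.is_connected:
            warnings.warn(
                f"neighbor graph has {graph.n_components} components; "
                f"restricting to the largest ({graph.lcc_size} of "
                f"{graph.n_points} nodes)", stacklevel=2)
            flags.append("lcc_restricted")
            graph, dist, kept = geo.restrict_to_lcc(graph, dist)
            settings["lcc_size"] = int(len(kept))
        settings["n_nodes"] = graph.n_points
        src = None
        if sources is not None and sources < graph.n_points:
            rng = np.random.default_rng(seed)
            src = rng.choice(graph.n_points, size=sources, replace=False)
            settings["n_sources"] = sources
        dist = geo.graph_geodesics(graph, sources=src)
    elif dist is None:
        dist = met.euclidean_distances(cloud)

    density = estimate_density(dist, bins=bins)
    if density.plateau:
        flags.append("r_max_plateau")
    gfit = gaussian_left_fit(density, window_mult=window_mult)
    d_fit_val, resid, dflag = fit_d(density)
    if dflag:
        flags.append(dflag)
    d_min, curve = rmsd_scan(density, d_range)
    if curve["rmsd"].count(min(curve["rmsd"])) > 1:
        flags.append("rmsd_tie")
    try:
        d_from_R = invert_R(gfit.ratio_R, window_mult)
    except ValueError:
        d_from_R = None
        flags.append("R_outside_inversion_table")
    return IDEstimate(
        sigma=gfit.sigma, curvature_a=gfit.curvature_a,
        ratio_R=gfit.ratio_R, d_fit=d_fit_val, d_fit_residual=resid,
        d_min=d_min, rmsd_curve=curve, d_from_R=d_from_R,
        r_max=density.r_max_pos, spread_s=density.spread_s,
        n_pairs=density.n_pairs, settings=settings, flags=flags)
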