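"""Synthetic manifold samplers and analytic reference densities.

Every benchmark shape used to validate the intrinsic-dimension estimator is
generated here with reproducible seeding: uniform hypercubes, balls, Gaussian
clouds, hypersphere surfaces (with exact arc-length geodesics), the Swiss
roll, the T-times-twisted Moebius band, a noisy planar square, and an
oscillating wave surface.  Analytic pairwise-distance densities for the
hypersphere and the ball are provided as ground truth for the estimator and
the test suite.

Conventions
-----------
A "D-dimensional hypersphere" is the D-dimensional *surface* of the unit
sphere embedded in D+1 coordinates; its geodesic (arc-length) distances live
in [0, pi] and their density is proportional to sin^(D-1)(r).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import betainc, gammaln

__all__ = [
    "ShapeSpec",
    "PointCloud",
    "sample_hypercube",
    "sample_ball",
    "sample_gaussian",
    "sample_hypersphere_surface",
    "sample_swiss_roll",
    "sample_mobius",
    "sample_noisy_square",
    "sample_wave_surface",
    "analytic_hypersphere_density",
    "analytic_ball_distance_density",
    "SHAPE_SAMPLERS",
]


@dataclass(frozen=True)
class ShapeSpec:
    """Description of a synthetic dataset: shape family, dimension, size, seed.

    Parameters
    ----------
    name:
        Shape identifier (one of the sampler names, e.g. ``"hypercube"``).
    dim:
        Intrinsic dimension ``D`` of the shape (positive integer).
    n_points:
        Sample size ``N`` (at least 2).
    seed:
        Seed for :func:`numpy.random.default_rng`.
    params:
        Shape-specific parameters (radius, noise amplitude, number of
        half-twists, wave frequency, ...).
    """

    name: str
    dim: int = 2
    n_points: int = 1000
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if self.dim < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")
        for key, val in self.params.items():
            if key.startswith("noise") and key.endswith("amp") and val < 0:
                raise ValueError(f"noise amplitude must be >= 0, got {val}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class PointCloud:
    """``N x M`` coordinate matrix with optional per-point labels.

    ``meta`` keeps the generating parameters (including intrinsic
    coordinates for the folded shapes) so tests can recover them.
    """

    coords: np.ndarray
    labels: Optional[list] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be a 2-D array (N points x M coordinates)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


def sample_hypercube(spec: ShapeSpec) -> PointCloud:
    """N i.i.d. points uniform on the unit hypercube [0, 1]^D."""
    rng = spec.rng()
    coords = rng.random((spec.n_points, spec.dim))
    return PointCloud(coords, meta={"shape": "hypercube", "dim": spec.dim})


def sample_ball(spec: ShapeSpec) -> PointCloud:
    """N points uniform (in volume) inside the D-ball of the given radius.

    Direction from a normalized Gaussian draw, radius from ``U**(1/D)`` so
    that the radial density is ``D * rho**(D-1)``.
    """
    radius = float(spec.params.get("radius", 1.0))
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    rng = spec.rng()
    direction = _unit_vectors(rng, spec.n_points, spec.dim)
    rho = radius * rng.random(spec.n_points) ** (1.0 / spec.dim)
    return PointCloud(direction * rho[:, None],
                      meta={"shape": "ball", "dim": spec.dim, "radius": radius})


def sample_gaussian(spec: ShapeSpec) -> PointCloud:
    """N points from the standard D-variate normal."""
    rng = spec.rng()
    coords = rng.standard_normal((spec.n_points, spec.dim))
    return PointCloud(coords, meta={"shape": "gaussian", "dim": spec.dim})


def sample_hypersphere_surface(spec: ShapeSpec, with_distances: bool = True):
    """N points uniform on the unit sphere S^D embedded in D+1 coordinates.

    Returns ``(cloud, arcs)`` where ``arcs`` is the exact geodesic
    (arc-length) distance set, each entry ``arccos(x_i . x_j)`` in [0, pi];
    with ``with_distances=False`` only the cloud is returned (``arcs`` is
    ``None``).  Uniformity is exact: normalized Gaussian vectors.
    """
    from .metrics import arc_distances

    rng = spec.rng()
    coords = _unit_vectors(rng, spec.n_points, spec.dim + 1)
    cloud = PointCloud(coords, meta={"shape": "hypersphere", "dim": spec.dim})
    arcs = arc_distances(cloud) if with_distances else None
    return cloud, arcs


def _unit_vectors(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    """Draw n uniformly distributed unit vectors in R^m, resampling the
    (probability-zero) degenerate draws whose norm underflows."""
    v = rng.standard_normal((n, m))
    norms = np.linalg.norm(v, axis=1)
    while np.any(norms < 1e-12):  # pragma: no cover - probability ~0
        bad = norms < 1e-12
        v[bad] = rng.standard_normal((int(bad.sum()), m))
        norms = np.linalg.norm(v, axis=1)
    return v / norms[:, None]


def sample_swiss_roll(n_points: int, seed: int = 0) -> PointCloud:
    """Swiss roll: a 2-D strip rolled up in 3-space.

    Parametrization ``(t cos t, h, t sin t)`` with ``t`` uniform on
    [3 pi/2, 9 pi/2] and ``h`` uniform on [0, 21] -- the standard benchmark
    construction.  The intrinsic (unrolled) coordinates are stored in
    ``meta`` so the isometry to a flat rectangle can be checked.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    rng = np.random.default_rng(seed)
    t = rng.uniform(1.5 * np.pi, 4.5 * np.pi, n_points)
    h = rng.uniform(0.0, 21.0, n_points)
    coords = np.column_stack([t * np.cos(t), h, t * np.sin(t)])
    # arc-length along the spiral gives the unrolled first coordinate
    arclen = 0.5 * (t * np.sqrt(1 + t**2) + np.arcsinh(t))
    return PointCloud(coords, meta={"shape": "swiss_roll", "dim": 2,
                                    "t": t, "h": h, "arclength": arclen})


def sample_mobius(n_points: int, half_twists: int = 1, width: float = 1.0,
                  noise_dims: int = 0, noise_amp: float = 0.0,
                  seed: int = 0) -> PointCloud:
    """Moebius-type band with ``half_twists`` half twists, optionally padded
    with extra coordinates of uniform noise in [-noise_amp, +noise_amp].

    Parametrization with u in [0, 2 pi), v in [-width/2, width/2]::

        x = (1 + v cos(T u / 2)) cos u
        y = (1 + v cos(T u / 2)) sin u
        z = v sin(T u / 2)

    ``half_twists=10`` gives the "10-Moebius strip" benchmark, a
    non-orientable surface isometric (in graph distance) to a cylinder side.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if half_twists < 1:
        raise ValueError("half_twists must be >= 1")
    if width <= 0:
        raise ValueError("width must be > 0")
    if noise_dims > 0 and noise_amp <= 0:
        raise ValueError("noise_dims > 0 requires noise_amp > 0")
    if noise_amp < 0:
        raise ValueError("noise_amp must be >= 0")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 2 * np.pi, n_points)
    v = rng.uniform(-width / 2, width / 2, n_points)
    half = half_twists * u / 2
    band = np.column_stack([(1 + v * np.cos(half)) * np.cos(u),
                            (1 + v * np.cos(half)) * np.sin(u),
                            v * np.sin(half)])
    if noise_dims > 0:
        noise = rng.uniform(-noise_amp, noise_amp, (n_points, noise_dims))
        band = np.hstack([band, noise])
    return PointCloud(band, meta={"shape": "mobius", "dim": 2,
                                  "half_twists": half_twists, "u": u, "v": v})


def sample_noisy_square(n_points: int, noise_width: float = 0.1,
                        seed: int = 0) -> PointCloud:
    """Unit square in the (x, y) plane with thin uniform orthogonal noise.

    ``(x, y)`` uniform in [0, 1]^2; ``z`` uniform in
    [-noise_width/2, +noise_width/2].  The multiscale dimension profile of
    this cloud shows a slope-3 regime below the noise width and a slope-2
    plateau above it.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if noise_width < 0:
        raise ValueError("noise_width must be >= 0")
    rng = np.random.default_rng(seed)
    coords = np.column_stack([rng.random(n_points), rng.random(n_points),
                              rng.uniform(-noise_width / 2, noise_width / 2,
                                          n_points)])
    return PointCloud(coords, meta={"shape": "noisy_square", "dim": 2,
                                    "noise_width": noise_width})


def sample_wave_surface(n_points: int, frequency_a: float = 4.0,
                        seed: int = 0) -> PointCloud:
    """Graph surface z(x, y) = [cos(pi a x) + sin(pi a y)] / 2 over [-1, 1]^2.

    A 2-D manifold with non-constant curvature; the spatial frequency ``a``
    controls how densely the surface oscillates and therefore how many
    points are needed for a faithful graph reconstruction.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if frequency_a <= 0:
        raise ValueError("frequency_a must be > 0")
    rng = np.random.default_rng(seed)
    xy = rng.uniform(-1.0, 1.0, (n_points, 2))
    z = (np.cos(np.pi * frequency_a * xy[:, 0])
         + np.sin(np.pi * frequency_a * xy[:, 1])) / 2
    return PointCloud(np.column_stack([xy, z]),
                      meta={"shape": "wave", "dim": 2, "frequency_a": frequency_a})


def analytic_hypersphere_density(D: float, r_grid: np.ndarray) -> np.ndarray:
    """Geodesic-distance density of the D-dimensional unit hypersphere.

    ``p(r) = C sin^(D-1)(r)`` on [0, pi], normalized to unit mass.  The
    normalization is the Wallis integral,
    ``1/C = int_0^pi sin^(D-1) = sqrt(pi) Gamma(D/2) / Gamma((D+1)/2)``,
    valid for real D >= 1 so the least-squares fit can treat D as a
    continuous parameter.
    """
    if D < 1:
        raise ValueError(f"D must be >= 1, got {D}")
    r = np.asarray(r_grid, dtype=float)
    if np.any(r < 0) or np.any(r > np.pi + 1e-12):
        raise ValueError("r_grid must lie in [0, pi]")
    log_norm = 0.5 * np.log(np.pi) + gammaln(D / 2) - gammaln((D + 1) / 2)
    with np.errstate(divide="ignore"):
        sin_r = np.clip(np.sin(np.clip(r, 0.0, np.pi)), 0.0, 1.0)
        vals = np.where(sin_r > 0, sin_r ** (D - 1), 1.0 if D == 1 else 0.0)
    return vals * np.exp(-log_norm)


def analytic_ball_distance_density(D: int, r_grid: np.ndarray) -> np.ndarray:
    """Density of the Euclidean distance between two uniform points in the
    unit D-ball (diagnostic reference; support [0, 2]).

    Closed form ``p(r) = D r^(D-1) I_x((D+1)/2, 1/2)`` with
    ``x = 1 - r^2/4`` and ``I`` the regularized incomplete beta function.
    For D=1 this reduces to the triangular law (2 - r)/2.
    """
    if D < 1:
        raise ValueError(f"D must be >= 1, got {D}")
    r = np.asarray(r_grid, dtype=float)
    if np.any(r < 0) or np.any(r > 2 + 1e-12):
        raise ValueError("r_grid must lie in [0, 2]")
    x = np.clip(1.0 - r**2 / 4.0, 0.0, 1.0)
    return D * r ** (D - 1) * betainc((D + 1) / 2.0, 0.5, x)


#: samplers that take a ShapeSpec directly (CLI dispatch table)
SHAPE_SAMPLERS = {
    "hypercube": sample_hypercube,
    "ball": sample_ball,
    "gaussian": sample_gaussian,
}
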