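"""The p(r)-based intrinsic-dimension estimator.

Oracles: exact Gaussian densities tabulated on a grid (the quadratic
log-fit must recover sigma exactly), inverse-CDF sampling from the
sin^(D-1) model (parameter recovery), and self-consistency of the RMSD
scan on its own generating model.
"""

import numpy as np
import pytest

from idgraph import (
    DistanceSet,
    analytic_R_of_D,
    estimate_density,
    estimate_id,
    fit_d,
    gaussian_left_fit,
    hypersphere_model,
    invert_R,
    rmsd_scan,
)
from idgraph.estimator import DistanceDensity, FitError
from idgraph.io import MSA
from idgraph.shapes import analytic_hypersphere_density


def tabulated_density(centers, p, counts_scale=1e6):
    """Wrap an exact density evaluated on bin centers as a DistanceDensity."""
    width = centers[1] - centers[0]
    p = p / (p.sum() * width)
    counts = np.maximum(1, (p * counts_scale).astype(int))
    mean = (centers * p).sum() * width
    s = np.sqrt(((centers - mean) ** 2 * p).sum() * width)
    r_max = centers[np.argmax(p)]
    return DistanceDensity(centers, p, counts, width, float(r_max),
                           float(s), int(counts.sum()))


def sample_from_sphere_density(D, n, seed=0):
    """Inverse-CDF draws from the sin^(D-1) geodesic law (sampling oracle)."""
    grid = np.linspace(0, np.pi, 20_001)
    pdf = analytic_hypersphere_density(D, grid)
    cdf = np.concatenate([[0], np.cumsum((pdf[1:] + pdf[:-1]) / 2
                                         * np.diff(grid))])
    cdf /= cdf[-1]
    u = np.random.default_rng(seed).random(n)
    vals = np.interp(u, cdf, grid)
    return DistanceSet(vals, n_points=n, metric_tag="arc", is_complete=False)


# ---------------------------------------------------------------- density

def test_density_normalized_and_rmax(sphere_arcs):
    arcs = sphere_arcs(10, 2000)
    dens = estimate_density(arcs)
    assert dens.integral() == pytest.approx(1.0, abs=1e-6)
    # sin^9 peaks at pi/2
    assert abs(dens.r_max_pos - np.pi / 2) <= dens.bin_width
    assert dens.r_max_pos >= arcs.values.min()
    assert dens.r_max_pos <= arcs.values.max()


def test_density_flat_law_flags_plateau():
    vals = np.random.default_rng(1).uniform(0, np.pi, 50_000)
    dens = estimate_density(DistanceSet(vals, 50_000, "arc",
                                        is_complete=False))
    assert dens.plateau


def test_density_integer_bins_for_hamming(rng):
    alphabet = np.array(list("ACDEFG-"))
    seqs = ["".join(rng.choice(alphabet, 40)) for _ in range(30)]
    from idgraph import hamming_distances

    d = hamming_distances(MSA([str(i) for i in range(30)], seqs))
    dens = estimate_density(d)
    assert dens.bin_width == pytest.approx(1.0)
    assert np.allclose(dens.bin_centers, np.round(dens.bin_centers))


def test_density_degenerate_distances_rejected():
    d = DistanceSet(np.full(200, 2.0), 200, "user", is_complete=False)
    with pytest.raises(FitError, match="identical"):
        estimate_density(d)


# ----------------------------------------------------- gaussian left fit

def test_gaussian_left_fit_recovers_exact_gaussian():
    centers = np.linspace(0.5, 9.5, 400)
    p = np.exp(-0.5 * (centers - 5.0) ** 2)
    dens = tabulated_density(centers, p)
    dens.r_max_pos = 5.0
    dens.spread_s = 1.0
    fit = gaussian_left_fit(dens)
    assert fit.sigma == pytest.approx(1.0, rel=1e-6)
    assert fit.ratio_R == pytest.approx(5.0, rel=1e-6)
    assert fit.curvature_a == pytest.approx(-0.5, rel=1e-6)


def test_gaussian_left_fit_rejects_convex_density():
    centers = np.linspace(0.1, 2.0, 100)
    p = np.exp(+2.0 * (centers - 2.0) ** 2)  # convex log-density
    dens = tabulated_density(centers, p)
    dens.r_max_pos = centers[-1]
    dens.spread_s = 1.0
    with pytest.raises(FitError, match="non-concave"):
        gaussian_left_fit(dens)


def test_gaussian_left_fit_needs_enough_bins():
    centers = np.linspace(0.0, 1.0, 6)
    dens = tabulated_density(centers, np.array([0, 0, 0, 1, 2, 1.0]) + 1e-9)
    dens.r_max_pos = centers[-2]
    dens.spread_s = 0.01  # window excludes almost everything
    with pytest.raises(FitError, match="populated bins"):
        gaussian_left_fit(dens)


# --------------------------------------------------------- model and fits

def test_hypersphere_model_constant_for_d1():
    x = np.linspace(0.1, np.pi, 50)
    m = hypersphere_model(x, 1.0)
    assert np.ptp(m) < 1e-12


def test_hypersphere_model_mode_and_normalization():
    x = np.linspace(0.01, np.pi, 1001)
    for D in (2.0, 5.5, 12.0):
        m = hypersphere_model(x, D)
        assert x[np.argmax(m)] == pytest.approx(np.pi / 2, abs=0.01)
        assert np.trapezoid(m, x) == pytest.approx(1.0, abs=1e-6)
    width = x[1] - x[0]
    m = hypersphere_model(x, 7.0, bin_width=width)
    assert m.sum() * width == pytest.approx(1.0, abs=1e-12)


def test_fit_d_recovers_generating_dimension():
    draws = sample_from_sphere_density(7, 1_000_000, seed=11)
    dens = estimate_density(draws)
    d_fit, resid, flag = fit_d(dens)
    assert d_fit == pytest.approx(7.0, abs=0.1)
    assert flag is None


def test_rmsd_scan_self_consistency():
    draws = sample_from_sphere_density(6, 500_000, seed=5)
    dens = estimate_density(draws)
    d_min, curve = rmsd_scan(dens, (1, 20))
    assert d_min == 6
    # locally convex around the minimum
    i = curve["d"].index(d_min)
    r = curve["rmsd"]
    assert r[i - 1] > r[i] < r[i + 1]


def test_rmsd_scan_range_validation(sphere_arcs):
    dens = estimate_density(sphere_arcs(5, 500))
    with pytest.raises(ValueError):
        rmsd_scan(dens, (5, 6))
    with pytest.raises(ValueError):
        rmsd_scan(dens, (0, 10))


# ------------------------------------------------- analytic R(D) relation

def test_analytic_R_monotone_and_bounded():
    ds = np.arange(2, 51)
    rs = np.array([analytic_R_of_D(d) for d in ds])
    assert np.all(np.diff(rs) > 0)
    # finite-window fit sees the faster-than-quadratic decay of log sin,
    # so R exceeds the point-curvature bound (pi/2) sqrt(D-1)
    assert np.all(rs >= (np.pi / 2) * np.sqrt(ds - 1))


def test_analytic_R_grid_converged():
    for D in (2, 10, 30):
        r1 = analytic_R_of_D(D, grid_size=4001)
        r2 = analytic_R_of_D(D, grid_size=8001)
        assert abs(r1 - r2) < 1e-3


def test_invert_R_round_trip():
    for D in (2.0, 3.5, 7.0, 15.0, 40.0):
        assert invert_R(analytic_R_of_D(D)) == pytest.approx(D, abs=1e-2)


def test_invert_R_out_of_range():
    with pytest.raises(ValueError, match="outside"):
        invert_R(0.5)
    with pytest.raises(ValueError):
        analytic_R_of_D(1.0)


# ------------------------------------------------------------ pipeline

def test_estimate_id_scale_invariance(sphere_arcs):
    arcs = sphere_arcs(5, 800)
    est = estimate_id(arcs)
    scaled = DistanceSet(arcs.values * 123.4, arcs.n_points, "user")
    est2 = estimate_id(scaled)
    assert est2.ratio_R == pytest.approx(est.ratio_R, rel=1e-6)
    assert est2.d_fit == pytest.approx(est.d_fit, rel=1e-4)
    assert est2.d_min == est.d_min


def test_estimate_id_small_sample_discriminates_dimension():
    # small samples with exact geodesics on S^10: at N=1000 the RMSD
    # minimum picks 10 exactly in at least half the replicates; even at
    # N=100 every estimate stays far closer to 10 than to 20
    from idgraph import ShapeSpec, sample_hypersphere_surface

    exact_1000 = 0
    for seed in range(20):
        spec = ShapeSpec("hypersphere", dim=10, n_points=1000, seed=seed)
        _, arcs = sample_hypersphere_surface(spec)
        exact_1000 += estimate_id(arcs).d_min == 10
    assert exact_1000 >= 10

    for seed in range(10):
        spec = ShapeSpec("hypersphere", dim=10, n_points=100, seed=seed)
        _, arcs = sample_hypersphere_surface(spec)
        d_min = estimate_id(arcs).d_min
        assert abs(d_min - 10) < abs(d_min - 20)


def test_estimate_id_lcc_warning(rng):
    from idgraph import PointCloud

    pts = np.vstack([rng.normal(size=(40, 2)),
                     rng.normal(size=(10, 2)) + 1000])
    with pytest.warns(UserWarning, match="restricting to the largest"):
        est = estimate_id(PointCloud(pts), k=3)
    assert "lcc_restricted" in est.flags
    assert est.settings["lcc_size"] == 40


def test_estimate_id_graph_requires_k(rng):
    from idgraph import PointCloud

    with pytest.raises(ValueError, match="requires k"):
        estimate_id(PointCloud(rng.normal(size=(30, 2))), use_graph=True)
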