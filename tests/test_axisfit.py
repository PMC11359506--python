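"""Outlier trim, SVD initialization, weights, cylinder fit, selection."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from deitbone import axisfit, phantom
from deitbone.axisfit import (AxisEstimate, compute_weights, fit_cylinder,
                              initial_axis_svd, select_bone_cluster,
                              trim_outliers)


# ---------------------------------------------------------------- trim ----

def test_trim_keeps_all_when_variance_zero():
    keep = trim_outliers(np.full(20, 0.5))
    assert keep.all()


def test_trim_drops_single_extreme_value():
    v = np.zeros(1000)
    v[-1] = 10.0
    keep = trim_outliers(v)
    assert keep[:-1].all() and not keep[-1]


def test_trim_fraction_on_normal_data(rng):
    """The band mean +/- 1.9 SD trims 2*Phi(-1.9) of standard-normal draws."""
    v = rng.standard_normal(100_000)
    frac = 1.0 - trim_outliers(v).mean()
    expected = 2 * norm.cdf(-1.9)       # 0.05743...
    assert frac == pytest.approx(expected, abs=0.003)


def test_trim_empty_cluster_is_error():
    with pytest.raises(axisfit.EmptyClusterError):
        trim_outliers(np.array([]))


# ----------------------------------------------------------------- svd ----

def test_svd_axis_collinear_points():
    est = initial_axis_svd(np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2.0]]))
    np.testing.assert_allclose(est.n_b, [0, 0, 1], atol=1e-12)
    np.testing.assert_allclose(est.p_b, [0, 0, 1], atol=1e-12)


def test_svd_centroid_two_points():
    est = initial_axis_svd(np.array([[0, 0, 0], [2, 0, 0.0]]))
    np.testing.assert_allclose(est.p_b, [1, 0, 0], atol=1e-12)


def test_svd_identical_points_degenerate():
    with pytest.raises(axisfit.DegenerateGeometryError):
        initial_axis_svd(np.ones((5, 3)))


def test_svd_recovers_tilted_cylinder_axis(rng):
    """5000 points filling a tilted cylinder: the dominant singular
    direction is the cylinder axis to within 0.5 degrees."""
    u = np.array([math.sin(math.radians(10)), 0, math.cos(math.radians(10))])
    e1 = np.array([math.cos(math.radians(10)), 0, -math.sin(math.radians(10))])
    e2 = np.array([0.0, 1.0, 0.0])
    t = rng.uniform(-0.1, 0.1, 5000)
    r = 0.015 * np.sqrt(rng.uniform(0, 1, 5000))
    th = rng.uniform(0, 2 * math.pi, 5000)
    pts = (t[:, None] * u + (r * np.cos(th))[:, None] * e1
           + (r * np.sin(th))[:, None] * e2)
    est = initial_axis_svd(pts)
    ang = math.degrees(math.acos(min(1.0, abs(float(est.n_b @ u)))))
    assert ang < 0.5


# ------------------------------------------------------------- weights ----

def _axis_for(zeta):
    return AxisEstimate(p_b=np.zeros(3), n_b=np.array([0, 0, 1.0]),
                        zeta=np.asarray(zeta, float), stage="initial")


def test_weight_at_mean_zeta_equals_shift():
    pts = np.zeros((3, 3))
    est = _axis_for([-0.05, 0.0, 0.05])
    wp = compute_weights(pts, est, (0.0, 0.3), (0.14, 0.16), 0.15)
    # the middle point sits at mean(zeta): its weight is exactly h
    assert wp.w[1] == pytest.approx(wp.h)
    assert wp.h > 0


def test_weight_pure_parabola_when_electrodes_in_plane():
    est = _axis_for([-0.06, 0.02, 0.04])
    wp = compute_weights(np.zeros((3, 3)), est, (0.0, 0.3), (0.15, 0.15), 0.15)
    assert wp.h == 0.0
    f = min(0.15, 0.15) ** 2 / 4
    zeta = est.zeta - est.zeta.mean()
    np.testing.assert_allclose(wp.w, zeta ** 2 / (4 * f))


def test_weights_even_in_centred_zeta():
    est = _axis_for([-0.07, 0.07, 0.0])
    wp = compute_weights(np.zeros((3, 3)), est, (0.0, 0.3), (0.14, 0.16), 0.15)
    assert wp.w[0] == pytest.approx(wp.w[1])


def test_weights_plane_on_boundary_is_error():
    est = _axis_for([0.0, 0.1])
    with pytest.raises(axisfit.DegenerateGeometryError):
        compute_weights(np.zeros((2, 3)), est, (0.0, 0.3), (0.0, 0.0), 0.0)


def test_inverted_weights_decay_off_plane():
    est = _axis_for(np.linspace(-0.1, 0.1, 9))
    wp = compute_weights(np.zeros((9, 3)), est, (0.0, 0.3), (0.14, 0.16),
                         0.15, invert=True)
    assert np.all(wp.w > 0)
    assert wp.w[4] == wp.w.max()          # near-plane point weighted most
    assert wp.w[0] == pytest.approx(wp.w.min())


# ------------------------------------------------------------ cylinder ----

def _shell_points(axis, centre, radius=0.015, half_len=0.1,
                  n_axial=20, n_ring=18):
    """Symmetric grid on a cylinder shell: the weighted line fit of this
    cloud has its exact minimum on the true axis for any axial weights."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    e1 = np.cross(a, [0, 0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(a, [0, 1.0, 0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    t = np.linspace(-half_len, half_len, n_axial)
    th = 2 * math.pi * np.arange(n_ring) / n_ring
    tt, hh = np.meshgrid(t, th, indexing="ij")
    tt, hh = tt.ravel(), hh.ravel()
    return (centre + tt[:, None] * a
            + radius * np.cos(hh)[:, None] * e1
            + radius * np.sin(hh)[:, None] * e2)


def _fit(pts, **kw):
    init = initial_axis_svd(pts)
    return init, fit_cylinder(pts, init, (0.0, 0.3), (0.148, 0.152), 0.15,
                              **kw)


def test_shell_points_give_exact_axis_and_objective():
    """Noise-free points on a radius-r0 shell: the axis is recovered and the
    objective equals the sum of squared weights (unit residual per point)."""
    u = np.array([0.05, 0.02, 1.0])
    u /= np.linalg.norm(u)
    pts = _shell_points(u, np.array([0.01, -0.005, 0.15]))
    init, opt = _fit(pts)
    ang = math.acos(min(1.0, abs(float(opt.n_b @ u))))
    assert ang < 1e-4
    # every point sits exactly at distance r0, so each contributes w_i^2
    # regardless of its weight; the fit freezes the weights at the initial
    # axis, so evaluate the expected objective with those
    wp = compute_weights(pts, init, (0.0, 0.3), (0.148, 0.152), 0.15)
    assert opt.eps_r == pytest.approx(float(np.sum(wp.w ** 2)), rel=1e-6)


def test_r0_rescales_objective_but_not_argmin():
    pts = _shell_points([0.03, 0.0, 1.0], np.array([0.0, 0.01, 0.15]))
    init = initial_axis_svd(pts)
    kw = dict(z_extent=(0.0, 0.3), electrode_z_extent=(0.148, 0.152),
              z_m=0.15)
    a = fit_cylinder(pts, init, r0=0.015, **kw)
    b = fit_cylinder(pts, init, r0=0.045, **kw)
    np.testing.assert_allclose(a.n_b, b.n_b, atol=1e-6)
    np.testing.assert_allclose(a.p_b, b.p_b, atol=1e-7)
    assert a.eps_r == pytest.approx(9 * b.eps_r, rel=1e-5)


def test_noisy_cylinder_matches_grid_search_oracle(rng):
    """With 5 % coordinate noise the fit lands within 1 degree of the truth
    and within grid resolution of a dense direction search over the same
    objective."""
    u = np.array([math.sin(math.radians(4)), 0, math.cos(math.radians(4))])
    pts = _shell_points(u, np.array([0.0, 0.0, 0.15]), n_axial=40)
    pts = pts + rng.normal(0, 0.00075, pts.shape)   # 5 % of r0
    init, opt = _fit(pts, invert_weights=True)
    ang = math.degrees(math.acos(min(1.0, abs(float(opt.n_b @ u)))))
    assert ang < 1.0

    wp = compute_weights(pts, init, (0.0, 0.3), (0.148, 0.152), 0.15,
                         invert=True)
    best, best_val = None, np.inf
    for th in np.radians(np.arange(0.0, 8.001, 0.25)):
        for ph in np.radians(np.arange(0.0, 360.0, 15.0)):
            n = np.array([math.sin(th) * math.cos(ph),
                          math.sin(th) * math.sin(ph), math.cos(th)])
            val = axisfit.cylinder_objective(pts, wp.w, opt.p_b, n)
            if val < best_val:
                best, best_val = n, val
    grid_ang = math.degrees(math.acos(min(1.0, abs(float(opt.n_b @ best)))))
    assert grid_ang < 1.0   # grid resolution


def test_fit_never_increases_objective():
    rng = np.random.default_rng(5)
    pts = _shell_points([0.1, 0.05, 1.0], np.array([0.01, 0.0, 0.15]))
    pts = pts + rng.normal(0, 0.002, pts.shape)
    init, opt = _fit(pts)
    # objective at the optimizer's own starting point (centre projected to
    # the electrode plane, weights frozen at the initial axis)
    n0 = init.n_b
    pb0 = init.p_b + (0.15 - init.p_b[2]) / n0[2] * n0
    w0 = compute_weights(pts, init, (0.0, 0.3), (0.148, 0.152), 0.15).w
    eps_start = axisfit.cylinder_objective(pts, w0, pb0, n0)
    assert opt.eps_r <= eps_start * (1 + 1e-12)


def test_rigid_motion_equivariance():
    pts = _shell_points([0.02, -0.04, 1.0], np.array([0.0, 0.0, 0.15]))
    init, opt = _fit(pts)
    shift = np.array([0.012, -0.007, 0.0])
    init2, opt2 = _fit(pts + shift)
    np.testing.assert_allclose(opt2.n_b, opt.n_b, atol=1e-6)
    np.testing.assert_allclose(opt2.p_b, opt.p_b + shift, atol=1e-6)

    ang = math.radians(25)
    R = np.array([[math.cos(ang), -math.sin(ang), 0],
                  [math.sin(ang), math.cos(ang), 0], [0, 0, 1.0]])
    init3, opt3 = _fit(pts @ R.T)
    np.testing.assert_allclose(opt3.n_b, R @ opt.n_b, atol=1e-5)


@pytest.mark.parametrize("tilt", [0.0, 2.0, 5.0])
def test_tilt_recovery_from_true_bone_elements(tilt):
    """Synthetic clusters taken directly from the phantom's bone elements
    (bypassing reconstruction) recover the tilt within 0.2 degrees."""
    p = phantom.build_phantom("cylinder", mesh_density=0.012,
                              bone_tilt_deg=tilt)
    mask = np.isin(p.tissue_label,
                   [int(phantom.Tissue.BONE), int(phantom.Tissue.MARROW)])
    pts = p.element_centroids[mask]
    z = p.vertices[:, 2]
    el_z = np.concatenate([z[n] for n in p.electrode_nodes])
    init = initial_axis_svd(pts)
    opt = fit_cylinder(pts, init, (z.min(), z.max()),
                       (el_z.min(), el_z.max()), p.z_m)
    for est in (init, opt):
        ang = math.degrees(
            math.acos(min(1.0, abs(float(est.n_b @ p.true_axis.n_f)))))
        assert ang < 0.2


# ----------------------------------------------------------- selection ----

def _estimate(extent, mean=-0.1, rng_=( -0.2, 0.0)):
    zeta = np.array([0.0, extent])
    return AxisEstimate(p_b=np.zeros(3), n_b=np.array([0, 0, 1.0]),
                        zeta=zeta, stage="optimal", mean_delta=mean,
                        delta_range=rng_)


def test_single_cluster_selected():
    e = _estimate(0.2)
    assert select_bone_cluster([e]) is e


def test_strictly_largest_extent_wins():
    long, short = _estimate(0.200), _estimate(0.040, mean=-0.9)
    assert select_bone_cluster([short, long]) is long


def test_similar_extent_tie_broken_by_lower_mean():
    a = _estimate(0.200, mean=-0.05)
    b = _estimate(0.195, mean=-0.30)
    assert select_bone_cluster([a, b], rtol=0.10) is b


def test_near_identical_means_fall_back_to_range():
    a = _estimate(0.200, mean=-0.300, rng_=(-0.5, 0.0))
    b = _estimate(0.198, mean=-0.301, rng_=(-1.5, 0.0))
    assert select_bone_cluster([a, b], rtol=0.10) is b


def test_empty_selection_is_no_bone_error():
    with pytest.raises(axisfit.NoBoneFoundError):
        select_bone_cluster([])
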