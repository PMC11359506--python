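"""Bone centre and axis estimation from segmented element clusters.

For each candidate cluster: element centroids are trimmed of conductivity-
difference outliers (outside mean +/- 1.9 SD), an initial axis comes from
the dominant right singular vector of the centred centroid cloud, and the
final estimate refines centre and direction by minimizing a weighted
orthogonal-distance objective

    eps_r = sum_i w_i^2 ||p_i - p_b - zeta_i n_b||^2 / r0^2,
    zeta_i = <p_i - p_b | n_b>,

with L-BFGS-B over spherical axis angles and the in-plane centre offsets
(the along-axis component of p_b is a gauge freedom and is pinned to the
electrode plane).  The per-point weights follow a parabola in the axial
coordinate, with apex at the electrode plane; as written the weights grow
away from the plane — ``invert_weights`` flips the parabola for the reading
where off-plane points are down-weighted instead.

The femur is selected among clusters as the one with the largest axial
extent; near-ties are resolved by lower mean conductivity difference, then
by larger difference range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

TRIM_SD = 1.9
#: Radius (m) of the reported fitted cylinder; a pure scale factor of eps_r.
FIT_RADIUS = 0.015
#: Relative delta-zeta window treated as "similar extent" during selection.
SIMILAR_EXTENT_RTOL = 0.05


class DegenerateGeometryError(ValueError):
    pass


class EmptyClusterError(ValueError):
    pass


class NoBoneFoundError(RuntimeError):
    """No candidate cluster survived segmentation / trimming."""


@dataclass(eq=False)
class AxisEstimate:
    p_b: np.ndarray               # centre point (m)
    n_b: np.ndarray               # unit axis, z-component >= 0
    zeta: np.ndarray              # per-point axial coordinates
    stage: str                    # "initial" | "optimal"
    eps_r: float = np.nan
    converged: bool = True
    mean_delta: float = np.nan    # cluster stats carried along for selection
    delta_range: tuple = (np.nan, np.nan)

    @property
    def zeta_extent(self) -> float:
        return float(self.zeta.max() - self.zeta.min()) if len(self.zeta) else 0.0


@dataclass(frozen=True)
class WeightProfile:
    f: float
    h: float
    w: np.ndarray


def trim_outliers(delta_values: np.ndarray, sd_factor: float = TRIM_SD
                  ) -> np.ndarray:
    """Mask of values strictly inside mean +/- sd_factor * SD.

    With zero spread nothing is trimmed (the band is degenerate but the
    values are all equal to the mean, which we keep by convention).
    """
    v = np.asarray(delta_values, float)
    if v.size == 0:
        raise EmptyClusterError("empty cluster")
    sd = v.std()
    if sd == 0:
        return np.ones(v.shape, dtype=bool)
    m = v.mean()
    keep = (v > m - sd_factor * sd) & (v < m + sd_factor * sd)
    if not keep.any():
        raise EmptyClusterError("outlier trim removed every element")
    return keep


def initial_axis_svd(points: np.ndarray) -> AxisEstimate:
    """Centroid + dominant singular direction of the centred point cloud."""
    p = np.asarray(points, float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 2:
        raise DegenerateGeometryError("need at least two 3D points")
    pb = p.mean(axis=0)
    c = p - pb
    if not np.any(np.abs(c) > 0):
        raise DegenerateGeometryError("all points identical")
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    n = vt[0]
    if n[2] < 0:
        n = -n
    n = n / np.linalg.norm(n)
    return AxisEstimate(p_b=pb, n_b=n, zeta=c @ n, stage="initial")


def compute_weights(points: np.ndarray, axis: AxisEstimate,
                    z_extent: tuple, electrode_z_extent: tuple, z_m: float,
                    invert: bool = False) -> WeightProfile:
    """Parabolic axial weights with apex at the electrode plane.

    ``f`` scales the parabola from the electrode plane's clearance to the
    mesh ends; ``h`` lifts it by the (squared, f-normalized) spread of the
    electrode vertices about the plane, so weights stay positive whenever
    the electrodes have finite extent.
    """
    z_min, z_max = z_extent
    if not (z_min < z_m < z_max):
        raise DegenerateGeometryError("electrode plane outside mesh extent")
    f = min(z_m - z_min, z_max - z_m) ** 2 / 4.0
    if f == 0:
        raise DegenerateGeometryError("electrode plane on mesh boundary")
    zel_min, zel_max = electrode_z_extent
    h = 0.5 * ((z_m - zel_min) ** 2 / (4 * f) + (zel_max - z_m) ** 2 / (4 * f))
    zeta = np.asarray(axis.zeta, float)
    w = (zeta - zeta.mean()) ** 2 / (4 * f) + h
    if invert:
        # Reliability-decay reading: down-weight off-plane points with a
        # bounded 4:1 profile.  The as-printed parabola spans several orders
        # of magnitude in w^2 because h is tiny for a single belt, which
        # would let a handful of extreme points own the fit.
        span = np.ptp(w)
        if span > 0:
            w = 1.0 + 3.0 * (w.max() - w) / span
        else:
            w = np.ones_like(w)
    return WeightProfile(f=f, h=h, w=w)


def _axis_from_angles(theta, phi):
    return np.array([math.sin(theta) * math.cos(phi),
                     math.sin(theta) * math.sin(phi),
                     math.cos(theta)])


def cylinder_objective(points, weights, p_b, n_b, r0=FIT_RADIUS):
    d = points - p_b
    zeta = d @ n_b
    resid = d - zeta[:, None] * n_b
    return float(np.sum(weights ** 2 * np.sum(resid ** 2, axis=1)) / r0 ** 2)


def fit_cylinder(points: np.ndarray, initial: AxisEstimate,
                 z_extent: tuple, electrode_z_extent: tuple, z_m: float,
                 r0: float = FIT_RADIUS, invert_weights: bool = False,
                 freeze_weights: bool = True,
                 gtol: float = 1e-9, max_iter: int = 500) -> AxisEstimate:
    """Refine centre and axis by weighted orthogonal-distance minimization.

    Parameters are the spherical angles of the axis and the in-plane centre
    offsets; the centre's axial coordinate is fixed at the electrode plane.
    Weights are recomputed from the current axis each evaluation unless
    ``freeze_weights``.
    """
    p = np.asarray(points, float)
    if len(p) < 6:
        raise DegenerateGeometryError("need at least 6 points for a cylinder fit")

    n0 = initial.n_b
    theta0 = math.acos(np.clip(n0[2], -1, 1))
    phi0 = math.atan2(n0[1], n0[0])
    # pin the centre to the electrode plane along the initial axis
    if abs(n0[2]) < 1e-12:
        raise DegenerateGeometryError("initial axis parallel to electrode plane")
    pb0 = initial.p_b + (z_m - initial.p_b[2]) / n0[2] * n0
    x0 = np.array([theta0, phi0, pb0[0], pb0[1]])

    frozen = None
    if freeze_weights:
        frozen = compute_weights(p, initial, z_extent, electrode_z_extent,
                                 z_m, invert_weights).w

    def unpack(x):
        n = _axis_from_angles(x[0], x[1])
        pb = np.array([x[2], x[3], z_m])
        return pb, n

    def objective(x):
        pb, n = unpack(x)
        zeta = (p - pb) @ n
        if frozen is not None:
            w = frozen
        else:
            w = compute_weights(
                p, AxisEstimate(p_b=pb, n_b=n, zeta=zeta, stage="eval"),
                z_extent, electrode_z_extent, z_m, invert_weights).w
        return cylinder_objective(p, w, pb, n, r0)

    # Trust-region-style bounds around the initialization: the refinement is
    # a local polish of the SVD estimate, so the axis may swing at most
    # ~15 degrees and the centre shift at most ~5 cm from their start.
    bounds = [(x0[0] - math.radians(15), x0[0] + math.radians(15)),
              (x0[1] - math.pi, x0[1] + math.pi),
              (x0[2] - 0.05, x0[2] + 0.05),
              (x0[3] - 0.05, x0[3] + 0.05)]
    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                   options=dict(gtol=gtol, maxiter=max_iter))
    eps0 = objective(x0)
    if not res.success and res.fun > eps0:
        pb, n = unpack(x0)
        est = replace(initial, p_b=pb, n_b=n, zeta=(p - pb) @ n,
                      stage="optimal", eps_r=eps0, converged=False)
        return est
    pb, n = unpack(res.x)
    if n[2] < 0:
        n = -n
    return replace(initial, p_b=pb, n_b=n, zeta=(p - pb) @ n,
                   stage="optimal", eps_r=float(res.fun),
                   converged=bool(res.success))


def estimate_cluster_axis(cluster, delta_sigma, mesh,
                          invert_weights: bool = False,
                          freeze_weights: bool = True,
                          r0: float = FIT_RADIUS):
    """Full per-cluster estimate: trim, SVD initialization, cylinder fit.

    Returns (initial, optimal) AxisEstimates annotated with the cluster's
    trimmed mean difference and difference range.
    """
    values = np.asarray(getattr(delta_sigma, "delta_sigma", delta_sigma), float)
    dv = values[cluster.element_ids]
    keep = trim_outliers(dv)
    ids = cluster.element_ids[keep]
    pts = mesh.element_centroids[ids]
    if len(pts) < 6:
        raise EmptyClusterError("too few elements after outlier trim")

    z = mesh.vertices[:, 2]
    z_extent = (float(z.min()), float(z.max()))
    el_z = np.concatenate([z[n] for n in mesh.electrode_nodes])
    el_extent = (float(el_z.min()), float(el_z.max()))

    init = initial_axis_svd(pts)
    stats = dict(mean_delta=float(dv[keep].mean()),
                 delta_range=(float(dv[keep].min()), float(dv[keep].max())))
    init = replace(init, **stats)
    w0 = compute_weights(pts, init, z_extent, el_extent, mesh.z_m, invert_weights)
    init = replace(init, eps_r=cylinder_objective(pts, w0.w, init.p_b,
                                                  init.n_b, r0))
    opt = fit_cylinder(pts, init, z_extent, el_extent, mesh.z_m, r0=r0,
                       invert_weights=invert_weights,
                       freeze_weights=freeze_weights)
    opt = replace(opt, **stats)
    return init, opt


def select_bone_cluster(estimates: list[AxisEstimate],
                        rtol: float = SIMILAR_EXTENT_RTOL) -> AxisEstimate:
    """Pick the femur among candidate cluster estimates.

    Largest axial extent wins; candidates within ``rtol`` of the largest are
    tie-broken by lower mean conductivity difference, then by larger
    difference range.
    """
    if not estimates:
        raise NoBoneFoundError("no candidate clusters")
    extents = np.array([e.zeta_extent for e in estimates])
    best = extents.max()
    cand = [e for e in estimates if e.zeta_extent >= (1 - rtol) * best]
    if len(cand) == 1:
        return cand[0]
    means = np.array([e.mean_delta for e in cand])
    m0 = means.min()
    # near-identical mean differences cannot discriminate; fall back to the
    # cluster covering the widest difference range (the bone core reaches
    # the deepest values)
    low = np.flatnonzero(np.abs(means - m0) <= rtol / 2 * abs(m0) + 1e-15)
    if len(low) == 1:
        return cand[low[0]]
    ranges = [cand[i].delta_range[1] - cand[i].delta_range[0] for i in low]
    return cand[low[int(np.argmax(ranges))]]
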