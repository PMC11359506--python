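"""End-to-end orchestration: phantom -> forward -> inverse -> axis -> metrics.

A single run simulates the reference voltages V1 (all tissues) and the
boneless reference voltages V0 on the same fine mesh, so their difference
carries only the tissue signal; the sensitivity matrix and the
reconstruction live on an independently generated coarser mesh of the same
solid (data model and inversion model stay distinct).  The difference image
is segmented, a cylinder axis is fitted to the candidate bone cluster, and
the positional and angular deviations against the ground-truth marrow axis
are reported.

The study grid replicates the five phantom/configuration combinations:
cylinder with configurations 1-2 and realistic cross-section with
configurations 1-3.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import axisfit, forward, inverse, phantom, segmentation
from .axisfit import NoBoneFoundError
from .phantom import (CFG1_HOMOGENEOUS, CFG2_SKIN_FAT, CFG3_SKIN_FAT_INTRA,
                      CONDUCTIVITY_100KHZ, Tissue)

log = logging.getLogger(__name__)

#: The five tested model/configuration combinations.
STUDY_GRID = (
    ("cylinder", CFG1_HOMOGENEOUS),
    ("cylinder", CFG2_SKIN_FAT),
    ("realistic", CFG1_HOMOGENEOUS),
    ("realistic", CFG2_SKIN_FAT),
    ("realistic", CFG3_SKIN_FAT_INTRA),
)


class DeviationGeometryError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All knobs of one end-to-end run; defaults mirror the study conditions."""

    shape: str = "cylinder"
    config: str = CFG1_HOMOGENEOUS
    fine_density: float = 0.008      # m, simulation (V1) mesh
    inverse_density: float = 0.011   # m, reconstruction mesh
    lam: float = inverse.DEFAULT_LAMBDA
    cg_max_iter: int = 200           # truncated-CG budget (the regularizer)
    n_electrodes: int = 16
    amplitude: float = forward.DEFAULT_AMPLITUDE
    frequency: float = forward.DEFAULT_FREQUENCY
    contact_impedance: float = forward.DEFAULT_CONTACT_IMPEDANCE
    invert_weights: bool = True   # down-weight off-plane points in the fit
    noise_snr_db: float | None = None
    seed: int = 0
    phantom_kwargs: dict = field(default_factory=dict)


@dataclass
class DeviationEntry:
    delta_p_mm: float             # in-plane positional deviation at z_m
    phi_deg: float                # angular deviation, folded to [0, 90]
    delta_p3d_mm: float           # 3D true-centre-to-estimated-line distance
    stage: str


@dataclass
class RunResult:
    model: str
    config: str
    initial: DeviationEntry
    optimal: DeviationEntry
    estimate_initial: axisfit.AxisEstimate
    estimate_optimal: axisfit.AxisEstimate
    n_clusters: int
    recon: inverse.DeltaSigmaField
    metadata: dict


def conductivity_contrast(sigma_tissue: float,
                          sigma_ref: float = CONDUCTIVITY_100KHZ[Tissue.MUSCLE]
                          ) -> float:
    """Relative contrast |sigma_ref - sigma_tissue| / sigma_ref in percent."""
    return abs(sigma_ref - sigma_tissue) / sigma_ref * 100.0


def compute_deviation(estimate: axisfit.AxisEstimate, truth, z_m: float
                      ) -> DeviationEntry:
    """Positional and angular deviation of an axis estimate vs ground truth.

    Positional deviation is the in-plane distance between the two axes'
    intersections with the electrode plane ``z = z_m``; the angle is
    ``arccos |<n_b, n_f>|``.  The 3D point-to-line distance from the true
    marrow centre to the estimated axis is reported alongside.
    """
    for n in (estimate.n_b, truth.n_f):
        if abs(n[2]) < 1e-9:
            raise DeviationGeometryError("axis parallel to the electrode plane")
    q_est = estimate.p_b + (z_m - estimate.p_b[2]) / estimate.n_b[2] * estimate.n_b
    q_true = truth.o_m + (z_m - truth.o_m[2]) / truth.n_f[2] * truth.n_f
    dp = float(np.linalg.norm(q_est[:2] - q_true[:2])) * 1e3
    cosang = abs(float(np.dot(estimate.n_b, truth.n_f)))
    phi = math.degrees(math.acos(min(1.0, cosang)))
    d = q_true - estimate.p_b
    d3 = float(np.linalg.norm(d - (d @ estimate.n_b) * estimate.n_b)) * 1e3
    return DeviationEntry(delta_p_mm=dp, phi_deg=phi, delta_p3d_mm=d3,
                          stage=estimate.stage)


def _build_meshes(cfg: PipelineConfig):
    kw = dict(cfg.phantom_kwargs)
    kw.setdefault("n_electrodes", cfg.n_electrodes)
    fine = phantom.build_phantom(cfg.shape, mesh_density=cfg.fine_density,
                                 seed=cfg.seed, **kw)
    inv = phantom.build_phantom(cfg.shape, mesh_density=cfg.inverse_density,
                                seed=cfg.seed, **kw)
    return fine, inv


def _reconstruct(cfg: PipelineConfig, fine, inv, v1: forward.VoltageFrame,
                 protocol: forward.StimulationProtocol):
    # V0 is simulated on the same fine mesh as V1, so the measurement
    # difference carries only the bone/tissue signal; the sensitivity matrix
    # and the reconstruction live on the independently generated coarser
    # mesh, which keeps data generation and inversion models distinct.
    v0 = forward.solve_forward(fine, phantom.make_boneless(fine, cfg.config),
                               protocol, cfg.contact_impedance,
                               provenance="simulated_boneless_V0")
    sigma0 = phantom.make_boneless(inv, cfg.config)
    jac = forward.compute_jacobian(inv, sigma0, protocol,
                                   contact_impedance=cfg.contact_impedance)
    delta_v = v1.flatten() - v0.flatten()
    reg = inverse.RegularizationConfig(lam=cfg.lam, max_iter=cfg.cg_max_iter)
    recon = inverse.reconstruct_delta_sigma(delta_v, jac, inv, reg)
    return recon, jac, v0


def _segment_and_fit(cfg: PipelineConfig, inv, recon):
    try:
        partition = segmentation.compute_bin_partition(recon, inv)
    except segmentation.DegeneratePartitionError as err:
        raise NoBoneFoundError(
            f"degenerate difference image: {err}") from err
    clusters = segmentation.filter_clusters(
        segmentation.grow_clusters(partition, inv), inv)
    pairs = []
    for cl in clusters:
        try:
            pairs.append(axisfit.estimate_cluster_axis(
                cl, recon, inv, invert_weights=cfg.invert_weights))
        except (axisfit.EmptyClusterError, axisfit.DegenerateGeometryError):
            continue
    if not pairs:
        raise NoBoneFoundError(
            f"no usable cluster among {len(clusters)} candidates")
    chosen = axisfit.select_bone_cluster([opt for _, opt in pairs])
    idx = next(i for i, (_, opt) in enumerate(pairs) if opt is chosen)
    return pairs[idx][0], pairs[idx][1], len(clusters), partition


def run_pipeline(cfg: PipelineConfig,
                 _prebuilt=None) -> RunResult:
    """Execute one full phantom/configuration run."""
    protocol = forward.build_protocol(cfg.n_electrodes, "opposite",
                                      cfg.amplitude, cfg.frequency)
    if _prebuilt is None:
        fine, inv = _build_meshes(cfg)
        v1 = forward.solve_forward(fine, phantom.assign_conductivities(fine),
                                   protocol, cfg.contact_impedance,
                                   provenance="simulated_reference_V1")
    else:
        fine, inv, v1 = _prebuilt
    if cfg.noise_snr_db is not None:
        v1 = forward.add_measurement_noise(v1, cfg.noise_snr_db, cfg.seed)

    recon, jac, v0 = _reconstruct(cfg, fine, inv, v1, protocol)
    init, opt, n_clusters, _ = _segment_and_fit(cfg, inv, recon)

    truth = inv.true_axis
    result = RunResult(
        model=cfg.shape, config=cfg.config,
        initial=compute_deviation(init, truth, inv.z_m),
        optimal=compute_deviation(opt, truth, inv.z_m),
        estimate_initial=init, estimate_optimal=opt,
        n_clusters=n_clusters, recon=recon,
        metadata=dict(seed=cfg.seed, lam=cfg.lam,
                      fine_elements=fine.n_elements,
                      inverse_elements=inv.n_elements,
                      n_measurements=protocol.n_measurements,
                      cg_iterations=recon.solver_iterations),
    )
    log.info("%s/%s: initial %.2f mm / %.2f deg, optimal %.2f mm / %.2f deg",
             cfg.shape, cfg.config, result.initial.delta_p_mm,
             result.initial.phi_deg, result.optimal.delta_p_mm,
             result.optimal.phi_deg)
    return result


def run_study(base: PipelineConfig | None = None,
              grid=STUDY_GRID) -> list[RunResult]:
    """Run all study combinations, reusing each shape's meshes and V1."""
    base = base or PipelineConfig()
    cache = {}
    results = []
    for shape, config in grid:
        cfg = PipelineConfig(**{**asdict(base), "shape": shape,
                                "config": config})
        if shape not in cache:
            protocol = forward.build_protocol(cfg.n_electrodes, "opposite",
                                              cfg.amplitude, cfg.frequency)
            fine, inv = _build_meshes(cfg)
            v1 = forward.solve_forward(
                fine, phantom.assign_conductivities(fine), protocol,
                cfg.contact_impedance, provenance="simulated_reference_V1")
            cache[shape] = (fine, inv, v1)
        results.append(run_pipeline(cfg, _prebuilt=cache[shape]))
    return results


def study_report(results: list[RunResult]) -> pd.DataFrame:
    """Deviation table over all runs plus an arithmetic-mean row."""
    rows = [dict(model=r.model, config=r.config,
                 initial_dp_mm=r.initial.delta_p_mm,
                 optimal_dp_mm=r.optimal.delta_p_mm,
                 initial_phi_deg=r.initial.phi_deg,
                 optimal_phi_deg=r.optimal.phi_deg) for r in results]
    df = pd.DataFrame(rows)
    mean = df.drop(columns=["model", "config"]).mean()
    df.loc[len(df)] = dict(model="mean", config="", **mean.to_dict())
    return df
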