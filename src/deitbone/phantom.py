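"""Synthetic FEM thigh phantoms for differential EIT bone localization.

Generates conforming tetrahedral meshes of a thigh-like volume — concentric
skin / subcutaneous-fat shells around a muscle bulk with an embedded
cortical-bone + marrow cylinder — plus a 16-electrode single-plane belt and
the ground-truth marrow axis.  Two shapes are supported: a plain cylinder and
a "realistic" variant obtained by pushing every node of the cylinder mesh
through a smooth planar deformation map (anisotropic scaling plus low-order
harmonic boundary perturbation), so that the outer boundary and all internal
compartments are distorted consistently.

All coordinates are SI metres; conductivities S/m.  The electrode belt sits
at ``z_m = length / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from functools import cached_property

import numpy as np
from scipy.spatial import Delaunay


# --------------------------------------------------------------------------
# Tissue table (100 kHz conductivities, S/m)
# --------------------------------------------------------------------------

class Tissue(IntEnum):
    SKIN = 0
    FAT_SUBCUT = 1
    FAT_INTRA = 2
    MUSCLE = 3
    BONE = 4
    MARROW = 5


#: Conductivity of each tissue compartment at 100 kHz (S/m).
CONDUCTIVITY_100KHZ = {
    Tissue.SKIN: 0.065,
    Tissue.FAT_SUBCUT: 0.03,
    Tissue.FAT_INTRA: 0.03,
    Tissue.MUSCLE: 0.37,
    Tissue.BONE: 0.02,
    Tissue.MARROW: 0.002,
}

SUPPORTED_FREQUENCY_HZ = 100e3

#: Boneless-reference configurations: which tissues keep their tabulated
#: conductivity; everything else is replaced by muscle.
CFG1_HOMOGENEOUS = "cfg1_homogeneous"
CFG2_SKIN_FAT = "cfg2_skin_fat"
CFG3_SKIN_FAT_INTRA = "cfg3_skin_fat_intra"
CONFIGS = (CFG1_HOMOGENEOUS, CFG2_SKIN_FAT, CFG3_SKIN_FAT_INTRA)

_CONFIG_KEEPS = {
    CFG1_HOMOGENEOUS: frozenset(),
    CFG2_SKIN_FAT: frozenset({Tissue.SKIN, Tissue.FAT_SUBCUT}),
    CFG3_SKIN_FAT_INTRA: frozenset({Tissue.SKIN, Tissue.FAT_SUBCUT,
                                    Tissue.FAT_INTRA}),
}


class GeometryError(ValueError):
    """Requested phantom geometry is infeasible (e.g. bone exits the surface)."""


class MeshingError(RuntimeError):
    """The mesh generator produced a degenerate or inverted mesh."""


class LabelError(ValueError):
    """An element carries an unknown tissue label."""


class UnsupportedParameterError(ValueError):
    """A physical parameter outside the supported range was requested."""


# --------------------------------------------------------------------------
# Default dimensions (not tabulated anywhere authoritative; anatomically
# plausible mid-thigh values consistent with the 1.5 cm fitted-cylinder
# radius used downstream).  All overridable through build_phantom.
# --------------------------------------------------------------------------

OUTER_RADIUS = 0.070
BONE_RADIUS = 0.015
MARROW_RADIUS = 0.007
LENGTH = 0.300
SKIN_THICKNESS = 0.002
FAT_THICKNESS = 0.008
N_ELECTRODES = 16
ELECTRODE_DIAMETER = 0.007


@dataclass(frozen=True)
class DeformParams:
    """Smooth planar map turning the cylinder into a realistic cross-section.

    The map first perturbs the radius with low-order harmonics (amplitude
    growing quadratically from the centre so the map stays smooth and
    bijective), then applies anisotropic scaling.  The identity is
    ``DeformParams(1, 1, 0, 0)``.
    """

    scale_x: float = 1.25
    scale_y: float = 0.85
    amp1: float = 0.04
    amp2: float = 0.08
    amp3: float = 0.05
    phase2: float = 0.6
    phase3: float = 1.9
    reference_radius: float = OUTER_RADIUS

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        r = np.hypot(xy[..., 0], xy[..., 1])
        theta = np.arctan2(xy[..., 1], xy[..., 0])
        s = (r / self.reference_radius) ** 2
        g = 1.0 + s * (self.amp1 * np.cos(theta)
                       + self.amp2 * np.cos(2 * theta + self.phase2)
                       + self.amp3 * np.cos(3 * theta + self.phase3))
        out = np.empty_like(xy)
        out[..., 0] = self.scale_x * r * g * np.cos(theta)
        out[..., 1] = self.scale_y * r * g * np.sin(theta)
        return out


IDENTITY_DEFORM = DeformParams(1.0, 1.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class TrueAxis:
    """Ground-truth marrow-centre line: point ``o_m`` and unit vector ``n_f``."""

    o_m: np.ndarray
    n_f: np.ndarray


@dataclass
class ThighPhantom:
    """Tetrahedral thigh model with tissue labels and electrode belt."""

    vertices: np.ndarray          # (n_nodes, 3) metres
    tets: np.ndarray              # (n_elems, 4) int
    tissue_label: np.ndarray      # (n_elems,) Tissue values
    electrode_nodes: list         # 16 int arrays (boundary node ids)
    electrode_faces: list         # 16 (k, 3) arrays of boundary triangles
    ground_nodes: np.ndarray      # common-ground node set
    z_m: float                    # electrode-plane height (m)
    true_axis: TrueAxis
    shape: str                    # "cylinder" | "realistic"
    params: dict = field(default_factory=dict)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    @cached_property
    def element_volumes(self) -> np.ndarray:
        v = self.vertices[self.tets]
        d = v[:, 1:] - v[:, :1]
        return np.abs(np.linalg.det(d)) / 6.0

    @cached_property
    def element_centroids(self) -> np.ndarray:
        return self.vertices[self.tets].mean(axis=1)

    @cached_property
    def _face_table(self):
        """All element faces, each as a sorted vertex triple."""
        t = self.tets
        faces = np.concatenate([
            t[:, [1, 2, 3]], t[:, [0, 2, 3]], t[:, [0, 1, 3]], t[:, [0, 1, 2]],
        ])
        owner = np.tile(np.arange(len(t)), 4)
        faces = np.sort(faces, axis=1)
        order = np.lexsort(faces.T[::-1])
        return faces[order], owner[order]

    @cached_property
    def face_adjacency(self) -> np.ndarray:
        """(n_pairs, 2) element pairs sharing a triangular face."""
        faces, owner = self._face_table
        same = np.all(faces[1:] == faces[:-1], axis=1)
        return np.column_stack([owner[:-1][same], owner[1:][same]])

    @cached_property
    def boundary_faces(self) -> np.ndarray:
        """(n_bfaces, 3) vertex triples appearing in exactly one element."""
        faces, _ = self._face_table
        same = np.all(faces[1:] == faces[:-1], axis=1)
        interior = np.concatenate([same, [False]]) | np.concatenate([[False], same])
        return faces[~interior]

    @cached_property
    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_faces)

    @cached_property
    def surface_elements(self) -> np.ndarray:
        """Element ids owning at least one boundary face."""
        faces, owner = self._face_table
        same = np.all(faces[1:] == faces[:-1], axis=1)
        interior = np.concatenate([same, [False]]) | np.concatenate([[False], same])
        return np.unique(owner[~interior])

    def is_conforming(self) -> bool:
        """Every face is shared by exactly one or two elements."""
        faces, _ = self._face_table
        _, counts = np.unique(faces, axis=0, return_counts=True)
        return bool(np.all(counts <= 2))


@dataclass
class ConductivityField:
    """Per-element conductivity on a phantom mesh."""

    sigma: np.ndarray
    config: str
    frequency: float

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("conductivities must be strictly positive")


# --------------------------------------------------------------------------
# Disk triangulation and prism extrusion
# --------------------------------------------------------------------------

def _disk_points(outer_radius, h, interfaces, n_boundary):
    """Ring-structured point set covering the disk of ``outer_radius``.

    Radial stations honour the tissue interface radii so shell labels are
    crisp; the outermost ring has exactly ``n_boundary`` equally spaced nodes
    starting at angle 0 (so electrode centres coincide with mesh nodes).
    """
    r_fat_in, r_skin_in = interfaces
    stations = list(np.linspace(0.0, r_fat_in, max(2, int(round(r_fat_in / h)) + 1)))
    n_fat = max(1, int(round((r_skin_in - r_fat_in) / h)))
    stations += list(np.linspace(r_fat_in, r_skin_in, n_fat + 1)[1:])
    stations.append(outer_radius)

    pts = [np.zeros((1, 2))]
    for k, r in enumerate(stations[1:], start=1):
        if r >= r_skin_in - 1e-12:
            n_k = n_boundary
            offset = 0.0
        else:
            n_k = max(6, int(round(2 * math.pi * r / h)))
            offset = (k % 2) * math.pi / n_k
        th = offset + 2 * math.pi * np.arange(n_k) / n_k
        pts.append(np.column_stack([r * np.cos(th), r * np.sin(th)]))
    return np.concatenate(pts)


def _z_stations(length, z_m, h, fine_half_width):
    """Layer heights, symmetric about the electrode plane, refined near it."""
    hf = h / 2.0
    n_fine = max(1, int(round(fine_half_width / hf)))
    fine = z_m + hf * np.arange(n_fine + 1)
    top_span = length - fine[-1]
    n_coarse = max(1, int(math.ceil(top_span / (1.5 * h))))
    coarse = np.linspace(fine[-1], length, n_coarse + 1)[1:]
    upper = np.concatenate([fine, coarse])
    lower = (2 * z_m - upper[1:])[::-1]
    return np.concatenate([lower, upper])


_PRISM_ROT = {0: (0, 1, 2, 3, 4, 5), 1: (1, 2, 0, 4, 5, 3), 2: (2, 0, 1, 5, 3, 4),
              3: (3, 5, 4, 0, 2, 1), 4: (4, 3, 5, 1, 0, 2), 5: (5, 4, 3, 2, 1, 0)}


def _split_prisms(tri, n_slice, n_layers):
    """Split each extruded prism into 3 tets with the min-vertex diagonal rule.

    Every quadrilateral face takes the diagonal through its lowest-numbered
    vertex, which is a face-local rule and therefore yields a conforming
    tetrahedral mesh across neighbouring prisms.
    """
    tets = []
    for layer in range(n_layers):
        base = layer * n_slice
        bot = tri + base
        top = bot + n_slice
        prisms = np.concatenate([bot, top], axis=1)  # (n_tri, 6)
        argmin = np.argmin(prisms, axis=1)
        for j in range(6):
            rows = prisms[argmin == j][:, _PRISM_ROT[j]]
            if len(rows) == 0:
                continue
            v = rows.T  # v[0..5]
            use15 = np.minimum(v[1], v[5]) < np.minimum(v[2], v[4])
            a = rows[use15]
            tets.append(np.concatenate([a[:, [0, 1, 2, 5]], a[:, [0, 1, 5, 4]],
                                        a[:, [0, 4, 5, 3]]]))
            b = rows[~use15]
            tets.append(np.concatenate([b[:, [0, 1, 2, 4]], b[:, [0, 4, 2, 5]],
                                        b[:, [0, 4, 5, 3]]]))
    return np.concatenate(tets)


def _orient_positive(vertices, tets):
    v = vertices[tets]
    det = np.linalg.det(v[:, 1:] - v[:, :1])
    flip = det < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    if np.any(np.abs(np.linalg.det(vertices[tets][:, 1:] - vertices[tets][:, :1])) < 1e-18):
        raise MeshingError("degenerate (zero-volume) tetrahedra in generated mesh")
    return tets


# --------------------------------------------------------------------------
# Ground-truth bone axis
# --------------------------------------------------------------------------

def _bone_centre_at(z, bone_offset, tilt_rad, tilt_azimuth, z_m):
    """Undeformed marrow-centre (x, y) at height z."""
    lateral = math.tan(tilt_rad) * (np.asarray(z) - z_m)
    return np.stack([
        bone_offset[0] + lateral * math.cos(tilt_azimuth),
        bone_offset[1] + lateral * math.sin(tilt_azimuth),
    ], axis=-1)


def _fit_line(points):
    """Least-squares 3D line through points: (point on line, unit direction)."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    n = vt[0]
    if n[2] < 0:
        n = -n
    return c, n / np.linalg.norm(n)


# --------------------------------------------------------------------------
# Public operations
# --------------------------------------------------------------------------

def build_phantom(shape="cylinder",
                  outer_radius=OUTER_RADIUS,
                  bone_radius=BONE_RADIUS,
                  marrow_radius=MARROW_RADIUS,
                  length=LENGTH,
                  bone_offset=(0.0, 0.0),
                  bone_tilt_deg=0.0,
                  tilt_azimuth_deg=0.0,
                  mesh_density=0.007,
                  deform_params=None,
                  seed=0,
                  skin_thickness=SKIN_THICKNESS,
                  fat_thickness=FAT_THICKNESS,
                  n_electrodes=N_ELECTRODES,
                  electrode_diameter=ELECTRODE_DIAMETER,
                  n_fat_inclusions=3) -> ThighPhantom:
    """Generate a labelled tetrahedral thigh phantom.

    Parameters
    ----------
    shape : {"cylinder", "realistic"}
        ``realistic`` pushes the cylinder mesh through ``deform_params``
        (default: anisotropic 1.25x/0.85x scaling with 2nd/3rd harmonic
        boundary perturbation) and, unless overridden, offsets the bone
        laterally and seeds intramuscular fat inclusions.
    bone_offset : (float, float)
        In-plane marrow-centre position at the electrode plane, metres,
        *before* deformation.
    mesh_density : float
        Target in-plane element edge length in metres.  The belt region is
        refined axially and the outer boundary azimuthally so that the 7 mm
        electrodes are resolved by a few boundary faces.
    seed : int
        Seeds the intramuscular-inclusion placement only; the mesh itself is
        deterministic.
    """
    if not (0 < marrow_radius < bone_radius < outer_radius):
        raise GeometryError("need 0 < marrow_radius < bone_radius < outer_radius")
    if length <= 0:
        raise GeometryError("length must be positive")
    if shape not in ("cylinder", "realistic"):
        raise GeometryError(f"unknown shape {shape!r}")

    bone_offset = tuple(np.broadcast_to(np.asarray(bone_offset, float), (2,)))
    if shape == "realistic":
        if deform_params is None:
            deform_params = DeformParams(reference_radius=outer_radius)
        if bone_offset == (0.0, 0.0):
            bone_offset = (0.012, 0.0)
    else:
        if deform_params is None:
            deform_params = replace(IDENTITY_DEFORM, reference_radius=outer_radius)
        n_fat_inclusions = 0

    z_m = length / 2.0
    tilt = math.radians(bone_tilt_deg)
    azim = math.radians(tilt_azimuth_deg)
    r_skin_in = outer_radius - skin_thickness
    r_fat_in = r_skin_in - fat_thickness

    # feasibility: bone must stay inside the outer surface over the full length
    for z in np.linspace(0.0, length, 33):
        c = _bone_centre_at(z, bone_offset, tilt, azim, z_m)
        if np.hypot(*c) + bone_radius >= outer_radius:
            raise GeometryError("bone axis exits the outer surface")

    h = float(mesh_density)
    n_boundary = n_electrodes * max(1, int(round(2 * math.pi * outer_radius
                                                 / (n_electrodes * h / 2))))
    pts2 = _disk_points(outer_radius, h, (r_fat_in, r_skin_in), n_boundary)
    tri = Delaunay(pts2).simplices

    zs = _z_stations(length, z_m, h, fine_half_width=1.5 * electrode_diameter / 2)
    n_slice = len(pts2)
    vertices = np.empty((n_slice * len(zs), 3))
    for i, z in enumerate(zs):
        vertices[i * n_slice:(i + 1) * n_slice, :2] = pts2
        vertices[i * n_slice:(i + 1) * n_slice, 2] = z
    tets = _split_prisms(tri, n_slice, len(zs) - 1)
    tets = _orient_positive(vertices, tets)

    # ---- tissue labels (in the undeformed frame) -------------------------
    cent = vertices[tets].mean(axis=1)
    r_c = np.hypot(cent[:, 0], cent[:, 1])
    bc = _bone_centre_at(cent[:, 2], bone_offset, tilt, azim, z_m)
    d_axis = np.hypot(cent[:, 0] - bc[:, 0], cent[:, 1] - bc[:, 1]) \
        * math.cos(tilt)  # perpendicular distance to the tilted axis
    label = np.full(len(tets), int(Tissue.MUSCLE))
    label[r_c > r_fat_in] = int(Tissue.FAT_SUBCUT)
    label[r_c > r_skin_in] = int(Tissue.SKIN)
    label[d_axis <= bone_radius] = int(Tissue.BONE)
    label[d_axis <= marrow_radius] = int(Tissue.MARROW)

    rng = np.random.default_rng(seed)
    inclusions = []
    for _ in range(n_fat_inclusions):
        for _attempt in range(100):
            ang = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(0.45, 0.75) * r_fat_in
            cx, cy = rad * math.cos(ang), rad * math.sin(ang)
            cz = rng.uniform(0.3, 0.7) * length
            # Distinctly shorter than the bone column: intramuscular fat
            # pockets a few centimetres long, so their axial extent never
            # rivals the femur's.
            ax = rng.uniform(0.007, 0.011)
            ay = rng.uniform(0.005, 0.008)
            az = rng.uniform(0.015, 0.030)
            centre_b = _bone_centre_at(cz, bone_offset, tilt, azim, z_m)
            if (math.hypot(cx - centre_b[0], cy - centre_b[1])
                    > bone_radius + max(ax, ay) + 0.020
                    and math.hypot(cx, cy) + max(ax, ay) < r_fat_in - 0.003):
                inclusions.append((cx, cy, cz, ax, ay, az))
                break
    for (cx, cy, cz, ax, ay, az) in inclusions:
        inside = ((cent[:, 0] - cx) ** 2 / ax ** 2
                  + (cent[:, 1] - cy) ** 2 / ay ** 2
                  + (cent[:, 2] - cz) ** 2 / az ** 2) <= 1.0
        label[inside & (label == int(Tissue.MUSCLE))] = int(Tissue.FAT_INTRA)

    # ---- deformation -----------------------------------------------------
    vertices = vertices.copy()
    vertices[:, :2] = deform_params.apply(vertices[:, :2])
    tets = _orient_positive(vertices, tets)

    # ---- ground-truth marrow axis (post-deformation) ---------------------
    z_samples = np.linspace(0.0, length, 65)
    line_xy = deform_params.apply(
        _bone_centre_at(z_samples, bone_offset, tilt, azim, z_m))
    line = np.column_stack([line_xy, z_samples])
    c0, n_f = _fit_line(line)
    # report the marrow centre in the electrode plane
    o_m = c0 + (z_m - c0[2]) / n_f[2] * n_f
    true_axis = TrueAxis(o_m=o_m, n_f=n_f)

    phantom = ThighPhantom(
        vertices=vertices, tets=tets, tissue_label=label,
        electrode_nodes=[], electrode_faces=[], ground_nodes=np.array([], int),
        z_m=z_m, true_axis=true_axis, shape=shape,
        params=dict(outer_radius=outer_radius, bone_radius=bone_radius,
                    marrow_radius=marrow_radius, length=length,
                    bone_offset=bone_offset, bone_tilt_deg=bone_tilt_deg,
                    tilt_azimuth_deg=tilt_azimuth_deg, mesh_density=h,
                    skin_thickness=skin_thickness, fat_thickness=fat_thickness,
                    n_electrodes=n_electrodes,
                    electrode_diameter=electrode_diameter,
                    deform=vars(deform_params) if not isinstance(deform_params, dict)
                    else deform_params,
                    inclusions=inclusions, seed=seed),
    )
    _attach_electrodes(phantom, deform_params, outer_radius, n_electrodes,
                       electrode_diameter)
    return phantom


def _attach_electrodes(phantom, deform_params, outer_radius, n_electrodes,
                       electrode_diameter):
    """Select boundary faces under each electrode disc and the ground node.

    Electrode centres sit equi-angularly (undeformed frame) on the outer
    surface at ``z_m`` and are carried through the deformation map, so both
    a fine and a coarse mesh of the same solid agree on electrode positions.
    """
    bfaces = phantom.boundary_faces
    fc = phantom.vertices[bfaces].mean(axis=1)
    lateral = (np.hypot(fc[:, 0], fc[:, 1])
               > 0.3 * outer_radius)  # exclude end caps
    radius = electrode_diameter / 2.0

    theta = 2 * math.pi * np.arange(n_electrodes) / n_electrodes
    centres_xy = deform_params.apply(
        np.column_stack([outer_radius * np.cos(theta),
                         outer_radius * np.sin(theta)]))
    centres = np.column_stack([centres_xy, np.full(n_electrodes, phantom.z_m)])

    el_faces, el_nodes = [], []
    for c in centres:
        d = np.linalg.norm(fc - c, axis=1)
        pick = np.flatnonzero((d <= radius) & lateral)
        if len(pick) == 0:  # very coarse mesh: use the nearest lateral face
            pick = np.array([np.flatnonzero(lateral)[
                np.argmin(d[lateral])]])
        el_faces.append(bfaces[pick])
        el_nodes.append(np.unique(bfaces[pick]))
    phantom.electrode_faces = el_faces
    phantom.electrode_nodes = el_nodes

    # common ground: boundary node mid-way between electrodes 0 and 1
    th_g = math.pi / n_electrodes
    g_xy = deform_params.apply(np.array([outer_radius * math.cos(th_g),
                                         outer_radius * math.sin(th_g)]))
    g = np.array([g_xy[0], g_xy[1], phantom.z_m])
    bnodes = phantom.boundary_nodes
    taken = np.unique(np.concatenate(el_nodes))
    free = np.setdiff1d(bnodes, taken)
    pool = free if len(free) else bnodes
    phantom.ground_nodes = np.array(
        [pool[np.argmin(np.linalg.norm(phantom.vertices[pool] - g, axis=1))]])


def assign_conductivities(phantom: ThighPhantom, config: str = "reference",
                          frequency: float = SUPPORTED_FREQUENCY_HZ
                          ) -> ConductivityField:
    """Full-tissue conductivity field (the V1-generating reference state)."""
    if not math.isclose(frequency, SUPPORTED_FREQUENCY_HZ):
        raise UnsupportedParameterError(
            f"only {SUPPORTED_FREQUENCY_HZ / 1e3:.0f} kHz conductivities are tabulated")
    labels = phantom.tissue_label
    valid = {int(t) for t in Tissue}
    bad = set(np.unique(labels)) - valid
    if bad:
        raise LabelError(f"unknown tissue labels {sorted(bad)}")
    lut = np.empty(len(Tissue))
    for t in Tissue:
        lut[int(t)] = CONDUCTIVITY_100KHZ[t]
    return ConductivityField(sigma=lut[labels], config=config, frequency=frequency)


def make_boneless(phantom: ThighPhantom, config: str,
                  frequency: float = SUPPORTED_FREQUENCY_HZ) -> ConductivityField:
    """Boneless-reference conductivity field used to simulate V0.

    Bone and marrow are always replaced by muscle; ``config`` selects which
    other compartments keep their tabulated values (cfg1: none — homogeneous
    muscle; cfg2: skin + subcutaneous fat; cfg3: additionally the
    intramuscular fat).
    """
    if config not in _CONFIG_KEEPS:
        raise UnsupportedParameterError(f"unknown configuration {config!r}")
    ref = assign_conductivities(phantom, config=config, frequency=frequency)
    sigma = np.full(phantom.n_elements, CONDUCTIVITY_100KHZ[Tissue.MUSCLE])
    keep = _CONFIG_KEEPS[config]
    for t in keep:
        mask = phantom.tissue_label == int(t)
        sigma[mask] = ref.sigma[mask]
    return ConductivityField(sigma=sigma, config=config, frequency=frequency)
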