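"""Binning and region-growing segmentation of the reconstructed difference image.

The reconstructed per-element conductivity difference is partitioned into 15
bins: after discarding electrode-proximal elements, the sorted values are
scanned for a "flat" central region (where most elements carry a
near-constant background difference), a robust line is fitted through it,
and the RMS deviation of the flat region from that line defines a dead band
around the background level.  Nine equal bins (b1-b9) cover the values below
the band, five (b11-b15) the values above; the band itself is bin b10.

Because bone and marrow are the least conductive tissues, the femur appears
in the low bins; elements in bins above ``b_max = 7`` are never clustered
(b8 is deliberately left out as a guard gap, b9 holds transitional
elements).  Clusters are face-connected components grown from ascending
element ids; small clusters touching the outer surface or an electrode are
discarded as reconstruction artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Reference sample count the flat-region slope threshold was calibrated on.
N0_REFERENCE = 230_000
SLOPE_WINDOW = 100
SLOPE_FACTOR = 0.002
B_LO = 9
B_HI = 5
B_MAX = 7
MIN_CLUSTER = 64
#: Elements with a vertex within this many electrode diameters of an
#: electrode centroid are excluded from the partition.  The high-sensitivity
#: artefact zone around the belt extends to roughly five electrode diameters
#: (about 1.3 electrode spacings for a 16-electrode belt on a thigh-sized
#: section), as calibrated on the cylinder verification phantom.
ELECTRODE_EXCLUSION_DIAMETERS = 5.0


class DegeneratePartitionError(ValueError):
    """The difference field has no usable spread (e.g. all values equal)."""


class PartitionSizeError(ValueError):
    pass


@dataclass
class BinPartition:
    bin_edges: np.ndarray          # 16 ascending boundaries -> 15 bins
    bin_index: np.ndarray          # per element, 1..15; 0 marks excluded
    excluded_elements: np.ndarray  # electrode-proximal element ids
    flat_stats: tuple              # (x0, y0, dy, delta_rms)

    def elements_in(self, *bins) -> np.ndarray:
        return np.flatnonzero(np.isin(self.bin_index, bins))


@dataclass
class Cluster:
    element_ids: np.ndarray
    touches_surface: bool = False
    touches_electrode: bool = False
    mean_delta: float = 0.0
    delta_range: tuple = (0.0, 0.0)

    @property
    def size(self) -> int:
        return len(self.element_ids)


def electrode_proximal_elements(mesh, exclusion_radius=None) -> np.ndarray:
    """Element ids with a vertex near any electrode centroid."""
    if not len(mesh.electrode_nodes):
        return np.array([], dtype=int)
    if exclusion_radius is None:
        exclusion_radius = (ELECTRODE_EXCLUSION_DIAMETERS
                            * getattr(mesh, "params", {}).get(
                                "electrode_diameter", 0.007))
    centres = np.array([mesh.vertices[n].mean(axis=0)
                        for n in mesh.electrode_nodes])
    d = np.linalg.norm(mesh.vertices[:, None, :] - centres[None], axis=2)
    close_node = d.min(axis=1) <= exclusion_radius
    return np.flatnonzero(close_node[mesh.tets].any(axis=1))


def flat_region(sorted_values: np.ndarray,
                window: int = SLOPE_WINDOW,
                factor: float = SLOPE_FACTOR,
                n0: int = N0_REFERENCE) -> slice:
    """Contiguous index range of the flat part of the sorted difference values.

    A sample is flat when its lag-``window`` slope falls below the mean of
    the first and last slopes scaled by ``factor * n0 / N``; the returned
    range spans from the first to the last flat sample inclusive, as a
    half-open slice.  Isolated as a single function so the selector can be
    swapped wholesale.
    """
    N = len(sorted_values)
    slope = sorted_values[window:] - sorted_values[:-window]
    thresh = 0.5 * (slope[0] + slope[-1]) * factor * (n0 / N)
    flat = np.flatnonzero(slope < thresh)
    if len(flat) == 0:
        raise DegeneratePartitionError("no flat region in sorted differences")
    return slice(int(flat[0]), int(flat[-1]) + window + 1)


def compute_bin_partition(delta_sigma, mesh, *,
                          exclusion_radius=None,
                          window: int = SLOPE_WINDOW,
                          factor: float = SLOPE_FACTOR,
                          n0: int = N0_REFERENCE,
                          b_lo: int = B_LO, b_hi: int = B_HI) -> BinPartition:
    """Assign every retained element to one of 15 difference bins."""
    values = np.asarray(getattr(delta_sigma, "delta_sigma", delta_sigma), float)
    if values.shape[0] != mesh.n_elements:
        raise ValueError("delta_sigma length must equal element count")
    excluded = electrode_proximal_elements(mesh, exclusion_radius)
    retained = np.setdiff1d(np.arange(mesh.n_elements), excluded)
    if len(retained) < 2 * window:
        raise PartitionSizeError(
            f"need at least {2 * window} retained elements, got {len(retained)}")

    vals = values[retained]
    order = np.argsort(vals, kind="stable")
    v_sorted = vals[order]
    if np.ptp(v_sorted) == 0:
        raise DegeneratePartitionError("all difference values identical")

    sl = flat_region(v_sorted, window, factor, n0)
    flat = v_sorted[sl]
    x = np.arange(sl.start, sl.stop, dtype=float)
    x0 = float(np.median(x))
    y0 = float(np.median(flat))
    dx = x - x0
    denom = float(np.sum(dx * dx))
    dy = float(np.sum(dx * (flat - y0)) / denom) if denom > 0 else 0.0
    resid = flat - (y0 + dx * dy)
    d_rms = float(np.sqrt(np.mean(resid ** 2)))
    if d_rms == 0.0:
        raise DegeneratePartitionError("flat region has zero RMS deviation")

    v_min, v_max = float(v_sorted[0]), float(v_sorted[-1])
    lo_start, lo_stop = v_min + d_rms, y0 - d_rms
    hi_start, hi_stop = y0 + d_rms, v_max - d_rms
    if not lo_start < lo_stop:
        raise DegeneratePartitionError("low bin interval collapsed")
    if not hi_start < hi_stop:
        # Nearly no values above the flat band (all tissue contrasts are
        # negative here); keep the high bins as an empty sliver so the
        # partition stays well-formed — they are never clustered anyway.
        hi_stop = hi_start + b_hi * np.finfo(float).eps * max(1.0, abs(hi_start))
    edges = np.concatenate([
        np.linspace(lo_start, lo_stop, b_lo + 1),       # b1..b9 edges
        np.linspace(hi_start, hi_stop, b_hi + 1),       # b11..b15 edges
    ])

    bins = np.zeros(mesh.n_elements, dtype=int)
    v = values[retained]
    lo_w = (lo_stop - lo_start) / b_lo
    hi_w = (hi_stop - hi_start) / b_hi
    idx = np.empty(len(v), dtype=int)
    below = v < lo_stop
    idx[below] = 1 + np.clip(((v[below] - lo_start) // lo_w).astype(int),
                             0, b_lo - 1)
    band = (v >= lo_stop) & (v < hi_start)
    idx[band] = b_lo + 1                                # b10
    above = v >= hi_start
    idx[above] = b_lo + 2 + np.clip(((v[above] - hi_start) // hi_w).astype(int),
                                    0, b_hi - 1)
    bins[retained] = idx
    return BinPartition(bin_edges=edges, bin_index=bins,
                        excluded_elements=excluded,
                        flat_stats=(x0, y0, dy, d_rms))


def _adjacency_lists(mesh):
    pairs = mesh.face_adjacency
    n = mesh.n_elements
    counts = np.zeros(n, dtype=int)
    np.add.at(counts, pairs[:, 0], 1)
    np.add.at(counts, pairs[:, 1], 1)
    offs = np.concatenate([[0], np.cumsum(counts)])
    neigh = np.empty(offs[-1], dtype=int)
    fill = offs[:-1].copy()
    for a, b in pairs:
        neigh[fill[a]] = b
        fill[a] += 1
        neigh[fill[b]] = a
        fill[b] += 1
    return offs, neigh


def grow_clusters(partition: BinPartition, mesh,
                  b_max: int = B_MAX) -> list[Cluster]:
    """Face-connected flood fill over elements with bin index <= b_max.

    Seeds iterate in ascending element id, so cluster numbering is
    deterministic.  Excluded (bin 0) and high-bin elements are never
    assigned.
    """
    eligible = (partition.bin_index >= 1) & (partition.bin_index <= b_max)
    offs, neigh = _adjacency_lists(mesh)
    assigned = np.full(mesh.n_elements, -1, dtype=int)
    clusters = []
    for seed in range(mesh.n_elements):
        if not eligible[seed] or assigned[seed] >= 0:
            continue
        k = len(clusters)
        stack = [seed]
        assigned[seed] = k
        members = []
        while stack:
            e = stack.pop()
            members.append(e)
            for nb in neigh[offs[e]:offs[e + 1]]:
                if eligible[nb] and assigned[nb] < 0:
                    assigned[nb] = k
                    stack.append(nb)
        clusters.append(Cluster(element_ids=np.sort(np.array(members))))
    return clusters


def filter_clusters(clusters: list[Cluster], mesh,
                    min_size: int = MIN_CLUSTER) -> list[Cluster]:
    """Discard small clusters touching the outer surface or an electrode.

    A cluster is removed iff it has fewer than ``min_size`` elements AND is
    adjacent to the mesh boundary or to any electrode node set.  Survivors
    are returned sorted by ascending size (the downstream axis estimator
    processes them in that order).
    """
    surface = set(mesh.surface_elements.tolist())
    el_nodes = set()
    for nodes in mesh.electrode_nodes:
        el_nodes.update(nodes.tolist())
    kept = []
    for cl in clusters:
        cl.touches_surface = any(e in surface for e in cl.element_ids)
        cl.touches_electrode = bool(
            el_nodes.intersection(mesh.tets[cl.element_ids].ravel().tolist()))
        if cl.size < min_size and (cl.touches_surface or cl.touches_electrode):
            continue
        kept.append(cl)
    return sorted(kept, key=lambda c: c.size)
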