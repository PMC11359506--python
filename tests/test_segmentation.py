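"""Binning and region growing against small constructed meshes and oracles."""

import numpy as np
import pytest

from deitbone import segmentation as sg
from deitbone.phantom import ThighPhantom, TrueAxis


def _stub_mesh(vertices, tets, electrode_nodes=()):
    """A bare tetrahedral mesh reusing the phantom's cached geometry."""
    return ThighPhantom(
        vertices=np.asarray(vertices, float), tets=np.asarray(tets, int),
        tissue_label=np.zeros(len(tets), int),
        electrode_nodes=[np.asarray(n, int) for n in electrode_nodes],
        electrode_faces=[], ground_nodes=np.array([0]),
        z_m=0.0, true_axis=TrueAxis(np.zeros(3), np.array([0, 0, 1.0])),
        shape="cylinder")


def _chain_mesh(n):
    """n tets in a face-connected chain: tet k = vertices (k, k+1, k+2, k+3)."""
    verts = np.random.default_rng(0).standard_normal((n + 3, 3))
    tets = np.array([[k, k + 1, k + 2, k + 3] for k in range(n)])
    return _stub_mesh(verts, tets)


@pytest.fixture(scope="module")
def synthetic_partition():
    """Flat background plus a distinct negative mode, partitioned."""
    rng = np.random.default_rng(42)
    values = np.concatenate([rng.normal(0.0, 1e-4, 10_000),
                             np.full(500, -0.3)])
    mesh = _chain_mesh(len(values))
    part = sg.compute_bin_partition(values, mesh)
    return values, part


def test_fifteen_bins_nine_below_five_above(synthetic_partition):
    _, part = synthetic_partition
    assert len(part.bin_edges) == 16
    assert np.all(np.diff(part.bin_edges[:10]) > 0)   # low edges ascending
    assert part.bin_index.max() <= 15
    assert part.bin_index.min() >= 1                  # nothing excluded here


def test_uniform_partition_arithmetic():
    edges = np.linspace(-0.9, -0.1, 10)
    assert edges[0] == pytest.approx(-0.9)
    widths = np.diff(edges)
    np.testing.assert_allclose(widths, 0.0888888889, rtol=1e-8)


def test_negative_mode_lands_below_flat_band(synthetic_partition):
    values, part = synthetic_partition
    low = part.bin_index[values == -0.3]
    assert np.all((low >= 1) & (low <= 9))
    background = part.bin_index[np.abs(values) < 5e-4]
    assert np.all(background == 10)


def test_flat_region_is_contiguous_and_dominant(synthetic_partition):
    values, _ = synthetic_partition
    sl = sg.flat_region(np.sort(values))
    assert sl.stop - sl.start > 0.5 * len(values)


def test_degenerate_field_rejected():
    mesh = _chain_mesh(300)
    with pytest.raises(sg.DegeneratePartitionError):
        sg.compute_bin_partition(np.zeros(300), mesh)


def test_too_few_elements_rejected():
    mesh = _chain_mesh(50)
    with pytest.raises(sg.PartitionSizeError):
        sg.compute_bin_partition(np.linspace(0, 1, 50), mesh)


def _grow(mesh, bins):
    part = sg.BinPartition(bin_edges=np.arange(16.0), bin_index=bins,
                           excluded_elements=np.array([], int),
                           flat_stats=(0, 0, 0, 1))
    return sg.grow_clusters(part, mesh)


def test_two_adjacent_low_bin_tets_form_one_cluster():
    mesh = _chain_mesh(2)
    clusters = _grow(mesh, np.array([5, 7]))
    assert len(clusters) == 1
    assert set(clusters[0].element_ids) == {0, 1}


def test_bin_eight_is_discarded_as_gap():
    mesh = _chain_mesh(2)
    clusters = _grow(mesh, np.array([7, 8]))
    assert len(clusters) == 1
    assert set(clusters[0].element_ids) == {0}


def test_excluded_elements_never_cluster():
    mesh = _chain_mesh(3)
    clusters = _grow(mesh, np.array([3, 0, 3]))   # middle element excluded
    assert [set(c.element_ids) for c in clusters] == [{0}, {2}]


def test_clusters_match_networkx_components_on_random_meshes():
    """Flood fill equals connected components of the bin<=7 subgraph,
    with adjacency recomputed by brute force and components by networkx."""
    import itertools
    import networkx as nx
    from scipy.spatial import Delaunay

    rng = np.random.default_rng(99)
    for trial in range(50):
        pts = rng.standard_normal((30 + int(rng.integers(0, 30)), 3))
        tets = Delaunay(pts).simplices
        mesh = _stub_mesh(pts, tets)
        bins = rng.integers(1, 16, len(tets))
        clusters = _grow(mesh, bins)

        faces = {}
        for e, tet in enumerate(tets):
            for tri in itertools.combinations(sorted(tet), 3):
                faces.setdefault(tri, []).append(e)
        g = nx.Graph()
        g.add_nodes_from(np.flatnonzero(bins <= 7).tolist())
        for owners in faces.values():
            for a, b in itertools.combinations(owners, 2):
                if bins[a] <= 7 and bins[b] <= 7:
                    g.add_edge(a, b)
        expected = {frozenset(c) for c in nx.connected_components(g)}
        got = {frozenset(c.element_ids.tolist()) for c in clusters}
        assert got == expected, f"trial {trial}"


def test_growth_is_deterministic():
    rng = np.random.default_rng(3)
    from scipy.spatial import Delaunay
    pts = rng.standard_normal((60, 3))
    mesh = _stub_mesh(pts, Delaunay(pts).simplices)
    bins = rng.integers(1, 16, mesh.n_elements)
    a = _grow(mesh, bins)
    b = _grow(mesh, bins)
    assert [c.element_ids.tolist() for c in a] == \
           [c.element_ids.tolist() for c in b]


class _FilterMesh:
    """Minimal mesh stub exposing what filter_clusters touches."""

    def __init__(self, n, surface, tets, electrode_nodes):
        self.surface_elements = np.asarray(surface, int)
        self.tets = np.asarray(tets, int)
        self.electrode_nodes = [np.asarray(e, int) for e in electrode_nodes]
        self.n_elements = n


def _cluster(ids):
    return sg.Cluster(element_ids=np.asarray(ids, int))


def test_small_surface_cluster_discarded():
    tets = np.tile(np.arange(4), (63, 1))
    mesh = _FilterMesh(63, surface=[0], tets=tets, electrode_nodes=[])
    kept = sg.filter_clusters([_cluster(range(63))], mesh)
    assert kept == []


def test_small_interior_cluster_kept():
    tets = np.tile(np.arange(4) + 100, (10, 1))
    mesh = _FilterMesh(10, surface=[], tets=tets, electrode_nodes=[[0, 1]])
    kept = sg.filter_clusters([_cluster(range(10))], mesh)
    assert len(kept) == 1


def test_large_surface_cluster_kept_and_sorted_ascending():
    tets = np.tile(np.arange(4), (80, 1))
    mesh = _FilterMesh(80, surface=[0], tets=tets, electrode_nodes=[])
    big = _cluster(range(64))          # 64 elements: size rule not met
    small = _cluster(range(64, 74))    # interior
    kept = sg.filter_clusters([big, small], mesh)
    assert [c.size for c in kept] == [10, 64]
    assert kept[1].touches_surface


def test_electrode_contact_flag():
    tets = np.array([[0, 1, 2, 3], [4, 5, 6, 7]])
    mesh = _FilterMesh(2, surface=[], tets=tets, electrode_nodes=[[3]])
    kept = sg.filter_clusters([_cluster([0]), _cluster([1])], mesh)
    flags = {tuple(c.element_ids): c.touches_electrode for c in kept}
    assert flags[(1,)] is False
    # cluster 0 contains electrode node 3 -> discarded (size < 64)
    assert (0,) not in flags
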