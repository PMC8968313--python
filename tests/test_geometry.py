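"""Synthetic LA geometry, fibrosis fields, lesion sets, IDW, and VTK I/O."""

import numpy as np
import networkx as nx
import pytest

from atrialab.geometry import (REGION_CODES, TISSUE_CODES, AtrialMesh,
                               MeshParseError, apply_lesions,
                               build_idealized_la, fill_gaps,
                               generate_fibrosis, idw_interpolate,
                               lesion_mask, make_focal_lesion,
                               make_pvi_lesions, read_mesh, write_mesh)


def _components(mesh):
    """Independent connectivity oracle over the non-ablated adjacency."""
    act = mesh.active()
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in np.flatnonzero(act))
    e = mesh.edges()
    g.add_edges_from(map(tuple, e[act[e[:, 0]] & act[e[:, 1]]]))
    return g


def _pv_body_disconnected(mesh):
    g = _components(mesh)
    act = mesh.active()
    comp = {}
    for ci, cset in enumerate(nx.connected_components(g)):
        for n in cset:
            comp[n] = ci
    pv = {comp[int(i)] for i in mesh.pv_nodes() if act[i]}
    body = {comp[int(i)] for i in mesh.region_nodes("la_body") if act[i]}
    return pv.isdisjoint(body)


# ---------------------------------------------------------------------------
# Mesh generation
# ---------------------------------------------------------------------------
def test_mesh_edge_length_matches_target(la_mesh):
    s = la_mesh.summary()
    assert abs(s["mean_edge_um"] - 800.0) / 800.0 < 0.15
    assert s["sd_edge_um"] / s["mean_edge_um"] < 0.5


def test_node_count_scales_inverse_square():
    a = build_idealized_la(24, 24, 1200, 2.0, seed=0)
    b = build_idealized_la(24, 24, 600, 2.0, seed=0)
    ratio = b.n_nodes / a.n_nodes
    assert abs(ratio - 4.0) / 4.0 < 0.2


def test_four_disjoint_nonempty_pv_regions(la_mesh):
    sets = [set(la_mesh.region_nodes(f"pv{i}")) for i in range(1, 5)]
    for s in sets:
        assert len(s) > 0
    for i in range(4):
        for j in range(i + 1, 4):
            assert not sets[i] & sets[j]


def test_fiber_vectors_unit_norm(la_mesh):
    nrm = np.linalg.norm(la_mesh.fibers, axis=1)
    np.testing.assert_allclose(nrm, 1.0, atol=1e-12)


def test_infeasible_geometry_rejected():
    with pytest.raises(ValueError, match="infeasib"):
        build_idealized_la(16, 16, 800, 3.0, seed=0)   # rings collide


def test_mesh_generation_bit_reproducible():
    a = build_idealized_la(24, 24, 900, 2.0, seed=5)
    b = build_idealized_la(24, 24, 900, 2.0, seed=5)
    assert np.array_equal(a.points, b.points)
    assert np.array_equal(a.triangles, b.triangles)


# ---------------------------------------------------------------------------
# Fibrosis
# ---------------------------------------------------------------------------
def test_fibrosis_zero_density(la_mesh):
    m = generate_fibrosis(la_mesh, 0.0, seed=1)
    assert (m.tissue == TISSUE_CODES["fibrotic"]).sum() == 0


@pytest.mark.parametrize("seed", [0, 3])
def test_fibrosis_density_within_band(la_mesh, seed):
    m = generate_fibrosis(la_mesh, 0.30, cluster_radius_mm=2.0, seed=seed)
    body = (la_mesh.region == REGION_CODES["la_body"]).sum()
    frac = (m.tissue == TISSUE_CODES["fibrotic"]).sum() / body
    assert 0.27 <= frac <= 0.33


def test_fibrosis_deterministic(la_mesh):
    a = generate_fibrosis(la_mesh, 0.25, seed=9)
    b = generate_fibrosis(la_mesh, 0.25, seed=9)
    assert np.array_equal(a.tissue, b.tissue)


def test_fibrosis_only_touches_body(la_mesh):
    m = generate_fibrosis(la_mesh, 0.30, seed=2)
    fib = m.tissue == TISSUE_CODES["fibrotic"]
    assert np.all(m.region[fib] == REGION_CODES["la_body"])


# ---------------------------------------------------------------------------
# PVI lesion sets
# ---------------------------------------------------------------------------
def test_cpvi_disconnects_pv_from_body(la_mesh, cpvi_lesions):
    m = apply_lesions(la_mesh, cpvi_lesions)
    assert _pv_body_disconnected(m)


def test_gaps_preserve_connectivity_and_fill_restores(la_mesh,
                                                      pvi_gap_lesions,
                                                      cpvi_lesions):
    m = apply_lesions(la_mesh, pvi_gap_lesions)
    assert not _pv_body_disconnected(m)
    # removing every gap corridor disconnects again
    filled = fill_gaps(pvi_gap_lesions, pvi_gap_lesions.gap_ids())
    mf = apply_lesions(la_mesh, filled)
    assert _pv_body_disconnected(mf)
    # completion property: identical ablated sets
    mc = apply_lesions(la_mesh, cpvi_lesions)
    assert np.array_equal(mf.tissue, mc.tissue)


def test_four_gaps_with_stable_ids(pvi_gap_lesions):
    ids = pvi_gap_lesions.gap_ids()
    assert len(ids) == 4
    assert len(set(ids)) == 4


def test_fill_no_gaps_is_identity(pvi_gap_lesions):
    assert fill_gaps(pvi_gap_lesions, []) == pvi_gap_lesions


def test_fill_unknown_gap_rejected(pvi_gap_lesions):
    with pytest.raises(KeyError, match="nope"):
        fill_gaps(pvi_gap_lesions, ["nope"])


def test_partial_fill_keeps_remaining_corridors(la_mesh, pvi_gap_lesions):
    ids = pvi_gap_lesions.gap_ids()
    part = fill_gaps(pvi_gap_lesions, ids[:2])
    m = apply_lesions(la_mesh, part)
    assert not _pv_body_disconnected(m)


def test_gap_corridor_width_near_2mm(la_mesh, pvi_gap_lesions):
    """Discrete corridor width brackets the 2-mm contract within one edge."""
    m = apply_lesions(la_mesh, pvi_gap_lesions)
    edge_mm = la_mesh.mean_edge_um() / 1000.0
    ring = pvi_gap_lesions.rings[0]
    gap = next(g for g in pvi_gap_lesions.gaps if g.ring_name == ring.name)
    dist, s = ring.curve_distance_and_arcpos(m.points[:, :2])
    in_band = dist <= ring.width_mm / 2.0
    L = ring.arc_length
    ds = np.abs((s - gap.arc_pos_mm + L / 2.0) % L - L / 2.0)
    active = m.active()
    open_width = 2.0 * ds[in_band & active & (ds < 4.0)].max()
    wall_width = 2.0 * ds[in_band & ~active].min()
    measured = 0.5 * (open_width + wall_width)
    assert abs(measured - 2.0) <= edge_mm


def test_ring_band_is_edge_connected(la_mesh, cpvi_lesions):
    """Each ring's ablated nodes form one connected band (no holes)."""
    mask = lesion_mask(la_mesh, cpvi_lesions)
    for ring in cpvi_lesions.rings:
        dist, _ = ring.curve_distance_and_arcpos(la_mesh.points[:, :2])
        band = mask & (dist <= ring.width_mm / 2.0)
        g = nx.Graph()
        g.add_nodes_from(int(i) for i in np.flatnonzero(band))
        e = la_mesh.edges()
        g.add_edges_from(map(tuple, e[band[e[:, 0]] & band[e[:, 1]]]))
        assert nx.number_connected_components(g) == 1


def test_apply_lesions_idempotent_and_local(la_mesh, cpvi_lesions):
    once = apply_lesions(la_mesh, cpvi_lesions)
    twice = apply_lesions(once, cpvi_lesions)
    assert np.array_equal(once.tissue, twice.tissue)
    mask = lesion_mask(la_mesh, cpvi_lesions)
    assert np.array_equal(once.tissue[~mask], la_mesh.tissue[~mask])


# ---------------------------------------------------------------------------
# Focal lesions
# ---------------------------------------------------------------------------
def test_focal_lesion_minimum_and_growth(la_mesh):
    edge_mm = la_mesh.mean_edge_um() / 1000.0
    center = int(np.argmin(np.linalg.norm(
        la_mesh.points[:, :2] - [12.0, 12.0], axis=1)))
    small = apply_lesions(la_mesh, make_focal_lesion(la_mesh, center, edge_mm))
    assert (small.tissue == TISSUE_CODES["ablated"]).sum() >= 1
    n1 = (apply_lesions(la_mesh, make_focal_lesion(la_mesh, center, 2.0))
          .tissue == 2).sum()
    n2 = (apply_lesions(la_mesh, make_focal_lesion(la_mesh, center, 4.0))
          .tissue == 2).sum()
    assert abs(n2 / n1 - 4.0) < 1.5       # ~quadratic in radius
    with pytest.raises(ValueError):
        make_focal_lesion(la_mesh, center, 0.1)


# ---------------------------------------------------------------------------
# IDW interpolation
# ---------------------------------------------------------------------------
def test_idw_constant_field(la_mesh):
    vals = idw_interpolate([[5.0, 5.0], [15.0, 18.0]], [7.5, 7.5], la_mesh)
    np.testing.assert_allclose(vals, 7.5, rtol=1e-12)


def test_idw_symmetry_midpoint():
    mesh = AtrialMesh(np.array([[5.0, 0.0, 0.0]]), np.empty((0, 3), int),
                      np.zeros(1, np.int32), np.zeros(1, np.int32),
                      np.array([[1.0, 0.0, 0.0]]))
    v = idw_interpolate([[0.0, 0.0], [10.0, 0.0]], [0.0, 10.0], mesh)
    assert v[0] == pytest.approx(5.0)


def test_idw_matches_hand_computation():
    node = np.array([[1.0, 1.0, 0.0]])
    mesh = AtrialMesh(node, np.empty((0, 3), int), np.zeros(1, np.int32),
                      np.zeros(1, np.int32), np.array([[1.0, 0.0, 0.0]]))
    samples = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 3.0]])
    values = np.array([1.0, 5.0, 9.0])
    d = np.array([np.sqrt(2.0), np.sqrt(10.0), np.sqrt(5.0)])
    w = d ** -2.0
    expected = np.sum(w * values) / np.sum(w)
    v = idw_interpolate(samples, values, mesh, power=2.0)
    assert v[0] == pytest.approx(expected, rel=1e-12)


def test_idw_exact_at_sample(la_mesh):
    p = la_mesh.points[100, :2]
    v = idw_interpolate([p, [0.0, 0.0]], [42.0, 0.0], la_mesh)
    assert v[100] == pytest.approx(42.0)


def test_idw_requires_samples(la_mesh):
    with pytest.raises(ValueError):
        idw_interpolate(np.empty((0, 2)), np.empty(0), la_mesh)


# ---------------------------------------------------------------------------
# VTK I/O
# ---------------------------------------------------------------------------
def test_vtk_round_trip(tmp_path, la_mesh, pvi_gap_lesions):
    m = apply_lesions(generate_fibrosis(la_mesh, 0.2, seed=4),
                      pvi_gap_lesions)
    m.point_data["df_hz"] = np.linspace(0, 10, m.n_nodes)
    path = tmp_path / "mesh.vtk"
    write_mesh(m, path)
    r = read_mesh(path)
    np.testing.assert_allclose(r.points, m.points, atol=1e-8)
    assert np.array_equal(r.triangles, m.triangles)
    assert np.array_equal(r.region, m.region)
    assert np.array_equal(r.tissue, m.tissue)
    np.testing.assert_allclose(r.fibers, m.fibers, atol=1e-8)
    np.testing.assert_allclose(r.point_data["df_hz"], m.point_data["df_hz"],
                               atol=1e-7)


def test_vtk_missing_tissue_defaults_with_warning(tmp_path, la_mesh):
    path = tmp_path / "m.vtk"
    write_mesh(la_mesh, path)
    text = path.read_text()
    start = text.index("SCALARS tissue_label")
    end = text.index("VECTORS fiber")
    path.write_text(text[:start] + text[end:])
    with pytest.warns(UserWarning, match="tissue_label"):
        r = read_mesh(path)
    assert np.all(r.tissue == TISSUE_CODES["normal"])


def test_vtk_bad_triangle_index_raises(tmp_path):
    path = tmp_path / "bad.vtk"
    path.write_text("""# vtk DataFile Version 3.0
bad
ASCII
DATASET POLYDATA
POINTS 3 double
0 0 0
1 0 0
0 1 0
POLYGONS 1 4
3 0 1 99
""")
    with pytest.raises(MeshParseError, match="line"):
        read_mesh(path)
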