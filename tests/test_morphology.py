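"""SWC parsing and morphometrics: exact geometry, Sholl oracle, invariances."""

import numpy as np
import pytest

from gpephys.morphology import (
    Morphology,
    SwcError,
    branch_order_diameters,
    morpho_metrics,
    read_swc,
    sholl,
    write_swc,
)
from gpephys.synth.cells import CellParams, DendriteGeometry
from gpephys.synth.morph import generate_swc


def _morph(rows):
    arr = np.array(rows, dtype=float)
    return Morphology(ids=arr[:, 0].astype(int), types=arr[:, 1].astype(int),
                      xyz=arr[:, 2:5], radii=arr[:, 5],
                      parents=arr[:, 6].astype(int))


def straight_dendrite(n_nodes=10, total_len=100.0, radius=1.0):
    rows = [[1, 1, 0, 0, 0, 5.0, -1]]
    for k in range(1, n_nodes + 1):
        rows.append([k + 1, 3, k * total_len / n_nodes, 0, 0, radius, k])
    return _morph(rows)


def y_tree(stem=50.0, branch=50.0, stem_r=1.0, branch_r=0.5):
    rows = [[1, 1, 0, 0, 0, 5.0, -1],
            [2, 3, stem, 0, 0, stem_r, 1],
            [3, 3, stem + branch, 10, 0, branch_r, 2],
            [4, 3, stem + branch, -10, 0, branch_r, 2]]
    # place daughters exactly branch length away
    for row in rows[2:]:
        d = np.array(row[2:5]) - np.array([stem, 0, 0])
        row[2:5] = (np.array([stem, 0, 0]) + d / np.linalg.norm(d) * branch).tolist()
    return _morph(rows)


# ---------------------------------------------------------------------------
# i/o and validation
# ---------------------------------------------------------------------------

def test_minimal_two_node_file(tmp_path):
    p = tmp_path / "m.swc"
    p.write_text("# comment\n1 1 0 0 0 5 -1\n2 3 10 0 0 1 1\n")
    m = read_swc(p)
    assert m.n_nodes == 2
    assert morpho_metrics(m).total_dendritic_length == pytest.approx(10.0)


def test_undefined_parent_names_line(tmp_path):
    p = tmp_path / "bad.swc"
    p.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 1 9\n")
    with pytest.raises(SwcError, match="undefined parent 9"):
        read_swc(p)


def test_nonpositive_radius_rejected(tmp_path):
    p = tmp_path / "bad.swc"
    p.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 0 1\n")
    with pytest.raises(SwcError, match="radius"):
        read_swc(p)


def test_wrong_column_count_names_line(tmp_path):
    p = tmp_path / "bad.swc"
    p.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 1\n")
    with pytest.raises(SwcError, match="bad.swc:2"):
        read_swc(p)


def test_two_roots_rejected():
    with pytest.raises(SwcError, match="one root"):
        _morph([[1, 1, 0, 0, 0, 5, -1], [2, 1, 1, 0, 0, 5, -1]])


def test_write_read_identity(tmp_path, y_geometry):
    cell = CellParams(group="prototypic_PV", R_in=120, C_m=100, E_L=-70,
                      V_T=-42, g_h=0, tau_h=50, E_h=-30,
                      dendrite_geometry=y_geometry)
    m = generate_swc(cell, 3)
    m2 = read_swc(write_swc(m, tmp_path / "g.swc"))
    assert np.allclose(m.xyz, m2.xyz, atol=1e-5)
    assert np.array_equal(m.parents, m2.parents)


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def test_cylinder_metrics_exact():
    m = straight_dendrite()
    mm = morpho_metrics(m)
    assert mm.total_dendritic_length == pytest.approx(100.0)
    assert mm.bifurcation_count == 0
    assert mm.termination_count == 1
    assert mm.primary_dendrite_count == 1
    assert mm.mean_dendrite_length == pytest.approx(100.0)
    assert mm.soma_area == pytest.approx(np.pi * 25.0)
    lateral = 2 * np.pi * 1.0 * 100.0
    assert mm.total_surface_area == pytest.approx(4 * np.pi * 25.0 + lateral, rel=1e-6)


def test_symmetric_y_counts():
    mm = morpho_metrics(y_tree())
    assert mm.total_dendritic_length == pytest.approx(150.0)
    assert mm.bifurcation_count == 1
    assert mm.termination_count == 2
    assert mm.primary_dendrite_count == 1


def test_no_dendrites_flagged():
    m = _morph([[1, 1, 0, 0, 0, 5, -1]])
    mm = morpho_metrics(m)
    assert mm.total_dendritic_length == 0.0
    assert "no_dendrites" in mm.flags


# ---------------------------------------------------------------------------
# Sholl
# ---------------------------------------------------------------------------

def test_sholl_straight_dendrite():
    prof = sholl(straight_dendrite(), step=10.0)
    assert np.array_equal(prof.radii, np.arange(10.0, 101.0, 10.0))
    assert np.all(prof.intersections == 1)


def test_sholl_y_tree():
    # daughters end ~99.5 um from the soma, so spheres run 10..90 um
    prof = sholl(y_tree(), step=10.0)
    expect = [1, 1, 1, 1, 1, 2, 2, 2, 2]
    assert list(prof.intersections) == expect


def _brute_force_sholl(m, radii, step_um=0.1):
    """Independent oracle: densely resample every segment and count sign
    changes of (distance - r)."""
    center = m.soma_centroid()
    counts = np.zeros(len(radii), dtype=int)
    for pi, ci in m.dendrite_segments():
        a, b = m.xyz[pi], m.xyz[ci]
        n = max(2, int(np.linalg.norm(b - a) / step_um))
        pts = a + (b - a) * np.linspace(0, 1, n)[:, None]
        d = np.linalg.norm(pts - center, axis=1)
        for k, r in enumerate(radii):
            s = np.sign(d - r)
            crossings = np.sum(s[:-1] * s[1:] < 0)
            if s[-1] == 0:  # endpoint exactly on the sphere counts once
                crossings += 1
            counts[k] += max(crossings, 0)
    return counts


def test_sholl_matches_brute_force_oracle(y_geometry):
    cell = CellParams(group="prototypic_PV", R_in=120, C_m=100, E_L=-70,
                      V_T=-42, g_h=0, tau_h=50, E_h=-30,
                      dendrite_geometry=y_geometry)
    for seed in range(25):
        m = generate_swc(cell, seed)
        prof = sholl(m, step=10.0)
        brute = _brute_force_sholl(m, prof.radii)
        assert np.array_equal(prof.intersections, brute)


def test_sholl_step_must_be_positive():
    with pytest.raises(ValueError):
        sholl(straight_dendrite(), step=0.0)


# ---------------------------------------------------------------------------
# branch orders
# ---------------------------------------------------------------------------

def test_unbranched_dendrite_all_order_one():
    od = branch_order_diameters(straight_dendrite(radius=1.0))
    assert od.order1 == pytest.approx(2.0)
    assert np.isnan(od.order2)
    assert "order2_empty" in od.flags


def test_y_orders_and_diameters():
    od = branch_order_diameters(y_tree(stem_r=1.0, branch_r=0.5))
    assert od.order1 == pytest.approx(2.0, rel=0.3)  # stem diameter ~2 um
    assert od.order2 == pytest.approx(1.0, rel=0.3)
    assert od.order1 > od.order2


def test_tapered_tree_diameters_decrease_across_orders(y_geometry):
    cell = CellParams(group="prototypic_PV", R_in=120, C_m=100, E_L=-70,
                      V_T=-42, g_h=0, tau_h=50, E_h=-30,
                      dendrite_geometry=y_geometry)
    o1s, o2s, ohs = [], [], []
    for seed in range(20):
        od = branch_order_diameters(generate_swc(cell, seed))
        o1s.append(od.order1)
        if not np.isnan(od.order2):
            o2s.append(od.order2)
        if not np.isnan(od.higher):
            ohs.append(od.higher)
    assert np.mean(o1s) > np.mean(o2s) > np.mean(ohs)


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------

def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def test_metrics_invariant_under_rigid_motion(rng, y_geometry):
    cell = CellParams(group="prototypic_PV", R_in=120, C_m=100, E_L=-70,
                      V_T=-42, g_h=0, tau_h=50, E_h=-30,
                      dendrite_geometry=y_geometry)
    m = generate_swc(cell, 8)
    Q = _random_rotation(rng)
    shift = rng.normal(size=3) * 50
    m2 = Morphology(ids=m.ids.copy(), types=m.types.copy(),
                    xyz=m.xyz @ Q.T + shift, radii=m.radii.copy(),
                    parents=m.parents.copy())
    a, b = morpho_metrics(m), morpho_metrics(m2)
    assert a.total_dendritic_length == pytest.approx(b.total_dendritic_length)
    assert a.total_surface_area == pytest.approx(b.total_surface_area)
    assert a.bifurcation_count == b.bifurcation_count
    assert np.array_equal(sholl(m).intersections, sholl(m2).intersections)


def test_scaling_coordinates_scales_lengths_and_areas(y_geometry):
    cell = CellParams(group="prototypic_PV", R_in=120, C_m=100, E_L=-70,
                      V_T=-42, g_h=0, tau_h=50, E_h=-30,
                      dendrite_geometry=y_geometry)
    m = generate_swc(cell, 9)
    k = 2.5
    m2 = Morphology(ids=m.ids.copy(), types=m.types.copy(), xyz=m.xyz * k,
                    radii=m.radii * k, parents=m.parents.copy())
    a, b = morpho_metrics(m), morpho_metrics(m2)
    assert b.total_dendritic_length == pytest.approx(k * a.total_dendritic_length)
    assert b.soma_area == pytest.approx(k**2 * a.soma_area)
    assert b.total_surface_area == pytest.approx(k**2 * a.total_surface_area, rel=1e-6)
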