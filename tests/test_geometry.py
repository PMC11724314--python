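"""Spatial primitives against brute-force and closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

import modscape as ms
from modscape import fixtures as fx
from modscape.geometry import octahedral_angle_rms
from conftest import random_rotation


def _cloud_model(n=2000, seed=42, box=40.0):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, box, (n, 3))
    atoms = [(f"C{i + 1}", "C", tuple(p)) for i, p in enumerate(pts)]
    return fx.build_model([("A", 1, "CLD", atoms)], classify=False), pts


def test_neighbor_search_equals_all_pairs_scan():
    model, pts = _cloud_model()
    rng = np.random.default_rng(7)
    for _ in range(5):
        center = rng.uniform(0, 40, 3)
        radius = rng.uniform(3, 8)
        got = {a.serial for a, _ in ms.neighbor_search(model, center, radius)}
        expected = {i for i, p in enumerate(pts)
                    if np.linalg.norm(p - center) <= radius}
        assert got == expected


def test_neighbor_search_interval_is_closed_and_sorted():
    model = fx.build_model([("A", 1, "CLD", [
        ("C1", "C", (0.0, 0.0, 0.0)),
        ("C2", "C", (5.0, 0.0, 0.0)),      # exactly at the radius
        ("C3", "C", (0.0, 3.0, 0.0)),
    ])], classify=False)
    hits = ms.neighbor_search(model, np.zeros(3), 5.0)
    assert [a.name for a, _ in hits] == ["C1", "C3", "C2"]
    assert hits[-1][1] == pytest.approx(5.0)
    # radius just below the nearest non-self neighbour -> only the centre atom
    assert len(ms.neighbor_search(model, np.zeros(3), 2.9)) == 1
    with pytest.raises(ValueError):
        ms.neighbor_search(model, np.zeros(3), -1.0)


_SMALL_CLOUD, _SMALL_PTS = None, None


def _small_cloud():
    global _SMALL_CLOUD, _SMALL_PTS
    if _SMALL_CLOUD is None:
        _SMALL_CLOUD, _SMALL_PTS = _cloud_model(n=400, seed=17, box=25.0)
    return _SMALL_CLOUD, _SMALL_PTS


@settings(derandomize=True, max_examples=25, deadline=None)
@given(cx=st.floats(0, 25), cy=st.floats(0, 25), cz=st.floats(0, 25),
       radius=st.floats(0.5, 10))
def test_neighbor_search_property_matches_oracle(cx, cy, cz, radius):
    model, pts = _small_cloud()
    center = np.array([cx, cy, cz])
    got = {a.serial for a, _ in ms.neighbor_search(model, center, radius)}
    expected = {i for i, p in enumerate(pts)
                if np.linalg.norm(p - center) <= radius}
    assert got == expected


def test_neighbor_search_is_symmetric():
    model, pts = _cloud_model(n=300, seed=3, box=20.0)
    r = 4.0
    shells = {i: {a.serial for a, _ in ms.neighbor_search(model, pts[i], r)}
              for i in range(0, 300, 37)}
    for i, shell in shells.items():
        for j in shells:
            assert (j in shell) == (i in shells[j])


def _hexagon_specs(rot=np.eye(3), displaced=None):
    atoms = []
    for k, name in enumerate(["N1", "C2", "N3", "C4", "C5", "C6"]):
        p = 1.4 * np.array([math.cos(math.radians(60 * k)),
                            math.sin(math.radians(60 * k)), 0.0])
        if displaced is not None and k == 0:
            p = p + np.array([0.0, 0.0, displaced])
        atoms.append((name, name[0], tuple(rot @ p)))
    return [("A", 1, "U", atoms)]


def test_planar_hexagon_fits_exactly():
    model = fx.build_model(_hexagon_specs())
    plane = ms.fit_base_plane(model, ms.ResidueKey("A", 1, "", "U"))
    assert plane.fit_rms == pytest.approx(0.0, abs=1e-9)
    assert abs(np.dot(plane.normal, [0, 0, 1])) == pytest.approx(1.0, abs=1e-9)
    assert np.linalg.norm(plane.normal) == pytest.approx(1.0, abs=1e-12)


def test_displaced_ring_rms_matches_independent_least_squares():
    delta = 0.3
    model = fx.build_model(_hexagon_specs(displaced=delta))
    plane = ms.fit_base_plane(model, ms.ResidueKey("A", 1, "", "U"))
    pts = np.stack([a.pos for a in model.atoms])

    # independent oracle: direct minimisation over plane parameters
    def cost(params):
        theta, phi, d = params
        n = np.array([math.sin(theta) * math.cos(phi),
                      math.sin(theta) * math.sin(phi), math.cos(theta)])
        return np.mean((pts @ n - d) ** 2)

    best = min(
        (minimize(cost, x0, method="Nelder-Mead",
                  options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 5000})
         for x0 in ([0.1, 0.1, 0.0], [0.5, 1.0, 0.1])),
        key=lambda r: r.fun)
    assert plane.fit_rms == pytest.approx(math.sqrt(best.fun), abs=1e-6)


def test_incomplete_ring_raises():
    model = fx.build_model([("A", 1, "U", [("N1", "N", (0, 0, 0)),
                                           ("C2", "C", (1.4, 0, 0))])])
    with pytest.raises(ValueError, match="ring incomplete"):
        ms.fit_base_plane(model, ms.ResidueKey("A", 1, "", "U"))


def test_hbond_detection_window_and_element_filter():
    model = fx.make_psu_probe(3.1, comp="PSU", partner_kind="water", seed=1)
    key = ms.ResidueKey("A", 224, "", "PSU")
    probe = model.atom(key, "N1")
    bonds = [b for b in ms.detect_hbonds(model, probe)
             if b.partner_b.residue_key != key]
    assert len(bonds) == 1
    assert bonds[0].distance == pytest.approx(3.1, abs=1e-6)
    assert bonds[0].partner_b.residue_key.comp == "HOH"
    # acceptor at 3.6 A with default d_max 3.5 -> no bond
    far = fx.make_psu_probe(3.6, comp="PSU", partner_kind="water", seed=1)
    assert [b for b in ms.detect_hbonds(far, far.atom(key, "N1"))
            if b.partner_b.residue_key != key] == []
    # carbon pairs are never hydrogen bonds
    cmodel = fx.build_model([("A", 1, "CLD", [("C1", "C", (0, 0, 0)),
                                              ("C2", "C", (3.0, 0, 0))])],
                            classify=False)
    with pytest.raises(ValueError, match="probe"):
        ms.detect_hbonds(cmodel, cmodel.atoms[0])
    assert ms.detect_hbonds(cmodel, cmodel.atoms[0], check_probe=False) == []
    with pytest.raises(ValueError):
        ms.detect_hbonds(model, probe, d_min=3.5, d_max=3.0)


def test_ideal_octahedron_angles():
    atoms = [("MG", "Mg", (0.0, 0.0, 0.0))]
    for i, d in enumerate(np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                                    [0, -1, 0], [0, 0, 1], [0, 0, -1]])):
        atoms.append((f"O{i + 1}", "O", tuple(2.1 * d)))
    model = fx.build_model([("M", 1, "MG", atoms)], classify=False)
    shell = ms.coordination_sphere(model, model.atoms[0], r_max=3.5)
    assert len(shell) == 6
    angles = np.array(shell.angle_stats)
    expected = np.array([90.0] * 12 + [180.0] * 3)
    np.testing.assert_allclose(angles, expected, atol=1e-6)
    assert octahedral_angle_rms(angles) == pytest.approx(0.0, abs=1e-6)
    # isolated centre -> empty shell
    lone = fx.build_model([("M", 1, "MG", [("MG", "Mg", (0, 0, 0))])],
                          classify=False)
    assert len(ms.coordination_sphere(lone, lone.atoms[0], 3.5)) == 0


def test_geometry_is_rigid_transform_invariant(psu_cases):
    model, _, _ = psu_cases
    R, t = random_rotation(99)
    moved = model.transformed(R, t)
    key = ms.ResidueKey("A", 101, "", "PSU")
    p1 = ms.fit_base_plane(model, key)
    p2 = ms.fit_base_plane(moved, key)
    assert p2.fit_rms == pytest.approx(p1.fit_rms, abs=1e-9)
    b1 = ms.detect_hbonds(model, model.atom(key, "N1"))
    b2 = ms.detect_hbonds(moved, moved.atom(key, "N1"))
    assert [round(b.distance, 9) for b in b1] == \
           [round(b.distance, 9) for b in b2]
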