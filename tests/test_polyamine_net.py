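"""Polyamine contact maps, network tracing and stacking descriptors."""

import math

import networkx as nx
import numpy as np
import pytest

import modscape as ms
from modscape import fixtures as fx
from modscape.geometry import COVALENT_CUTOFF, HBOND_WINDOW
from conftest import random_rotation


def test_planted_polyamine_contacts_match_manifest(toy_assembly):
    model, manifest, _ = toy_assembly
    for site in (s for s in manifest.sites if s["kind"] == "polyamine"):
        key = ms.ResidueKey(*site["residue_key"])
        cmap = ms.map_polyamine_contacts(model, key)
        assert cmap.species == site["params"]["species"]
        by_class = {}
        for _, _, cls, _ in cmap.contacts:
            by_class[cls] = by_class.get(cls, 0) + 1
        assert by_class.get("phosphate-O", 0) == \
            site["params"]["n_phosphate_contacts"]
        assert len(cmap.water_bridges) == site["params"]["n_water_bridges"]
        # every bridge leg independently re-validates as a hydrogen bond
        for bridge in cmap.water_bridges:
            legs = ms.detect_hbonds(model, bridge.water)
            partners = {b.partner_b.serial for b in legs}
            assert bridge.amine.serial in partners
            assert bridge.partner.serial in partners


def test_isolated_polyamine_has_no_contacts():
    specs, manifest = fx.make_toy_assembly(
        {"modifications": {}, "polyamines": {"PUT": 1},
         "anchor_polyamines": False, "standard_nt": 0, "standard_aa": 0},
        seed=9)
    model = fx.build_model(specs)
    key = manifest.keys_of("polyamine")[0]
    cmap = ms.map_polyamine_contacts(model, key)
    assert cmap.contacts == [] and cmap.water_bridges == []


def test_non_polyamine_residue_is_rejected(toy_assembly):
    model, _, _ = toy_assembly
    key = next(k for k in model.residues if k.comp == "PSU")
    with pytest.raises(ValueError, match="not a polyamine"):
        ms.map_polyamine_contacts(model, key)


def _water_cloud(n=40, seed=13, box=12.0):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, box, (n, 3))
    specs = [("W", i + 1, "HOH", [("O", "O", tuple(p))])
             for i, p in enumerate(pts)]
    return fx.build_model(specs), pts


def test_network_depth_zero_is_seeds_only(toy_assembly):
    model, manifest, _ = toy_assembly
    key = manifest.keys_of("polyamine")[0]
    seed = model.atom(key, "N1")
    net = ms.hbond_network(model, [seed], 0)
    assert net.nodes == [seed.serial]
    assert net.graph.number_of_edges() == 0
    with pytest.raises(ValueError, match="empty seed"):
        ms.hbond_network(model, [], 2)


def test_network_matches_exhaustive_shortest_path_oracle():
    model, pts = _water_cloud()
    # independent oracle: full pairwise adjacency + shortest-path radius
    full = nx.Graph()
    full.add_nodes_from(range(len(pts)))
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = float(np.linalg.norm(pts[i] - pts[j]))
            if HBOND_WINDOW[0] <= d <= HBOND_WINDOW[1]:
                full.add_edge(i, j)
    seed = model.atoms[0]
    for depth in (1, 2, 3):
        net = ms.hbond_network(model, [seed], depth)
        lengths = nx.single_source_shortest_path_length(full, 0, cutoff=depth)
        assert set(net.nodes) == set(lengths)


def test_network_grows_monotonically_and_ignores_seed_order(toy_assembly):
    model, manifest, _ = toy_assembly
    keys = manifest.keys_of("polyamine")
    seeds = [model.atom(keys[0], "N1"), model.atom(keys[1], "N1")]
    sizes = [len(ms.hbond_network(model, seeds, d).nodes) for d in range(5)]
    assert sizes == sorted(sizes)
    fwd = ms.hbond_network(model, seeds, 3).nodes
    rev = ms.hbond_network(model, list(reversed(seeds)), 3).nodes
    assert fwd == rev


def test_network_crosses_metals_as_coordination_edges():
    specs = [
        ("W", 1, "HOH", [("O", "O", (0.0, 0.0, 0.0))]),
        ("M", 1, "MG", [("MG", "Mg", (2.1, 0.0, 0.0))]),
        ("W", 2, "HOH", [("O", "O", (4.2, 0.0, 0.0))]),
    ]
    model = fx.build_model(specs)
    net = ms.hbond_network(model, [model.atoms[0]], 2)
    assert len(net.nodes) == 3
    kinds = {data["kind"] for _, _, data in net.graph.edges(data=True)}
    assert kinds == {"coordination"}


def test_stacking_descriptor_constructed_geometries():
    def hexagon(offset, rot=np.eye(3)):
        atoms = []
        for k, name in enumerate(["N1", "C2", "N3", "C4", "C5", "C6"]):
            p = 1.4 * np.array([math.cos(math.radians(60 * k)),
                                math.sin(math.radians(60 * k)), 0.0])
            atoms.append((name, name[0], tuple(rot @ p + offset)))
        return atoms

    # translated 3.4 A along the shared normal: ideal stack
    model = fx.build_model([("A", 1, "U", hexagon(np.zeros(3))),
                            ("A", 2, "U", hexagon(np.array([0, 0, 3.4])))])
    d = ms.stacking_descriptor(model, ms.ResidueKey("A", 1, "", "U"),
                               ms.ResidueKey("A", 2, "", "U"))
    assert d.plane_distance == pytest.approx(3.4, abs=1e-9)
    assert d.angle == pytest.approx(0.0, abs=1e-6)
    assert d.lateral_offset == pytest.approx(0.0, abs=1e-6)

    # coplanar side-by-side rings
    model2 = fx.build_model([("A", 1, "U", hexagon(np.zeros(3))),
                             ("A", 2, "U", hexagon(np.array([6.0, 0, 0])))])
    d2 = ms.stacking_descriptor(model2, ms.ResidueKey("A", 1, "", "U"),
                                ms.ResidueKey("A", 2, "", "U"))
    assert d2.plane_distance == pytest.approx(0.0, abs=1e-9)
    assert d2.angle == pytest.approx(0.0, abs=1e-6)
    assert d2.lateral_offset == pytest.approx(6.0, abs=1e-9)


def test_contact_maps_invariant_under_rigid_transform(toy_assembly):
    model, manifest, _ = toy_assembly
    key = manifest.keys_of("polyamine")[0]
    R, t = random_rotation(21)
    moved = model.transformed(R, t)
    a = [(c[0].name, c[2], round(c[3], 6))
         for c in ms.map_polyamine_contacts(model, key).contacts]
    b = [(c[0].name, c[2], round(c[3], 6))
         for c in ms.map_polyamine_contacts(moved, key).contacts]
    assert a == b
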