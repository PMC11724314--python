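"""Coordination-geometry classification of Mg2+/K+/water centres."""

import math

import numpy as np
import pytest

import modscape as ms
from modscape import fixtures as fx
from modscape.ion_classify import (LABEL_K, LABEL_MG, LABEL_UNASSIGNED,
                                   LABEL_WATER, IonThresholds, classify_site)
from conftest import random_rotation

OCT = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                [0, 0, 1], [0, 0, -1]], float)
PENT = np.array([[math.cos(2 * math.pi * k / 5),
                  math.sin(2 * math.pi * k / 5), 0.0] for k in range(5)])


def _site_model(center_comp, center_elem, dirs, dists, ligand_comp="HOH"):
    specs = [("M", 1, center_comp,
              [(center_elem.upper(), center_elem, (0.0, 0.0, 0.0))])]
    for i, (d, r) in enumerate(zip(dirs, dists)):
        specs.append(("W", i + 1, ligand_comp,
                      [("O", "O", tuple(np.asarray(d) * r))]))
    return fx.build_model(specs)


def _shell(model):
    return ms.coordination_sphere(model, model.atoms[0], r_max=3.5)


def test_octahedral_short_shell_is_magnesium():
    dists = [1.8, 1.9, 2.1, 2.2, 2.3, 2.4]
    site = classify_site(_shell(_site_model("MG", "Mg", OCT, dists)))
    assert site.label == LABEL_MG
    assert site.water_ligand_count == 6
    # one ligand removed: the rule needs only >= 4 in-window ligands
    site5 = classify_site(_shell(_site_model("MG", "Mg", OCT[:5], dists[:5])))
    assert site5.label == LABEL_MG


def test_pentagonal_long_shell_is_potassium():
    dists = [2.8, 2.9, 3.0, 3.1, 3.2]
    site = classify_site(_shell(_site_model("K", "K", PENT, dists)))
    assert site.label == LABEL_K
    # strict mode reproduces the observed 2.8-3.2 window exactly
    shifted = classify_site(_shell(_site_model("K", "K", PENT, [2.6] * 5)),
                            IonThresholds(strict=True))
    assert shifted.label != LABEL_K


def test_water_and_empty_shell_rules():
    two = classify_site(_shell(_site_model("HOH", "O", OCT[:2], [2.8, 3.0])))
    assert two.label == LABEL_WATER
    empty = classify_site(_shell(fx.build_model(
        [("M", 1, "MG", [("MG", "Mg", (0.0, 0.0, 0.0))])])))
    assert empty.label == LABEL_UNASSIGNED


def test_scaling_a_magnesium_site_never_reorders_labels():
    """Scaling 2.1 A distances upward walks Mg -> unassigned -> K -> water."""
    rank = {LABEL_MG: 0, LABEL_UNASSIGNED: 1, LABEL_K: 1, LABEL_WATER: 2}
    labels = []
    for scale in np.arange(1.0, 1.67, 0.02):
        site = classify_site(_shell(_site_model("MG", "Mg", OCT,
                                                [2.1 * scale] * 6)))
        labels.append(site.label)
    ranks = [rank[l] for l in labels]
    assert ranks == sorted(ranks)
    assert labels[0] == LABEL_MG
    assert LABEL_K in labels and labels[-1] == LABEL_WATER


def test_label_invariant_under_transform_and_ligand_order(ion_field):
    model, manifest, _, _ = ion_field
    R, t = random_rotation(4)
    moved = model.transformed(R, t)
    for kind in ("Mg", "K", "water"):
        key = manifest.keys_of(kind)[0]
        s1 = classify_site(ms.coordination_sphere(model, model.atoms_of(key)[0]))
        s2 = classify_site(ms.coordination_sphere(moved, moved.atoms_of(key)[0]))
        assert s1.label == s2.label == kind
        # ligand input order must not matter
        shell = ms.coordination_sphere(model, model.atoms_of(key)[0])
        shell.ligands = list(reversed(shell.ligands))
        assert classify_site(shell).label == kind


def test_full_field_recovery_at_small_jitter(ion_field):
    model, manifest, _, _ = ion_field
    report = ms.classify_all(model, mode="deposited")
    assert fx.recovery_rate(report, manifest) == 1.0
    # label-stripped mode recovers the same labels for the planted centres
    stripped = ms.classify_all(model, mode="label_stripped")
    assert fx.recovery_rate(stripped, manifest) == 1.0


def test_cross_validation_table_properties(tmp_path):
    specs, manifest = fx.make_ion_field(0, 0, 12, jitter_sigma=0.03, seed=23)
    model = fx.build_model(specs)
    table = ms.cross_validate(model)
    # deposited = planted -> diagonal
    off_diag = table.values.sum() - np.trace(table.values)
    assert off_diag == 0
    assert table.loc["water", "water"] > 12      # centres plus partner waters

    # mislabel one planted water centre as potassium: the deposited component
    # id is wrong, the atom itself (and hence all geometry) is unchanged
    small = next(s for s in manifest.sites if s["kind"] == "water")
    key = ms.ResidueKey(*small["residue_key"])
    bad = []
    for c, n, comp, atoms in specs:
        if (c, n) == (key.chain, key.number):
            bad.append(("K", 99, "K", atoms))
        else:
            bad.append((c, n, comp, atoms))
    model_bad = fx.build_model(bad)
    table_bad = ms.cross_validate(model_bad)
    assert table_bad.values.sum() - np.trace(table_bad.values) == 1
    assert table_bad.loc["K", "water"] == 1

    # row sums equal deposited category counts
    rep = ms.census(model_bad)
    n_water = rep.category_counts.get("water", 0)
    n_metal = rep.category_counts.get("metal", 0)
    assert table_bad.loc["water"].sum() == n_water
    assert table_bad.loc["K"].sum() + table_bad.loc["Mg"].sum() == n_metal


def test_non_target_metals_pass_through_flagged():
    model = fx.build_model([("Z", 1, "ZN", [("ZN", "Zn", (0.0, 0.0, 0.0))]),
                            ("W", 1, "HOH", [("O", "O", (2.1, 0.0, 0.0))])])
    report = ms.classify_all(model, mode="deposited")
    zn = next(s for s in report.sites if s.residue_key.comp == "ZN")
    assert zn.label == "Zn" and zn.flagged


def test_recovery_degrades_monotonically_with_jitter():
    rates = []
    for sigma in (0.05, 0.15, 0.3):
        reps = []
        for rep_i in range(2):
            specs, manifest = fx.make_ion_field(
                15, 15, 15, jitter_sigma=sigma, seed=100 + rep_i)
            model = fx.build_model(specs)
            reps.append(fx.recovery_rate(ms.classify_all(model), manifest))
        rates.append(sum(reps) / len(reps))
    assert rates[0] == 1.0
    assert rates[0] >= rates[1] >= rates[2]
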