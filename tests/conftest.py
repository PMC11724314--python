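"""Shared fixtures: small synthetic structures with ground-truth manifests."""

from __future__ import annotations

import numpy as np
import pytest

import modscape as ms
from modscape import fixtures as fx

#: toy-assembly spec used across census/polyamine tests (counts chosen so the
#: combined-class tally rule is exercised: 2 Psi + 3 Nm + 1 combined + 1 m5C)
TOY_SPEC = {
    "modifications": {
        "pseudouridine": 2,
        "ribose-2prime-O-methyl": 3,
        "combined": 1,
        "m5C": 1,
        "beta-hydroxy-histidine": 1,
    },
    "polyamines": {"PUT": 1, "SPD": 1},
    "ptc_anchor": True,
}


@pytest.fixture(scope="session")
def ion_field(tmp_path_factory):
    path = tmp_path_factory.mktemp("ion") / "ion_field.cif"
    specs, manifest = fx.make_ion_field(8, 8, 8, jitter_sigma=0.05, seed=11,
                                        path=path)
    model = ms.load_structure(path)
    return model, manifest, path, specs


@pytest.fixture(scope="session")
def psu_cases(tmp_path_factory):
    path = tmp_path_factory.mktemp("psu") / "psu_cases.cif"
    specs, manifest = fx.make_psu_cases(seed=7, path=path)
    model = ms.load_structure(path, chain_roles=manifest.chain_roles)
    return model, manifest, path


@pytest.fixture(scope="session")
def toy_assembly(tmp_path_factory):
    path = tmp_path_factory.mktemp("toy") / "toy.cif"
    specs, manifest = fx.make_toy_assembly(TOY_SPEC, seed=5, path=path)
    model = ms.load_structure(path, chain_roles=manifest.chain_roles)
    return model, manifest, path


def random_rotation(seed: int) -> tuple[np.ndarray, np.ndarray]:
    """A seeded random rigid-body transform (rotation, translation)."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-30, 30, 3)
    return R, t
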