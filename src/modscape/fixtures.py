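"""Deterministic synthetic-structure generator with ground-truth manifests.

Every other module is testable without downloading anything: this module
plants ideal/jittered coordination sites, pseudouridine-like base/acceptor
geometries and toy multi-chain assemblies at mutually isolated grid points,
writes them as standard mmCIF, and records exactly what was planted (kinds,
residue keys, distances, jitter, seed) in a JSON manifest.

Planted parameter windows mirror the species being emulated: octahedral Mg
sites with ligand distances in 1.8-2.4 A, pentagonal K sites at 2.8-3.2 A,
waters with 1-3 partners at 2.6-3.4 A, pseudouridine acceptors straddling the
3.2 A rule in and out of the base plane.  Base rings are idealised regular
polygons with 1.4 A sides; chemical realism beyond what the geometry rules
read is not attempted.  Regeneration from the same (spec, seed) is
byte-identical; jitter that would push a planted distance out of its window
triggers bounded re-draws of the whole site, never an out-of-spec site.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from . import chemistry as chem
from .model_io import (AtomRecord, ComponentMap, ResidueKey, ResidueRecord,
                       StructureModel, classify_components)

#: minimum separation between planted sites (Angstrom)
MIN_SITE_SEPARATION = 12.0


class FixtureError(RuntimeError):
    """A site could not be planted within its parameter windows."""


# ---------------------------------------------------------------------------
# residue specs: (chain, number, comp, [(atom_name, element, (x, y, z)), ...])

ResidueSpec = tuple[str, int, str, list[tuple[str, str, tuple[float, float, float]]]]


@dataclass
class FixtureManifest:
    """Ground truth for a generated fixture."""

    generator: str
    seed: int
    sites: list[dict] = field(default_factory=list)
    chain_roles: dict[str, str] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def add_site(self, kind: str, key: ResidueKey, **params) -> None:
        self.sites.append({"kind": kind, "residue_key": list(key),
                           "params": params})

    def keys_of(self, *kinds: str) -> list[ResidueKey]:
        wanted = set(kinds)
        return [ResidueKey(*s["residue_key"]) for s in self.sites
                if s["kind"] in wanted]

    def to_json_obj(self) -> dict:
        return {"generator": self.generator, "seed": self.seed,
                "chain_roles": self.chain_roles, "sites": self.sites,
                "extra": self.extra}

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json_obj(), indent=2) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FixtureManifest":
        obj = json.loads(Path(path).read_text())
        return cls(generator=obj["generator"], seed=obj["seed"],
                   sites=obj["sites"], chain_roles=obj.get("chain_roles", {}),
                   extra=obj.get("extra", {}))


def build_model(specs: list[ResidueSpec], chain_roles: dict[str, str] | None = None,
                classify: bool = True) -> StructureModel:
    """Assemble an in-memory :class:`StructureModel` from residue specs."""
    atoms: list[AtomRecord] = []
    residues: dict[ResidueKey, ResidueRecord] = {}
    for chain, number, comp, atom_list in specs:
        key = ResidueKey(chain, number, "", comp)
        rec = residues.setdefault(key, ResidueRecord(key, seq_index=number))
        for name, element, pos in atom_list:
            serial = len(atoms)
            atoms.append(AtomRecord(serial, name, element, key,
                                    np.asarray(pos, float)))
            rec.atom_indices.append(serial)
    model = StructureModel(atoms, residues, dict(chain_roles or {}),
                           source="<fixture>")
    if classify:
        classify_components(model, ComponentMap.default())
    return model


def write_mmcif(specs: list[ResidueSpec], path: str | Path) -> Path:
    """Write residue specs as a standard mmCIF file (deterministic bytes)."""
    st = gemmi.Structure()
    st.name = "fixture"       # fixed block name: bytes depend only on (spec, seed)
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for chain_id, number, comp, atom_list in specs:
        chain = chains.get(chain_id)
        if chain is None:
            chain = gemmi.Chain(chain_id)
            chains[chain_id] = chain
        res = gemmi.Residue()
        res.name = comp
        res.seqid = gemmi.SeqId(number, " ")
        res.het_flag = "H"
        for name, element, pos in atom_list:
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(*[round(float(c), 4) for c in pos])
            atom.occ = 1.0
            atom.b_iso = 20.0
            res.add_atom(atom)
        chain.add_residue(res)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))
    return Path(path)


# ---------------------------------------------------------------------------
# random-geometry helpers


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalised quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _grid_points(n: int, spacing: float) -> list[np.ndarray]:
    side = max(1, math.ceil(n ** (1 / 3)))
    pts = []
    for i in range(n):
        ix, rem = divmod(i, side * side)
        iy, iz = divmod(rem, side)
        pts.append(np.array([ix, iy, iz], float) * spacing)
    return pts


OCTAHEDRAL_DIRS = np.array([
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
], float)

PENTAGONAL_DIRS = np.array([
    [math.cos(2 * math.pi * k / 5), math.sin(2 * math.pi * k / 5), 0.0]
    for k in range(5)
])


def _perpendiculars(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    p1 = np.cross(d, helper)
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(d, p1)
    return p1, p2


def _phosphate_spec(chain: str, number: int, o1_pos: np.ndarray,
                    outward: np.ndarray) -> ResidueSpec:
    """A PO4 residue whose O1 sits at ``o1_pos``; the rest points outward."""
    d = outward / np.linalg.norm(outward)
    p1, p2 = _perpendiculars(d)
    p_pos = o1_pos + 1.55 * d
    atoms = [("OP1", "O", tuple(o1_pos)), ("P", "P", tuple(p_pos))]
    for i, ang in enumerate((0.0, 2 * math.pi / 3, 4 * math.pi / 3), start=2):
        u = d + math.cos(ang) * p1 + math.sin(ang) * p2
        u /= np.linalg.norm(u)
        atoms.append((f"OP{i}", "O", tuple(p_pos + 1.5 * u)))
    return (chain, number, "PO4", atoms)


# ---------------------------------------------------------------------------
# ion fields


def _plant_shell(rng, center, dirs, window, sigma, max_retries=2000):
    """Ligand positions around ``center``: planted distances stay in ``window``."""
    n = len(dirs)
    for _ in range(max_retries):
        R = _random_rotation(rng)
        rotated = dirs @ R.T
        dists = rng.uniform(window[0], window[1], n)
        pos = center + rotated * dists[:, None] + rng.normal(0.0, sigma, (n, 3))
        actual = np.linalg.norm(pos - center, axis=1)
        if np.all((actual >= window[0]) & (actual <= window[1])):
            return pos, actual
    raise FixtureError(f"could not keep {n} jittered ligand distances inside "
                       f"{window} at sigma={sigma}")


def _plant_water_shell(rng, center, window, sigma, max_retries=2000):
    n_partners = int(rng.integers(1, 4))
    for _ in range(max_retries):
        dirs = rng.normal(size=(n_partners, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        ok = True
        for i in range(n_partners):
            for j in range(i + 1, n_partners):
                if np.dot(dirs[i], dirs[j]) > math.cos(math.radians(60)):
                    ok = False
        if not ok:
            continue
        dists = rng.uniform(window[0], window[1], n_partners)
        pos = center + dirs * dists[:, None] + rng.normal(0.0, sigma,
                                                          (n_partners, 3))
        actual = np.linalg.norm(pos - center, axis=1)
        if not np.all((actual >= window[0]) & (actual <= window[1])):
            continue
        # keep partner waters mutually at ordinary H-bond separations so they
        # themselves classify as waters
        if n_partners > 1:
            from scipy.spatial.distance import pdist

            if pdist(pos).min() < 2.56:
                continue
        return pos, actual
    raise FixtureError(f"could not plant a water site at sigma={sigma}")


MG_DISTANCE_WINDOW = (1.8, 2.4)
K_DISTANCE_WINDOW = (2.8, 3.2)
WATER_DISTANCE_WINDOW = (2.6, 3.4)


def make_ion_field(n_mg: int, n_k: int, n_water: int,
                   jitter_sigma: float = 0.05, seed: int = 0,
                   path: str | Path | None = None,
                   ) -> tuple[list[ResidueSpec], FixtureManifest]:
    """Plant jittered Mg / K / water coordination sites on an isolated grid.

    Mg sites are octahedra with ligand distances in 1.8-2.4 A, K sites
    pentagons at 2.8-3.2 A, waters get 1-3 partners at 2.6-3.4 A; some Mg/K
    ligands are phosphate oxygens, the rest waters.  When ``path`` is given
    the mmCIF and a ``.manifest.json`` sidecar are written there.
    """
    if min(n_mg, n_k, n_water) < 0:
        raise ValueError("site counts must be >= 0")
    rng = np.random.default_rng(seed)
    manifest = FixtureManifest(generator="make_ion_field", seed=seed)
    manifest.extra = {"jitter_sigma": jitter_sigma,
                      "counts": {"Mg": n_mg, "K": n_k, "water": n_water}}
    total = n_mg + n_k + n_water
    grid = _grid_points(total, spacing=14.0)
    specs: list[ResidueSpec] = []
    water_no, po4_no = 1, 1

    def add_ligands(center, positions, n_po4):
        nonlocal water_no, po4_no
        for i, lpos in enumerate(positions):
            if i < n_po4:
                outward = lpos - center
                specs.append(_phosphate_spec("X", po4_no, lpos, outward))
                po4_no += 1
            else:
                specs.append(("W", water_no, "HOH", [("O", "O", tuple(lpos))]))
                water_no += 1

    site_idx = 0
    for i in range(n_mg):
        center = grid[site_idx]; site_idx += 1
        pos, actual = _plant_shell(rng, center, OCTAHEDRAL_DIRS,
                                   MG_DISTANCE_WINDOW, jitter_sigma)
        n_po4 = int(rng.integers(0, 3))
        specs.append(("M", i + 1, "MG", [("MG", "Mg", tuple(center))]))
        add_ligands(center, pos, n_po4)
        manifest.add_site("Mg", ResidueKey("M", i + 1, "", "MG"),
                          distances=[round(float(d), 4) for d in actual],
                          jitter_sigma=jitter_sigma, n_phosphate=n_po4)
    for i in range(n_k):
        center = grid[site_idx]; site_idx += 1
        pos, actual = _plant_shell(rng, center, PENTAGONAL_DIRS,
                                   K_DISTANCE_WINDOW, jitter_sigma)
        n_po4 = int(rng.integers(0, 3))
        specs.append(("K", i + 1, "K", [("K", "K", tuple(center))]))
        add_ligands(center, pos, n_po4)
        manifest.add_site("K", ResidueKey("K", i + 1, "", "K"),
                          distances=[round(float(d), 4) for d in actual],
                          jitter_sigma=jitter_sigma, n_phosphate=n_po4)
    for i in range(n_water):
        center = grid[site_idx]; site_idx += 1
        pos, actual = _plant_water_shell(rng, center, WATER_DISTANCE_WINDOW,
                                         jitter_sigma)
        specs.append(("V", i + 1, "HOH", [("O", "O", tuple(center))]))
        add_ligands(center, pos, 0)
        manifest.add_site("water", ResidueKey("V", i + 1, "", "HOH"),
                          distances=[round(float(d), 4) for d in actual],
                          jitter_sigma=jitter_sigma)

    _check_separation(grid)
    if path is not None:
        write_mmcif(specs, path)
        manifest.save(Path(path).with_suffix(".manifest.json"))
    return specs, manifest


def _check_separation(points, min_sep: float = MIN_SITE_SEPARATION) -> None:
    if len(points) < 2:
        return
    from scipy.spatial import cKDTree

    tree = cKDTree(np.stack(points))
    close = tree.query_pairs(r=min_sep - 1e-9)
    if close:
        raise FixtureError(f"planted sites closer than {min_sep} A: {sorted(close)[:3]}")


def recovery_rate(report, manifest: FixtureManifest) -> float:
    """Fraction of manifest sites whose assigned label matches the planted kind."""
    assigned = {site.residue_key: site.label for site in report.sites}
    planted = [(ResidueKey(*s["residue_key"]), s["kind"]) for s in manifest.sites
               if s["kind"] in ("Mg", "K", "water")]
    if not planted:
        return float("nan")
    hits = sum(1 for key, kind in planted if assigned.get(key) == kind)
    return hits / len(planted)


# ---------------------------------------------------------------------------
# pseudouridine cases


def _pyrimidine_ring_local() -> dict[str, np.ndarray]:
    """Idealised six-membered ring (1.4 A sides) with exocyclic O2/O4, z = 0."""
    R = 1.4
    names = chem.PYRIMIDINE_RING
    ring = {name: R * np.array([math.cos(math.radians(60 * k)),
                                math.sin(math.radians(60 * k)), 0.0])
            for k, name in enumerate(names)}
    for base_atom, exo in (("C2", "O2"), ("C4", "O4")):
        v = ring[base_atom]
        ring[exo] = v * (1 + 1.23 / np.linalg.norm(v))
    return ring


def _purine_ring_local(exocyclic: dict[str, str]) -> dict[str, np.ndarray]:
    """Idealised fused purine ring: hexagon plus pentagon on the C4-C5 edge."""
    ring = {k: v for k, v in _pyrimidine_ring_local().items()
            if k in chem.PYRIMIDINE_RING}
    c4, c5 = ring["C4"], ring["C5"]
    mid = (c4 + c5) / 2
    out = mid / np.linalg.norm(mid)          # away from the hexagon centre
    side = float(np.linalg.norm(c5 - c4))
    r5 = side / (2 * math.sin(math.pi / 5))
    apo = r5 * math.cos(math.pi / 5)
    pc = mid + apo * out
    # rotate C4 - pc about z in 72-degree steps, outward from the hexagon
    def rot(v, deg):
        a = math.radians(deg)
        return np.array([v[0] * math.cos(a) - v[1] * math.sin(a),
                         v[0] * math.sin(a) + v[1] * math.cos(a), 0.0])
    v4 = c4 - pc
    cands = [pc + rot(v4, 72), pc + rot(v4, -72)]
    n9 = max(cands, key=lambda p: float(np.linalg.norm(p - c5)))
    step = 72 if np.allclose(n9, cands[0]) else -72
    c8 = pc + rot(v4, 2 * step)
    n7 = pc + rot(v4, 3 * step)
    ring.update({"N9": n9, "C8": c8, "N7": n7})
    for base_atom, exo in exocyclic.items():
        v = ring[base_atom]
        ring[exo] = v * (1 + 1.33 / np.linalg.norm(v))
    return ring


#: exocyclic atoms per base letter
_BASE_RINGS = {
    "U": lambda: _pyrimidine_ring_local(),
    "C": lambda: {**{k: v for k, v in _pyrimidine_ring_local().items()
                     if k != "O4"},
                  "N4": _pyrimidine_ring_local()["O4"]},
    "A": lambda: _purine_ring_local({"C6": "N6"}),
    "G": lambda: _purine_ring_local({"C6": "O6", "C2": "N2"}),
}

#: base letter used for the ring of each planted component id
_COMP_BASE = {
    "U": "U", "PSU": "U", "OMU": "U", "PSM": "U", "UR3": "U",
    "C": "C", "OMC": "C", "5MC": "C", "M4C": "C", "4OC": "C",
    "A": "A", "A2M": "A", "1MA": "A", "6MZ": "A",
    "G": "G", "OMG": "G",
}

#: ribose/phosphate stub, local coordinates (below the base plane)
_SUGAR_STUB = [
    ("C1'", "C", (2.4, 0.0, -1.2)),
    ("O4'", "O", (3.3, 0.8, -1.2)),
    ("O2'", "O", (2.9, -1.0, -2.2)),
    ("O3'", "O", (3.6, -1.8, -3.0)),
    ("P", "P", (4.5, 0.0, -2.0)),
    ("OP1", "O", (5.2, 0.9, -1.5)),
    ("OP2", "O", (5.2, -0.9, -1.5)),
    ("O5'", "O", (4.0, 0.0, -3.3)),
]


def nucleotide_spec(chain: str, number: int, comp: str,
                    origin: np.ndarray, rotation: np.ndarray,
                    with_sugar: bool = True) -> ResidueSpec:
    """An idealised nucleotide residue at ``origin`` with the given orientation."""
    base = _BASE_RINGS[_COMP_BASE[comp]]()
    atoms = []
    for name, pos in base.items():
        elem = name[0]
        atoms.append((name, elem, tuple(rotation @ pos + origin)))
    if with_sugar:
        for name, elem, pos in _SUGAR_STUB:
            atoms.append((name, elem,
                          tuple(rotation @ np.asarray(pos, float) + origin)))
    return (chain, number, comp, atoms)


def _probe_geometry(comp: str) -> tuple[str, np.ndarray]:
    """Probe atom name and its local position on the idealised ring."""
    name = "N1" if comp in ("PSU", "PSM") else "C5"
    ring = _BASE_RINGS[_COMP_BASE[comp]]()
    return name, ring[name]


def psu_case_specs(chain: str, number: int, comp: str, origin: np.ndarray,
                   rotation: np.ndarray, distance: float | None,
                   out_of_plane: float = 0.0, partner_kind: str = "water",
                   partner_number: int = 0) -> list[ResidueSpec]:
    """A base ring plus (optionally) one planted acceptor at an exact geometry.

    The acceptor sits ``distance`` from the probe atom (N1 for pseudouridine
    components, C5 for uridine) with a perpendicular offset of
    ``out_of_plane`` from the base plane; ``distance=None`` plants no partner
    (bare case).  Partner kinds: water, phosphate, ribose-O2prime.
    """
    specs = [nucleotide_spec(chain, number, comp, origin, rotation,
                             with_sugar=False)]
    if distance is None:
        return specs
    probe_name, probe_local = _probe_geometry(comp)
    radial = probe_local / np.linalg.norm(probe_local)
    in_plane = math.sqrt(max(distance ** 2 - out_of_plane ** 2, 0.0))
    target_local = probe_local + in_plane * radial + np.array(
        [0.0, 0.0, out_of_plane])
    target = rotation @ target_local + origin
    if partner_kind == "water":
        specs.append(("W", partner_number, "HOH", [("O", "O", tuple(target))]))
    elif partner_kind == "phosphate":
        outward = rotation @ radial
        specs.append(_phosphate_spec("X", partner_number, target, outward))
    elif partner_kind == "ribose-O2prime":
        away = rotation @ (radial * 1.4)
        specs.append(("R", partner_number, "U",
                      [("O2'", "O", tuple(target)),
                       ("C1'", "C", tuple(target + away))]))
    else:
        raise ValueError(f"unknown partner kind {partner_kind!r}")
    return specs


def make_psu_cases(seed: int = 0, path: str | Path | None = None
                   ) -> tuple[list[ResidueSpec], FixtureManifest]:
    """The four canonical pseudouridine test geometries.

    1. in-plane water at 3.0 A            -> supported
    2. in-plane phosphate oxygen at 3.4 A -> unsupported (beyond the cutoff)
    3. ribose O2' at 3.0 A, 2.0 A out of the base plane -> unsupported
    4. bare ring, no O/N within 6 A       -> unresolved-environment
    """
    rng = np.random.default_rng(seed)
    manifest = FixtureManifest(generator="make_psu_cases", seed=seed)
    grid = _grid_points(4, spacing=14.0)
    cases = [
        ("psu-supported", 3.0, 0.0, "water"),
        ("psu-unsupported", 3.4, 0.0, "phosphate"),
        ("psu-unsupported", 3.0, 2.0, "ribose-O2prime"),
        ("psu-bare", None, 0.0, None),
    ]
    specs: list[ResidueSpec] = []
    for i, (kind, dist, oop, partner) in enumerate(cases):
        number = 101 + i
        rot = _random_rotation(rng)
        specs.extend(psu_case_specs("A", number, "PSU", grid[i], rot,
                                    dist, oop, partner or "water",
                                    partner_number=i + 1))
        manifest.add_site(kind, ResidueKey("A", number, "", "PSU"),
                          distance=dist, out_of_plane=oop,
                          partner_kind=partner)
    manifest.chain_roles = {"A": "28S"}
    _check_separation(grid)
    if path is not None:
        write_mmcif(specs, path)
        manifest.save(Path(path).with_suffix(".manifest.json"))
    return specs, manifest


def make_psu_probe(distance: float, out_of_plane: float = 0.0,
                   comp: str = "PSU", partner_kind: str = "water",
                   seed: int = 0) -> StructureModel:
    """Single planted base/acceptor geometry as an in-memory model (for sweeps)."""
    rng = np.random.default_rng(seed)
    rot = _random_rotation(rng)
    specs = psu_case_specs("A", 224, comp, np.zeros(3), rot, distance,
                           out_of_plane, partner_kind, partner_number=1)
    return build_model(specs, chain_roles={"A": "28S"})


# ---------------------------------------------------------------------------
# toy assemblies


#: component id planted for each modification class
_CLASS_COMPONENT = {
    chem.CLS_PSU: "PSU", chem.CLS_NM: "OMU", chem.CLS_COMBINED: "PSM",
    chem.CLS_M1A: "1MA", chem.CLS_M4C: "M4C", chem.CLS_M5C: "5MC",
    chem.CLS_M6A: "6MZ", chem.CLS_M3U: "UR3",
    chem.CLS_HIS_BOX: "OHI", chem.CLS_HIS_TAU: "HIC", chem.CLS_LYS_EPS: "MLZ",
}

_POLYAMINE_LENGTH = {"PUT": 6, "SPD": 10, "SPM": 14}   # heavy atoms, N at ends
_POLYAMINE_N_POSITIONS = {"PUT": (0, 5), "SPD": (0, 4, 9),
                          "SPM": (0, 4, 9, 13)}


def _polyamine_atoms(comp: str, origin: np.ndarray
                     ) -> list[tuple[str, str, tuple[float, float, float]]]:
    n_atoms = _POLYAMINE_LENGTH[comp]
    n_pos = set(_POLYAMINE_N_POSITIONS[comp])
    atoms = []
    for i in range(n_atoms):
        elem = "N" if i in n_pos else "C"
        pos = origin + np.array([1.25 * i, 0.5 * (i % 2), 0.0])
        atoms.append((f"{elem}{i + 1}", elem, tuple(pos)))
    return atoms


def _amino_acid_spec(chain: str, number: int, comp: str, origin: np.ndarray
                     ) -> ResidueSpec:
    backbone = [("N", "N", (0.0, 0.0, 0.0)), ("CA", "C", (1.46, 0.0, 0.0)),
                ("C", "C", (2.2, 1.3, 0.0)), ("O", "O", (3.4, 1.3, 0.3)),
                ("CB", "C", (2.1, -1.0, 1.0))]
    atoms = [(n, e, tuple(np.asarray(p) + origin)) for n, e, p in backbone]
    if comp in ("OHI", "HIC", "HIS", "MHS"):
        ring = chem.SIDECHAIN_RINGS["HIS"]
        r5 = 1.4 / (2 * math.sin(math.pi / 5))
        for k, name in enumerate(ring):
            ang = 2 * math.pi * k / 5
            pos = origin + np.array([2.1 + r5 * math.cos(ang),
                                     -2.4 + r5 * math.sin(ang), 1.6])
            atoms.append((name, name[0], tuple(pos)))
        if comp == "OHI":
            atoms.append(("OB", "O", tuple(origin + np.array([3.0, -1.0, 2.2]))))
    elif comp == "MLZ":
        atoms.append(("NZ", "N", tuple(origin + np.array([3.0, -2.0, 2.0]))))
        atoms.append(("CM", "C", tuple(origin + np.array([4.2, -2.6, 2.2]))))
    return (chain, number, comp, atoms)


def make_toy_assembly(spec: dict, seed: int = 0,
                      path: str | Path | None = None
                      ) -> tuple[list[ResidueSpec], FixtureManifest]:
    """Multi-chain toy assembly whose census and contact maps are fully
    predicted by the manifest.

    ``spec`` keys (all optional):

    * ``modifications``: mapping modification class -> count (planted in
      chain A, role 28S, except protein classes which go to chain P);
    * ``polyamines``: mapping species (PUT/SPD/SPM) -> count, each anchored by
      terminal amines to phosphate oxygens at 2.9 A with one water bridge
      (amine - water 2.8 A, water - phosphate 2.8 A), unless
      ``anchor_polyamines`` is false;
    * ``standard_nt`` / ``standard_aa``: filler residue counts (defaults 4/2);
    * ``ptc_anchor``: plant an adenosine A4397 in chain A as distance anchor.
    """
    rng = np.random.default_rng(seed)
    mods: dict[str, int] = dict(spec.get("modifications", {}))
    polyamines: dict[str, int] = dict(spec.get("polyamines", {}))
    anchor_polyamines = bool(spec.get("anchor_polyamines", True))
    n_std_nt = int(spec.get("standard_nt", 4))
    n_std_aa = int(spec.get("standard_aa", 2))
    want_anchor = bool(spec.get("ptc_anchor", False))

    for cls in mods:
        if cls not in _CLASS_COMPONENT:
            raise ValueError(f"no component for modification class {cls!r}")
    protein_classes = {chem.CLS_HIS_BOX, chem.CLS_HIS_TAU, chem.CLS_LYS_EPS}

    n_sites = (sum(mods.values()) + sum(polyamines.values()) + n_std_nt
               + n_std_aa + 2 + int(want_anchor))
    grid = _grid_points(n_sites, spacing=20.0)
    site = iter(grid)
    specs: list[ResidueSpec] = []
    manifest = FixtureManifest(generator="make_toy_assembly", seed=seed)
    manifest.chain_roles = {"A": "28S", "B": "5.8S", "P": "uL2"}
    manifest.extra = {"spec": {
        "modifications": mods, "polyamines": polyamines,
        "standard_nt": n_std_nt, "standard_aa": n_std_aa,
        "anchor_polyamines": anchor_polyamines, "ptc_anchor": want_anchor}}

    a_no, p_no, q_no, w_no, x_no = 101, 201, 301, 501, 601
    for cls in sorted(mods):
        comp = _CLASS_COMPONENT[cls]
        for _ in range(mods[cls]):
            origin = next(site)
            if cls in protein_classes:
                specs.append(_amino_acid_spec("P", p_no, comp, origin))
                key = ResidueKey("P", p_no, "", comp)
                p_no += 1
            else:
                specs.append(nucleotide_spec("A", a_no, comp, origin,
                                             _random_rotation(rng)))
                key = ResidueKey("A", a_no, "", comp)
                a_no += 1
            manifest.add_site("modified-residue", key, modification_class=cls)

    filler = ["G", "U", "A", "C"]
    for i in range(n_std_nt):
        comp = filler[i % 4]
        specs.append(nucleotide_spec("A", a_no, comp, next(site),
                                     _random_rotation(rng)))
        a_no += 1
    for i in range(2):      # small 5.8S chain
        specs.append(nucleotide_spec("B", 11 + i, filler[i % 4], next(site),
                                     _random_rotation(rng)))
    for _ in range(n_std_aa):
        specs.append(_amino_acid_spec("P", p_no, "ALA", next(site)))
        p_no += 1
    if want_anchor:
        origin = next(site)
        specs.append(nucleotide_spec("A", 4397, "A", origin,
                                     _random_rotation(rng)))
        manifest.add_site("ptc-anchor", ResidueKey("A", 4397, "", "A"),
                          origin=[round(float(c), 4) for c in origin])

    for species in sorted(polyamines):
        for _ in range(polyamines[species]):
            origin = next(site)
            atoms = _polyamine_atoms(species, origin)
            specs.append(("Q", q_no, species, atoms))
            key = ResidueKey("Q", q_no, "", species)
            n_idx = _POLYAMINE_N_POSITIONS[species]
            terminals = [np.asarray(atoms[i][2]) for i in (n_idx[0], n_idx[-1])]
            n_contacts = 0
            if anchor_polyamines:
                for t in terminals:
                    specs.append(_phosphate_spec(
                        "X", x_no, t + np.array([0.0, 2.9, 0.0]),
                        np.array([0.0, 1.0, 0.0])))
                    x_no += 1
                    n_contacts += 1
                wpos = terminals[0] + np.array([0.0, -2.8, 0.0])
                specs.append(("W", w_no, "HOH", [("O", "O", tuple(wpos))]))
                w_no += 1
                specs.append(_phosphate_spec(
                    "X", x_no, wpos + np.array([0.0, -2.8, 0.0]),
                    np.array([0.0, -1.0, 0.0])))
                x_no += 1
            manifest.add_site("polyamine", key, species=species,
                              anchored=anchor_polyamines,
                              n_phosphate_contacts=n_contacts,
                              n_water_bridges=1 if anchor_polyamines else 0)
            q_no += 1

    _check_separation(grid)
    if path is not None:
        write_mmcif(specs, path)
        manifest.save(Path(path).with_suffix(".manifest.json"))
    return specs, manifest


def reference_from_manifest(manifest: FixtureManifest):
    """Reference modification list implied by a toy-assembly manifest."""
    from .mod_census import ReferenceModList, ReferenceRow

    rows = []
    for s in manifest.sites:
        if s["kind"] != "modified-residue":
            continue
        key = ResidueKey(*s["residue_key"])
        role = manifest.chain_roles.get(key.chain, key.chain)
        rows.append(ReferenceRow(role, key.number,
                                 s["params"]["modification_class"]))
    return ReferenceModList(rows, source=f"manifest:{manifest.generator}")
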