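"""Atomic-model I/O and residue classification.

Parses mmCIF/PDB files (via gemmi) into a light-weight :class:`StructureModel`
holding per-atom records and per-residue category annotations, classifies every
residue through an editable :class:`ComponentMap`, and writes deterministic
TSV/JSON reports.

Conventions
-----------
* Residues are addressed by author numbering (``ResidueKey``), the numbering
  the literature uses; the sequential (label) index is stored alongside.
* Alternate locations are collapsed to the highest-occupancy conformer
  (ties broken by alphabetical altloc id) so downstream geometry is
  single-conformer and deterministic.
* Zero-occupancy atoms are retained and flagged; geometry includes them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

import gemmi
import numpy as np
import pandas as pd

from . import chemistry as chem


class ParseError(ValueError):
    """Raised when an input file cannot be parsed into a usable model."""


class ResidueKey(NamedTuple):
    """Author-numbering address of a residue: (chain, number, icode, comp_id)."""

    chain: str
    number: int
    icode: str
    comp: str

    def __str__(self) -> str:  # e.g. "A/PSU224"
        return f"{self.chain}/{self.comp}{self.number}{self.icode}"


@dataclass
class AtomRecord:
    serial: int                 # 0-based position in the model's atom list
    name: str
    element: str
    residue_key: ResidueKey
    pos: np.ndarray             # (3,) float64, Angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""
    zero_occupancy: bool = False

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} not in [0, 1]")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")


@dataclass
class ResidueRecord:
    key: ResidueKey
    seq_index: int | None = None          # sequential (label) numbering, if any
    is_polymer: bool = False
    category: str | None = None
    modification_class: str | None = None
    atom_indices: list[int] = field(default_factory=list)

    @property
    def tally_classes(self) -> frozenset[str]:
        return chem.tally_classes(self.modification_class)


class ComponentMap:
    """Editable table mapping component ids to (category, modification_class).

    Unmapped polymer residues fall back to the standard nucleotide / amino-acid
    category inferred from their entity type and atom content; unmapped
    non-polymer residues become ``other-ligand``.
    """

    def __init__(self, table: dict[str, tuple[str, str | None]] | None = None):
        self.table: dict[str, tuple[str, str | None]] = dict(table or {})

    @classmethod
    def default(cls) -> "ComponentMap":
        text = resources.files("modscape.data").joinpath("component_map.tsv").read_text()
        return cls.from_tsv_text(text)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ComponentMap":
        return cls.from_tsv_text(Path(path).read_text())

    @classmethod
    def from_tsv_text(cls, text: str) -> "ComponentMap":
        table: dict[str, tuple[str, str | None]] = {}
        for line in text.splitlines():
            line = line.rstrip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "component_id":
                continue
            comp = fields[0].strip()
            category = fields[1].strip()
            mod_class = fields[2].strip() if len(fields) > 2 and fields[2].strip() else None
            if category not in chem.CATEGORIES:
                raise ValueError(f"component map: unknown category {category!r} for {comp}")
            if comp in table:
                raise ValueError(f"component map: duplicate entry for {comp}")
            table[comp] = (category, mod_class)
        return cls(table)

    def add(self, comp: str, category: str, modification_class: str | None = None) -> None:
        self.table[comp] = (category, modification_class)

    def lookup(self, residue: ResidueRecord, atom_names: Iterable[str]) -> tuple[str, str | None]:
        comp = residue.key.comp
        if comp in self.table:
            return self.table[comp]
        if comp in chem.STANDARD_RIBONUCLEOTIDES or comp in chem.STANDARD_DEOXYNUCLEOTIDES:
            return chem.CAT_STD_NT, None
        if comp in chem.STANDARD_AMINO_ACIDS:
            return chem.CAT_STD_AA, None
        if residue.is_polymer:
            # fall back on element/atom composition of the parent entity
            names = set(atom_names)
            if names & {"C1'", "O4'", "P", "O2'", "N9"}:
                return chem.CAT_STD_NT, None
            return chem.CAT_STD_AA, None
        return chem.CAT_OTHER, None


@dataclass
class StructureModel:
    """Atoms + residues + chain roles of a parsed assembly."""

    atoms: list[AtomRecord]
    residues: dict[ResidueKey, ResidueRecord]
    chain_roles: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        self._coords: np.ndarray | None = None
        self._kdtree = None

    # -- spatial caches ----------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        if self._coords is None:
            if self.atoms:
                self._coords = np.stack([a.pos for a in self.atoms])
            else:
                self._coords = np.empty((0, 3))
        return self._coords

    @property
    def kdtree(self):
        if self._kdtree is None:
            from scipy.spatial import cKDTree

            self._kdtree = cKDTree(self.coords)
        return self._kdtree

    def invalidate_caches(self) -> None:
        self._coords = None
        self._kdtree = None

    # -- accessors ---------------------------------------------------------
    def atoms_of(self, key: ResidueKey) -> list[AtomRecord]:
        return [self.atoms[i] for i in self.residues[key].atom_indices]

    def atom(self, key: ResidueKey, name: str) -> AtomRecord:
        for a in self.atoms_of(key):
            if a.name == name:
                return a
        raise KeyError(f"residue {key} has no atom {name!r}")

    def find_atom(self, key: ResidueKey, name: str) -> AtomRecord | None:
        for a in self.atoms_of(key):
            if a.name == name:
                return a
        return None

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for key in self.residues:
            seen.setdefault(key.chain, None)
        return list(seen)

    def role_of(self, chain: str) -> str:
        return self.chain_roles.get(chain, "unassigned")

    def chains_with_role(self, role: str) -> list[str]:
        return [c for c, r in self.chain_roles.items() if r == role]

    def residues_in_category(self, *categories: str) -> list[ResidueRecord]:
        wanted = set(categories)
        return [r for r in self.residues.values() if r.category in wanted]

    # -- transforms (used by invariance tests and by callers aligning models)
    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigid-body transformed copy of the model."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_atoms = [
            AtomRecord(a.serial, a.name, a.element, a.residue_key, R @ a.pos + t,
                       a.occupancy, a.b_factor, a.altloc, a.zero_occupancy)
            for a in self.atoms
        ]
        new_res = {
            k: ResidueRecord(r.key, r.seq_index, r.is_polymer, r.category,
                             r.modification_class, list(r.atom_indices))
            for k, r in self.residues.items()
        }
        return StructureModel(new_atoms, new_res, dict(self.chain_roles), self.source)


# ---------------------------------------------------------------------------
# loading


def _normalize_atom_name(name: str) -> str:
    return name.replace("*", "'")


def _collapse_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc id."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in residue:
        by_name.setdefault(atom.name, []).append(atom)
    kept = []
    for name, alts in by_name.items():
        alts.sort(key=lambda a: (-a.occ, a.altloc or "~"))
        kept.append(alts[0])
    # preserve file order of the surviving atoms
    order = {id(a): i for i, a in enumerate(residue)}
    kept.sort(key=lambda a: order[id(a)])
    return kept


def _read_chain_roles_mmcif(path: Path) -> dict[str, str]:
    """Heuristic chain-role map from _entity.pdbx_description in an mmCIF file."""
    roles: dict[str, str] = {}
    try:
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
        desc = {}
        for row in block.find("_entity.", ["id", "?pdbx_description"]):
            if row.has(1):
                desc[row.str(0)] = row.str(1)
        for row in block.find("_struct_asym.", ["id", "entity_id"]):
            text = desc.get(row.str(1), "").upper()
            for token in ("28S", "25S", "5.8S", "5S", "18S", "16S", "23S"):
                if token in text:
                    roles[row.str(0)] = token
                    break
            else:
                if text and "RNA" not in text and "WATER" not in text:
                    roles[row.str(0)] = desc[row.str(1)]
    except Exception:
        return {}
    return roles


def load_structure(
    path: str | Path,
    format: str = "auto",
    component_map: ComponentMap | None = None,
    chain_roles: dict[str, str] | None = None,
    classify: bool = True,
) -> StructureModel:
    """Load an atomic model from mmCIF or PDB into a :class:`StructureModel`.

    Parameters
    ----------
    path
        Input coordinate file.
    format
        ``mmcif``, ``pdb`` or ``auto`` (extension/content sniffing via gemmi).
    component_map
        Mapping used to categorise residues; the shipped default when omitted.
    chain_roles
        Explicit chain -> role labels (e.g. ``{"A": "28S"}``); overrides the
        mmCIF entity-description heuristic.
    classify
        Annotate residue categories immediately (default).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: no atoms")
    fmt = {"mmcif": gemmi.CoorFormat.Mmcif,
           "pdb": gemmi.CoorFormat.Pdb,
           "auto": gemmi.CoorFormat.Detect}[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    st.setup_entities()

    atoms: list[AtomRecord] = []
    residues: dict[ResidueKey, ResidueRecord] = {}
    if len(st) == 0:
        raise ParseError(f"{path}: no atoms")
    model = st[0]
    for chain in model:
        for seq_index, res in enumerate(chain, start=1):
            key = ResidueKey(chain.name, res.seqid.num, (res.seqid.icode or "").strip(),
                             res.name)
            if key in residues:
                rec = residues[key]
            else:
                label_seq = res.label_seq if res.label_seq is not None else seq_index
                rec = ResidueRecord(
                    key,
                    seq_index=label_seq,
                    is_polymer=(res.entity_type == gemmi.EntityType.Polymer),
                )
                residues[key] = rec
            for atom in _collapse_altlocs(res):
                serial = len(atoms)
                occ = min(max(float(atom.occ), 0.0), 1.0)
                atoms.append(AtomRecord(
                    serial=serial,
                    name=_normalize_atom_name(atom.name),
                    element=atom.element.name or "X",
                    residue_key=key,
                    pos=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=occ,
                    b_factor=float(atom.b_iso),
                    altloc=atom.altloc or "",
                    zero_occupancy=(atom.occ <= 0.0),
                ))
                rec.atom_indices.append(serial)

    if not atoms:
        raise ParseError(f"{path}: no atoms")

    roles = dict(chain_roles) if chain_roles else {}
    if not roles and path.suffix.lower() in {".cif", ".mmcif"}:
        roles = _read_chain_roles_mmcif(path)

    sm = StructureModel(atoms, residues, roles, source=str(path))
    if classify:
        classify_components(sm, component_map or ComponentMap.default())
    return sm


def classify_components(model: StructureModel, component_map: ComponentMap | None = None
                        ) -> StructureModel:
    """Annotate every residue with its category and modification class.

    Idempotent; unknown non-polymer components become ``other-ligand``.
    """
    cmap = component_map or ComponentMap.default()
    for rec in model.residues.values():
        names = [model.atoms[i].name for i in rec.atom_indices]
        category, mod_class = cmap.lookup(rec, names)
        rec.category = category
        rec.modification_class = mod_class
    return model


def save_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model back to mmCIF (single conformer, author numbering)."""
    st = gemmi.Structure()
    st.name = Path(path).stem
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for key, rec in model.residues.items():
        chain = chains.get(key.chain)
        if chain is None:
            chain = gemmi.Chain(key.chain)
            chains[key.chain] = chain
        res = gemmi.Residue()
        res.name = key.comp
        res.seqid = gemmi.SeqId(key.number, key.icode or " ")
        res.het_flag = "A" if rec.is_polymer else "H"
        for i in rec.atom_indices:
            a = model.atoms[i]
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.pos)
            atom.occ = a.occupancy
            atom.b_iso = a.b_factor
            res.add_atom(atom)
        chain.add_residue(res)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    doc = st.make_mmcif_document()
    doc.write_file(str(path))


# ---------------------------------------------------------------------------
# report writing


def _round_floats(obj, ndigits: int = 3):
    if isinstance(obj, float):
        if not math.isfinite(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_report(report, path: str | Path, format: str = "tsv") -> Path:
    """Serialise a report deterministically (fixed field order, 3-decimal floats).

    ``report`` must expose ``to_frame()`` (for TSV) and ``to_json_obj()``
    (for JSON); bare DataFrames are accepted for TSV.
    """
    path = Path(path)
    if format == "tsv":
        frame = report if isinstance(report, pd.DataFrame) else report.to_frame()
        text = frame.to_csv(sep="\t", index=False, float_format="%.3f",
                            lineterminator="\n")
        path.write_text(text)
    elif format == "json":
        obj = report.to_json_obj() if hasattr(report, "to_json_obj") else report
        path.write_text(json.dumps(_round_floats(obj), indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path
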