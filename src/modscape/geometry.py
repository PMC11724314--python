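"""Spatial primitives: neighbour search, base-plane fits, hydrogen bonds,
coordination shells.

All distance comparisons use closed intervals and ties in sort order are
broken by atom serial, so every operation is exactly reproducible and can be
checked against a brute-force all-pairs oracle.  Hydrogen bonds are inferred
from donor/acceptor *heavy-atom* separation alone (hydrogens are absent from
the use case); the default window is 2.4-3.5 Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import chemistry as chem
from .model_io import AtomRecord, ResidueKey, StructureModel

#: default heavy-atom hydrogen-bond window, Angstrom
HBOND_WINDOW = (2.4, 3.5)
#: pairs closer than this are covalently bonded, never hydrogen bonds
COVALENT_CUTOFF = 1.8
#: elements accepted as hydrogen-bond donors/acceptors by default
HBOND_ELEMENTS = frozenset({"N", "O"})


@dataclass(frozen=True)
class HBond:
    partner_a: AtomRecord
    partner_b: AtomRecord
    distance: float


@dataclass(frozen=True)
class BasePlane:
    normal: np.ndarray      # unit vector
    centroid: np.ndarray    # Angstrom
    fit_rms: float          # Angstrom
    ring_atoms: tuple[AtomRecord, ...]

    def signed_offset(self, point: np.ndarray) -> float:
        """Perpendicular distance of ``point`` from the plane (signed)."""
        return float(np.dot(np.asarray(point, float) - self.centroid, self.normal))


@dataclass
class CoordinationShell:
    center: AtomRecord
    ligands: list[tuple[AtomRecord, float]]   # sorted by distance ascending
    angle_stats: list[float]                  # all L-center-L angles, degrees

    @property
    def distances(self) -> np.ndarray:
        return np.array([d for _, d in self.ligands])

    def __len__(self) -> int:
        return len(self.ligands)


def neighbor_search(
    model: StructureModel,
    center: np.ndarray,
    radius: float,
    exclude: set[ResidueKey] | None = None,
) -> list[tuple[AtomRecord, float]]:
    """All atoms within ``radius`` of ``center`` (closed interval).

    Returns (atom, distance) pairs sorted by distance, ties by atom serial;
    atoms of residues in ``exclude`` are omitted.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    center = np.asarray(center, dtype=float)
    if model.coords.shape[0] == 0:
        return []
    # query slightly beyond radius, then apply the exact closed-interval test
    idx = model.kdtree.query_ball_point(center, radius * (1 + 1e-9) + 1e-9)
    out = []
    for i in idx:
        atom = model.atoms[i]
        if exclude and atom.residue_key in exclude:
            continue
        d = float(np.linalg.norm(atom.pos - center))
        if d <= radius:
            out.append((atom, d))
    out.sort(key=lambda pair: (pair[1], pair[0].serial))
    return out


def fit_base_plane(model: StructureModel, residue_key: ResidueKey) -> BasePlane:
    """Least-squares plane through the ring atoms of a base (or aromatic side chain).

    The normal is the singular direction of least variance; its sign is fixed
    to have a non-negative z component (ties broken on y then x) so the result
    is deterministic.
    """
    residue = model.residues[residue_key]
    atom_by_name = {model.atoms[i].name: model.atoms[i] for i in residue.atom_indices}
    names = chem.ring_atom_names(residue_key.comp, atom_by_name)
    ring = [atom_by_name[n] for n in names if n in atom_by_name]
    if len(ring) < 3:
        raise ValueError(f"ring incomplete: residue {residue_key} has "
                         f"{len(ring)} resolved ring atoms (need >= 3)")
    pts = np.stack([a.pos for a in ring])
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # SVD: right singular vector of the smallest singular value is the normal
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    for comp in (2, 1, 0):
        if abs(normal[comp]) > 1e-12:
            if normal[comp] < 0:
                normal = -normal
            break
    fit_rms = float(np.sqrt(np.mean(np.square(centered @ normal))))
    return BasePlane(normal=normal, centroid=centroid, fit_rms=fit_rms,
                     ring_atoms=tuple(ring))


def detect_hbonds(
    model: StructureModel,
    atom: AtomRecord,
    d_min: float = HBOND_WINDOW[0],
    d_max: float = HBOND_WINDOW[1],
    elements: frozenset[str] = HBOND_ELEMENTS,
    check_probe: bool = True,
) -> list[HBond]:
    """Heavy-atom hydrogen bonds of ``atom``: O/N partners in [d_min, d_max].

    Partners covalently bonded within the same residue (closer than the
    covalent cutoff) are excluded.  ``check_probe=False`` lets callers probe
    from non-O/N atoms (e.g. the C5 position of uridine).
    """
    if d_min >= d_max:
        raise ValueError(f"d_min ({d_min}) must be < d_max ({d_max})")
    if check_probe and atom.element not in elements:
        raise ValueError(f"probe atom {atom.name} is {atom.element}, not one of "
                         f"{sorted(elements)}; pass check_probe=False to override")
    bonds = []
    for partner, d in neighbor_search(model, atom.pos, d_max):
        if partner.serial == atom.serial:
            continue
        if partner.element not in elements:
            continue
        if partner.residue_key == atom.residue_key and d < COVALENT_CUTOFF:
            continue
        if d < d_min:
            continue
        bonds.append(HBond(atom, partner, d))
    return bonds


def coordination_sphere(
    model: StructureModel,
    center_atom: AtomRecord,
    r_max: float = 3.5,
    elements: frozenset[str] = HBOND_ELEMENTS,
) -> CoordinationShell:
    """O/N ligand shell of a candidate ion/water centre, with all L-M-L angles."""
    ligands = []
    for partner, d in neighbor_search(model, center_atom.pos, r_max):
        if partner.serial == center_atom.serial:
            continue
        if partner.element not in elements:
            continue
        ligands.append((partner, d))
    angles = ligand_angles(center_atom.pos, [a.pos for a, _ in ligands])
    return CoordinationShell(center=center_atom, ligands=ligands, angle_stats=angles)


def ligand_angles(center: np.ndarray, ligand_positions) -> list[float]:
    """All pairwise ligand-center-ligand angles in degrees, sorted ascending."""
    vecs = [np.asarray(p, float) - np.asarray(center, float) for p in ligand_positions]
    angles = []
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            cosang = np.dot(vecs[i], vecs[j]) / (
                np.linalg.norm(vecs[i]) * np.linalg.norm(vecs[j]))
            angles.append(float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))))
    angles.sort()
    return angles


def octahedral_angle_rms(angles) -> float:
    """RMS deviation of observed L-M-L angles from the nearest ideal 90/180 degrees.

    Returns ``inf`` for fewer than one angle (shells of < 2 ligands carry no
    angular evidence).
    """
    if len(angles) == 0:
        return float("inf")
    dev = [min(abs(a - 90.0), abs(a - 180.0)) for a in angles]
    return float(np.sqrt(np.mean(np.square(dev))))
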