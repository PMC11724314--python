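"""Polyamine contact maps, water-mediated hydrogen-bond networks and
base-stacking descriptors.

Polyamines (putrescine, spermidine, spermine) are aliphatic polycations whose
amine nitrogens hydrogen-bond to phosphate oxygens, waters and nucleobase
acceptors; they sit in water-filled cavities and take part in extended
water-mediated networks.  The network tracer performs a breadth-first
expansion from seed atoms over heavy-atom hydrogen-bond edges, crossing
waters freely and adding metal-coordination edges whenever a metal is
encountered; carbon atoms terminate expansion (they are neither donors nor
acceptors).  Stacking is reported purely geometrically (plane separation,
inter-plane angle, lateral offset) -- interpretation is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from . import chemistry as chem
from .geometry import (COVALENT_CUTOFF, HBOND_WINDOW, fit_base_plane,
                       neighbor_search)
from .model_io import AtomRecord, ResidueKey, StructureModel

#: distance window for metal-coordination edges, Angstrom
COORDINATION_WINDOW = (1.8, 3.35)

PARTNER_CLASSES = ("phosphate-O", "water", "base", "ribose", "protein", "other")


def _contact_partner_class(model: StructureModel, partner: AtomRecord) -> str:
    comp = partner.residue_key.comp
    rec = model.residues[partner.residue_key]
    if comp in chem.WATER_COMPONENTS:
        return "water"
    if partner.name in chem.PHOSPHATE_OXYGENS:
        return "phosphate-O"
    if rec.category in (chem.CAT_STD_AA, chem.CAT_MOD_AA):
        return "protein"
    if rec.category in (chem.CAT_STD_NT, chem.CAT_MOD_NT):
        if partner.name in chem.RIBOSE_OXYGENS:
            return "ribose"
        # remaining O/N of a nucleotide: ring and exocyclic base atoms
        return "base"
    return "other"


@dataclass
class WaterBridge:
    amine: AtomRecord
    water: AtomRecord
    partner: AtomRecord
    d_amine_water: float
    d_water_partner: float


@dataclass
class PolyamineContactMap:
    residue_key: ResidueKey
    species: str                                  # PUT / SPD / SPM
    contacts: list[tuple[AtomRecord, AtomRecord, str, float]] = field(
        default_factory=list)                     # (amine N, partner, class, d)
    water_bridges: list[WaterBridge] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "polyamine": str(self.residue_key),
            "species": self.species,
            "amine": a.name,
            "partner": f"{p.residue_key}/{p.name}",
            "partner_class": cls,
            "distance": d,
        } for a, p, cls, d in self.contacts]
        cols = ["polyamine", "species", "amine", "partner", "partner_class",
                "distance"]
        return pd.DataFrame(rows, columns=cols)

    def to_json_obj(self) -> dict:
        return {
            "polyamine": str(self.residue_key),
            "species": self.species,
            "contacts": self.to_frame().to_dict(orient="records"),
            "water_bridges": [{
                "amine": b.amine.name,
                "water": str(b.water.residue_key),
                "partner": f"{b.partner.residue_key}/{b.partner.name}",
                "d_amine_water": b.d_amine_water,
                "d_water_partner": b.d_water_partner,
            } for b in self.water_bridges],
        }


def map_polyamine_contacts(
    model: StructureModel,
    residue_key: ResidueKey,
    window: tuple[float, float] = HBOND_WINDOW,
) -> PolyamineContactMap:
    """Contacts and water bridges of one polyamine molecule.

    Every amine nitrogen's O/N partners inside the hydrogen-bond window are
    classified; bridges enumerate amine -> water -> second-shell partner paths
    with both legs in-window.
    """
    rec = model.residues[residue_key]
    if rec.category != chem.CAT_POLYAMINE:
        raise ValueError(f"residue {residue_key} is not a polyamine "
                         f"(category {rec.category})")
    cmap = PolyamineContactMap(residue_key=residue_key, species=residue_key.comp)
    amines = [a for a in model.atoms_of(residue_key) if a.element == "N"]
    for amine in amines:
        for partner, d in neighbor_search(model, amine.pos, window[1],
                                          exclude={residue_key}):
            if partner.element not in ("O", "N") or d < window[0]:
                continue
            cls = _contact_partner_class(model, partner)
            cmap.contacts.append((amine, partner, cls, d))
            if cls != "water":
                continue
            for second, d2 in neighbor_search(model, partner.pos, window[1],
                                              exclude={residue_key,
                                                       partner.residue_key}):
                if second.element not in ("O", "N") or d2 < window[0]:
                    continue
                cmap.water_bridges.append(
                    WaterBridge(amine, partner, second, d, d2))
    return cmap


def map_all_polyamines(model: StructureModel,
                       window: tuple[float, float] = HBOND_WINDOW
                       ) -> list[PolyamineContactMap]:
    return [map_polyamine_contacts(model, key, window)
            for key, rec in model.residues.items()
            if rec.category == chem.CAT_POLYAMINE]


# ---------------------------------------------------------------------------
# hydrogen-bond network tracing


@dataclass
class NetworkGraph:
    """Atoms as nodes, hydrogen/coordination bonds as edges, rooted in seeds."""

    graph: nx.Graph
    seeds: tuple[int, ...]          # atom serials
    depth: int
    model: StructureModel

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    def atom(self, serial: int) -> AtomRecord:
        return self.model.atoms[serial]

    def contains_atom(self, key: ResidueKey, name: str) -> bool:
        return any(self.atom(n).residue_key == key and self.atom(n).name == name
                   for n in self.graph.nodes)

    def edge_frame(self) -> pd.DataFrame:
        rows = []
        for u, v, data in sorted(self.graph.edges(data=True)):
            au, av = self.atom(u), self.atom(v)
            rows.append({
                "atom_a": f"{au.residue_key}/{au.name}",
                "atom_b": f"{av.residue_key}/{av.name}",
                "distance": data["distance"],
                "kind": data["kind"],
            })
        return pd.DataFrame(rows, columns=["atom_a", "atom_b", "distance", "kind"])

    def to_frame(self) -> pd.DataFrame:
        return self.edge_frame()

    def to_json_obj(self) -> dict:
        return {
            "seeds": [f"{self.atom(s).residue_key}/{self.atom(s).name}"
                      for s in self.seeds],
            "depth": self.depth,
            "n_nodes": self.graph.number_of_nodes(),
            "edges": self.edge_frame().to_dict(orient="records"),
        }

    def write_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for n in self.nodes:
            a = self.atom(n)
            g.add_node(n, atom=a.name, residue=str(a.residue_key),
                       element=a.element)
        for u, v, data in self.graph.edges(data=True):
            g.add_edge(u, v, distance=float(data["distance"]), kind=data["kind"])
        nx.write_graphml(g, str(path))


def _is_metal(atom: AtomRecord) -> bool:
    return atom.element in chem.METAL_ELEMENTS


def _network_neighbors(model: StructureModel, atom: AtomRecord,
                       window: tuple[float, float],
                       coord_window: tuple[float, float]
                       ) -> list[tuple[AtomRecord, float, str]]:
    """Edges leaving one node: H-bonds to O/N plus coordination to/from metals."""
    out = []
    r = max(window[1], coord_window[1])
    for partner, d in neighbor_search(model, atom.pos, r):
        if partner.serial == atom.serial:
            continue
        metal_pair = _is_metal(atom) or _is_metal(partner)
        if metal_pair:
            if partner.element not in ("O", "N") and not _is_metal(partner):
                continue
            if coord_window[0] <= d <= coord_window[1]:
                out.append((partner, d, "coordination"))
            continue
        if partner.element not in ("O", "N"):
            continue
        if partner.residue_key == atom.residue_key and d < COVALENT_CUTOFF:
            continue
        if window[0] <= d <= window[1]:
            out.append((partner, d, "hbond"))
    return out


def hbond_network(
    model: StructureModel,
    seeds: Iterable[AtomRecord],
    max_depth: int,
    window: tuple[float, float] = HBOND_WINDOW,
    coord_window: tuple[float, float] = COORDINATION_WINDOW,
) -> NetworkGraph:
    """Breadth-first hydrogen-bond network from seed atoms, depth-truncated.

    Node identity is the atom serial, so the result is independent of seed
    iteration order; after the expansion every in-window edge between two
    discovered nodes is closed, so the edge set depends only on the node set.
    """
    seeds = sorted({s.serial for s in seeds})
    if not seeds:
        raise ValueError("empty seed set")
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    g = nx.Graph()
    for s in seeds:
        g.add_node(s)
    frontier = list(seeds)
    depth_of = {s: 0 for s in seeds}
    for depth in range(max_depth):
        next_frontier = []
        for serial in sorted(frontier):
            atom = model.atoms[serial]
            for partner, d, kind in _network_neighbors(model, atom, window,
                                                       coord_window):
                if partner.serial not in depth_of:
                    depth_of[partner.serial] = depth + 1
                    g.add_node(partner.serial)
                    next_frontier.append(partner.serial)
                g.add_edge(serial, partner.serial, distance=d, kind=kind)
        frontier = next_frontier
        if not frontier:
            break
    # close edges among discovered nodes (e.g. between two frontier atoms)
    for serial in sorted(g.nodes):
        atom = model.atoms[serial]
        for partner, d, kind in _network_neighbors(model, atom, window,
                                                   coord_window):
            if partner.serial in depth_of:
                g.add_edge(serial, partner.serial, distance=d, kind=kind)
    return NetworkGraph(graph=g, seeds=tuple(seeds), depth=max_depth, model=model)


# ---------------------------------------------------------------------------
# stacking descriptors


class StackingDescriptor(NamedTuple):
    plane_distance: float   # Angstrom, mean perpendicular centroid separation
    angle: float            # degrees in [0, 90]
    lateral_offset: float   # Angstrom, in-plane centroid separation


def stacking_descriptor(model: StructureModel, residue_a: ResidueKey,
                        residue_b: ResidueKey) -> StackingDescriptor:
    """Plane-to-plane geometry of two rings (no energy model).

    ``plane_distance`` is the mean of the centroid separations projected onto
    either normal, ``angle`` the inter-plane angle folded into [0, 90] degrees,
    ``lateral_offset`` the residual in-plane component of the separation.
    """
    pa = fit_base_plane(model, residue_a)
    pb = fit_base_plane(model, residue_b)
    d = pb.centroid - pa.centroid
    angle = float(np.degrees(np.arccos(
        np.clip(abs(np.dot(pa.normal, pb.normal)), 0.0, 1.0))))
    plane_dist = 0.5 * (abs(np.dot(d, pa.normal)) + abs(np.dot(d, pb.normal)))
    sep2 = float(np.dot(d, d))
    lateral = float(np.sqrt(max(sep2 - plane_dist ** 2, 0.0)))
    return StackingDescriptor(plane_distance=float(plane_dist), angle=angle,
                              lateral_offset=lateral)
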