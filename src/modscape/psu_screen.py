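"""Pseudouridine plausibility from hydrogen-bond geometry.

Pseudouridine (Psi) is the C-glycosidic isomer of uridine: the base is
attached through C5, which frees N1 as an additional ring N-H donor.  In a
model without hydrogens that donor reveals itself geometrically: an O/N
partner within hydrogen-bonding distance of N1 (< 3.2 A) lying in the plane
of the aromatic ring.  The same test applied to the C5 atom of a modelled
uridine (the atom that would occupy the N1 position were the base flipped)
screens for positions that may in fact be pseudouridine.

Partners are classified as water, phosphate oxygen or ribose 2'-hydroxyl --
the three donor/acceptor classes seen for ribosomal pseudouridines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chemistry as chem
from .geometry import HBOND_WINDOW, fit_base_plane, neighbor_search
from .model_io import AtomRecord, ResidueKey, StructureModel

VERDICT_SUPPORTED = "supported"
VERDICT_UNSUPPORTED = "unsupported"
VERDICT_UNRESOLVED = "unresolved-environment"

#: heavy-atom distance below which the extra donor pattern is accepted
DEFAULT_CUTOFF = 3.2
#: maximum perpendicular offset of the partner from the base plane
DEFAULT_COPLANARITY_TOL = 1.0
#: radius probed for any O/N at all; an empty environment means the region is
#: unresolved (no ordered solvent), not that the pattern is absent
DEFAULT_SEARCH_RADIUS = 6.0


@dataclass
class PsuAssessment:
    """Per-residue pseudouridine evidence record."""

    residue_key: ResidueKey
    probe_atom: str                     # "N1" for Psi components, "C5" for U
    best_partner: AtomRecord | None
    distance: float | None
    out_of_plane: float | None          # perpendicular offset from base plane
    partner_class: str                  # water/phosphate/ribose-O2prime/other/none
    verdict: str

    def to_row(self) -> dict:
        pk = self.best_partner
        return {
            "chain": self.residue_key.chain,
            "number": self.residue_key.number,
            "comp": self.residue_key.comp,
            "probe": self.probe_atom,
            "partner": f"{pk.residue_key}/{pk.name}" if pk else "",
            "partner_class": self.partner_class,
            "distance": self.distance if self.distance is not None else float("nan"),
            "out_of_plane": (self.out_of_plane if self.out_of_plane is not None
                             else float("nan")),
            "verdict": self.verdict,
        }


@dataclass
class PsuReport:
    assessments: list[PsuAssessment] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = ["chain", "number", "comp", "probe", "partner", "partner_class",
                "distance", "out_of_plane", "verdict"]
        return pd.DataFrame([a.to_row() for a in self.assessments], columns=cols)

    def to_json_obj(self) -> dict:
        return {"assessments": [a.to_row() for a in self.assessments]}


def _is_psu_component(rec) -> bool:
    return chem.CLS_PSU in rec.tally_classes


def _probe_atom_name(rec) -> str:
    return "N1" if _is_psu_component(rec) else "C5"


def assess_residue(
    model: StructureModel,
    residue_key: ResidueKey,
    cutoff: float = DEFAULT_CUTOFF,
    coplanarity_tol: float = DEFAULT_COPLANARITY_TOL,
    search_radius: float = DEFAULT_SEARCH_RADIUS,
    d_min: float = HBOND_WINDOW[0],
) -> PsuAssessment:
    """Assess the extra-donor hydrogen-bond pattern at one U/Psi residue.

    The probe is N1 for pseudouridine components and C5 for uridine.  The
    best partner is the nearest O/N of *another* residue that lies within the
    coplanarity tolerance of the base plane; the verdict is ``supported`` when
    its distance is strictly below the cutoff, ``unresolved-environment`` when
    no O/N of any other residue exists within the search radius, and
    ``unsupported`` otherwise.
    """
    rec = model.residues[residue_key]
    is_psu = _is_psu_component(rec)
    is_u = residue_key.comp in chem.URIDINE_COMPONENTS
    if not (is_psu or is_u):
        raise ValueError(f"residue {residue_key} is neither a uridine nor a "
                         "pseudouridine component")
    probe_name = _probe_atom_name(rec)
    probe = model.atom(residue_key, probe_name)
    plane = fit_base_plane(model, residue_key)

    candidates = []       # (atom, distance, |out_of_plane|) with d >= d_min
    any_environment = False
    for atom, d in neighbor_search(model, probe.pos, search_radius,
                                   exclude={residue_key}):
        if atom.element not in ("O", "N"):
            continue
        any_environment = True
        if d < d_min:
            continue
        offset = abs(plane.signed_offset(atom.pos))
        candidates.append((atom, d, offset))

    if not any_environment:
        return PsuAssessment(residue_key, probe_name, None, None, None,
                             chem.PARTNER_NONE, VERDICT_UNRESOLVED)

    in_plane = [c for c in candidates if c[2] <= coplanarity_tol]
    pool = in_plane if in_plane else candidates
    if not pool:
        return PsuAssessment(residue_key, probe_name, None, None, None,
                             chem.PARTNER_NONE, VERDICT_UNSUPPORTED)
    atom, d, offset = min(pool, key=lambda c: (c[1], c[0].serial))
    # the rule is strictly d < cutoff; the 1e-9 guard keeps a partner sitting
    # exactly at the cutoff from being accepted through rounding noise
    supported = (bool(in_plane) and d < cutoff - 1e-9
                 and offset <= coplanarity_tol)
    verdict = VERDICT_SUPPORTED if supported else VERDICT_UNSUPPORTED
    partner_class = chem.classify_psu_partner(atom.residue_key.comp, atom.name)
    return PsuAssessment(residue_key, probe_name, atom, d, offset,
                         partner_class, verdict)


def validate_modeled_psu(model: StructureModel, **kwargs) -> PsuReport:
    """Assess every residue modelled as pseudouridine (including combined Psi-m)."""
    report = PsuReport()
    for key, rec in model.residues.items():
        if _is_psu_component(rec):
            report.assessments.append(assess_residue(model, key, **kwargs))
    return report


def screen_uridines(model: StructureModel, **kwargs) -> PsuReport:
    """Screen every standard uridine for a pseudouridine-like acceptor at C5.

    Callers filter ``verdict == "supported"`` as pseudouridine candidates.
    """
    report = PsuReport()
    for key, rec in model.residues.items():
        if key.comp in chem.URIDINE_COMPONENTS and rec.category == chem.CAT_STD_NT:
            if model.find_atom(key, "C5") is None:
                continue
            report.assessments.append(assess_residue(model, key, **kwargs))
    return report
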