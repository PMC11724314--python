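"""Modification census: per-chain / per-class inventory, distances to the
peptidyl-transferase-centre anchor, and comparison against a reference list.

Tally convention: a combined 2'-O-methylpseudouridine position adds one to
*both* the pseudouridine and the ribose-methylation class tallies but counts
once toward total positions -- the only convention under which the per-class
tallies and the total can coexist.  The report keeps both views (positions
and class tallies) so the alternative convention is one switch away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import chemistry as chem
from .model_io import ResidueKey, StructureModel


class AnchorError(ValueError):
    """The configured distance anchor cannot be resolved in the model."""


@dataclass(frozen=True)
class ReferenceRow:
    chain_role: str
    number: int
    expected_class: str


@dataclass
class ReferenceModList:
    """User-supplied catalogue of expected modifications (e.g. from MS data)."""

    rows: list[ReferenceRow]
    source: str = ""

    def __post_init__(self) -> None:
        keys = [(r.chain_role, r.number) for r in self.rows]
        if len(keys) != len(set(keys)):
            raise ValueError("reference list has duplicate (chain, number) keys")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceModList":
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.rstrip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "chain_role":
                continue
            rows.append(ReferenceRow(fields[0], int(fields[1]), fields[2]))
        return cls(rows, source=str(path))


@dataclass
class CensusReport:
    """Inventory of modified residues with totals, tallies and reference checks."""

    rows: list[dict] = field(default_factory=list)   # per modified residue
    per_chain_class: dict[tuple[str, str], int] = field(default_factory=dict)
    class_tallies: dict[str, int] = field(default_factory=dict)
    category_counts: dict[str, int] = field(default_factory=dict)
    total_rrna_modifications: int = 0
    total_protein_modifications: int = 0
    confirmed: list[dict] = field(default_factory=list)
    reported_but_absent: list[dict] = field(default_factory=list)
    observed_but_unreported: list[dict] = field(default_factory=list)
    unresolved_reference: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = ["chain", "chain_role", "number", "comp", "class",
                "distance_to_ptc"]
        return pd.DataFrame(self.rows, columns=cols)

    def to_json_obj(self) -> dict:
        return {
            "total_rrna_modifications": self.total_rrna_modifications,
            "total_protein_modifications": self.total_protein_modifications,
            "class_tallies": dict(sorted(self.class_tallies.items())),
            "category_counts": dict(sorted(self.category_counts.items())),
            "per_chain_class": {f"{c}|{cls}": n for (c, cls), n
                                in sorted(self.per_chain_class.items())},
            "residues": self.rows,
            "reference_comparison": {
                "confirmed": self.confirmed,
                "reported_but_absent": self.reported_but_absent,
                "observed_but_unreported": self.observed_but_unreported,
                "unresolved": self.unresolved_reference,
            },
        }


def distance_to_ptc(model: StructureModel, residue_key: ResidueKey,
                    anchor: set[ResidueKey] | list[ResidueKey]) -> float:
    """Minimum heavy-atom distance from a residue to any anchor residue."""
    anchor = list(anchor)
    for key in anchor:
        if key not in model.residues:
            raise AnchorError(f"anchor residue {key} not present in the model")
    res_pts = np.stack([a.pos for a in model.atoms_of(residue_key)
                        if a.element != "H"])
    anchor_pts = np.stack([a.pos for k in anchor for a in model.atoms_of(k)
                           if a.element != "H"])
    return float(cdist(res_pts, anchor_pts).min())


def resolve_anchor(model: StructureModel, chain_role: str, number: int
                   ) -> set[ResidueKey]:
    """Anchor residue set from a (chain role, author number) specification."""
    chains = set(model.chains_with_role(chain_role))
    if not chains:           # fall back: the role may name a chain id directly
        chains = {chain_role} if chain_role in model.chains() else set()
    keys = {k for k in model.residues if k.chain in chains and k.number == number}
    if not keys:
        raise AnchorError(f"anchor {chain_role}:{number} not found "
                          f"(roles known: {sorted(set(model.chain_roles.values()))})")
    return keys


def census(model: StructureModel,
           ptc_anchor: set[ResidueKey] | None = None) -> CensusReport:
    """Inventory every modified residue, with the combined-class tally rule.

    Row order is deterministic: (chain, author number, insertion code).
    ``ptc_anchor`` (a resolved residue-key set) enables the distance column.
    """
    report = CensusReport()
    tallies: dict[str, int] = {}
    modified = []
    for key, rec in sorted(model.residues.items(),
                           key=lambda kv: (kv[0].chain, kv[0].number, kv[0].icode)):
        report.category_counts[rec.category] = \
            report.category_counts.get(rec.category, 0) + 1
        if rec.category not in (chem.CAT_MOD_NT, chem.CAT_MOD_AA):
            continue
        modified.append((key, rec))
        for cls in sorted(rec.tally_classes):
            tallies[cls] = tallies.get(cls, 0) + 1
            pc = (key.chain, cls)
            report.per_chain_class[pc] = report.per_chain_class.get(pc, 0) + 1
        if rec.category == chem.CAT_MOD_NT:
            report.total_rrna_modifications += 1
        else:
            report.total_protein_modifications += 1
        dist = (distance_to_ptc(model, key, ptc_anchor)
                if ptc_anchor else float("nan"))
        report.rows.append({
            "chain": key.chain,
            "chain_role": model.role_of(key.chain),
            "number": key.number,
            "comp": key.comp,
            "class": rec.modification_class,
            "distance_to_ptc": dist,
        })
    report.class_tallies = tallies
    return report


def compare_reference(report: CensusReport, ref: ReferenceModList,
                      model: StructureModel) -> CensusReport:
    """Fill the reference-comparison lists of a census report.

    * ``confirmed`` -- reference position modelled with a matching class;
    * ``reported_but_absent`` -- position modelled but unmodified or with a
      different class;
    * ``unresolved`` -- position absent from the model altogether (unbuilt
      region);
    * ``observed_but_unreported`` -- modelled modification missing from the
      reference.
    """
    role_to_chains: dict[str, list[str]] = {}
    for chain in model.chains():
        role_to_chains.setdefault(model.role_of(chain), []).append(chain)

    unmatched = sorted({r.chain_role for r in ref.rows
                        if r.chain_role not in role_to_chains
                        and r.chain_role not in model.chains()})
    if unmatched:
        raise ValueError("reference chain labels not mappable to model chains: "
                         + ", ".join(unmatched))

    observed: dict[tuple[str, int], tuple[ResidueKey, frozenset[str]]] = {}
    for row in report.rows:
        key = ResidueKey(row["chain"], row["number"], "", row["comp"])
        rec_key = next(k for k in model.residues
                       if k.chain == row["chain"] and k.number == row["number"])
        observed[(row["chain"], row["number"])] = (
            rec_key, model.residues[rec_key].tally_classes)

    matched_positions = set()
    report.confirmed, report.reported_but_absent = [], []
    report.unresolved_reference, report.observed_but_unreported = [], []
    for r in ref.rows:
        chains = role_to_chains.get(r.chain_role, [r.chain_role])
        entry = {"chain_role": r.chain_role, "number": r.number,
                 "expected_class": r.expected_class}
        model_keys = [k for k in model.residues
                      if k.chain in chains and k.number == r.number]
        if not model_keys:
            report.unresolved_reference.append(entry)
            continue
        hit = None
        for k in model_keys:
            tset = model.residues[k].tally_classes
            if r.expected_class in tset or r.expected_class == \
                    model.residues[k].modification_class:
                hit = k
                break
        if hit is not None:
            report.confirmed.append({**entry, "comp": hit.comp})
            matched_positions.add((hit.chain, hit.number))
        else:
            report.reported_but_absent.append(
                {**entry, "modelled_as": model_keys[0].comp})
    for (chain, number), (key, _) in observed.items():
        if (chain, number) not in matched_positions:
            report.observed_but_unreported.append({
                "chain": chain, "chain_role": model.role_of(chain),
                "number": number, "comp": key.comp,
                "class": model.residues[key].modification_class,
            })
    return report
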