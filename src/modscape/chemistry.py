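"""Atom-name and component tables used across the package.

All tables are plain module-level data so they can be inspected and, where a
deposited entry deviates, monkey-patched or overridden through the public
configuration hooks.  Atom names follow the wwPDB convention with prime
characters (O2', OP1, ...); asterisk variants found in legacy PDB files are
normalised on load.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# residue categories (the partition every residue falls into)

CAT_STD_NT = "standard-ribonucleotide"
CAT_MOD_NT = "modified-ribonucleotide"
CAT_STD_AA = "standard-amino-acid"
CAT_MOD_AA = "modified-amino-acid"
CAT_METAL = "metal"
CAT_WATER = "water"
CAT_POLYAMINE = "polyamine"
CAT_OTHER = "other-ligand"

CATEGORIES = (
    CAT_STD_NT,
    CAT_MOD_NT,
    CAT_STD_AA,
    CAT_MOD_AA,
    CAT_METAL,
    CAT_WATER,
    CAT_POLYAMINE,
    CAT_OTHER,
)

# ---------------------------------------------------------------------------
# modification classes; "combined" positions (2'-O-methylpseudouridine) tally
# in both the pseudouridine and the ribose-methylation class counts.

CLS_PSU = "pseudouridine"
CLS_NM = "ribose-2prime-O-methyl"
CLS_COMBINED = "combined"
CLS_M1A = "m1A"
CLS_M4C = "m4C"
CLS_M5C = "m5C"
CLS_M6A = "m6A"
CLS_M3U = "m3U"
CLS_HIS_BOX = "beta-hydroxy-histidine"
CLS_HIS_TAU = "tau-N-methyl-histidine"
CLS_LYS_EPS = "epsilon-N-methyl-lysine"

MODIFICATION_CLASSES = (
    CLS_PSU, CLS_NM, CLS_COMBINED, CLS_M1A, CLS_M4C, CLS_M5C, CLS_M6A,
    CLS_M3U, CLS_HIS_BOX, CLS_HIS_TAU, CLS_LYS_EPS,
)

BASE_MOD_CLASSES = frozenset({CLS_M1A, CLS_M4C, CLS_M5C, CLS_M6A, CLS_M3U})

#: which class tallies a modification class contributes to
CLASS_TALLIES: dict[str, frozenset[str]] = {
    cls: frozenset({cls}) for cls in MODIFICATION_CLASSES if cls != CLS_COMBINED
}
CLASS_TALLIES[CLS_COMBINED] = frozenset({CLS_PSU, CLS_NM})


def tally_classes(modification_class: str | None) -> frozenset[str]:
    """Class tallies a residue with the given modification class counts in."""
    if modification_class is None:
        return frozenset()
    return CLASS_TALLIES.get(modification_class, frozenset({modification_class}))


# ---------------------------------------------------------------------------
# standard components

STANDARD_RIBONUCLEOTIDES = frozenset({"A", "C", "G", "U", "N"})
STANDARD_DEOXYNUCLEOTIDES = frozenset({"DA", "DC", "DG", "DT", "DN"})
STANDARD_AMINO_ACIDS = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
})
WATER_COMPONENTS = frozenset({"HOH", "DOD", "WAT"})
URIDINE_COMPONENTS = frozenset({"U"})

#: metal component id -> display label used in classification reports
METAL_COMPONENTS: dict[str, str] = {
    "MG": "Mg", "K": "K", "NA": "Na", "ZN": "Zn", "MN": "Mn", "CA": "Ca",
    "FE": "Fe", "NI": "Ni", "CO": "Co", "CU": "Cu",
}
METAL_ELEMENTS = frozenset({"Mg", "K", "Na", "Zn", "Mn", "Ca", "Fe", "Ni", "Co", "Cu"})

POLYAMINE_SPECIES = ("PUT", "SPD", "SPM")

# ---------------------------------------------------------------------------
# ring-atom tables for plane fitting

PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
PURINE_RING = PYRIMIDINE_RING + ("N7", "C8", "N9")

#: aromatic side-chain rings of amino acids (plane fitting / stacking)
SIDECHAIN_RINGS: dict[str, tuple[str, ...]] = {
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}


#: modified amino acids sharing the parent side-chain ring
RING_ALIASES = {"OHI": "HIS", "HIC": "HIS", "MHS": "HIS", "PTR": "TYR"}


def ring_atom_names(comp_id: str, atom_names) -> tuple[str, ...]:
    """Resolve the ring-atom name table for a residue.

    Nucleotides use the purine table when an N9 atom is present, otherwise the
    pyrimidine table; amino acids fall back to the side-chain ring table.
    """
    names = set(atom_names)
    comp_id = RING_ALIASES.get(comp_id, comp_id)
    if comp_id in SIDECHAIN_RINGS and "N1" not in names:
        return SIDECHAIN_RINGS[comp_id]
    if "N9" in names:
        return PURINE_RING
    if "N1" in names or "C5" in names:
        return PYRIMIDINE_RING
    if comp_id in SIDECHAIN_RINGS:
        return SIDECHAIN_RINGS[comp_id]
    return ()


# ---------------------------------------------------------------------------
# hydrogen-bond partner typing (heavy-atom names)

PHOSPHATE_OXYGENS = frozenset({"OP1", "OP2", "OP3", "O3'", "O5'"})
RIBOSE_O2PRIME = "O2'"
RIBOSE_OXYGENS = frozenset({"O2'", "O4'"})

PARTNER_WATER = "water"
PARTNER_PHOSPHATE = "phosphate"
PARTNER_RIBOSE_O2 = "ribose-O2prime"
PARTNER_OTHER = "other"
PARTNER_NONE = "none"


def classify_psu_partner(comp_id: str, atom_name: str) -> str:
    """Partner class for the pseudouridine screen: water / phosphate / ribose O2'."""
    if comp_id in WATER_COMPONENTS:
        return PARTNER_WATER
    if atom_name in PHOSPHATE_OXYGENS:
        return PARTNER_PHOSPHATE
    if atom_name == RIBOSE_O2PRIME:
        return PARTNER_RIBOSE_O2
    return PARTNER_OTHER
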