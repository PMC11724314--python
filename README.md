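# modscape

Geometric annotation of the chemical landscape of large ribonucleoprotein
atomic models.

Atomic models built into ~1.8 Å cryo-EM maps of ribosomal subunits carry a
rich chemical inventory beyond the polymer itself: over a hundred modified
ribonucleotides (pseudouridines, 2′-O-methylations, base methylations),
modified amino acids (β-hydroxy- and methyl-histidines, methyl-lysines),
Mg²⁺ and K⁺ ions, polyamines (putrescine, spermidine, spermine) and
thousands of ordered waters.  Reading that inventory out of a model is a
set of geometric procedures, and `modscape` implements them as a tested,
reusable pipeline for structural biologists who build or re-analyse such
models:

* **Census** — classify every residue through an editable component map and
  inventory modifications per chain and class, with distances to a
  peptidyl-transferase-centre anchor and comparison against a reference
  modification list (confirmed / reported-but-absent / unreported /
  unresolved).
* **Pseudouridine screen** — pseudouridine's C-glycosidic bond frees N1 as
  an extra ring N–H donor; in a hydrogen-free model that donor shows as an
  O/N partner (water, phosphate oxygen, or ribose 2′-OH) at *d* < 3.2 Å
  from N1, coplanar with the base.  The screen verifies the pattern for
  modelled Ψ and probes the C5 position of modelled uridines for
  overlooked candidates.
* **Ion discrimination** — Mg²⁺ forms octahedral [Mg(H₂O)ₙX₆₋ₙ] shells
  with 1.8–2.4 Å coordination bonds, K⁺ ~5-fold shells at 2.8–3.2 Å,
  waters a few partners at ordinary hydrogen-bond separations; the
  classifier labels every single-atom centre Mg / K / water / unassigned
  from shell size, distance windows and octahedricity, with a
  deposited-vs-geometry confusion table.
* **Polyamines and networks** — amine contact maps (phosphate anchoring,
  water bridges) and breadth-first tracing of water-mediated hydrogen-bond
  networks from seed atoms, exportable as edge lists and GraphML; base
  stacking as plane-geometry descriptors.
* **Synthetic fixtures** — a deterministic generator of planted
  coordination sites, pseudouridine geometries and toy assemblies with
  ground-truth manifests, so the whole pipeline is testable without
  downloading anything.

Hydrogen bonds are inferred from heavy-atom separation (2.4–3.5 Å default
window) since hydrogens are absent from the use case.  All list orderings
are deterministic and the spatial primitives are exact — tested for set
equality against brute-force oracles.  See `docs/methods.md` for the full
rule set and its rationale.

## Worked example

Generate a toy assembly with a known modification inventory, then annotate
it:

```sh
modscape fixtures --kind toy --seed 3 --out toy.cif \
  --spec-json '{"modifications": {"pseudouridine": 2, "ribose-2prime-O-methyl": 3,
                "combined": 1, "m5C": 1}, "polyamines": {"SPD": 2}}'
modscape census toy.cif --chain-role A=28S --out toy_out
```

which logs

```
census: 7 rRNA + 0 protein modifications
```

and writes `toy_out/census.tsv`, beginning:

```
chain	chain_role	number	comp	class	distance_to_ptc
A	28S	101	PSM	combined	
A	28S	102	5MC	m5C	
A	28S	103	PSU	pseudouridine	
```

(the distance column fills in when the model contains the configured
anchor residue).  Seven positions, but the class tallies count eight
entries: the PSM residue (2′-O-methylpseudouridine) is one position
contributing to *both* the pseudouridine tally (2 + 1 = 3) and the
ribose-methylation tally (3 + 1 = 4).  The same calls from Python:

```python
import modscape as ms
model = ms.load_structure("toy.cif", chain_roles={"A": "28S"})
ms.census(model).class_tallies
# {'pseudouridine': 3, 'ribose-2prime-O-methyl': 4, 'm5C': 1}
ms.validate_modeled_psu(model)   # per-residue Ψ evidence records
ms.classify_all(model)           # Mg/K/water labels with rationales
```

Other subcommands: `annotate` (full bundle plus run metadata),
`classify-ions --cross-validate`, `validate-psu`, `screen-uridines`,
`polyamines`, `network --seed-atom CHAIN:NUMBER:ATOM`, and `show-config`
(prints every default so a reproduction is self-documenting).  A deposited
mmCIF entry is annotated the same way: `modscape annotate 8qyx.cif`.

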