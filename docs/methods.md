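# Methods

`modscape` reads annotations out of an atomic model of a large
ribonucleoprotein assembly — the kind of model built into a ~1.8 Å cryo-EM
map of a 60S ribosomal subunit — using geometry alone.  No map, no density
evidence, no energies: everything below is a statement about heavy-atom
coordinates.  This note records the procedures, the defaults and why they
are what they are, what the synthetic data does and does not emulate, and
the numerical choices that make results reproducible to the byte.

## Model representation

Structures are parsed with gemmi into a flat atom list plus per-residue
records keyed by **author numbering** `(chain, number, icode, component id)`
— the numbering the literature cites (positions such as 28S A4397); the
sequential label index is kept alongside.  Alternate conformations are
collapsed to the highest-occupancy conformer (ties broken alphabetically by
altloc id) so all geometry is single-conformer and deterministic.
Zero-occupancy atoms are retained and flagged; they participate in geometry
by default.

Every residue is assigned one of eight categories — standard/modified
ribonucleotide, standard/modified amino acid, metal, water, polyamine,
other ligand — through an editable TSV component map
(`modscape/data/component_map.tsv`).  The map ships with defaults for
pseudouridine (PSU), the 2′-O-methyl nucleotides (OMC/OMG/OMU/A2M), the base
methylations m¹A/m⁴C/m⁵C/m⁶A/m³U, β-hydroxy-histidine, τ-N-methyl-histidine,
ε-N-methyl-lysine, the polyamines SPM/SPD/PUT, Mg/K/Na/Zn and water.  Ids
for the rarer modifications are marked as candidates in the file comments
and must be verified against the wwPDB chemical component dictionary for the
specific entry being analysed; shipping them as data rather than constants
keeps that audit trivial.  A *combined* class (2′-O-methylpseudouridine)
contributes one position to the inventory but one count to **each** of the
pseudouridine and ribose-methylation tallies — the only convention under
which per-class tallies and a printed total can coexist; the census report
keeps positions and tallies separate so the alternative convention is a
one-line change.

Unmapped components of polymer entities fall back to a standard nucleotide
or amino-acid category from their atom content; they never become "other
ligand".  Chain roles (28S/5.8S/5S/protein names) come from an explicit map
in configuration or fixture manifests; for mmCIF input a heuristic matches
`_entity.pdbx_description` text when no map is given.

## Hydrogen bonds without hydrogens

Hydrogens are absent from the use case, so hydrogen bonds are inferred from
donor/acceptor **heavy-atom** separation alone: O/N partners within
2.4–3.5 Å (closed interval).  Pairs within the same residue closer than the
covalent cutoff of 1.8 Å are bonds, never hydrogen bonds.  Distance
comparisons use closed intervals throughout and ties in any ordering are
broken by atom serial, so every list the package returns is exactly
reproducible and checkable against an all-pairs brute-force scan — the
neighbour search (a scipy cKD-tree with an exact closed-interval
post-filter) is tested for set equality against that oracle, not for
approximate agreement.

## Pseudouridine plausibility

Pseudouridine is the C-glycosidic isomer of uridine; its freed N1–H is an
extra ring donor, and in a hydrogen-free model that donor shows up as an O/N
partner (water, a neighbouring phosphate oxygen, or a ribose 2′-OH) that is

1. within hydrogen-bonding distance — strictly **< 3.2 Å** — of N1, and
2. **coplanar** with the aromatic ring.

For residues modelled as uridine the same test is applied at C5, the atom
that would occupy the N1 position if the base were C-linked; a hit marks the
position as a pseudouridine candidate.

Defaults and their reasoning:

* **cutoff 3.2 Å, strict** — the identification rule; a 1 × 10⁻⁹ Å guard
  keeps a partner planted exactly at the cutoff from being accepted through
  floating-point rounding.
* **coplanarity tolerance 1.0 Å** perpendicular offset from the
  least-squares base plane.  No numeric tolerance accompanies the published
  "same plane" criterion, so the package states one, reports the measured
  offset per residue, and exposes the threshold in configuration so
  strictness is auditable.
* **search radius 6 Å** for the *unresolved-environment* verdict: a residue
  with no ordered O/N anywhere nearby (flexible regions without modelled
  solvent) is distinguished from one whose environment is resolved but
  lacks the pattern.  Only the latter counts as evidence against
  modification.
* The residue's **own atoms are never partners** — its ring carbonyls,
  ribose and phosphate say nothing about an extra donor — which is slightly
  stronger than the generic covalent-exclusion rule and deliberate.
* Partners are classed by atom name: water O; OP1/OP2/O3′/O5′ = phosphate;
  O2′ = ribose; anything else "other".

The verdict logic: *supported* needs an in-plane partner below the cutoff;
*unresolved-environment* needs an empty 6 Å environment; everything else is
*unsupported*, with the nearest partner and its out-of-plane offset
reported so the failure mode is visible.

## Metal and water discrimination

Mg²⁺, K⁺ and water oxygens are indistinguishable by scattering at these
resolutions but not by coordination chemistry: Mg²⁺ forms octahedral
[Mg(H₂O)ₙX₆₋ₙ] complexes with coordination bonds of 1.8–2.4 Å — shorter
than any hydrogen bond; K⁺, with its larger radius, shows ~5-fold shells at
2.8–3.2 Å; waters have a handful of partners at ordinary hydrogen-bond
separations.  The classifier extracts the O/N shell within 3.5 Å and
applies, in order:

* **Mg** — ≥ 4 ligands inside 1.8–2.4 Å *and* near-octahedral geometry:
  RMS deviation of the inner-shell L–M–L angles from the nearest ideal
  90°/180° of at most 20°.  The angle score uses only ligands inside the
  Mg window so distal second-shell oxygens cannot corrupt it.  Requiring 4
  rather than 6 ligands tolerates partially resolved surface sites.
* **K** — ≥ 4 ligands inside 2.55–3.35 Å and no contact short of 2.55 Å.
  The decision window is wider than the observed 2.8–3.2 Å range because an
  observed range is not a decision boundary; a strict mode reproduces the
  printed window exactly.  The minimum of 4 ligands (not 3) is what
  separates a genuine high-coordination K⁺ shell from a well-ordered water
  with two or three partners at similar distances.
* **water** — at least one partner and all partners within 2.55–3.5 Å.
  The lower bound sits at 2.55 Å rather than the generic hydrogen-bond
  minimum of 2.4 Å: contacts in 2.4–2.55 Å are metal-ambiguous, and
  vetoing them preserves the physically required ordering of labels when a
  shell is scaled outward — Mg → unassigned → K → water, never backward.
* **unassigned** otherwise, always with a rationale string.

If both metal rules fire (possible under customised windows) the label whose
window midpoint is nearest the mean ligand distance wins and the conflict is
recorded.  Deposited metals outside the Mg/K label set (Na⁺, Zn²⁺, …) keep
their deposited label and are flagged rather than re-assigned.  The
cross-validation table (deposited × geometry-assigned label) quantifies
agreement on a deposited model; note that a water coordinated to a metal is
deliberately *not* labelled water (its shortest contact is metal-like), so
first-shell waters land in "unassigned" — the table makes that visible
rather than hiding it.

## Polyamine contacts and network tracing

Polyamine (PUT/SPD/SPM) contact maps list every O/N partner of every amine
nitrogen within the hydrogen-bond window, classed as phosphate-O / water /
base / ribose / protein / other, plus all water bridges
(amine → water → second shell, both legs in-window).  Each bridge leg
re-validates independently through the generic hydrogen-bond detector.

Network tracing is a breadth-first expansion from seed atoms over
heavy-atom hydrogen-bond edges, crossing waters freely; when a metal is
encountered its coordination bonds (1.8–3.35 Å) become edges too.  Carbon
atoms terminate expansion — they are neither donors nor acceptors — which
is what makes the result a *water-mediated* network.  After expansion every
in-window edge between discovered nodes is closed, so the edge set depends
only on the node set, and the node set is independent of seed order and
grows monotonically with depth.  The default depth of 4 and window of
2.4–3.5 Å are reported alongside any network, since published network
renderings do not state theirs.

Stacking is reported as pure geometry — mean plane separation, inter-plane
angle folded into [0°, 90°], lateral centroid offset — never as an energy
or a "stabilisation"; interpretation stays with the caller.

## Census and reference comparison

The census inventories every modified residue per chain and class (ordered
by chain, then author number), applies the combined-class tally rule, and
optionally measures each modification's **minimum heavy-atom distance** to a
peptidyl-transferase-centre anchor (default 28S A4397).  Minimum heavy-atom
distance, not centroid distance, because "about N Å" statements in the
literature are atom-pair-agnostic and the minimum is deterministic.

Comparison against a user-supplied reference list (TSV: chain role, author
number, expected class) partitions positions into *confirmed*,
*reported-but-absent* (position modelled, modification not),
*observed-but-unreported*, and *unresolved* (position not modelled at all —
unbuilt regions must not be counted as evidence of absence).  The first
three lists partition the observed and resolvable reference keys exactly;
the property is asserted in the tests.

## Synthetic data: what it emulates, what it does not

The fixture generator plants, at grid points separated by ≥ 12 Å so sites
cannot interact:

* jittered octahedral Mg sites (ligand distances uniform in 1.8–2.4 Å, a
  random subset of ligands phosphate oxygens, the rest waters),
* pentagonal K sites (2.8–3.2 Å),
* waters with 1–3 partners (2.6–3.4 Å, mutually ≥ 2.56 Å),
* the four canonical pseudouridine geometries (in-plane partner at 3.0 Å;
  partner at 3.4 Å; in-window partner 2.0 Å out of plane; bare ring), with
  partner types cycled through water/phosphate/O2′,
* toy multi-chain assemblies with a declared count of modified residues per
  class and polyamines anchored to phosphates at 2.9 Å with a planted
  water bridge (2.8 Å legs).

Positional jitter is Gaussian per coordinate; a site whose jittered
distances leave the planted window is re-drawn (bounded retries), never
emitted out of spec — so classification degradation with jitter comes from
shell *geometry*, not from distance-window violations.  Coordinates are
drawn from a named, seeded generator; regeneration from the same (spec,
seed) is byte-identical, the seed is written into the manifest, and the
manifest predicts every downstream result (labels, verdicts, tallies,
contact counts) exactly.

What the fixtures do **not** emulate: crowding (real first-shell waters sit
in dense environments, not isolation), partial occupancy and correlated
disorder, distorted rings, shared ligands between adjacent sites, and any
density-level ambiguity.  Passing tests therefore demonstrate that the
rules are implemented exactly and behave correctly on unambiguous geometry;
they do not measure real-data accuracy, where the crowded environment makes
the classification genuinely harder.  Problem sizes used by the test suite
and the acceptance script — 300-site ion fields (3 replicates per jitter
level), 2000-atom oracle clouds, 60-water network graphs, toy assemblies of
a dozen residues — keep a full run in seconds while exercising every rule
boundary.

## Known limitations

* Heavy-atom distance criteria only: no donor–H–acceptor angles, no
  chemistry-aware donor/acceptor typing beyond the element filter and the
  name tables.
* First-shell waters of metals classify as unassigned (see above).
* K⁺ sites with fewer than four resolved ligands are not recoverable by the
  default rules; lowering `k_min_ligands` trades that against water/K
  confusion.
* The census trusts the component map; a wrong component id propagates
  (which is why the map is shipped as auditable data).
* Occupancy- and density-based evidence (map contouring, occupancy
  refinement) is out of scope by design.
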