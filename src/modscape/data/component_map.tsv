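# Default component map: component_id -> (category, modification_class).
# Edit or extend to match the entry being analysed.
#
# Modified-nucleotide / modified-amino-acid ids marked "verify" are best-effort
# candidates and must be checked against the wwPDB chemical component dictionary
# (CCD) for the specific deposited entry before release: ids for rare
# modifications are easy to get wrong.
#
# category is one of: standard-ribonucleotide, modified-ribonucleotide,
# standard-amino-acid, modified-amino-acid, metal, water, polyamine,
# other-ligand.  modification_class "combined" means the residue contributes to
# both the pseudouridine and the ribose-2prime-O-methyl tallies (one position,
# two class counts).
component_id	category	modification_class
PSU	modified-ribonucleotide	pseudouridine
OMU	modified-ribonucleotide	ribose-2prime-O-methyl
OMC	modified-ribonucleotide	ribose-2prime-O-methyl
OMG	modified-ribonucleotide	ribose-2prime-O-methyl
A2M	modified-ribonucleotide	ribose-2prime-O-methyl
# PSM: 2'-O-methylpseudouridine (combined class) -- candidate id, verify;
# some entries encode this position as PSU plus a separate methyl annotation.
PSM	modified-ribonucleotide	combined
1MA	modified-ribonucleotide	m1A
# M4C / 4OC: N4-methylcytidine -- candidate ids, verify.
M4C	modified-ribonucleotide	m4C
4OC	modified-ribonucleotide	m4C
5MC	modified-ribonucleotide	m5C
# 6MZ: N6-methyladenosine (ribo) -- candidate id, verify.
6MZ	modified-ribonucleotide	m6A
UR3	modified-ribonucleotide	m3U
# OHI: (2S,3S) beta-hydroxy-histidine -- candidate id, verify.
OHI	modified-amino-acid	beta-hydroxy-histidine
# HIC / MHS: tau-N-methyl-histidine (N-epsilon-2 methyl) -- candidate ids, verify.
HIC	modified-amino-acid	tau-N-methyl-histidine
MHS	modified-amino-acid	tau-N-methyl-histidine
MLZ	modified-amino-acid	epsilon-N-methyl-lysine
SPM	polyamine
SPD	polyamine
PUT	polyamine
MG	metal
K	metal
NA	metal
ZN	metal
MN	metal
HOH	water
DOD	water
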