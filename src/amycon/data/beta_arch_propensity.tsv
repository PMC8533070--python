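# Synthetic composite beta-arch/aggregation propensity scale, 0..1.
# Constructed for the bundled simplified arch scanner: high values for
# beta-branched hydrophobics, aromatics and the amide residues (Q/N) that
# favour cross-beta stacking; low values for charged residues and proline.
# Informed by published beta-sheet/aggregation propensity orderings but not
# copied from any single published scale.
A	0.55
C	0.75
D	0.15
E	0.12
F	0.90
G	0.40
H	0.50
I	0.95
K	0.20
L	0.85
M	0.75
N	0.80
P	0.08
Q	0.80
R	0.25
S	0.60
T	0.65
V	0.90
W	0.80
Y	0.85
X	0.5925
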