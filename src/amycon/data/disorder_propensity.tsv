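# Synthetic disorder propensity scale, 0..1 (high = disorder-promoting).
# Ordering follows the consensus disorder-promoting ranking (P, E, S, Q, K,
# G, R strongly disorder-promoting; W, F, I, Y, V, L order-promoting);
# values are this package's own, for the bundled simplified disorder scorer.
A	0.60
C	0.30
D	0.70
E	0.90
F	0.15
G	0.75
H	0.45
I	0.20
K	0.80
L	0.22
M	0.35
N	0.60
P	0.95
Q	0.80
R	0.70
S	0.85
T	0.55
V	0.25
W	0.10
Y	0.18
X	0.52
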