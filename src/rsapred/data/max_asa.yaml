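# Maximum accessible surface area per residue type (A^2), from extended
# Ala-X-Ala tri-peptide conformations (Ahmad, Gromiha & Sarai 2003).
# Used to normalise DSSP ACC values to relative solvent accessibility.
# Replaceable: point the pipeline at any 20-entry table with the same keys.
A: 110.2
R: 229.0
N: 146.4
D: 144.1
C: 140.4
Q: 178.6
E: 174.7
G: 78.7
H: 181.9
I: 185.0
L: 183.1
K: 205.7
M: 200.1
F: 200.7
P: 141.9
S: 117.2
T: 138.7
W: 240.5
Y: 213.7
V: 153.7
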