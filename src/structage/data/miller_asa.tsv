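# Reference maximum solvent-accessible surface areas (Angstrom^2) for residue X
# in an extended Gly-X-Gly tripeptide, after Miller, Janin, Lesk & Chothia (1987).
# Used to normalize DSSP ACC values into relative solvent accessibility (RSA).
aa	asa_ref
A	113.0
R	241.0
N	158.0
D	151.0
C	140.0
Q	189.0
E	183.0
G	85.0
H	194.0
I	182.0
L	180.0
K	211.0
M	204.0
F	218.0
P	143.0
S	122.0
T	146.0
W	259.0
Y	229.0
V	160.0
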