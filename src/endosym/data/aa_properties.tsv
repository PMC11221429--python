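# Per-residue property table, v1.
# hydrophobicity: normalized hydrophobicity index at pH 7 (Monera et al. 1995,
#   J. Pept. Sci. 1:319-329), the scale tabulated on common amino-acid
#   reference charts; dimensionless, Gly = 0, Phe = 100.
# amino_pka / carboxyl_pka: pKa of the free amino acid's alpha-amino and
#   alpha-carboxyl groups (standard biochemistry reference values, as in
#   Lehninger and commercial reference charts); pH units.
residue	hydrophobicity	amino_pka	carboxyl_pka
A	41	9.69	2.34
C	49	10.28	1.96
D	-55	9.60	1.88
E	-31	9.67	2.19
F	100	9.13	1.83
G	0	9.60	2.34
H	8	9.17	1.82
I	99	9.60	2.36
K	-23	8.95	2.18
L	97	9.60	2.36
M	74	9.21	2.28
N	-28	8.80	2.02
P	-46	10.60	1.99
Q	-10	9.13	2.17
R	-14	9.04	2.17
S	-5	9.15	2.21
T	13	9.10	2.09
V	76	9.62	2.32
W	97	9.39	2.83
Y	63	9.11	2.20
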