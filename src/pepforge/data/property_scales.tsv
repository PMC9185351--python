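# Per-residue physicochemical scales used by the improved pseudo amino acid composition encoder.
# One row per canonical residue; values are raw (un-standardized) published scale values.
# hydrophobicity: Kyte-Doolittle (1982) hydropathy index.
# hydrophilicity: Hopp-Woods (1981) hydrophilicity.
# charge: net side-chain charge at pH 7 (His partially protonated, +0.1).
# flexibility: Bhaskaran-Ponnuswamy (1988) average flexibility index.
# irreplaceability: affine inverse of Dayhoff relative mutability (134 - mutability); affine choice is
#   irrelevant downstream because every scale is standardized across the 20 residues before use.
# solvent_accessible_surface_area: Tien et al. (2013) theoretical maximum ASA, A^2.
# polarity: Grantham (1974) polarity.
# polarizability: Charton-Charton (1982) polarizability parameter.
# rigidity: side-chain conformational rigidity, 1/(1 + rotatable side-chain bonds); proline elevated
#   for backbone ring closure.
residue	hydrophobicity	hydrophilicity	charge	flexibility	irreplaceability	solvent_accessible_surface_area	polarity	polarizability	rigidity
A	1.8	-0.5	0.0	0.357	34	129	8.1	0.046	1.0
C	2.5	-1.0	0.0	0.346	114	167	5.5	0.128	0.5
D	-3.5	3.0	-1.0	0.511	28	193	13.0	0.105	0.333
E	-3.5	3.0	-1.0	0.497	32	223	12.3	0.151	0.25
F	2.8	-2.5	0.0	0.314	93	240	5.2	0.29	0.333
G	-0.4	0.0	0.0	0.544	85	104	9.0	0.0	1.0
H	-3.2	-0.5	0.1	0.323	68	224	10.4	0.23	0.333
I	4.5	-1.8	0.0	0.462	38	197	5.2	0.186	0.333
K	-3.9	3.0	1.0	0.466	78	236	11.3	0.219	0.2
L	3.8	-1.8	0.0	0.365	94	201	4.9	0.186	0.333
M	1.9	-1.3	0.0	0.295	40	224	5.7	0.221	0.25
N	-3.5	0.2	0.0	0.463	0	195	11.6	0.134	0.333
P	-1.6	0.0	0.0	0.509	78	159	8.0	0.131	1.5
Q	-3.5	0.2	0.0	0.493	41	225	10.5	0.18	0.25
R	-4.5	3.0	1.0	0.529	69	274	10.5	0.291	0.167
S	-0.8	0.3	0.0	0.507	14	155	9.2	0.062	0.5
T	-0.7	-0.4	0.0	0.444	37	172	8.6	0.108	0.5
V	4.2	-1.5	0.0	0.386	60	174	5.9	0.14	0.5
W	-0.9	-3.4	0.0	0.305	116	285	5.4	0.409	0.333
Y	-1.3	-2.3	0.0	0.42	93	263	6.2	0.298	0.333
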