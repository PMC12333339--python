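# bitterspace core monomer library v1.0
id	name	smiles	attachments	natural	one_letter	terminal
A	Alanine	N[C@@H](C)C(=O)O	R1:0:H;R2:3:OH	1	A	0
R	Arginine	N[C@@H](CCCNC(=N)N)C(=O)O	R1:0:H;R2:9:OH	1	R	0
N	Asparagine	N[C@@H](CC(N)=O)C(=O)O	R1:0:H;R2:6:OH	1	N	0
D	Aspartic acid	N[C@@H](CC(=O)O)C(=O)O	R1:0:H;R2:6:OH;R3:3:OH	1	D	0
C	Cysteine	N[C@@H](CS)C(=O)O	R1:0:H;R2:4:OH	1	C	0
E	Glutamic acid	N[C@@H](CCC(=O)O)C(=O)O	R1:0:H;R2:7:OH;R3:4:OH	1	E	0
Q	Glutamine	N[C@@H](CCC(N)=O)C(=O)O	R1:0:H;R2:7:OH	1	Q	0
G	Glycine	NCC(=O)O	R1:0:H;R2:2:OH	1	G	0
H	Histidine	N[C@@H](Cc1c[nH]cn1)C(=O)O	R1:0:H;R2:8:OH	1	H	0
I	Isoleucine	N[C@@H]([C@@H](C)CC)C(=O)O	R1:0:H;R2:6:OH	1	I	0
L	Leucine	N[C@@H](CC(C)C)C(=O)O	R1:0:H;R2:6:OH	1	L	0
K	Lysine	N[C@@H](CCCCN)C(=O)O	R1:0:H;R2:7:OH	1	K	0
M	Methionine	N[C@@H](CCSC)C(=O)O	R1:0:H;R2:6:OH	1	M	0
F	Phenylalanine	N[C@@H](Cc1ccccc1)C(=O)O	R1:0:H;R2:9:OH	1	F	0
P	Proline	N1CCC[C@H]1C(=O)O	R1:0:H;R2:5:OH	1	P	0
S	Serine	N[C@@H](CO)C(=O)O	R1:0:H;R2:4:OH	1	S	0
T	Threonine	N[C@@H]([C@@H](O)C)C(=O)O	R1:0:H;R2:5:OH	1	T	0
W	Tryptophan	N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O	R1:0:H;R2:12:OH	1	W	0
Y	Tyrosine	N[C@@H](Cc1ccc(O)cc1)C(=O)O	R1:0:H;R2:10:OH	1	Y	0
V	Valine	N[C@@H](C(C)C)C(=O)O	R1:0:H;R2:5:OH	1	V	0
dL	D-Leucine	N[C@H](CC(C)C)C(=O)O	R1:0:H;R2:6:OH	0		0
dF	D-Phenylalanine	N[C@H](Cc1ccccc1)C(=O)O	R1:0:H;R2:9:OH	0		0
dW	D-Tryptophan	N[C@H](Cc1c[nH]c2ccccc12)C(=O)O	R1:0:H;R2:12:OH	0		0
Nle	Norleucine	N[C@@H](CCCC)C(=O)O	R1:0:H;R2:6:OH	0		0
Nva	Norvaline	N[C@@H](CCC)C(=O)O	R1:0:H;R2:5:OH	0		0
Orn	Ornithine	N[C@@H](CCCN)C(=O)O	R1:0:H;R2:6:OH	0		0
MetO	Methionine sulfoxide	N[C@@H](CCS(C)=O)C(=O)O	R1:0:H;R2:7:OH	0		0
pS	Phosphoserine	N[C@@H](COP(=O)(O)O)C(=O)O	R1:0:H;R2:8:OH	0		0
pGlu	Pyroglutamic acid	O=C1CC[C@H](C(=O)O)N1	R2:5:OH	0		1
Ac	Acetyl (acetic acid cap)	CC(=O)O	R2:1:OH	0		1
Lac	Lactoyl (lactic acid cap)	CC(O)C(=O)O	R2:3:OH	0		1
Succ	Succinyl (succinic acid cap)	OC(=O)CCC(=O)O	R2:1:OH	0		1
OMe	Methyl ester cap (methanol)	CO	R1:1:H	0		1
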