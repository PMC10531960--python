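# Candidate tuning-site residue states of the UV-opsin paralog clades.
# scheme: Rhodopsin = bovine Rhodopsin numbering; CrUVop2 = jewel-beetle
# UV-opsin-2 numbering (sites conventionally printed with an asterisk).
# Cell notation: '/' or ',' separate clade-wide variants; parentheses mark
# a single-member minor variant, e.g. K(T).
site	scheme	aphid_ancestral	aphid_uv_anc	aphid_uv_der	ph_ancestral	ph_uv_anc	ph_uv_der
15	Rhodopsin	L	L	M	L	L	L
29	CrUVop2	P	A	P	T	T	L
33	Rhodopsin	Y	Y	Y	Y	Y	H
45	CrUVop2	E	E	E	A	E	A
47	CrUVop2	D	S	R	E	D	E
43	Rhodopsin	L	M	S	I/L	L	V
47	Rhodopsin	F	F	L	F	F	Y
52	Rhodopsin	V/I/L	L	V	L	L	F
63	Rhodopsin	L/I	C	C	C	C	S
84	Rhodopsin	F	F	F	F	F	L
85	Rhodopsin	V/M	V/L/C	S	M/L	M/L	L
87	Rhodopsin	M	M	V	M	M	M
90	Rhodopsin	K	K	V	K	K	K
94	Rhodopsin	F	F	L	F	F	F
102	Rhodopsin	G	G	K(T)	G	G	G
105	Rhodopsin	Q	Q	P	L	T/S	A
125	Rhodopsin	G/S	S	G	A	S	S
183	Rhodopsin	Y	Y	F	Y	Y	F
201	Rhodopsin	R	R,K	K	R	Q	R
204	Rhodopsin	V	L/V	V	V	V	T
244	Rhodopsin	(D)S	Q	Q	Q	Q	M
264	Rhodopsin	S	S/A	A	S	S	A
273	Rhodopsin	L	M	M(L)	L	M	L
286	Rhodopsin	G	G	I	G	G	G/V
293	Rhodopsin	C	I	V	L	C	L
294	Rhodopsin	C,T,A	F	F	T	T	A
295	Rhodopsin	C	C	A	C	C	C
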