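species	B_opsin	UV_opsin	LW_opsin
Pcel	1	1	1
Dcit	1	1	1
Btab	1	1	1
Apis	0	1	1
Mper	0	1	1
Rmai	0	1	1
Sfla	0	1	1
Cced	0	1	1
Nlug	0	1	1
Lstri	0	1	1
Sfur	0	1	1
Ncin	1	1	1
Evit	1	1	1
Monu	1	1	1
Cari	1	1	1
Tdod	1	1	1
Bque	1	1	1
Xgre	1	1	1
Clec	0	1	1
Rpro	0	1	1
Gbue	0	1	1
Ofas	0	1	1
Hhal	0	1	1
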