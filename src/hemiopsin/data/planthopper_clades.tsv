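clade	member
UV-der	Nlug_UVder
UV-der	Lstri_UVder
UV-der	Sfur_UVder
UV-anc	Nlug_UVanc
UV-anc	Lstri_UVanc
UV-anc	Sfur_UVanc
outgroup	Ncin_UVop
outgroup	Evit_UVop
outgroup	Monu_UVop
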