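clade	member
UV-der	Apis_UVder
UV-der	Mper_UVder
UV-der	Rmai_UVder
UV-der	Sfla_UVder
UV-der	Cced_UVder
UV-anc	Apis_UVanc
UV-anc	Mper_UVanc
UV-anc	Rmai_UVanc
UV-anc	Sfla_UVanc
UV-anc	Cced_UVanc
outgroup	Pcel_UVop
outgroup	Dcit_UVop
outgroup	Focc_UVop
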