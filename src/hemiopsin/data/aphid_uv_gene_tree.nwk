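(Focc_UVop,((Pcel_UVop,Dcit_UVop)PsyllidUV,((Cced_UVanc,(Sfla_UVanc,(Rmai_UVanc,(Apis_UVanc,Mper_UVanc))))anc_clade,(Cced_UVder,(Sfla_UVder,(Rmai_UVder,(Apis_UVder,Mper_UVder))))der_clade)AphidDup)SternoUV)Root;
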