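(Focc_UVop,(((Evit_UVop,Monu_UVop),Ncin_UVop)MembracoideaUV,(((Lstri_UVanc,Sfur_UVanc),Nlug_UVanc)anc_clade,((Lstri_UVder,Sfur_UVder),Nlug_UVder)der_clade)FulgoroideaDup)AuchUV)Root;
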