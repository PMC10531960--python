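site	scheme	provenance
90	Rhodopsin	demonstrated UV/blue switch (chromophore counterion region, TM2)
105	Rhodopsin	proposed tuning site
125	Rhodopsin	proposed tuning site
293	Rhodopsin	demonstrated tuning site
294	Rhodopsin	demonstrated tuning site
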