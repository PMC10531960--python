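(Focc,(((Pcel,Dcit)Psylloidea,(Btab,(Cced,(Sfla,(Rmai,(Apis,Mper))))Aphidoidea)AphidWhitefly)Sternorrhyncha,((((Lstri,Sfur),Nlug)Fulgoroidea,(((Evit,Monu),Ncin)Membracoidea,(Cari,(Tdod,Bque)Cicadoidea))Cicadomorpha)Auchenorrhyncha,(Xgre,((Clec,Rpro),(Gbue,(Ofas,Hhal)))Heteroptera)Heteropterodea)Euhemiptera)Hemiptera)Root;
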