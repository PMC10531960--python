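# Genomic coordinates of the tandem-duplicated UV-opsin paralogs.
# Coordinates are 1-based inclusive NCBI gene ranges.
# Note: the R. maidis pair is annotated on NC_040877/NC_040878 in the
# source records, but the printed interlocus distance requires one
# linkage group; both rows are normalized to NC_040877 here (likely a
# typo in the source; see linkage_group_note).
species	protein_id	locus_id	linkage_group	start	end	intervening_genes	linkage_group_note
Nilaparvata lugens	XP_039285228	LOC111058697	5	75381302	75410087
Nilaparvata lugens	XP_039285232	LOC111051439	5	75416027	75437887	0
Acyrthosiphon pisum	XP_001951588	LOC100163348	A3	27235720	27247458
Acyrthosiphon pisum	XP_001951613	LOC100161312	A3	27217337	27226019	0
Myzus persicae	XP_022162222	LOC111028006	NW_019101158	450218	461548
Myzus persicae	XP_022162214	LOC111027999	NW_019101158	432490	442835	1
Rhopalosiphum maidis	XP_026808077	LOC113550447	NC_040877	46583828	46592054		as printed
Rhopalosiphum maidis	XP_026807991	LOC113550397	NC_040877	46570436	46578338	0	normalized from NC_040878
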