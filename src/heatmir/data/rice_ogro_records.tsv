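locus_id	gene_symbol	character_major	character_minor	isolation	objective	reference_doi
LOC_Os05g51830	OsHDT1	Resistance or tolerance	Bacterial blight resistance	Knockdown overexpression	Resistance to Magnaporthe oryzae and Xanthomonas oryzae pv. oryzae	10.1105/tpc.112.101972
LOC_Os05g51830	OsHDT1	Resistance or tolerance	Blast resistance	Knockdown overexpression	Resistance to Magnaporthe oryzae and Xanthomonas oryzae pv. oryzae	10.1105/tpc.112.101972
LOC_Os01g64980	Os-pollux	Resistance or tolerance	Other soil stress tolerance	Mutant	Mycorrhizal symbiosis	10.1104/pp.108.131540
LOC_Os05g30220	OsRP1L1	Resistance or tolerance	Bacterial blight resistance	Overexpression	Resistance to Xanthomonas oryzae pv. oryzicola	10.1007/s11033-011-1122-6 10.1007-s11105-012-0537-0
LOC_Os05g47780	OsHRZ2	Resistance or tolerance	Other soil stress tolerance	Knockdown	Fe acquisition	10.1038/ncomms3792
LOC_Os06g46270	OMTN4	Resistance or tolerance	Drought tolerance	Overexpression	Drought sensitivity	10.1093/jxb/eru072
LOC_Os08g45000	OsPT6	Resistance or tolerance	Other soil stress tolerance	Knockdown	Phosphate uptake and translocation	10.1111/j.1365-313X.2008.03726.x
LOC_Os10g38060	OsPLDbeta1	Resistance or tolerance	Blast resistance	Knockdown	Resistance to Pyricularia grisea and Xanthomonas oryzae pv. oryzae	10.1104/pp.108.131979
LOC_Os10g40100	OsRLCK306	Resistance or tolerance	Blast resistance	Knockdown	Promote invasion of bacteria (Xoc)	10.1007/s11033-014-3069-x
LOC_Os12g18360	Pi-ta	Resistance or tolerance	Blast resistance	Natural variation	Resistance to Magnaporthe grisea	10.1105/tpc.12.11.2033
LOC_Os02g18080	TDR	Morphological trait	Sterility	Others	Delated/non-degradation of tapetum tissue, collapse of the haploid microspores	10.1007/s11032-013-9972-3
LOC_Os04g46580	OsSPL7	Morphological trait	Panicle flower	Overexpression	Panicle development	10.1104/pp.106.084475
LOC_Os02g12380	HDA710	Morphological trait	Panicle flower	Knockdown	Flag leaf morphology, semidwarf, awn development	10.1016/j.bbrc.2009.07.162
LOC_Os04g55560	SHAT1	Morphological trait	Panicle flower	Mutant	Seed shattering, floral organ identity	10.1105/tpc.111.094383
LOC_Os06g46270	OMTN4	Physiological trait	Panicle flower	Overexpression	Low spikelet fertility	10.1093/jxb/eru072
LOC_Os05g51830	OsHDT1	Physiological trait	Flowering	Overexpression	Flowering time in hybrid, chromatin modification	10.1371/journal.pone.0021789
LOC_Os02g12380	HDA710	Morphological trait	Culm leaf	Knockdown	Flag leaf morphology, semidwarf, awn development	10.1016/j.bbrc.2009.07.162
LOC_Os06g46270	OMTN4	Morphological trait	Culm leaf	Knockdown overexpression	Leaf rolling, wilting during drought stress	10.1093/jxb/eru072
LOC_Os02g12380	HDA710	Morphological trait	Dwarf	Knockdown	Flag leaf morphology, semidwarf, awn development	10.1016/j.bbrc.2009.07.162
LOC_Os10g38060	OsPLDbeta1	Physiological trait	Germination dormancy	Knockdown	Sensitivity to ABA during germination stage	10.1038/cr.2007.77
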