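gene_id	aspect	term
LOC_Os02g04450	BP	metabolic process
LOC_Os02g04450	BP	biological regulation
LOC_Os02g04450	MF	binding
LOC_Os03g42320	BP	developmental process
LOC_Os03g42320	MF	transcription regulator activity
LOC_Os04g46580	BP	developmental process
LOC_Os04g46580	BP	biological regulation
LOC_Os04g46580	MF	transcription regulator activity
LOC_Os04g46580	CC	organelle
LOC_Os12g27102	BP	metabolic process
LOC_Os01g48850	BP	cellular process
LOC_Os01g48850	MF	catalytic activity
LOC_Os01g58730	BP	response to stimulus
LOC_Os01g58730	MF	binding
LOC_Os03g14260	BP	metabolic process
LOC_Os03g14260	MF	catalytic activity
LOC_Os03g14260	CC	organelle
LOC_Os05g43910	BP	localization
LOC_Os05g43910	MF	transporter activity
LOC_Os06g15680	BP	cellular component organization or biogenesis
LOC_Os06g15680	CC	protein-containing complex
LOC_Os07g37130	BP	multicellular organismal process
LOC_Os02g44380	BP	developmental process
LOC_Os02g44380	MF	transcription regulator activity
LOC_Os06g46270	BP	response to stimulus
LOC_Os06g46270	BP	biological regulation
LOC_Os06g46270	MF	transcription regulator activity
LOC_Os05g51830	BP	biological regulation
LOC_Os05g51830	MF	catalytic activity
LOC_Os05g51830	CC	organelle
LOC_Os10g38060	BP	metabolic process
LOC_Os10g38060	MF	catalytic activity
LOC_Os10g38060	CC	cell
LOC_Os02g18080	BP	developmental process
LOC_Os02g18080	MF	transcription regulator activity
LOC_Os08g20000	BP	metabolic process
LOC_Os08g20000	MF	catalytic activity
LOC_Os12g18360	BP	response to stimulus
LOC_Os12g18360	MF	binding
LOC_Os08g45000	BP	localization
LOC_Os08g45000	MF	transporter activity
LOC_Os08g45000	CC	cell
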