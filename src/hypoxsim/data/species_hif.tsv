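id	initial_conc	unit	module	is_phospho_form	phospho_pair	provenance
HIF1a	0.003341678223213578	nM	hif	False		reconstructed
ARNT	10.166028404264884	nM	hif	False		reconstructed
HIF_ARNT	0.033971595735102646	nM	hif	False		reconstructed
mRNA	0.16702099383460042	nM	hif	False		reconstructed
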