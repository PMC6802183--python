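id	reactants	products	rate_law	params	atp_dependent	drug_target	provenance
hif_syn		HIF1a	mass_action	kf=0.02	False		reconstructed
hif_phd_deg	HIF1a		michaelis_menten	vmax=6.0; km=1.0; o2_coupled=1	False		reconstructed
hif_basal_deg	HIF1a		degradation	k=0.005	False		reconstructed
hif_arnt_bind	HIF1a + ARNT	HIF_ARNT	mass_action	kf=0.1; kr=0.1	False		reconstructed
mrna_syn	HIF_ARNT	HIF_ARNT + mRNA	michaelis_menten	vmax=0.01; km=2.0	False		reconstructed
mrna_deg	mRNA		degradation	k=0.001	False		reconstructed
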