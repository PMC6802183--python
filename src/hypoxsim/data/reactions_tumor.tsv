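id	reactants	products	rate_law	params	atp_dependent	drug_target	provenance
vegf_syn		VEGF	vegf_synthesis	k_syn=0.004	False		reconstructed
vegf_deg	VEGF		degradation	k=0.011863384514296315	False		reconstructed
vegf_bind	VEGF + VEGFR	VVEGFR	vegf_binding	k1f=0.005; k1r=0.002	False	VEGF_binding	reconstructed
vvegfr_internalize	VVEGFR	VEGFR	mass_action	kf=0.01	False		reconstructed
vvegfr_dimerize	2 VVEGFR	VVR	mass_action	kf=0.01; kr=0.01	False		reconstructed
vvr_phospho	VVR	VVR_P	atp_phospho	vmax=1.0; k_prime=10.0; k_m_atp=20000.0	True		reconstructed
vvr_dephos	VVR_P	VVR	mass_action	kf=0.01	False		reconstructed
vvrp_pi3k_bind	VVR_P + PI3K	VVR_P_PI3K	mass_action	kf=0.01; kr=0.1	False		reconstructed
vvrp_pi3k_phos	VVR_P_PI3K	VVR_P + pPI3K	atp_phospho	vmax=40.0; k_prime=100.0; k_m_atp=20000.0	True		reconstructed
egf_bind	EGF + EGFR	EEGFR	mass_action	kf=0.003; kr=0.06	False		reconstructed
eegfr_pi3k_bind	EEGFR + PI3K	E_PI3K	mass_action	kf=0.005; kr=0.1	False		reconstructed
eegfr_pi3k_phos	E_PI3K	EEGFR + pPI3K	atp_phospho	vmax=7.0; k_prime=100.0; k_m_atp=20000.0	True		reconstructed
pi3k_dephos	pPI3K	PI3K	mass_action	kf=0.05	False		reconstructed
pip2_to_pip3	PIP2	PIP3	mass_action	kf=0.001; modifiers=pPI3K	False		reconstructed
pip3_to_pip2	PIP3	PIP2	degradation	k=0.1	False		reconstructed
pip3_akt_bind	PIP3 + Akt	PIP3_Akt	mass_action	kf=0.005; kr=0.1	False		reconstructed
pip3_pdk_bind	PIP3 + PDK	PIP3_PDK	mass_action	kf=0.003; kr=0.1	False		reconstructed
akt_phospho	PIP3_Akt	pPIP3_Akt	atp_phospho	kcat=0.15; enzyme=PIP3_PDK; k_prime=1000.0; k_m_atp=100000.0	True	AKT_phospho	reconstructed
pakt_release	pPIP3_Akt	PIP3 + pAkt	mass_action	kf=0.1	False		reconstructed
pakt_dephos	pAkt	Akt	michaelis_menten	vmax=0.15; km=5.0	False		reconstructed
sos_eegfr_bind	SOS + EEGFR	SOS_E	mass_action	kf=0.005; kr=0.05	False		reconstructed
sos_vvrp_bind	SOS + VVR_P	SOS_V	mass_action	kf=0.0005; kr=0.1	False		reconstructed
sos_inactivation	SOS	SOSi	atp_phospho	kcat=0.003; enzyme=pERK; k_prime=200.0; k_m_atp=100000.0	True		reconstructed
sos_reactivation	SOSi	SOS	mass_action	kf=0.005	False		reconstructed
raf_phospho_egf	RAF	pRAF	atp_phospho	kcat=0.1; enzyme=SOS_E; k_prime=150.0; k_m_atp=20000.0	True	RAF_phospho	reconstructed
raf_phospho_vegf	RAF	pRAF	atp_phospho	kcat=0.004; enzyme=SOS_V; k_prime=150.0; k_m_atp=20000.0	True	RAF_phospho	reconstructed
raf_dephos	pRAF	RAF	mass_action	kf=0.05	False		reconstructed
raf_inhib_by_akt	RAF	RAFi	atp_phospho	kcat=0.002; enzyme=pAkt; k_prime=200.0; k_m_atp=100000.0	True		reconstructed
rafi_recover	RAFi	RAF	mass_action	kf=0.02	False		reconstructed
mek_phospho	MEK	pMEK	atp_phospho	kcat=0.5; enzyme=pRAF; k_prime=250.0; k_m_atp=20000.0	True	MEK_phospho	reconstructed
mek_dephos	pMEK	MEK	mass_action	kf=0.05	False		reconstructed
erk_phospho	ERK	pERK	atp_phospho	kcat=0.8; enzyme=pMEK; k_prime=3000.0; k_m_atp=100000.0	True		reconstructed
erk_dephos	pERK	ERK	michaelis_menten	vmax=0.2; km=10.0	False		reconstructed
rsk_phospho	Rsk	pRsk	atp_phospho	kcat=0.1; enzyme=pERK; k_prime=200.0; k_m_atp=100000.0	True		reconstructed
rsk_dephos	pRsk	Rsk	mass_action	kf=0.05	False		reconstructed
plc_phospho	PLC	PLCR	atp_phospho	kcat=0.05; enzyme=EEGFR; k_prime=200.0; k_m_atp=100000.0	True		reconstructed
plcr_dephos	PLCR	PLC	mass_action	kf=0.05	False		reconstructed
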