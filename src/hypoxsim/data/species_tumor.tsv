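id	initial_conc	unit	module	is_phospho_form	phospho_pair	provenance
VEGF	0.09999999990245124	nM	tumor	False		reconstructed
VEGFR	6.752787725933489	nM	tumor	False		reconstructed
VVEGFR	0.2813661549727599	nM	tumor	False		reconstructed
VVR	0.07916691316415553	nM	tumor	False		reconstructed
VVR_P	0.7854509588561099	nM	tumor	True	VVR	reconstructed
PI3K	42.98179536990052	nM	tumor	False		reconstructed
VVR_P_PI3K	0.678863836684277	nM	tumor	False		reconstructed
pPI3K	6.588786930075535	nM	tumor	True	PI3K	reconstructed
EGF	0.2753242520562821	nM	tumor	False		reconstructed
EGFR	49.27532425205636	nM	tumor	False		reconstructed
EEGFR	0.6783345897264097	nM	tumor	False		reconstructed
E_PI3K	0.860553863339801	nM	tumor	False		reconstructed
PIP2	416.0446325522078	nM	tumor	False		reconstructed
PIP3	27.412294372880652	nM	tumor	False		reconstructed
Akt	30.299270669210834	nM	tumor	False		reconstructed
PIP3_Akt	40.19465802012057	nM	tumor	False		reconstructed
pPIP3_Akt	1.3339683232792199	nM	tumor	True	PIP3_Akt	reconstructed
pAkt	40.17210298738929	nM	tumor	True	Akt	reconstructed
PDK	27.98555326848813	nM	tumor	False		reconstructed
PIP3_PDK	23.01444673151187	nM	tumor	False		reconstructed
SOS	18.955060148062323	nM	tumor	False		reconstructed
SOS_E	1.2857872948775273	nM	tumor	False		reconstructed
SOS_V	0.07444135084235388	nM	tumor	False		reconstructed
SOSi	11.784711206217782	nM	tumor	False		reconstructed
RAF	107.51927705500523	nM	tumor	False		reconstructed
pRAF	1.0761685663723561	nM	tumor	True	RAF	reconstructed
RAFi	1.4045543786221681	nM	tumor	False		reconstructed
MEK	323.9260634856879	nM	tumor	False		reconstructed
pMEK	6.073936514310725	nM	tumor	True	MEK	reconstructed
ERK	123.11932092455633	nM	tumor	False		reconstructed
pERK	226.8806790754439	nM	tumor	True	ERK	reconstructed
Rsk	37.82741519160075	nM	tumor	False		reconstructed
pRsk	72.17258480839965	nM	tumor	True	Rsk	reconstructed
PLC	109.75964021503228	nM	tumor	False		reconstructed
PLCR	0.24035978496778063	nM	tumor	True	PLC	reconstructed
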