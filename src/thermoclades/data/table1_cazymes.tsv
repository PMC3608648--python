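genome	locus_tag	architecture	localization
T. italicus Ab9	Thit_0188	GH10	extracellular
T. mathranii subsp. mathranii A3	Tmath_0247	GH10	extracellular
T. mathranii subsp. mathranii A3	Tmath_1695	GH43	cell-bound
T. italicus Ab9	Thit_0190	GH52	extracellular
T. mathranii subsp. mathranii A3	Tmath_0249	GH52	extracellular
T. thermohydrosulfuricus WC1	TthWC1_1012	GH52	extracellular
T. siderophilus SR4	ThesiDRAFT1_1967	CE4	extracellular
T. thermohydrosulfuricus WC1	TthWC1_1808	CE4	extracellular
T. wiegelii Rt8.B1	Thewi_00017610	CE4	extracellular
T. italicus Ab9	Thit_1727	PL9	extracellular
T. siderophilus SR4	ThesiDRAFT1_0902	GH66-CBM35-CBM35-GH15	extracellular
T. thermohydrosulfuricus WC1	TthWC1_0529	GH66-CBM35-CBM35-GH15	extracellular
T. italicus Ab9	Thit_0192	CBM22-CBM22-GH10-CBM9-CBM9-SLH-SLH-SLH	extracellular
T. mathranii subsp. mathranii A3	Tmath_0251	CBM22-CBM22-GH10-CBM9-CBM9-SLH-SLH-SLH	extracellular
T. thermohydrosulfuricus WC1	TthWC1_1010	CBM22-CBM22-GH10-CBM9-CBM9-SLH-SLH-SLH	extracellular
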