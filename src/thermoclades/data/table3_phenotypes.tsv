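genome	glucose	cellobiose	arabinose	galactose	mannose	xylose	glucuronic_acid
T. brockii subsp. finnii Ako-1	+	+	-	+	+	+	NR
T. ethanolicus CCSD1	NR	NR	NR	NR	NR	NR	NR
T. pseudethanolicus 39E	+	+	-	+	+	+	NR
Thermoanaerobacter sp. X513	+	NR	NR	NR	NR	+	NR
Thermoanaerobacter sp. X514	+	NR	NR	NR	NR	+	NR
Thermoanaerobacter sp. X561	+	NR	NR	NR	NR	+	NR
T. italicus Ab9	+	+	+	+	+	+	NR
T. mathranii subsp. mathranii A3	+	+	+	-	+	+	NR
T. siderophilus SR4	+	+	-	NR	NR	+	NR
T. thermohydrosulfuricus WC1	+	+	-	+	+	+	NR
T. wiegelii Rt8.B1	+	+	-	+	+	+	NR
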