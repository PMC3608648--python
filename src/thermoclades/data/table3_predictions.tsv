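genome	glucose	cellobiose	arabinose	galactose	mannose	xylose	glucuronic_acid
T. brockii subsp. finnii Ako-1	+	+	-	+	+	+	-
T. ethanolicus CCSD1	+	+	-	+	+	+	-
T. pseudethanolicus 39E	+	+	-	+	+	+	-
Thermoanaerobacter sp. X513	+	+	-	+	+	+	-
Thermoanaerobacter sp. X514	+	+	-	+	+	+	-
Thermoanaerobacter sp. X561	+	+	-	+	+	+	-
T. italicus Ab9	+	+	+	+	+	+	+
T. mathranii subsp. mathranii A3	+	+	+	+	+	+	+
T. siderophilus SR4	+	+	-	+	+	+	-
T. thermohydrosulfuricus WC1	+	+	-	+	+	+	+
T. wiegelii Rt8.B1	+	+	-	+	+	+	-
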