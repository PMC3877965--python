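gene	association	p_value
ADD1	-	2.26E-02
DNM1L	+	4.70E-04
DSG2	+	1.63E-03
DSP	+	1.24E-02
HMGB2	+	3.97E-03
KPNB1	+	4.25E-02
LMNB1	+	4.85E-02
MAPT	-	9.91E-03
OCLN	-	1.72E-02
PAK2	+	4.56E-02
PKP1	+	5.65E-02
PRKCD	-	4.95E-03
PRKCQ	-	3.18E-02
SATB1	-	7.72E-02
STK24	+	1.87E-02
TJP1	+	7.72E-02
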