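apoptotic_execution_phase	Reactome	ADD1	DNM1L	DSG2	DSP	HMGB2	KPNB1	LMNB1	MAPT	OCLN	PAK2	PKP1	PRKCD	PRKCQ	SATB1	STK24	TJP1
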