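CSC	glioblastoma stem cell markers	SOX2	PROM1	SOX4	THY1	ASCL1
INVASIVE	experimentally supported GBM invasion genes	ZEB1	HNRNPC	WNT5A	DRAM1
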