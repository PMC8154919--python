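snp_id	gene	genotype	group	AA_current	GG_current	AG_current	AA_future	GG_future	AG_future
snp32991-scaffold385-133908	ARL13B	GG	DRY	0.33	0.18	0.49	0.37	0.15	0.48
snp32991-scaffold385-133908	ARL13B	GG	NOTDRY	0.15	0.37	0.48	0.18	0.34	0.49
snp35938-scaffold431-1169604	KLF12	AA,AG	DRY	0.81	0.01	0.18	0.75	0.02	0.23
snp35938-scaffold431-1169604	KLF12	AA,AG	NOTDRY	0.64	0.04	0.32	0.60	0.05	0.35
snp23847-scaffold240-2578654	CHD2	AA	DRY	0.59	0.05	0.36	0.54	0.07	0.39
snp23847-scaffold240-2578654	CHD2	AA	NOTDRY	0.36	0.16	0.48	0.33	0.18	0.49
snp44855-scaffold611-263638	PAK5	AG	DRY	0.01	0.84	0.15	0.01	0.80	0.19
snp44855-scaffold611-263638	PAK5	AG	NOTDRY	0.02	0.75	0.23	0.03	0.68	0.29
snp40739-scaffold521-1667886	RACGAP1	GG	HOT	0.06	0.56	0.37	0.05	0.61	0.34
snp40739-scaffold521-1667886	RACGAP1	GG	NOTHOT	0.02	0.73	0.25	0.02	0.77	0.21
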