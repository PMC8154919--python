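snp_id	gene	genotype	variable	group	p_current	b	delta_env
snp32991-scaffold385-133908	ARL13B	GG	isothermality	DRY	0.4296	0.3278	-0.1253
snp32991-scaffold385-133908	ARL13B	GG	isothermality	NOTDRY	0.6109	0.3278	-0.0935
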