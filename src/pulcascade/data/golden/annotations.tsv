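gene_id	label	evidence
ctg01_g0003	GH26	HMM;SEARCH
ctg01_g0004	GH130	HMM;SEARCH
ctg01_g0006	SUSC	HMM
ctg01_g0007	SUSD	HMM
ctg01_g0008	GH26	HMM;SEARCH
ctg01_g0009	GH26	HMM;SEARCH
ctg01_g0010	GH5	HMM;SEARCH
ctg01_g0011	GH27	HMM;SEARCH
ctg01_g0013	CE2	HMM;SEARCH
ctg01_g0025	SUSC	HMM
ctg01_g0026	SUSD	HMM
ctg01_g0047	GT	HMM
ctg01_g0048	GT	HMM
ctg01_g0049	SUSC	HMM
ctg01_g0050	SUSD	HMM
ctg01_g0051	GT	HMM
ctg02_g0021	GH26	HMM;SEARCH
ctg02_g0022	GH130	HMM;SEARCH
ctg02_g0024	SUSC	HMM
ctg02_g0025	SUSD	HMM
ctg02_g0026	GH26	HMM;SEARCH
ctg02_g0027	GH26	HMM;SEARCH
ctg02_g0028	GH5	HMM;SEARCH
ctg02_g0029	GH27	HMM;SEARCH
ctg02_g0031	CE2	HMM;SEARCH
ctg02_g0053	CE6	HMM;SEARCH
ctg02_g0054	GH3	HMM;SEARCH
ctg02_g0055	GH16	HMM;SEARCH
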