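family	count	fraction	retained
CE2	2	1.0	True
GH130	2	1.0	True
GH26	2	1.0	True
GH27	2	1.0	True
GH5	2	1.0	True
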