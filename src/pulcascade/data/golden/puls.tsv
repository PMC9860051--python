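contig_id	span_start	span_end	susc_gene	susd_gene	n_genes	n_anchors	families	cazyme_genes
ctg01	3	13	ctg01_g0006	ctg01_g0007	11	1	CE2;GH130;GH26;GH27;GH5	ctg01_g0003:GH26;ctg01_g0004:GH130;ctg01_g0008:GH26;ctg01_g0009:GH26;ctg01_g0010:GH5;ctg01_g0011:GH27;ctg01_g0013:CE2
ctg02	21	31	ctg02_g0024	ctg02_g0025	11	1	CE2;GH130;GH26;GH27;GH5	ctg02_g0021:GH26;ctg02_g0022:GH130;ctg02_g0026:GH26;ctg02_g0027:GH26;ctg02_g0028:GH5;ctg02_g0029:GH27;ctg02_g0031:CE2
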