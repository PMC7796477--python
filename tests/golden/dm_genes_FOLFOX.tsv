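gene	best_probe	p	fdr	delta_beta	logFC	n_promoter_probes
G0004	cg00000007	7.840854734818332e-12	5.880641051113749e-11	0.4119419125934165	2.6710201059598	2
G0006	cg00000012	8.334922943947897e-13	1.2502384415921846e-11	0.40987207235452283	2.6583182784192516	2
G0009	cg00000017	3.2991762143408255e-13	9.897528643022477e-12	0.3775519448005473	2.424931072077037	2
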