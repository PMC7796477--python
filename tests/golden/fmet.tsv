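gene	slope	r2	p	fdr	n	degenerate
G0001	-0.2416787538671986	0.00037709358152113604	0.9522353264372972	0.9522353264372972	12	False
G0002	2.269368769530135	0.03518627208586671	0.5593598712466681	0.9322664520777801	12	False
G0003	0.9915742148335556	0.010234108652736542	0.7544082904275564	0.9430103630344455	12	False
G0004	-4.1027346753211384	0.9742366961914007	2.8237314387434563e-09	1.2406294943413823e-08	12	False
G0005	4.515632438133448	0.24691252307980055	0.10028612299328488	0.2507153074832122	12	False
G0006	-3.8463109748693936	0.9727770318197563	3.7218884830241468e-09	1.2406294943413823e-08	12	False
G0007	-0.39109145629327935	0.0017122932080158714	0.8983988722631794	0.9522353264372972	12	False
G0008	-3.1009228451855484	0.09107894087675694	0.34042009358306796	0.6808401871661359	12	False
G0009	-4.15145785887257	0.9807023440008223	6.639647695862514e-10	6.639647695862513e-09	12	False
G0010	-3.205889809114299	0.015490876399727134	0.6999447365059205	0.9430103630344455	12	False
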