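time	survival	at_risk	events
1.0196339398676304	0.8333333333333333	6	1
5.070728605483732	0.8333333333333333	5	0
5.829158236485688	0.625	4	1
6.934343413430124	0.41666666666666663	3	1
22.371744618190718	0.20833333333333334	2	1
47.04599401293549	0.20833333333333334	1	0
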