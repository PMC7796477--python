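time	survival	at_risk	events
0.15996486423908746	0.8333333333333333	6	1
2.9468018118924006	0.8333333333333333	5	0
7.4796192564327075	0.625	4	1
7.841323298145173	0.41666666666666663	3	1
31.86336248321393	0.20833333333333334	2	1
32.06007312072132	0.0	1	1
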