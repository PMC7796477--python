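gene	provenance
G0004	FOLFOX
G0006	FOLFOX
G0009	FOLFOX
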