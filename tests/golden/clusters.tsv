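sample_id	cluster
FOLFOX_R01	hyper
FOLFOX_R02	hyper
FOLFOX_R03	hyper
FOLFOX_R04	hyper
FOLFOX_R05	hyper
FOLFOX_R06	hyper
FOLFOX_S01	hypo
FOLFOX_S02	hypo
FOLFOX_S03	hypo
FOLFOX_S04	hypo
FOLFOX_S05	hypo
FOLFOX_S06	hypo
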