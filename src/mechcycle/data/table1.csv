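replicate_id,ic50_mg_ml
P1,"0,15"
P2,"0,24"
P3,"0,11"
P4,"0,08"
P5,"0,14"
P6,"0,14"
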