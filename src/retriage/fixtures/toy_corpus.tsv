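# disease_id <TAB> ';'-joined term ids
D1	HP:0000004
D2	HP:0000005
D3	HP:0000003
D4	HP:0000003
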