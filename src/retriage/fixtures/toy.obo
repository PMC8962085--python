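format-version: 1.2
ontology: toy-phenotype

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0000002
name: Branch A
is_a: HP:0000001 ! All

[Term]
id: HP:0000003
name: Branch B
is_a: HP:0000001 ! All

[Term]
id: HP:0000004
name: Leaf A1
is_a: HP:0000002 ! Branch A

[Term]
id: HP:0000005
name: Leaf A2
is_a: HP:0000002 ! Branch A
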