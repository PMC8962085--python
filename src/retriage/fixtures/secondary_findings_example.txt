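# Example secondary-findings gene list (one symbol per line). The medically
# actionable gene list is configuration: supply your laboratory's current
# list here; this file is a small synthetic example for tests and demos.
BRCA1
BRCA2
MYH7
MYBPC3
TP53
LDLR
APOB
PCSK9
RET
SDHB
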