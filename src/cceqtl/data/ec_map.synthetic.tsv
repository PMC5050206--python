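gene_id	ec
G02	1.1.1.1
G04	1.1.1.1
G04	1.1.1.2
G07	1.1.1.2
G03	2.3.4.5
G05	2.3.4.5
G12	3.1.1.1
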