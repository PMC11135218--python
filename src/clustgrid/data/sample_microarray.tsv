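Genes	Time 1	Time 2	Time 3
Gene 1	0.25	0.22	0.65
Gene 2	-0.75	1.25	-0.63
Gene 3	0.05	0.66	0.75
Gene 4	1.25	-0.52	0.15
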