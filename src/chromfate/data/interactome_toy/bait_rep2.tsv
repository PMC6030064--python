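protein_id	unique_peptides
P01	3
P02	8
P03	4
P04	1
P05	2
P06	5
P07	1
P08	2
P09	2
P10	3
BG1	30
BG2	39
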