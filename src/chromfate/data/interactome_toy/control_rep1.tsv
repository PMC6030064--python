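protein_id	unique_peptides
P01	2
P02	4
P03	6
P04	0
P05	4
P06	6
P07	1
P08	2
P09	2
P10	8
BG1	40
BG2	25
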