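protein_id	unique_peptides
P01	10
P02	4
P03	1
P04	2
P05	0
P06	6
P07	4
P08	4
P09	2
P10	2
BG1	40
BG2	25
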