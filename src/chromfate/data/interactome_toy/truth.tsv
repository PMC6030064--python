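protein_id	candidate
P01	True
P02	True
P03	False
P04	True
P05	False
P06	False
P07	True
P08	True
P09	True
P10	False
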