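Saniwa	NAmerica
Polydaedalus	Africa
griseus	Africa,Asia
IndoAsianA	Asia
IndoAsianB	Asia
Australasian	Australasia
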