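motif_class	count
mono	139
di	140
tri	5
tetra	22
penta	3
hexa	5
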