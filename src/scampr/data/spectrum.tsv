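substitution_class	count
G/C->A/T	428
A/T->G/C	2
A/T->C/G	1
indel	1
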