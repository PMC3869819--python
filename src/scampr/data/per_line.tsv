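mutations_per_line	n_lines
0	1467
1	279
2	58
3	5
4	1
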