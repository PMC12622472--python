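experiment	n	mean	sd
1	28	23.51	12.60
2	45	27.49	15.15
3	67	26.87	14.07
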