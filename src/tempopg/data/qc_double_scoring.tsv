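era	scored_twice	discrepancies
historical	7506	7
intermediate	806	1
contemporary	1002	2
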