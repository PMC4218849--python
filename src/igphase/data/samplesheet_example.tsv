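sample	index
sample1	TATAGCCT
sample2	ATAGAGGC
sample3	CCTATCCT
sample4	GGCTCTGA
sample5	AGGCGAAG
sample6	TAATCTTA
sample7	CAGGACGT
sample8	GTACTGAC
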