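>IGHG1s*01 subclass=IgG1 note=synthetic reconstruction of CH1 nt 1-60
GCCTCCACCAAGGGCCCATCGGTCTTCCCCCTGGCACCCTCCTCCAAGAGCACCTCTGGG
>IGHG1s*03 subclass=IgG1 note=synthetic allele, identical in this window
GCCTCCACCAAGGGCCCATCGGTCTTCCCCCTGGCACCCTCCTCCAAGAGCACCTCTGGG
>IGHG2s*01 subclass=IgG2 note=synthetic reconstruction of CH1 nt 1-60
GCCTCCACCAAGGGCCCATCGGTCTTCCCCCTGGCGCCCTGCTCCAGGAGCACCTCCGAG
>IGHG3s*01 subclass=IgG3 note=synthetic reconstruction of CH1 nt 1-60
GCTTCCACCAAGGGCCCATCGGTCTTCCCCCTGGCGCCCTGCTCCAGGAGCACCTCTGGG
>IGHG4s*01 subclass=IgG4 note=synthetic reconstruction of CH1 nt 1-60
GCTTCCACCAAGGGCCCATCGGTCTTCCCCCTGGCGCCCTGCTCCAGGAGCACCTCCGAG
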