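pool	name	sequence
rt	HG_RT-in	AGAGGTGCTCTTGGAGC
rt	mu_RT-in	GGGAATTCTCACAGGAG
rt	Kappa_RT-in	CACACAACAGAGGCAG
rt	Lambda_RT-in	CACCAGTGTGGCCTTG
tso	TSO	AAGCAGTGGTATCAACGCAGAGTACATGGG
pcr1	TSO-PCR	AAGCAGTGGTATCAACGCAG
pcr1	unb_HG_IN_new	AGAGGTGCTCTTGGAG
pcr1	unb_Cmu_OUT	GGGAATTCTCACAGGAG
pcr1	unb_Kappa_OUT	CACACAACAGAGGCAGTTCC
pcr1	unb_Lambda_OUT	CACCAGTGTGGCCTTGTTGG
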