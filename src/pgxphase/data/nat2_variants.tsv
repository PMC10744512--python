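# NAT2 core star-allele SNVs, 1-based cDNA (coding) coordinates
# gene	var_id	coord	ref	alt
NAT2	c.191G>A	191	G	A
NAT2	c.282C>T	282	C	T
NAT2	c.341T>C	341	T	C
NAT2	c.481C>T	481	C	T
NAT2	c.590G>A	590	G	A
NAT2	c.803A>G	803	A	G
NAT2	c.857G>A	857	G	A
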