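# NAT2 population haplotype frequencies used by the statistical-phasing
# emulation. This is a hand-built behavioural fixture, not a cohort estimate:
# the weights are set so that frequency-maximizing joins reproduce the
# characteristic short-read mis-assignments observed against direct phasing
# (the *5,*11,*12 cis join is favored over *5,*11 + *12; the *6 + *13 trans
# join is favored over *6,*13 + *4). Editable; haplotypes absent from this
# table receive the floor frequency from thresholds.yaml.
# haplotype	frequency
*4	0.30
*5,*11,*12	0.25
*6	0.08
*13	0.08
*5,*11	0.03
*12	0.03
*5,*12	0.02
*11	0.02
*6,*12	0.02
*12,*13	0.02
*6,*13	0.015
*7	0.01
*14	0.01
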