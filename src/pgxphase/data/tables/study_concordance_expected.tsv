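# Reported per-sample SRS-vs-LRS concordance flags at the three comparison
# levels (reference transcription; used to cross-check compare_callsets).
# sample	haplotype	diplotype	phenotype
Sample 1	yes	yes	yes
Sample 2	no	yes	yes
Sample 3	no	no	yes
Sample 4	no	no	yes
Sample 5	no	yes	yes
Sample 6	yes	yes	yes
Sample 7	yes	yes	yes
Sample 8	yes	yes	yes
Sample 9	no	no	yes
Sample 10	no	no	yes
Sample 11	no	no	yes
Sample 12	no	yes	yes
Sample 13	yes	yes	yes
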