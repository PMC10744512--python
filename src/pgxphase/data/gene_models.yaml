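# Synthetic locus models for the three pharmacogenes. Reference sequences are
# generated deterministically at catalog load from the per-gene seed (random
# bases with the catalog reference base forced at every variant coordinate);
# no genome build is required because reads are simulated, not aligned.

NAT2:
  locus_length: 9936          # single-exon gene; coding SNVs use cDNA coords
  coordinate_frame: cDNA
  reference_seed: 20231127

UGT1A1:
  locus_length: 10000
  coordinate_frame: genomic-window
  reference_seed: 20231128
  repeat_locus:
    position: 3000            # 1-based start of the left anchor
    anchor_left: GGCCACTGCACC   # ends in C: cannot extend the TA run leftwards
    unit: TA
    reference_units: 6        # *1 allele
    anchor_right: CCCAGGTGGATG  # starts with C: truncated runs fail the anchor check

CYP2D6:
  locus_length: 6000          # one gene-unit copy; multi-copy haplotypes concatenate
  coordinate_frame: genomic-window
  reference_seed: 20231129
  spacer_length: 500          # intergenic spacer between tandem copies
  paralog:
    name: CYP2D7
    junction: 4500            # hybrid = 2D6[1..4500] + 2D7[4501..end]
    reference_seed: 20231130
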