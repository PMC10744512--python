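# Scoring bands, diplotype-level activity-score overrides, and caller thresholds.
#
# Overrides hold printed clinical scores that admit no consistent additive
# per-allele decomposition (duplication masked by deletion; hybrid-in-tandem
# scoring); keys are canonical diplotype strings.

# Band bounds carry explicit closure because printed scores sit exactly on
# the boundaries (0.5 -> PM but 1.25 -> NM for CYP2D6).
phenotype_bands:
  CYP2D6:            # activity score -> metabolizer status
    - {label: PM, max: 0.5, max_incl: true}                  # AS <= 0.5
    - {label: IM, min: 0.5, max: 1.25}                       # 0.5 < AS < 1.25
    - {label: NM, min: 1.25, min_incl: true, max: 2.25, max_incl: true}
    - {label: UM, min: 2.25}                                 # AS > 2.25
  UGT1A1:
    - {label: PM, max: 1.0}                                  # AS < 1.0
    - {label: IM, min: 1.0, min_incl: true, max: 2.0}        # 1.0 <= AS < 2.0
    - {label: NM, min: 2.0, min_incl: true}                  # AS >= 2.0

activity_overrides:
  CYP2D6:
    "*2 x 2/*5": 1.0
    "*4/*41,*68": 0.5
  UGT1A1:
    "*36/*60": 2.125
    "*36/*37": 1.3

nat2:
  slow_stars: ["*5", "*6", "*7", "*14"]
  rapid_stars: ["*4", "*12", "*13"]
  fragment_length: 200        # bp; SRS ambiguity criterion

ta_repeat:
  min_reads_per_mode: 3       # repeat-count modes need >=3 spanning reads
  star_by_count: {5: "*36", 6: "*1", 7: "*28", 8: "*37"}

copy_number:
  ratio_tolerance: 0.3        # max |ratio*2 - nearest integer| before no-call
  junction_min_reads: 3       # junction evidence threshold (hybrid and deletion)
  junction_reads_per_copy: 15 # expected junction reads per copy at nominal depth

regimes:
  SRS:
    read_length: 150
    fragment_length: 350
    depth: 100
    error_rate: 0.005
  LRS:
    read_length: 4985
    fragment_length: null
    depth: 30
    error_rate: 0.01

statistical_phasing:
  floor_frequency: 0.001      # haplotypes absent from the frequency table
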