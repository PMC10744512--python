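# Methods

This document describes the synthetic model, the calling algorithms, and the
numerical conventions used throughout the package, including where the model
deliberately emulates the behaviour of standard tools rather than
re-implementing them.

## Synthetic loci and the allele catalog

Each gene is modeled as a synthetic locus with a deterministic reference
sequence (generated from a fixed per-gene seed at catalog load, so no FASTA
fixtures are shipped) and a catalog of star alleles, each defined by a set of
variants with 1-based coordinates:

* **NAT2** — a 1-kb coding window in cDNA coordinates. Star alleles are
  defined by core SNVs at their standard cDNA positions (e.g. \*5 at 341,
  \*6 at 590, \*11 at 481, \*12 at 803, \*13 at 282), so inter-allele
  distances such as \*13–\*6 = 308 bp and \*12–\*5 = 462 bp are properties of
  the coordinate table, not free parameters.
* **UGT1A1** — a promoter/first-exon window containing a TATA-box TA
  dinucleotide repeat (reference 6 units between fixed anchor sequences) and
  two distal promoter SNVs (the \*60 allele and the \*93 marker). Repeat
  counts 5/6/7/8 map to \*36/\*1/\*28/\*37.
* **CYP2D6** — a 6.5-kb gene unit with ~23 intragenic tag SNVs (one per
  non-reference star allele), a downstream CYP2D7-like paralog used as the
  depth normalizer, and junction coordinates for hybrid (gene→paralog fusion)
  and whole-gene-deletion breakpoints. Multi-copy haplotypes (`*2 x 2`,
  `*4,*68`) are materialized as tandem gene units separated by spacers;
  hybrid units carry a single identifying tag SNV upstream of the junction.

Diplotype strings follow the usual grammar `hapA/hapB`, components separated
by commas, with copy multipliers `x N` (Unicode `×` accepted on input, ASCII
`x` emitted). Canonicalization orders components by star number and
haplotypes by a deterministic key, so string equality of canonical forms is
diplotype equality.

## Read simulation

Two regimes are configured in `thresholds.yaml`:

| regime | reads | depth | error rate |
|--------|-------|-------|------------|
| SRS | 2 × 150 bp pairs, 350 bp fragments | 100× | 0.5 % |
| LRS | 4985 bp single reads | 30× | 1 % |

Fragment start positions are uniform over a window extended one span to the
left of the locus, and reads are clipped to the locus, giving uniform
expected coverage everywhere including the edges (the profile a locus
embedded in flanking genomic sequence shows). Substitution errors are
injected per base at the regime rate. Reads record their haplotype of origin
and true coordinates as hidden truth; callers only consume what an aligner
would provide (sequence plus a coordinate frame map).

CYP2D6 depth evidence is simulated separately as a `DepthSignal`: the
paralog-normalized depth ratio carries multiplicative noise averaged over 12
bins (the way read-depth CNV callers average per-bin ratios), and
hybrid/deletion junction-spanning reads are Poisson with mean depth/2 per
copy. Deletion-junction reads are produced **only** under the long-read
regime: the breakpoint region is treated as unmappable for short reads. This
single asymmetry is what lets a duplication in trans with a deletion look
diploid to short reads.

## Phasing

**Direct (long-read) phasing** solves minimum error correction (MEC):
heterozygous sites are grouped into blocks (connected components of read
co-observation), and each block up to 15 sites is solved exactly by
exhausting the 2^(k−1) assignments (first site fixed to reference on
haplotype A; ties resolved lexicographically). Larger blocks use a
spanning-tree seed over pairwise cis/trans vote weights followed by
read-reassignment refinement. Switch errors and Hamming errors are computed
per block, invariant to global A/B relabeling within each block.

**Statistical (short-read) phasing** emulates a population-frequency phaser:
within-block phase comes from per-read evidence (mates are deliberately not
merged), blocks are cut between heterozygous sites farther apart than a read
length, and the relative orientation of blocks is chosen to maximize the
product of population frequencies of the two induced haplotype labels
(haplotypes absent from the table receive a floor of 0.001). The shipped
NAT2 frequency table is a hand-built behavioural fixture, not a cohort
estimate: its weights are chosen so that frequency-maximizing joins produce
the characteristic short-read mis-assignments (the `*5,*11,*12` cis join is
favored; the `*6 / *13` trans split is favored over `*6,*13 / *4`). Exact
ties are broken toward the canonically smaller diplotype and flagged as
ambiguous joins.

A NAT2 diplotype is classified *ambiguous* when it is heterozygous for at
least two distinct slow alleles whose core variants lie more than one
fragment length (200 bp) apart — exactly the configurations statistical
phasing cannot resolve from a single fragment.

## Star calling

* **NAT2** — pileup genotypes at every catalog position (depth < 3 = no-call;
  alt fraction ≤ 0.25 hom-ref, ≥ 0.75 hom-alt, else het), then phasing as
  above; each haplotype's alt-coordinate set is decomposed into star labels
  most-specific-first.
* **UGT1A1** — TA repeat units are counted in reads matching the left anchor
  (≤ 1 mismatch) and confirmed by the right anchor; count modes need at least
  3 spanning reads, and more than two modes is a no-call. The \*60 SNV, when
  genotyped from pileup, replaces the reference label on its haplotype; \*60
  and \*93 genotypes are also reported as auxiliary marker calls with their
  depths.
* **CYP2D6** — gene copies come from the depth ratio (no-call when the
  doubled ratio is more than 0.3 from an integer); hybrid and deletion
  junction evidence requires ≥ 3 reads. The structural category follows the
  copy-number triplet: 2 copies without junction evidence = snv/indel, < 2 =
  deletion, > 2 = duplication, 2 + hybrid junction = hybrid, anything mixed
  (including deletion co-detected with extra copies) = composite. The
  diplotype is then assembled by apportioning tag-variant allele fractions
  over the star-carrying units (largest-remainder, at least one copy per
  observed tag, iterated to a fixed point with the hybrid copy count),
  clustering tags linked in cis by ≥ 2 reads, and splitting the clusters into
  two parental alleles. Hybrid units cannot be linked to their tandem
  partners by reads (the tandem unit exceeds the read length), so a
  link-orphaned hybrid attaches to the partner with the fewest assigned
  copies — the convention matching how hybrids trail the rearranged allele.
  A whole-gene deletion on one parental allele is inferred from junction
  evidence (long reads) or from a single remaining star unit (both regimes).

## Scoring and phenotypes

Activity scores are additive: each component contributes its allele activity
times its copy count; deletion alleles contribute 0. A small diplotype-level
override table carries the clinical scores that admit no additive
decomposition (e.g. `*2 x 2/*5` → 1.0, `*4/*41,*68` → 0.5). Alleles of
unknown function make the score indeterminate (NaN) unless an override
applies. Score bands carry explicit interval closure, because printed scores
sit exactly on boundaries: for CYP2D6, PM is AS ≤ 0.5, IM is 0.5 < AS < 1.25,
NM is 1.25 ≤ AS ≤ 2.25, UM is AS > 2.25.

NAT2 phenotypes use the slow-haplotype count: a haplotype is slow if it
carries any of \*5, \*6, \*7, \*14; zero/one/two slow haplotypes give
rapid/intermediate/slow acetylator (RA/IA/SA).

## Concordance and tallies

Two call sets for one sample are compared at three levels, strictest first:
**haplotype** (diplotypes agree for every gene *and* every auxiliary promoter
marker genotype agrees — a marker genotyped by one method but hom-ref or
no-call at low depth in the other breaks this level), **diplotype**
(canonical string equality per gene), and **phenotype** (label equality).

Numerical conventions, chosen to match the bundled study tables and applied
consistently: concordance percentages are **truncated** to one decimal
(5/13 → 38.4), while cohort spread tallies **round half-up** to one decimal
(129/411 → 31.4).

## Limitations and emulation boundaries

* The frequency table and the block model are behavioural emulations of
  statistical phasers, not trained models; they reproduce characteristic
  mis-assignment patterns, not any specific tool's output.
* The bundled thirteen-sample study call sets are transcribed reference
  tables; two of their printed NAT2 acetylator statuses are mutually
  inconsistent with any haplotype-count rule and are kept verbatim (the test
  suite documents both exceptions).
* Hybrid alleles carry one identifying tag SNV each; real hybrid breakpoint
  micro-heterogeneity, alignment artifacts, and BAM/CRAM emission are out of
  scope, as are statistical tests on concordance rates.
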