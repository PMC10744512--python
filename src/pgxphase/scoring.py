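"""Activity scoring, phenotype banding, and NAT2 acetylator classification.

The default activity model is additive: a diplotype's score is the sum over
both haplotypes of each component allele's activity value times its copy
count. A small per-gene override table supplies clinically assigned scores
for diplotypes whose printed score is not additive (a duplication in trans
with a whole-gene deletion; a nonfunctional hybrid in tandem), keyed by the
canonical diplotype string. Components with unknown activity make the score
undefined unless an override applies.

Phenotype bands carry explicit interval closure on both ends because clinical
scores sit exactly on band boundaries with inconsistent sidedness (for
CYP2D6, 0.5 is a poor metabolizer but 2.25 is still a normal metabolizer).

NAT2 is classified by slow-allele count, not by score: two slow haplotypes
give a slow acetylator, one gives intermediate, none gives rapid. A diplotype
is reported with a phasing-ambiguity caveat when it is heterozygous for at
least two distinct slow alleles whose core variants are farther apart than a
short-read fragment, since the slow/slow vs slow-in-cis distinction then
rests on inference rather than direct read evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

from .catalog import Catalog, variant_distance
from .diplotypes import Diplotype, parse_diplotype

__all__ = [
    "ScoringError",
    "ActivityResult",
    "AmbiguityCall",
    "activity_score",
    "phenotype_from_score",
    "score_diplotype",
    "acetylator_status",
    "classify_ambiguity",
]


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ActivityResult:
    gene: str
    diplotype: str  # canonical string
    score: float  # NaN when indeterminate
    phenotype: str  # band label, or "indeterminate" when unknown activities block scoring
    source: str  # additive | override | none

    @property
    def overridden(self) -> bool:
        return self.source == "override"


@dataclass(frozen=True)
class AmbiguityCall:
    ambiguous: bool
    het_slow_stars: tuple[str, ...]
    max_pair_distance: Optional[int]  # bp between farthest het slow-allele pair


def _as_diplotype(dip: Diplotype | str, gene: Optional[str], cat: Catalog) -> Diplotype:
    if isinstance(dip, Diplotype):
        return dip.canonical()
    if gene is None:
        raise ScoringError("gene required when scoring a diplotype string")
    return parse_diplotype(gene, dip).canonical()


def activity_score(dip: Diplotype | str, cat: Catalog, gene: Optional[str] = None) -> tuple[float, bool]:
    """Activity score of a diplotype; returns (score, overridden).

    The override table is consulted first with the canonical diplotype string;
    otherwise the score is the additive sum of component activities weighted
    by copy count. Deletion alleles contribute 0 by definition; components
    with unknown activity raise.
    """
    d = _as_diplotype(dip, gene, cat)
    overrides = cat.activity_overrides.get(d.gene, {})
    key = d.canonical_string
    if key in overrides:
        return float(overrides[key]), True

    total = 0.0
    for hap in (d.hapA, d.hapB):
        for comp in hap.components:
            allele = cat.allele(d.gene, comp.star)
            if allele.is_deletion:
                continue
            if allele.activity_value is None:
                raise ScoringError(
                    f"{d.gene} {key}: activity of {comp.star} is unknown and no override applies"
                )
            total += allele.activity_value * comp.copies
    return total, False


def phenotype_from_score(score: float, cat: Catalog, gene: str) -> str:
    """Metabolizer status for a score, honoring each band's interval closure."""
    bands = cat.phenotype_bands.get(gene)
    if not bands:
        raise ScoringError(f"no phenotype bands defined for {gene}")
    for band in bands:
        lo, hi = band.get("min"), band.get("max")
        lo_ok = (
            True
            if lo is None
            else (score >= lo if band.get("min_incl", False) else score > lo)
        )
        hi_ok = (
            True
            if hi is None
            else (score <= hi if band.get("max_incl", False) else score < hi)
        )
        if lo_ok and hi_ok:
            return band["label"]
    raise ScoringError(f"{gene}: score {score} falls in no phenotype band")


def score_diplotype(dip: Diplotype | str, cat: Catalog, gene: Optional[str] = None) -> ActivityResult:
    """Score a diplotype and band the result.

    A component of unknown activity with no override does not raise here: the
    result is reported with phenotype "indeterminate" (score NaN), since a
    call set must still be representable when one allele is uncharacterized.
    """
    d = _as_diplotype(dip, gene, cat)
    try:
        score, overridden = activity_score(d, cat)
    except ScoringError:
        return ActivityResult(
            gene=d.gene,
            diplotype=d.canonical_string,
            score=float("nan"),
            phenotype="indeterminate",
            source="none",
        )
    return ActivityResult(
        gene=d.gene,
        diplotype=d.canonical_string,
        score=score,
        phenotype=phenotype_from_score(score, cat, d.gene),
        source="override" if overridden else "additive",
    )


# ---------------------------------------------------------------------------
# NAT2


def acetylator_status(dip: Diplotype | str, cat: Catalog, gene: str = "NAT2") -> str:
    """Acetylator phenotype from the number of slow haplotypes.

    A haplotype is slow if any of its components is a slow allele; otherwise
    rapid. Two slow haplotypes -> slow acetylator (SA), one -> intermediate
    (IA), none -> rapid (RA).
    """
    d = _as_diplotype(dip, gene, cat)
    slow_stars = set(cat.config.get("nat2", {}).get("slow_stars", []))
    n_slow = sum(
        1 for hap in (d.hapA, d.hapB) if any(c.star in slow_stars for c in hap.components)
    )
    return {0: "RA", 1: "IA", 2: "SA"}[n_slow]


def classify_ambiguity(dip: Diplotype | str, cat: Catalog, gene: str = "NAT2") -> AmbiguityCall:
    """Phasing-ambiguity flag for a NAT2 diplotype.

    Ambiguous iff the diplotype is heterozygous for at least two distinct slow
    alleles and some pair of those alleles' core variants lies farther apart
    than a short-read fragment (configured length): only then can short reads
    not establish whether the slow variants are in cis or in trans.
    """
    d = _as_diplotype(dip, gene, cat)
    cfg = cat.config.get("nat2", {})
    slow_stars = set(cfg.get("slow_stars", []))
    frag = int(cfg.get("fragment_length", 200))

    counts: dict[str, int] = {}
    for hap in (d.hapA, d.hapB):
        for comp in hap.components:
            counts[comp.star] = counts.get(comp.star, 0) + comp.copies
    het_slow = tuple(sorted(s for s, n in counts.items() if s in slow_stars and n == 1))

    max_dist: Optional[int] = None
    if len(het_slow) >= 2:
        max_dist = max(
            variant_distance(cat, gene, a, b) for a, b in combinations(het_slow, 2)
        )
    ambiguous = max_dist is not None and max_dist > frag
    return AmbiguityCall(ambiguous=ambiguous, het_slow_stars=het_slow, max_pair_distance=max_dist)
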