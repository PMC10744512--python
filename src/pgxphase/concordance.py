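"""Cross-platform concordance of star-allele calls, and cohort spread tallies.

Two call sets for the same samples (one per sequencing method) are compared
at three levels, strictest first:

* haplotype: the diplotypes agree for every gene AND every auxiliary promoter
  marker (distal-promoter SNVs genotyped alongside the main star call) has the
  same genotype under both methods. A marker that one method genotypes and the
  other reports as hom-ref or no-call at low depth breaks haplotype
  concordance even when the diplotype itself agrees.
* diplotype: canonical diplotype equality for every gene (haplotype phase
  matters, order of the two haplotypes does not).
* phenotype: equality of the predicted phenotype labels for every gene.

Summary percentages are reported to one decimal by truncation (a sample
either is or is not concordant; the convention reports the floor of the
exact percentage). Cohort spread tallies instead round half-up, matching the
convention used for population frequency tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .catalog import Catalog, _opt, _read_tsv
from .diplotypes import parse_diplotype

__all__ = [
    "MarkerCall",
    "GeneCall",
    "CallSet",
    "ConcordanceRecord",
    "ConcordanceSummary",
    "SpreadTally",
    "load_study_callsets",
    "load_expected_concordance",
    "load_spread_table",
    "compare_callsets",
    "compare_study",
    "summarize",
    "truncate_pct",
    "half_up_pct",
    "tally_spread",
    "deletion_partner_classifier",
    "ambiguity_classifier",
]

GENES = ("CYP2D6", "UGT1A1", "NAT2")


@dataclass(frozen=True)
class MarkerCall:
    var_id: str
    genotype: str  # hom-ref | het | hom-alt | no-call
    depth: int


@dataclass(frozen=True)
class GeneCall:
    gene: str
    diplotype: str  # canonical string
    phenotype: str
    markers: tuple[MarkerCall, ...] = ()


@dataclass
class CallSet:
    sample: str
    method: str  # SRS | LRS
    calls: dict[str, GeneCall] = field(default_factory=dict)  # gene -> call


@dataclass(frozen=True)
class ConcordanceRecord:
    sample: str
    haplotype: bool
    diplotype: bool
    phenotype: bool
    discordant_genes: tuple[str, ...]
    discordant_markers: tuple[str, ...]


@dataclass(frozen=True)
class ConcordanceSummary:
    n: int
    haplotype_n: int
    diplotype_n: int
    phenotype_n: int
    haplotype_pct: float
    diplotype_pct: float
    phenotype_pct: float


@dataclass(frozen=True)
class SpreadTally:
    total: int
    by_category: dict[str, int] = field(hash=False, default_factory=dict)
    pct_by_category: dict[str, float] = field(hash=False, default_factory=dict)
    distinct_diplotypes: dict[str, int] = field(hash=False, default_factory=dict)


# ---------------------------------------------------------------------------
# loading


def _data_path(name: str, data_dir: Optional[Path]) -> Path:
    if data_dir is not None:
        return Path(data_dir) / name
    return Path(str(resources.files("pgxphase").joinpath("data/tables"))) / name


def _parse_markers(cell: str) -> tuple[MarkerCall, ...]:
    if not cell:
        return ()
    out = []
    for item in cell.split(";"):
        var_id, genotype, depth = item.split(":")
        out.append(MarkerCall(var_id, genotype, int(depth)))
    return tuple(out)


def load_study_callsets(
    cat: Catalog, data_dir: Optional[Path] = None
) -> dict[tuple[str, str], CallSet]:
    """Load the study call sets, keyed (sample, method).

    Diplotype strings are re-canonicalized through the parser so equality
    comparisons never depend on how the source table ordered haplotypes.
    """
    rows = _read_tsv(_data_path("study_callsets.tsv", data_dir))
    callsets: dict[tuple[str, str], CallSet] = {}
    for row in rows:
        key = (row["sample"], row["method"])
        cs = callsets.setdefault(key, CallSet(row["sample"], row["method"]))
        gene = row["gene"]
        dip = parse_diplotype(gene, row["diplotype"]).canonical_string
        cs.calls[gene] = GeneCall(
            gene=gene,
            diplotype=dip,
            phenotype=row["phenotype"],
            markers=_parse_markers(_opt(row.get("aux_markers", "")) or ""),
        )
    return callsets


def load_expected_concordance(data_dir: Optional[Path] = None) -> dict[str, dict[str, bool]]:
    rows = _read_tsv(_data_path("study_concordance_expected.tsv", data_dir))
    return {
        r["sample"]: {level: r[level] == "yes" for level in ("haplotype", "diplotype", "phenotype")}
        for r in rows
    }


def load_spread_table(name: str, data_dir: Optional[Path] = None) -> list[dict]:
    """Load a cohort spread table (category / diplotype / count rows)."""
    rows = _read_tsv(_data_path(name, data_dir))
    for r in rows:
        r["count"] = int(r["count"])
    return rows


# ---------------------------------------------------------------------------
# comparison


def _marker_map(call: GeneCall) -> dict[str, str]:
    return {m.var_id: m.genotype for m in call.markers}


def compare_callsets(
    a: CallSet, b: CallSet, genes: Optional[tuple[str, ...]] = None
) -> ConcordanceRecord:
    """Concordance of two call sets for one sample at the three levels."""
    if a.sample != b.sample:
        raise ValueError(f"different samples: {a.sample} vs {b.sample}")
    if genes is None:
        if set(a.calls) != set(b.calls):
            only = sorted(set(a.calls) ^ set(b.calls))
            raise ValueError(f"genes present on one side only: {only}")
        genes = tuple(g for g in GENES if g in a.calls)
    discordant_genes = []
    discordant_markers = []
    phen_ok = True
    for gene in genes:
        ca, cb = a.calls[gene], b.calls[gene]
        if ca.diplotype != cb.diplotype:
            discordant_genes.append(gene)
        if ca.phenotype != cb.phenotype:
            phen_ok = False
        ma, mb = _marker_map(ca), _marker_map(cb)
        for var_id in sorted(set(ma) | set(mb)):
            if ma.get(var_id, "hom-ref") != mb.get(var_id, "hom-ref"):
                discordant_markers.append(var_id)
    dip_ok = not discordant_genes
    hap_ok = dip_ok and not discordant_markers
    return ConcordanceRecord(
        sample=a.sample,
        haplotype=hap_ok,
        diplotype=dip_ok,
        phenotype=phen_ok,
        discordant_genes=tuple(discordant_genes),
        discordant_markers=tuple(discordant_markers),
    )


def compare_study(
    callsets: dict[tuple[str, str], CallSet], genes: Optional[tuple[str, ...]] = None
) -> list[ConcordanceRecord]:
    samples = sorted(
        {s for s, _ in callsets}, key=lambda s: (len(s), s)  # Sample 2 before Sample 10
    )
    return [
        compare_callsets(callsets[(s, "SRS")], callsets[(s, "LRS")], genes=genes)
        for s in samples
    ]


# ---------------------------------------------------------------------------
# summaries


def truncate_pct(numerator: int, denominator: int) -> float:
    """Percentage truncated (not rounded) to one decimal place."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    return math.floor(numerator / denominator * 1000) / 10


def half_up_pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal place."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    return math.floor(numerator / denominator * 1000 + 0.5) / 10


def summarize(records: list[ConcordanceRecord]) -> ConcordanceSummary:
    n = len(records)
    h = sum(r.haplotype for r in records)
    d = sum(r.diplotype for r in records)
    p = sum(r.phenotype for r in records)
    return ConcordanceSummary(
        n=n,
        haplotype_n=h,
        diplotype_n=d,
        phenotype_n=p,
        haplotype_pct=truncate_pct(h, n),
        diplotype_pct=truncate_pct(d, n),
        phenotype_pct=truncate_pct(p, n),
    )


def tally_spread(
    rows: list[dict],
    classifier: Optional[callable] = None,
    cohort_size: Optional[int] = None,
) -> SpreadTally:
    """Tally a cohort spread table by category.

    Each row carries a diplotype and its count; the category comes from the
    row's own "category" column unless a classifier callable (row -> category
    label) is supplied. Percentages use the table's own total unless an
    explicit cohort size is given (categories drawn from a larger genotyped
    cohort), and round half-up to one decimal.
    """
    by_cat: dict[str, int] = {}
    distinct: dict[str, int] = {}
    for r in rows:
        category = classifier(r) if classifier is not None else r["category"]
        by_cat[category] = by_cat.get(category, 0) + r["count"]
        distinct[category] = distinct.get(category, 0) + 1
    total = sum(by_cat.values())
    denom = cohort_size if cohort_size is not None else total
    pct = {c: half_up_pct(n, denom) for c, n in by_cat.items()} if total else {}
    return SpreadTally(
        total=total, by_category=by_cat, pct_by_category=pct, distinct_diplotypes=distinct
    )


# ---------------------------------------------------------------------------
# row classifiers for tally_spread


def deletion_partner_classifier(cat: Catalog, gene: str = "CYP2D6"):
    """Classify a whole-gene-deletion diplotype by its partner allele's function.

    The partner is the haplotype that is not the deletion allele; its function
    class aggregates over components: any unknown component makes the partner
    "unknown function", otherwise all-normal is "normal function" and anything
    else is "decreased or no function".
    """

    def classify(row: dict) -> str:
        dip = parse_diplotype(gene, row["diplotype"])
        partner = None
        for hap in (dip.hapA, dip.hapB):
            if not any(cat.allele(gene, c.star).is_deletion for c in hap.components):
                partner = hap
        if partner is None:
            raise ValueError(f"{row['diplotype']}: no non-deletion partner haplotype")
        classes = {cat.allele(gene, c.star).function_class for c in partner.components}
        if "unknown" in classes:
            return "unknown function"
        if classes == {"normal"}:
            return "normal function"
        return "decreased or no function"

    return classify


def ambiguity_classifier(cat: Catalog, gene: str = "NAT2"):
    """Classify a NAT2 diplotype row as ambiguous / non-ambiguous."""
    from .scoring import classify_ambiguity

    def classify(row: dict) -> str:
        call = classify_ambiguity(row["diplotype"], cat, gene)
        return "ambiguous" if call.ambiguous else "non-ambiguous"

    return classify
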