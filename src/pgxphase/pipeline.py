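"""End-to-end orchestration: simulate reads, genotype, phase, call, score.

One call per (gene, sequencing method). The method determines both the read
regime and the phasing strategy:

* NAT2 — long reads phase directly (MEC over read observations); short reads
  phase within read-length blocks and join blocks by population haplotype
  frequency, the behaviour that produces the documented statistical-phasing
  mis-assignments.
* UGT1A1 — the promoter TA repeat is genotyped by anchored counting; the
  distal-promoter SNVs (*60 and the *93 marker) are genotyped from pileup and
  the *60 allele replaces the reference label on its haplotype.
* CYP2D6 — copy number and structure come from the paralog-normalized depth
  ratio plus junction reads; the diplotype is assembled from tag-variant
  allele fractions and read-backed cis links. Deletion-junction evidence
  exists only in the long-read channel, so a duplication in trans with a
  whole-gene deletion looks diploid to short reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .catalog import Catalog
from .concordance import CallSet, GeneCall, MarkerCall
from .diplotypes import Diplotype, Haplotype, StarComponent, parse_diplotype, star_sort_key
from .phasing import HetSite, PhaseResult, extract_observations, phase_direct, phase_statistical
from .scoring import ActivityResult, acetylator_status, classify_ambiguity, score_diplotype
from .simulate import DepthSignal, RegimeConfig, SimReadSet, TruthSample, simulate_sample
from .star_calling import (
    CNProfile,
    StarCallError,
    TARepeatCall,
    assemble_diplotype,
    assign_stars,
    call_cn_structure,
    collect_tag_evidence,
    count_ta_repeats,
)

logger = logging.getLogger(__name__)

__all__ = ["GeneResult", "PileupGenotypes", "genotype_pileup", "call_gene", "call_sample"]

MIN_GENOTYPE_DEPTH = 3  # below this a site is a no-call ("absence of coverage")
HOM_REF_MAX_FRACTION = 0.25
HOM_ALT_MIN_FRACTION = 0.75


@dataclass
class PileupGenotypes:
    """Per-site diploid genotypes from raw allele counts."""

    genotypes: dict[int, str]  # coord -> hom-ref | het | hom-alt | no-call
    depths: dict[int, int]

    def coords_with(self, genotype: str) -> list[int]:
        return sorted(c for c, g in self.genotypes.items() if g == genotype)


@dataclass
class GeneResult:
    gene: str
    method: str
    truth: TruthSample
    call: GeneCall
    activity: Optional[ActivityResult]
    details: dict = field(default_factory=dict)


def genotype_pileup(readset: SimReadSet, cat: Catalog, gene: str) -> PileupGenotypes:
    """Diploid genotypes at every catalog position from base-call fractions."""
    ev = collect_tag_evidence(readset, cat, gene)
    genotypes: dict[int, str] = {}
    depths: dict[int, int] = {}
    for coord in sorted(ev.ref_counts):
        depth = ev.ref_counts[coord] + ev.alt_counts[coord]
        depths[coord] = depth
        if depth < MIN_GENOTYPE_DEPTH:
            genotypes[coord] = "no-call"
            continue
        frac = ev.alt_counts[coord] / depth
        if frac <= HOM_REF_MAX_FRACTION:
            genotypes[coord] = "hom-ref"
        elif frac >= HOM_ALT_MIN_FRACTION:
            genotypes[coord] = "hom-alt"
        else:
            genotypes[coord] = "het"
    return PileupGenotypes(genotypes, depths)


def _hap_label_to_haplotype(label: str, ref_star: str) -> Haplotype:
    stars = label.split(",") if label else [ref_star]
    return Haplotype(tuple(StarComponent(s) for s in stars))


# ---------------------------------------------------------------------------
# per-gene callers


def _call_nat2(
    readset: SimReadSet, cat: Catalog, method: str, rng: np.random.Generator
) -> tuple[Diplotype, dict]:
    gene = "NAT2"
    pileup = genotype_pileup(readset, cat, gene)
    het_coords = pileup.coords_with("het")
    hom_alts = pileup.coords_with("hom-alt")
    variants = {v.coord: v for v in cat.variants_for(gene)}
    sites = [HetSite(c, variants[c].ref, variants[c].alt) for c in het_coords]
    ref_star = cat.reference_star(gene)

    if method == "LRS":
        obs = extract_observations(readset, sites)
        pr = phase_direct(obs, len(sites))
        hapA = {c for i, c in enumerate(het_coords) if pr.assignment[i] == 1} | set(hom_alts)
        hapB = {c for i, c in enumerate(het_coords) if pr.assignment[i] == 0} | set(hom_alts)
        dip = Diplotype(
            gene,
            _hap_label_to_haplotype(",".join(assign_stars(hapA, cat, gene)), ref_star),
            _hap_label_to_haplotype(",".join(assign_stars(hapB, cat, gene)), ref_star),
        ).canonical()
        return dip, {"phase": pr, "pileup": pileup}

    # SRS: within-block read-backed phase, frequency-driven joins across blocks
    obs = extract_observations(readset, sites, merge_pairs=False)
    pr = phase_direct(obs, len(sites))
    blocks = [[(het_coords[i], pr.assignment[i]) for i in block] for block in pr.blocks]
    sp = phase_statistical(blocks, hom_alts, cat, gene, rng=None)
    la, lb = sp.hap_labels
    dip = Diplotype(
        gene,
        _hap_label_to_haplotype(la, ref_star),
        _hap_label_to_haplotype(lb, ref_star),
    ).canonical()
    return dip, {"phase": sp, "pileup": pileup, "blocks": blocks}


def _call_ugt1a1(
    readset: SimReadSet, cat: Catalog, method: str
) -> tuple[Diplotype, tuple[MarkerCall, ...], TARepeatCall, dict]:
    gene = "UGT1A1"
    ta = count_ta_repeats(readset, cat, gene)
    pileup = genotype_pileup(readset, cat, gene)

    haps: list[list[str]] = [[ta.stars[0]], [ta.stars[1]]]
    snv_alleles = [
        a
        for a in cat.alleles_for(gene)
        if a.defining_variants and not a.is_marker and a.ta_repeats is None
    ]
    markers: list[MarkerCall] = []
    for allele in sorted(snv_alleles, key=lambda a: star_sort_key(a.name)):
        var = cat.variant(gene, next(iter(allele.defining_variants)))
        gt = pileup.genotypes.get(var.coord, "no-call")
        markers.append(MarkerCall(var.var_id, gt, pileup.depths.get(var.coord, 0)))
        copies = {"hom-ref": 0, "no-call": 0, "het": 1, "hom-alt": 2}[gt]
        for _ in range(copies):
            # the SNV allele replaces the reference label on its haplotype
            target = next((h for h in haps if "*1" in h), None)
            if target is not None:
                target[target.index("*1")] = allele.name
            else:
                min(haps, key=len).append(allele.name)
    for allele in cat.alleles_for(gene):
        if not allele.is_marker:
            continue
        var = cat.variant(gene, next(iter(allele.defining_variants)))
        gt = pileup.genotypes.get(var.coord, "no-call")
        markers.append(MarkerCall(var.var_id, gt, pileup.depths.get(var.coord, 0)))

    dip = Diplotype(
        gene,
        Haplotype(tuple(StarComponent(s) for s in sorted(haps[0], key=star_sort_key))),
        Haplotype(tuple(StarComponent(s) for s in sorted(haps[1], key=star_sort_key))),
    ).canonical()
    markers.sort(key=lambda m: m.var_id)
    return dip, tuple(markers), ta, {"pileup": pileup}


def _call_cyp2d6(
    readset: SimReadSet, signal: DepthSignal, cat: Catalog, regime: RegimeConfig
) -> tuple[Diplotype, CNProfile, dict]:
    gene = "CYP2D6"
    profile = call_cn_structure(signal, regime, cat)
    evidence = collect_tag_evidence(readset, cat, gene)
    dip = assemble_diplotype(profile, evidence, cat, gene)
    return dip, profile, {"evidence": evidence}


# ---------------------------------------------------------------------------
# orchestration


def call_gene(
    gene: str,
    truth_diplotype: Diplotype | str,
    method: str,
    cat: Catalog,
    rng: np.random.Generator,
    sample_id: str = "sim",
) -> GeneResult:
    """Simulate one sample for a gene and call it back with the given method."""
    if gene not in ("CYP2D6", "UGT1A1", "NAT2"):
        raise ValueError(f"unsupported gene {gene}")
    if isinstance(truth_diplotype, str):
        truth_diplotype = parse_diplotype(gene, truth_diplotype)
    regime = RegimeConfig.from_catalog(cat, method)
    truth, readset, signal = simulate_sample(truth_diplotype, cat, regime, rng, sample_id)

    markers: tuple[MarkerCall, ...] = ()
    details: dict = {}
    if gene == "NAT2":
        dip, details = _call_nat2(readset, cat, method, rng)
        phenotype = acetylator_status(dip, cat)
        activity = None
        details["ambiguity"] = classify_ambiguity(dip, cat)
    elif gene == "UGT1A1":
        dip, markers, ta, details = _call_ugt1a1(readset, cat, method)
        activity = score_diplotype(dip, cat)
        phenotype = activity.phenotype
        details["ta"] = ta
    elif gene == "CYP2D6":
        if signal is None:
            raise StarCallError("CYP2D6 calling requires a depth signal")
        dip, profile, details = _call_cyp2d6(readset, signal, cat, regime)
        activity = score_diplotype(dip, cat)
        phenotype = activity.phenotype
        details["cn_profile"] = profile
    else:
        raise ValueError(f"unsupported gene {gene}")

    call = GeneCall(
        gene=gene, diplotype=dip.canonical_string, phenotype=phenotype, markers=markers
    )
    return GeneResult(
        gene=gene, method=method, truth=truth, call=call, activity=activity, details=details
    )


def call_sample(
    diplotypes: dict[str, Diplotype | str],
    method: str,
    cat: Catalog,
    seed: int,
    sample_id: str = "sim",
) -> tuple[CallSet, dict[str, GeneResult]]:
    """Run the full per-gene pipeline for one sample under one method."""
    rng = np.random.default_rng(seed)
    cs = CallSet(sample=sample_id, method=method)
    results: dict[str, GeneResult] = {}
    for gene in sorted(diplotypes):
        res = call_gene(gene, diplotypes[gene], method, cat, rng, sample_id)
        cs.calls[gene] = res.call
        results[gene] = res
    return cs, results
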