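"""Star-allele assignment, promoter-repeat genotyping, and CYP2D6 structure calling.

Three callers live here, one per evidence channel:

* ``assign_stars`` translates a haplotype's set of alternate-allele positions
  into its star-allele composition by maximal subset matching against the
  allele definitions.
* ``count_ta_repeats`` genotypes the UGT1A1 promoter TA repeat by anchored
  counting on reads that span the whole repeat, then clusters per-read counts
  into at most two supported modes.
* ``call_cn_structure`` and ``assemble_diplotype`` invert the CYP2D6 depth,
  junction-read and tag-variant evidence into a structural category and a
  multi-copy diplotype. The diploid read-backed phaser does not apply when a
  haplotype carries several gene copies, so assembly instead combines
  allele-fraction copy estimates with cis linkage observed on single reads.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .catalog import Catalog, CatalogError
from .diplotypes import Diplotype, Haplotype, StarComponent, star_sort_key

logger = logging.getLogger(__name__)

__all__ = [
    "StarCallError",
    "TARepeatCall",
    "CNProfile",
    "TagEvidence",
    "assign_stars",
    "count_ta_repeats",
    "call_cn_structure",
    "collect_tag_evidence",
    "assemble_diplotype",
]


class StarCallError(ValueError):
    pass


# ---------------------------------------------------------------------------
# star assignment from variant content


def assign_stars(alt_coords: set[int] | frozenset[int], cat: Catalog, gene: str) -> list[str]:
    """Star components of a haplotype given the coords where it carries the alt.

    Alleles are matched most-specific-first (more defining variants first), so
    a multi-variant allele is preferred over the separate single-variant
    alleles it contains when both explain the same positions. Positions left
    unexplained raise. The empty set maps to an empty list (reference allele,
    rendered by the caller).
    """
    remaining = set(alt_coords)
    candidates = []
    for allele in cat.alleles_for(gene):
        if allele.is_reference or allele.is_deletion or allele.is_hybrid or allele.is_marker:
            continue
        if not allele.defining_variants:
            continue
        if allele.ta_repeats is not None:
            continue  # repeat alleles are called from repeat counts, not SNVs
        coords = frozenset(cat.variant(gene, v).coord for v in allele.defining_variants)
        candidates.append((allele.name, coords))
    candidates.sort(key=lambda c: (-len(c[1]), star_sort_key(c[0])))

    chosen: list[str] = []
    for name, coords in candidates:
        if coords and coords <= remaining:
            chosen.append(name)
            remaining -= coords
    if remaining:
        raise StarCallError(f"{gene}: no star allele explains alt positions {sorted(remaining)}")
    return sorted(chosen, key=star_sort_key)


# ---------------------------------------------------------------------------
# promoter TA-repeat genotyping


@dataclass(frozen=True)
class TARepeatCall:
    counts: tuple[int, int]  # repeat units per haplotype, ascending
    stars: tuple[str, str]
    n_spanning_reads: int
    histogram: dict[int, int] = field(hash=False, default_factory=dict)


def _find_anchor(seq: str, anchor: str, max_mismatches: int = 1) -> int:
    """First position of ``anchor`` in ``seq`` allowing up to one mismatch."""
    idx = seq.find(anchor)  # exact hit first: the overwhelmingly common case
    if idx >= 0:
        return idx
    n, m = len(seq), len(anchor)
    for i in range(n - m + 1):
        mm = 0
        for a, b in zip(seq[i : i + m], anchor):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        if mm <= max_mismatches:
            return i
    return -1


def _matches_anchor(fragment: str, anchor: str, max_mismatches: int = 1) -> bool:
    if len(fragment) != len(anchor):
        return False
    return sum(a != b for a, b in zip(fragment, anchor)) <= max_mismatches


def count_ta_repeats(readset, cat: Catalog, gene: str = "UGT1A1") -> TARepeatCall:
    """Genotype the promoter TA repeat by anchored counting of spanning reads.

    Only reads containing the full left anchor, a run of whole repeat units,
    and the full right anchor contribute; anything else (reads clipped inside
    the repeat, reads with errors in an anchor) is discarded rather than
    risking an off-by-one count. Per-read counts are pooled into modes; a mode
    needs the configured minimum support. The top two modes (ties resolved
    toward the lower repeat count) form the genotype; one mode means a
    homozygous call.
    """
    model = cat.gene_models[gene]
    locus = model.repeat_locus
    if locus is None:
        raise StarCallError(f"{gene} has no repeat locus")
    cfg = cat.config.get("ta_repeat", {})
    min_reads = int(cfg.get("min_reads_per_mode", 3))
    star_by_count = {int(k): v for k, v in cfg.get("star_by_count", {}).items()}

    histogram: Counter[int] = Counter()
    unit = locus.unit
    for read in readset.reads:
        seq = read.sequence
        idx = _find_anchor(seq, locus.anchor_left)
        if idx < 0:
            continue
        pos = idx + len(locus.anchor_left)
        n = 0
        while seq[pos : pos + len(unit)] == unit:
            n += 1
            pos += len(unit)
        if not _matches_anchor(seq[pos : pos + len(locus.anchor_right)], locus.anchor_right):
            continue  # right anchor not confirmed: read may be clipped or errored
        histogram[n] += 1

    modes = sorted(
        (c for c in histogram if histogram[c] >= min_reads),
        key=lambda c: (-histogram[c], c),
    )
    n_spanning = sum(histogram.values())
    if not modes:
        raise StarCallError(
            f"{gene}: no repeat-count mode reaches {min_reads} spanning reads "
            f"({n_spanning} spanning reads total): absence of coverage"
        )
    if len(modes) > 2:
        raise StarCallError(
            f"{gene}: more than two repeat-count modes above threshold: "
            + ", ".join(f"TA{c} x{histogram[c]}" for c in sorted(modes))
        )
    top = sorted(modes[:2]) if len(modes) >= 2 else [modes[0], modes[0]]
    stars = []
    for c in top:
        if c not in star_by_count:
            raise StarCallError(f"{gene}: no star allele defined for TA{c}")
        stars.append(star_by_count[c])
    return TARepeatCall(
        counts=(top[0], top[1]),
        stars=(stars[0], stars[1]),
        n_spanning_reads=n_spanning,
        histogram=dict(sorted(histogram.items())),
    )


# ---------------------------------------------------------------------------
# CYP2D6 copy number and structural category


@dataclass(frozen=True)
class CNProfile:
    gene_copies: int  # full-length gene copies (deleted alleles contribute 0)
    paralog_copies: int
    hybrid_copies: int
    has_deletion: bool
    category: str  # snv/indel | deletion | duplication | hybrid | composite

    @property
    def triplet(self) -> str:
        return f"{self.gene_copies}/{self.paralog_copies}/{self.hybrid_copies}"

    @property
    def star_units(self) -> int:
        """Star-carrying sequence units: full copies plus hybrid copies."""
        return self.gene_copies + self.hybrid_copies


def call_cn_structure(signal, regime, cat: Catalog, paralog_copies: int = 2) -> CNProfile:
    """Classify CYP2D6 structure from depth ratio and junction reads.

    The paralog-normalized depth ratio yields the full-copy count (no-call if
    it falls between integers by more than the tolerance). Hybrid- and
    deletion-junction reads are compared against the expected junction yield
    per copy at the regime's depth. Deletion-junction evidence only exists in
    the long-read channel; under short reads a deletion co-occurring with a
    duplication restores a diploid-looking ratio and goes undetected.
    """
    cfg = cat.config.get("copy_number", {})
    tolerance = float(cfg.get("ratio_tolerance", 0.3))
    min_reads = int(cfg.get("junction_min_reads", 3))
    per_copy = float(regime.depth) / 2.0

    doubled = signal.gene_ratio * paralog_copies
    gene_copies = int(round(doubled))
    if abs(doubled - gene_copies) > tolerance:
        raise StarCallError(f"copy-number no-call: normalized ratio {signal.gene_ratio:.3f}")
    hybrid_copies = 0
    if signal.hybrid_junction_reads >= min_reads:
        hybrid_copies = max(1, int(round(signal.hybrid_junction_reads / per_copy)))
    has_deletion = signal.deletion_junction_reads >= min_reads

    duplication_present = gene_copies > 2 or (has_deletion and gene_copies >= 2)
    if hybrid_copies and gene_copies == 2 and not has_deletion:
        category = "hybrid"
    elif hybrid_copies:
        category = "composite"
    elif has_deletion and duplication_present:
        # a deletion co-detected with extra copies on the partner allele
        category = "composite"
    elif duplication_present:
        category = "duplication"
    elif gene_copies < 2 or has_deletion:
        category = "deletion"
    else:
        category = "snv/indel"
    return CNProfile(gene_copies, paralog_copies, hybrid_copies, has_deletion, category)


# ---------------------------------------------------------------------------
# tag-variant evidence and multi-copy assembly


@dataclass
class TagEvidence:
    """Per-site allele counts and read-backed cis links between tag variants."""

    ref_counts: dict[int, int]  # gene-frame coord -> reference base calls
    alt_counts: dict[int, int]
    links: dict[frozenset[int], int]  # {coordA, coordB} -> reads carrying both alts


def collect_tag_evidence(readset, cat: Catalog, gene: str) -> TagEvidence:
    """Pile up reads over the tag-variant positions.

    Every copy a read crosses counts separately, so in a multi-copy haplotype
    the alternate-allele fraction at a position estimates (copies carrying the
    alt) / (total star-carrying units). A read showing the alternate allele at
    two positions links the corresponding stars in cis, since a read always
    derives from a single parental allele.
    """
    variants = {v.coord: v for v in cat.variants_for(gene)}
    ref_counts: dict[int, int] = {c: 0 for c in variants}
    alt_counts: dict[int, int] = {c: 0 for c in variants}
    links: Counter[frozenset[int]] = Counter()
    for read in readset.reads:
        read_end = read.start + read.length - 1
        alts_seen: set[int] = set()
        for seg in readset.frame_maps[read.haplotype_of_origin]:
            if seg.source != "gene":
                continue
            if seg.hap_end < read.start or seg.hap_start > read_end:
                continue
            for coord, var in variants.items():
                if not (seg.gene_start <= coord <= seg.gene_start + seg.length - 1):
                    continue
                hap_pos = seg.hap_start + (coord - seg.gene_start)
                if not (read.start <= hap_pos <= read_end):
                    continue
                base = read.sequence[hap_pos - read.start]
                if base == var.ref:
                    ref_counts[coord] += 1
                elif base == var.alt:
                    alt_counts[coord] += 1
                    alts_seen.add(coord)
        for a in alts_seen:
            for b in alts_seen:
                if a < b:
                    links[frozenset((a, b))] += 1
    return TagEvidence(ref_counts, alt_counts, dict(links))


def _star_of_coord(cat: Catalog, gene: str, coord: int) -> str:
    for allele in cat.alleles_for(gene):
        if allele.is_reference or allele.is_marker:
            continue
        coords = {cat.variant(gene, v).coord for v in allele.defining_variants}
        if coords == {coord}:
            return allele.name
    raise StarCallError(f"{gene}: position {coord} tags no star allele")


def assemble_diplotype(
    profile: CNProfile,
    evidence: TagEvidence,
    cat: Catalog,
    gene: str = "CYP2D6",
    min_link_reads: int = 2,
    min_alt_fraction: float = 0.1,
) -> Diplotype:
    """Assemble a multi-copy diplotype from structure and tag evidence.

    Copy counts per star come from rounding the alternate-allele fraction
    times the number of star-carrying units. Stars linked in cis by reads are
    grouped into one haplotype; a detected whole-gene deletion places the
    deletion allele alone on the second haplotype (the partner then carries
    every observed unit); units explained by no tag variant become
    reference-allele copies. The grouped components must resolve into exactly
    two parental alleles.

    Tandem units are longer than any read, so a hybrid copy is usually not
    read-linkable to its full-length partner. An unattached hybrid group is
    then assigned by a fixed rule: to the candidate partner with the fewest
    copies (hybrids arise by unequal crossover next to a single partner copy,
    not inside an amplified allele), ties broken toward the higher-numbered
    allele (derived alleles are the typical rearrangement partners). This is
    a deterministic modeling convention, not read evidence.
    """
    # alternate-allele fraction per eligible tag star
    fractions: dict[str, float] = {}
    for coord in sorted(evidence.alt_counts):
        total = evidence.alt_counts[coord] + evidence.ref_counts[coord]
        if total == 0:
            continue
        frac = evidence.alt_counts[coord] / total
        if frac < min_alt_fraction:
            continue
        fractions[_star_of_coord(cat, gene, coord)] = frac

    hybrid_stars = {s for s in fractions if cat.allele(gene, s).is_hybrid}
    if bool(hybrid_stars) != bool(profile.hybrid_copies):
        raise StarCallError(
            f"hybrid-junction evidence ({profile.hybrid_copies} copies) does not match "
            f"hybrid tag variants ({sorted(hybrid_stars)})"
        )

    # Copy counts by largest-remainder apportionment of the fractions over the
    # star-carrying units: every eligible star gets at least one copy, and the
    # total is constrained to the unit count, which absorbs per-site sampling
    # noise that independent rounding would turn into impossible copy sums.
    # Hybrid copies do not register in the depth ratio's full-copy count, so
    # the unit total is iterated to a fixed point with the hybrid copies.
    def apportion(units: int) -> dict[str, int]:
        quotas = {s: fractions[s] * units for s in fractions}
        ref_quota = max(0.0, units - sum(quotas.values()))
        copies = {s: max(1, int(q)) for s, q in quotas.items()}
        copies["__ref__"] = int(ref_quota)
        while sum(copies.values()) > units:  # floors overflow: trim the weakest quota
            shrinkable = [s for s in copies if copies[s] > (1 if s != "__ref__" else 0)]
            if not shrinkable:
                raise StarCallError(
                    f"tag variants imply more copies than the {units} units present"
                )
            victim = min(
                shrinkable,
                key=lambda s: (quotas.get(s, ref_quota) - copies[s], s == "__ref__"),
            )
            copies[victim] -= 1
        remainders = {s: quotas[s] - copies[s] for s in quotas}
        remainders["__ref__"] = ref_quota - copies["__ref__"]
        order = sorted(
            remainders,
            key=lambda s: (-remainders[s], s == "__ref__", star_sort_key(s) if s != "__ref__" else (0, "")),
        )
        i = 0
        while sum(copies.values()) < units:
            copies[order[i % len(order)]] += 1
            i += 1
        return copies

    hybrid_total = len(hybrid_stars)  # start: one copy per observed hybrid allele
    for _ in range(6):
        units = profile.gene_copies + hybrid_total
        if units <= 0:
            raise StarCallError("no star-carrying units to assemble")
        allocation = apportion(units)
        new_total = sum(allocation[s] for s in hybrid_stars)
        if new_total == hybrid_total:
            break
        hybrid_total = new_total

    star_copies = {s: c for s, c in allocation.items() if s != "__ref__" and c > 0}
    if allocation.get("__ref__", 0) > 0:
        star_copies[cat.reference_star(gene)] = allocation["__ref__"]

    # cis clusters from read-backed links
    coord_of = {}
    for star in star_copies:
        allele = cat.allele(gene, star)
        if allele.defining_variants:
            coord_of[star] = cat.variant(gene, next(iter(allele.defining_variants))).coord
    parent = {s: s for s in star_copies}

    def find(s: str) -> str:
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    for pair, n in evidence.links.items():
        if n < min_link_reads:
            continue
        stars = [s for s, c in coord_of.items() if c in pair]
        if len(stars) == 2:
            ra, rb = find(stars[0]), find(stars[1])
            if ra != rb:
                parent[ra] = rb

    clusters: dict[str, list[str]] = {}
    for star in star_copies:
        clusters.setdefault(find(star), []).append(star)
    groups = sorted(
        (sorted(members, key=star_sort_key) for members in clusters.values()),
        key=lambda g: star_sort_key(g[0]),
    )

    def hap(members: list[str], copies: Optional[dict[str, int]] = None) -> Haplotype:
        copies = copies or star_copies
        return Haplotype(tuple(StarComponent(s, copies[s]) for s in members))

    deletion_star = next((a.name for a in cat.alleles_for(gene) if a.is_deletion), None)
    if profile.has_deletion or units == 1:
        # junction-read evidence, or a single total unit (depth alone implies
        # a whole-gene deletion on the other allele, detectable by any regime)
        if deletion_star is None:
            raise StarCallError(f"{gene}: deletion evidence but no deletion allele defined")
        # the deleted allele contributes nothing: the partner carries every unit
        partner = sorted({s for g in groups for s in g}, key=star_sort_key)
        hapA = hap(partner)
        hapB = Haplotype((StarComponent(deletion_star, 1),))
        return Diplotype(gene, hapA, hapB).canonical()

    if len(groups) > 2:
        hybrid_groups = [g for g in groups if all(cat.allele(gene, s).is_hybrid for s in g)]
        partners = [g for g in groups if g not in hybrid_groups]
        if hybrid_groups and len(partners) == 2:
            for hg in hybrid_groups:
                target = min(
                    partners,
                    key=lambda g: (sum(star_copies[s] for s in g), -star_sort_key(g[0])[0]),
                )
                target.extend(hg)
                target.sort(key=star_sort_key)
            groups = partners

    if len(groups) == 2:
        return Diplotype(gene, hap(groups[0]), hap(groups[1])).canonical()
    if len(groups) == 1 and len(groups[0]) == 1:
        star = groups[0][0]
        total = star_copies[star]
        if total % 2 == 0:
            half = total // 2
            return Diplotype(
                gene,
                Haplotype((StarComponent(star, half),)),
                Haplotype((StarComponent(star, half),)),
            ).canonical()
    raise StarCallError(
        f"cannot resolve {sum(star_copies.values())} copies of "
        f"{sorted(star_copies, key=star_sort_key)} into two alleles"
    )
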