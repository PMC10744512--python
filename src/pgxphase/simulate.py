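"""Diploid truth-sample construction and read simulation.

Two sequencing regimes are modeled. The short-read regime (SRS) emits paired
150 bp reads from the two ends of fixed-length 350 bp fragments at high depth
with a sub-1% substitution error rate. The long-read regime (LRS) emits
single ~5 kb high-accuracy reads at 15-30x depth with a 1% substitution rate.
Reads carry their true coordinates and haplotype of origin; no aligner is run
anywhere in the pipeline (downstream callers receive the frame map an aligner
would reconstruct).

Multi-copy CYP2D6 haplotypes are materialized as tandem gene-unit copies
separated by a fixed intergenic spacer; hybrid star components splice the
CYP2D7 paralog sequence downstream of the junction. Copy-number and junction
evidence is modeled as a separate normalized depth signal
(:func:`simulate_depth_profile`) — depth, not assembly, is the CNV channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .catalog import Catalog, GeneModel
from .diplotypes import Diplotype, Haplotype, parse_diplotype

__all__ = [
    "RegimeConfig",
    "FrameSegment",
    "MaterializedHaplotype",
    "TruthSample",
    "SimRead",
    "SimReadSet",
    "CNTruth",
    "DepthSignal",
    "sample_diplotype",
    "materialize_haplotypes",
    "simulate_reads",
    "simulate_depth_profile",
    "simulate_sample",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RegimeConfig:
    """Sequencing-regime parameters (read geometry, depth, error rate)."""

    name: str  # "SRS" | "LRS"
    read_length: int
    depth: float
    error_rate: float
    fragment_length: Optional[int] = None  # paired regime only

    def __post_init__(self) -> None:
        if self.read_length <= 0 or self.depth <= 0:
            raise ValueError("read_length and depth must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error rate must be in [0, 1)")
        if self.paired and self.fragment_length < 2 * self.read_length:
            raise ValueError("fragment must fit two reads")

    @property
    def paired(self) -> bool:
        return self.fragment_length is not None

    @classmethod
    def from_catalog(cls, cat: Catalog, name: str, **overrides) -> "RegimeConfig":
        raw = dict(cat.config["regimes"][name])
        raw.update(overrides)
        return cls(
            name=name,
            read_length=int(raw["read_length"]),
            depth=float(raw["depth"]),
            error_rate=float(raw["error_rate"]),
            fragment_length=None if raw.get("fragment_length") in (None, "null") else int(raw["fragment_length"]),
        )


@dataclass(frozen=True)
class FrameSegment:
    """Maps a haplotype-frame interval onto the gene-model coordinate frame.

    ``source`` is "gene" (positions map 1:1 into the gene model), "paralog"
    (downstream of a hybrid junction) or "spacer" (intergenic filler).
    """

    hap_start: int  # 1-based start in the haplotype sequence
    length: int
    gene_start: int  # 1-based start in the gene frame (gene segments only)
    source: str

    @property
    def hap_end(self) -> int:
        return self.hap_start + self.length - 1


@dataclass
class MaterializedHaplotype:
    label: str  # "A" | "B"
    haplotype: Haplotype
    sequence: str
    frame_map: tuple[FrameSegment, ...]
    alt_coords: frozenset[int]  # gene-frame coords where any copy carries the alt


@dataclass(frozen=True)
class CNTruth:
    """True copy-number profile of a CYP2D6-like locus."""

    gene_copies: int  # full (non-hybrid) gene copies, both alleles
    paralog_copies: int  # normalizer, diploid = 2
    hybrid_copies: int
    deleted_alleles: int  # parental alleles carrying a whole-gene deletion


@dataclass
class TruthSample:
    sample_id: str
    gene: str
    diplotype: Diplotype
    hapA: MaterializedHaplotype
    hapB: MaterializedHaplotype
    variant_matrix: dict[int, tuple[int, int]]  # coord -> (hapA allele, hapB allele); 1 = alt
    cn: Optional[CNTruth] = None

    @property
    def het_coords(self) -> list[int]:
        return sorted(c for c, (a, b) in self.variant_matrix.items() if a != b)

    @property
    def hom_alt_coords(self) -> list[int]:
        return sorted(c for c, (a, b) in self.variant_matrix.items() if a == 1 and b == 1)


@dataclass(frozen=True)
class SimRead:
    read_id: str
    haplotype_of_origin: str  # "A" | "B"
    start: int  # 1-based, inclusive, haplotype frame
    length: int
    sequence: str
    fragment_id: Optional[str] = None
    error_positions: tuple[int, ...] = ()  # 0-based offsets within the read


@dataclass
class SimReadSet:
    reads: list[SimRead]
    regime: RegimeConfig
    frame_maps: dict[str, tuple[FrameSegment, ...]]  # haplotype label -> frame map


@dataclass(frozen=True)
class DepthSignal:
    """Normalized depth and junction-read evidence for CNV/structure calling."""

    gene_ratio: float  # gene depth / (paralog depth / paralog copies * 2)... normalized so 2 copies -> 1.0
    hybrid_junction_reads: int
    deletion_junction_reads: int


# ---------------------------------------------------------------------------
# diplotype sampling


def sample_diplotype(gene: str, prevalence: dict[str, float], rng: np.random.Generator) -> Diplotype:
    """Draw a diplotype proportional to the supplied weights (cohort spread)."""
    if not prevalence:
        raise ValueError("empty prevalence table")
    keys = sorted(prevalence)
    weights = np.array([prevalence[k] for k in keys], dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    choice = rng.choice(len(keys), p=weights / weights.sum())
    return parse_diplotype(gene, keys[choice])


# ---------------------------------------------------------------------------
# haplotype materialization


def _apply_snvs(seq: np.ndarray, cat: Catalog, gene: str, stars: Sequence[str]) -> frozenset[int]:
    """Substitute the alt base at every defining SNV of the given stars; in place."""
    placed: dict[int, str] = {}
    for star in stars:
        allele = cat.allele(gene, star)
        for var_id in allele.defining_variants:
            v = cat.variant(gene, var_id)
            if placed.get(v.coord, v.alt) != v.alt:
                raise ValueError(f"conflicting substitutions at {gene}:{v.coord}")
            placed[v.coord] = v.alt
            seq[v.coord - 1] = ord(v.alt)
    return frozenset(placed)


def _materialize_single_copy(hap: Haplotype, cat: Catalog, gene: str) -> tuple[str, tuple[FrameSegment, ...], frozenset[int]]:
    """Diploid single-copy loci: all star components decorate one gene copy."""
    model = cat.gene_models[gene]
    seq = np.frombuffer(model.reference_sequence.encode(), dtype=np.uint8).copy()
    alts = _apply_snvs(seq, cat, gene, hap.stars)

    ta_stars = [s for s in hap.stars if cat.allele(gene, s).ta_repeats is not None]
    if len(ta_stars) > 1:
        raise ValueError(f"haplotype {hap.render()} carries more than one repeat allele")
    if ta_stars and model.repeat_locus is not None:
        rep = model.repeat_locus
        units = cat.allele(gene, ta_stars[0]).ta_repeats
        ref_block = rep.anchor_left + rep.unit * rep.reference_units + rep.anchor_right
        new_block = rep.anchor_left + rep.unit * units + rep.anchor_right
        text = seq.tobytes().decode()
        idx = text.index(ref_block)
        text = text[:idx] + new_block + text[idx + len(ref_block) :]
        # coordinates downstream of the repeat shift; all catalog SNVs sit upstream
        shift_at = idx + len(new_block)
        segs = (
            FrameSegment(1, shift_at, 1, "gene"),
            FrameSegment(shift_at + 1, len(text) - shift_at, idx + len(ref_block) + 1, "gene"),
        )
        return text, segs, alts

    text = seq.tobytes().decode()
    return text, (FrameSegment(1, len(text), 1, "gene"),), alts


def _materialize_tandem(hap: Haplotype, cat: Catalog, gene: str) -> tuple[str, tuple[FrameSegment, ...], frozenset[int]]:
    """CYP2D6-like loci: each star component is a tandem gene-unit copy."""
    model = cat.gene_models[gene]
    junction = model.paralog.junction
    pieces: list[str] = []
    segs: list[FrameSegment] = []
    alts: set[int] = set()
    pos = 1
    spacer_seq = (model.reference_sequence[: model.spacer_length])[::-1]  # deterministic filler

    n_units = 0
    for comp in hap.components:
        allele = cat.allele(gene, comp.star)
        if allele.is_deletion:
            continue
        for _ in range(comp.copies):
            if n_units > 0:
                pieces.append(spacer_seq)
                segs.append(FrameSegment(pos, len(spacer_seq), 0, "spacer"))
                pos += len(spacer_seq)
            seq = np.frombuffer(model.reference_sequence.encode(), dtype=np.uint8).copy()
            copy_alts = _apply_snvs(seq, cat, gene, [comp.star])
            alts |= copy_alts
            if allele.is_hybrid:
                text = seq.tobytes().decode()[:junction] + model.paralog_sequence[junction:]
                segs.append(FrameSegment(pos, junction, 1, "gene"))
                segs.append(FrameSegment(pos + junction, len(text) - junction, junction + 1, "paralog"))
            else:
                text = seq.tobytes().decode()
                segs.append(FrameSegment(pos, len(text), 1, "gene"))
            pieces.append(text)
            pos += len(text)
            n_units += 1
    return "".join(pieces), tuple(segs), frozenset(alts)


def materialize_haplotypes(diplotype: Diplotype, cat: Catalog) -> TruthSample:
    """Materialize both haplotype sequences and the phased truth matrix."""
    gene = diplotype.gene
    model = cat.gene_models[gene]
    builder = _materialize_tandem if model.paralog is not None else _materialize_single_copy

    mats = []
    for label, hap in (("A", diplotype.hapA), ("B", diplotype.hapB)):
        seq, segs, alts = builder(hap, cat, gene)
        mats.append(MaterializedHaplotype(label, hap, seq, segs, alts))
    matA, matB = mats

    matrix = {
        v.coord: (int(v.coord in matA.alt_coords), int(v.coord in matB.alt_coords))
        for v in cat.variants_for(gene)
        if v.coord in matA.alt_coords or v.coord in matB.alt_coords
    }

    cn = None
    if model.paralog is not None:
        gene_copies = hybrid_copies = deleted = 0
        for hap in (diplotype.hapA, diplotype.hapB):
            alleles = [cat.allele(gene, c.star) for c in hap.components]
            if all(a.is_deletion for a in alleles):
                deleted += 1
            for comp, allele in zip(hap.components, alleles):
                if allele.is_deletion:
                    continue
                if allele.is_hybrid:
                    hybrid_copies += comp.copies
                else:
                    gene_copies += comp.copies
        cn = CNTruth(gene_copies, 2, hybrid_copies, deleted)

    return TruthSample("", gene, diplotype, matA, matB, matrix, cn)


# ---------------------------------------------------------------------------
# read simulation


def _inject_errors(seq: np.ndarray, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, tuple[int, ...]]:
    if rate <= 0:
        return seq, ()
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq, ()
    pos = rng.choice(len(seq), size=n_err, replace=False)
    out = seq.copy()
    # substitute with one of the three other bases
    for p in pos:
        others = _BASES[_BASES != out[p]]
        out[p] = others[rng.integers(0, 3)]
    return out, tuple(sorted(int(p) for p in pos))


def simulate_reads(truth: TruthSample, regime: RegimeConfig, rng: np.random.Generator) -> SimReadSet:
    """Simulate reads from both haplotypes at the regime's depth.

    Fragment starts are uniform over a window extended by one span on the
    left, and reads are clipped to the locus — the coverage profile a real
    locus embedded in flanking genomic sequence would show, with no depth
    falloff at the locus edges. Substitution errors occur at the configured
    per-base rate; the paired regime emits one read from each end of a
    fixed-length fragment. Haplotype of origin is recorded as hidden truth.
    """
    reads: list[SimRead] = []
    span = regime.fragment_length if regime.paired else regime.read_length
    for mat in (truth.hapA, truth.hapB):
        L = len(mat.sequence)
        if L == 0:  # whole-gene deletion allele: contributes no reads
            continue
        if span > L:
            raise ValueError(f"read span {span} exceeds haplotype length {L}")
        arr = np.frombuffer(mat.sequence.encode(), dtype=np.uint8)
        # expected depth at every position = depth/2 per haplotype:
        # each position is covered by `bases_per_fragment` of the L+span-1 starts
        bases_per_fragment = 2 * regime.read_length if regime.paired else regime.read_length
        n = max(1, int(round(regime.depth / 2 * (L + span - 1) / bases_per_fragment)))
        starts = rng.integers(2 - span, L + 1, size=n)

        def emit(read_id: str, mstart: int, frag_id: Optional[str]) -> None:
            cstart = max(1, mstart)
            cend = min(L, mstart + regime.read_length - 1)
            if cend < cstart:
                return  # mate falls entirely outside the locus
            raw = arr[cstart - 1 : cend]
            seq, errs = _inject_errors(raw, regime.error_rate, rng)
            reads.append(
                SimRead(
                    read_id=read_id,
                    haplotype_of_origin=mat.label,
                    start=cstart,
                    length=cend - cstart + 1,
                    sequence=seq.tobytes().decode(),
                    fragment_id=frag_id,
                    error_positions=errs,
                )
            )

        for i, start in enumerate(starts):
            start = int(start)
            if regime.paired:
                frag_id = f"{truth.sample_id}_{truth.gene}_{mat.label}_f{i}"
                emit(f"{frag_id}/1", start, frag_id)
                emit(f"{frag_id}/2", start + regime.fragment_length - regime.read_length, frag_id)
            else:
                emit(f"{truth.sample_id}_{truth.gene}_{mat.label}_r{i}", start, None)
    return SimReadSet(reads, regime, {"A": truth.hapA.frame_map, "B": truth.hapB.frame_map})


def simulate_depth_profile(
    cn: CNTruth,
    regime: RegimeConfig,
    rng: np.random.Generator,
    cv: float = 0.05,
    n_bins: int = 12,
) -> DepthSignal:
    """Simulate the normalized CYP2D6:CYP2D7 depth ratio and junction evidence.

    The reported ratio is copies/2 (paralog-normalized to the diploid
    baseline). Depth-ratio callers average many genomic bins; the noise model
    reflects that: each of ``n_bins`` bins (500 bp over the 6 kb gene unit)
    carries independent multiplicative noise at the given per-bin coefficient
    of variation, and the reported ratio is the bin mean. Hybrid-junction
    reads are Poisson with mean proportional to hybrid copies.
    Deletion-junction reads (whole-gene deletion breakpoint) are produced only
    by the long-read regime: the breakpoint lies in a segment whose short
    reads are not uniquely mappable, which is what allows a duplication to
    mask a deletion under SRS.
    """
    if cn.paralog_copies < 1:
        raise ValueError("paralog copies must be >= 1 (depth normalizer)")
    per_copy = float(regime.depth) / 2.0  # expected junction-spanning reads per copy
    ratio = cn.gene_copies / cn.paralog_copies  # diploid baseline (2/2) -> 1.0
    if cv > 0:
        ratio *= float(np.mean(rng.normal(1.0, cv, size=max(1, n_bins))))
        hybrid = int(rng.poisson(cn.hybrid_copies * per_copy))
        deletion = int(rng.poisson(cn.deleted_alleles * per_copy)) if regime.name == "LRS" else 0
    else:
        hybrid = int(round(cn.hybrid_copies * per_copy))
        deletion = int(round(cn.deleted_alleles * per_copy)) if regime.name == "LRS" else 0
    return DepthSignal(gene_ratio=ratio, hybrid_junction_reads=hybrid, deletion_junction_reads=deletion)


def simulate_sample(
    diplotype: Diplotype | str,
    cat: Catalog,
    regime: RegimeConfig,
    rng: np.random.Generator,
    sample_id: str = "sim",
) -> tuple[TruthSample, SimReadSet, Optional[DepthSignal]]:
    """Convenience wrapper: materialize a diplotype and simulate its reads."""
    if isinstance(diplotype, str):
        raise TypeError("pass a parsed Diplotype (use parse_diplotype)")
    truth = materialize_haplotypes(diplotype, cat)
    truth.sample_id = sample_id
    reads = simulate_reads(truth, regime, rng)
    signal = None
    if truth.cn is not None:
        signal = simulate_depth_profile(truth.cn, regime, rng)
    return truth, reads, signal
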