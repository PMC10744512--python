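"""Star-allele catalog: variant definitions, allele tables, and gene models.

The catalog packages the allele-definition tables for the three loci —
a NAT2-like single-exon gene (7 core coding SNVs, cDNA coordinates), a
UGT1A1-like promoter with a TATA-box TA repeat plus two distal promoter SNP
markers, and a CYP2D6-like locus with a CYP2D7 paralog and hybrid junction —
together with activity values, function classes, scoring bands and caller
thresholds.

Synthetic reference sequences are produced deterministically at load time from
per-gene seeds recorded in ``gene_models.yaml``; the catalog reference base is
forced at every variant coordinate, and the UGT1A1 promoter carries the
anchored TA run of the reference (*1) allele.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .diplotypes import parse_diplotype

__all__ = [
    "VariantDef",
    "StarAllele",
    "RepeatLocus",
    "Paralog",
    "GeneModel",
    "Catalog",
    "CatalogError",
    "load_catalog",
    "variant_distance",
    "function_class",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

FUNCTION_CLASSES = {"normal", "decreased", "none", "increased", "unknown"}
ACETYLATION_CLASSES = {"rapid", "slow", "unclassified"}


class CatalogError(ValueError):
    """Fatal catalog validation failure."""


@dataclass(frozen=True)
class VariantDef:
    gene: str
    var_id: str
    coord: int  # 1-based position in the gene model's coordinate frame
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise CatalogError(f"{self.gene} {self.var_id}: ref equals alt ({self.ref})")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise CatalogError(f"{self.gene} {self.var_id}: only single-base SNVs supported")


@dataclass(frozen=True)
class StarAllele:
    gene: str
    name: str
    defining_variants: frozenset[str]
    core_variant: Optional[str]  # single SNV used for inter-allele distances
    ta_repeats: Optional[int]  # promoter-repeat alleles only
    activity_value: Optional[float]  # None = unknown
    function_class: str
    acetylation_class: Optional[str]
    is_reference: bool = False
    is_deletion: bool = False
    is_hybrid: bool = False
    is_marker: bool = False

    def __post_init__(self) -> None:
        if self.function_class not in FUNCTION_CLASSES:
            raise CatalogError(f"{self.gene} {self.name}: bad function class {self.function_class!r}")
        if self.acetylation_class is not None and self.acetylation_class not in ACETYLATION_CLASSES:
            raise CatalogError(f"{self.gene} {self.name}: bad acetylation class")
        if self.function_class == "none" and (self.activity_value or 0) != 0:
            raise CatalogError(f"{self.gene} {self.name}: no-function allele must have activity 0")
        if self.defining_variants and self.ta_repeats is not None:
            raise CatalogError(
                f"{self.gene} {self.name}: an allele is discriminated by either "
                "defining variants or a repeat count, not both"
            )


@dataclass(frozen=True)
class RepeatLocus:
    position: int  # 1-based start of the left anchor
    anchor_left: str
    unit: str
    reference_units: int
    anchor_right: str


@dataclass(frozen=True)
class Paralog:
    name: str
    junction: int  # hybrid = gene[1..junction] + paralog[junction+1..end]
    reference_seed: int


@dataclass
class GeneModel:
    gene: str
    locus_length: int
    coordinate_frame: str  # "cDNA" | "genomic-window"
    reference_seed: int
    repeat_locus: Optional[RepeatLocus] = None
    paralog: Optional[Paralog] = None
    spacer_length: int = 500
    reference_sequence: str = ""
    paralog_sequence: str = ""


@dataclass
class Catalog:
    star_alleles: dict[tuple[str, str], StarAllele]
    variant_defs: dict[tuple[str, str], VariantDef]
    gene_models: dict[str, GeneModel]
    activity_overrides: dict[str, dict[str, float]]  # gene -> canonical diplotype -> AS
    phenotype_bands: dict[str, list[dict]]  # gene -> ordered bands with explicit closure
    config: dict
    haplotype_frequencies: dict[str, dict[str, float]]  # gene -> haplotype string -> freq

    # ---- queries -------------------------------------------------------
    def genes(self) -> list[str]:
        return sorted(self.gene_models)

    def allele(self, gene: str, name: str) -> StarAllele:
        try:
            return self.star_alleles[(gene, name)]
        except KeyError:
            raise KeyError(f"unknown star allele {gene} {name}") from None

    def variant(self, gene: str, var_id: str) -> VariantDef:
        return self.variant_defs[(gene, var_id)]

    def alleles_for(self, gene: str) -> list[StarAllele]:
        return [a for (g, _), a in sorted(self.star_alleles.items()) if g == gene]

    def variants_for(self, gene: str) -> list[VariantDef]:
        vs = [v for (g, _), v in self.variant_defs.items() if g == gene]
        return sorted(vs, key=lambda v: v.coord)

    def reference_star(self, gene: str) -> str:
        for a in self.alleles_for(gene):
            if a.is_reference:
                return a.name
        raise CatalogError(f"no reference allele for {gene}")

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        """Plain-data form; reference sequences regenerate from seeds on load."""
        return {
            "alleles": [
                {
                    "gene": a.gene,
                    "name": a.name,
                    "defining_variants": sorted(a.defining_variants),
                    "core_variant": a.core_variant,
                    "ta_repeats": a.ta_repeats,
                    "activity_value": a.activity_value,
                    "function_class": a.function_class,
                    "acetylation_class": a.acetylation_class,
                    "is_reference": a.is_reference,
                    "is_deletion": a.is_deletion,
                    "is_hybrid": a.is_hybrid,
                    "is_marker": a.is_marker,
                }
                for _, a in sorted(self.star_alleles.items())
            ],
            "variants": [
                {"gene": v.gene, "var_id": v.var_id, "coord": v.coord, "ref": v.ref, "alt": v.alt}
                for _, v in sorted(self.variant_defs.items())
            ],
            "gene_models": {
                g: {
                    "locus_length": m.locus_length,
                    "coordinate_frame": m.coordinate_frame,
                    "reference_seed": m.reference_seed,
                    "spacer_length": m.spacer_length,
                    "repeat_locus": None
                    if m.repeat_locus is None
                    else {
                        "position": m.repeat_locus.position,
                        "anchor_left": m.repeat_locus.anchor_left,
                        "unit": m.repeat_locus.unit,
                        "reference_units": m.repeat_locus.reference_units,
                        "anchor_right": m.repeat_locus.anchor_right,
                    },
                    "paralog": None
                    if m.paralog is None
                    else {
                        "name": m.paralog.name,
                        "junction": m.paralog.junction,
                        "reference_seed": m.paralog.reference_seed,
                    },
                }
                for g, m in sorted(self.gene_models.items())
            },
            "activity_overrides": self.activity_overrides,
            "phenotype_bands": self.phenotype_bands,
            "config": self.config,
            "haplotype_frequencies": self.haplotype_frequencies,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Catalog":
        variants = {
            (v["gene"], v["var_id"]): VariantDef(v["gene"], v["var_id"], v["coord"], v["ref"], v["alt"])
            for v in d["variants"]
        }
        alleles = {
            (a["gene"], a["name"]): StarAllele(
                gene=a["gene"],
                name=a["name"],
                defining_variants=frozenset(a["defining_variants"]),
                core_variant=a["core_variant"],
                ta_repeats=a["ta_repeats"],
                activity_value=a["activity_value"],
                function_class=a["function_class"],
                acetylation_class=a["acetylation_class"],
                is_reference=a["is_reference"],
                is_deletion=a["is_deletion"],
                is_hybrid=a["is_hybrid"],
                is_marker=a["is_marker"],
            )
            for a in d["alleles"]
        }
        models = {}
        for g, m in d["gene_models"].items():
            rep = m["repeat_locus"]
            par = m["paralog"]
            models[g] = GeneModel(
                gene=g,
                locus_length=m["locus_length"],
                coordinate_frame=m["coordinate_frame"],
                reference_seed=m["reference_seed"],
                spacer_length=m.get("spacer_length", 500),
                repeat_locus=None if rep is None else RepeatLocus(**rep),
                paralog=None if par is None else Paralog(**par),
            )
        cat = cls(
            star_alleles=alleles,
            variant_defs=variants,
            gene_models=models,
            activity_overrides={g: dict(v) for g, v in d["activity_overrides"].items()},
            phenotype_bands={g: list(bands) for g, bands in d["phenotype_bands"].items()},
            config=d["config"],
            haplotype_frequencies={g: dict(v) for g, v in d["haplotype_frequencies"].items()},
        )
        _build_references(cat)
        _validate(cat)
        return cat


# ---------------------------------------------------------------------------
# loading


def _read_tsv(path: Path) -> list[dict[str, str]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        header: list[str] | None = None
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                # the last comment line before data carries the column names
                candidate = line.lstrip("# ").split("\t")
                if len(candidate) > 1:
                    header = candidate
                continue
            if header is None:
                raise CatalogError(f"{path}: no header comment before data")
            fields = line.split("\t")
            if len(fields) != len(header):
                raise CatalogError(f"{path}: bad column count on line {line!r}")
            rows.append(dict(zip(header, fields)))
    return rows


def _opt(value: str) -> Optional[str]:
    return None if value in {"-", ""} else value


def default_data_dir() -> Path:
    return Path(str(importlib.resources.files("pgxphase") / "data"))


def load_catalog(data_dir: str | Path | None = None) -> Catalog:
    """Load and eagerly validate the packaged (or user-supplied) catalog."""
    root = Path(data_dir) if data_dir is not None else default_data_dir()

    variant_defs: dict[tuple[str, str], VariantDef] = {}
    star_alleles: dict[tuple[str, str], StarAllele] = {}
    for stem in ("nat2", "ugt1a1", "cyp2d6"):
        for row in _read_tsv(root / f"{stem}_variants.tsv"):
            v = VariantDef(row["gene"], row["var_id"], int(row["coord"]), row["ref"], row["alt"])
            key = (v.gene, v.var_id)
            if key in variant_defs:
                raise CatalogError(f"duplicate variant id {key}")
            variant_defs[key] = v
        for row in _read_tsv(root / f"{stem}_alleles.tsv"):
            flags = set((_opt(row["flags"]) or "").split(",")) - {""}
            act = _opt(row["activity_value"])
            defining = _opt(row["defining_variants"])
            a = StarAllele(
                gene=row["gene"],
                name=row["name"],
                defining_variants=frozenset(defining.split(",")) if defining else frozenset(),
                core_variant=_opt(row["core_variant"]),
                ta_repeats=int(row["ta_repeats"]) if _opt(row["ta_repeats"]) else None,
                activity_value=None if act in (None, "unknown") else float(act),
                function_class=row["function_class"],
                acetylation_class=_opt(row["acetylation_class"]),
                is_reference="reference" in flags,
                is_deletion="deletion" in flags,
                is_hybrid="hybrid" in flags,
                is_marker="marker" in flags,
            )
            star_alleles[(a.gene, a.name)] = a

    with open(root / "gene_models.yaml", encoding="utf-8") as fh:
        models_raw = yaml.safe_load(fh)
    gene_models: dict[str, GeneModel] = {}
    for gene, m in models_raw.items():
        rep = m.get("repeat_locus")
        par = m.get("paralog")
        gene_models[gene] = GeneModel(
            gene=gene,
            locus_length=int(m["locus_length"]),
            coordinate_frame=m["coordinate_frame"],
            reference_seed=int(m["reference_seed"]),
            spacer_length=int(m.get("spacer_length", 500)),
            repeat_locus=None
            if rep is None
            else RepeatLocus(
                position=int(rep["position"]),
                anchor_left=rep["anchor_left"],
                unit=rep["unit"],
                reference_units=int(rep["reference_units"]),
                anchor_right=rep["anchor_right"],
            ),
            paralog=None
            if par is None
            else Paralog(name=par["name"], junction=int(par["junction"]), reference_seed=int(par["reference_seed"])),
        )

    with open(root / "thresholds.yaml", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    bands = {gene: list(per_gene) for gene, per_gene in config["phenotype_bands"].items()}
    overrides = {g: dict(v) for g, v in config.get("activity_overrides", {}).items()}

    freqs: dict[str, dict[str, float]] = {"NAT2": {}}
    for row in _read_tsv(root / "nat2_haplotype_frequencies.tsv"):
        freqs["NAT2"][row["haplotype"]] = float(row["frequency"])

    cat = Catalog(
        star_alleles=star_alleles,
        variant_defs=variant_defs,
        gene_models=gene_models,
        activity_overrides=overrides,
        phenotype_bands=bands,
        config=config,
        haplotype_frequencies=freqs,
    )
    _build_references(cat)
    _validate(cat)
    return cat


def _random_sequence(length: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return _BASES[rng.integers(0, 4, size=length)]


def _build_references(cat: Catalog) -> None:
    for gene, model in cat.gene_models.items():
        seq = _random_sequence(model.locus_length, model.reference_seed)
        if model.repeat_locus is not None:
            rep = model.repeat_locus
            block = rep.anchor_left + rep.unit * rep.reference_units + rep.anchor_right
            start = rep.position - 1
            seq[start : start + len(block)] = np.frombuffer(block.encode(), dtype=np.uint8)
        for v in cat.variants_for(gene):
            seq[v.coord - 1] = ord(v.ref)
        model.reference_sequence = seq.tobytes().decode()
        if model.paralog is not None:
            pseq = _random_sequence(model.locus_length, model.paralog.reference_seed)
            model.paralog_sequence = pseq.tobytes().decode()


def _validate(cat: Catalog) -> None:
    # unique variant coordinates per gene, inside the locus
    for gene in cat.gene_models:
        coords = [v.coord for v in cat.variants_for(gene)]
        if len(coords) != len(set(coords)):
            raise CatalogError(f"{gene}: duplicate variant coordinate")
        model = cat.gene_models[gene]
        for v in cat.variants_for(gene):
            if not 1 <= v.coord <= model.locus_length:
                raise CatalogError(f"{gene} {v.var_id}: coord {v.coord} outside locus [1, {model.locus_length}]")
            if model.reference_sequence[v.coord - 1] != v.ref:
                raise CatalogError(f"{gene} {v.var_id}: reference base mismatch")
        if model.repeat_locus is not None:
            for anchor in (model.repeat_locus.anchor_left, model.repeat_locus.anchor_right):
                if model.reference_sequence.count(anchor) != 1:
                    raise CatalogError(f"{gene}: repeat anchor {anchor!r} must occur exactly once in the reference")

    # every defining variant resolves
    for (gene, name), allele in cat.star_alleles.items():
        for var_id in allele.defining_variants:
            if (gene, var_id) not in cat.variant_defs:
                raise CatalogError(f"{gene} {name}: defining variant {var_id!r} is not in the variant table")
        if allele.core_variant is not None and (gene, allele.core_variant) not in cat.variant_defs:
            raise CatalogError(f"{gene} {name}: core variant {allele.core_variant!r} is not in the variant table")

    # override keys parse as diplotypes of known alleles
    for gene, table in cat.activity_overrides.items():
        for key in table:
            d = parse_diplotype(gene, key)
            for hap in (d.hapA, d.hapB):
                for comp in hap.components:
                    if (gene, comp.star) not in cat.star_alleles:
                        raise CatalogError(f"override {key!r}: unknown allele {comp.star} for {gene}")


# ---------------------------------------------------------------------------
# query operations


def variant_distance(cat: Catalog, gene: str, star_a: str, star_b: str) -> int:
    """Distance in bp between the core defining SNVs of two star alleles.

    This is the quantity that determines whether a composite heterozygote can
    be phased from a single short-read fragment: alleles whose core SNVs lie
    farther apart than the fragment length fall into separate phase blocks.
    """

    def core_coord(name: str) -> int:
        allele = cat.allele(gene, name)
        if allele.core_variant is None:
            raise ValueError(f"{gene} {name} has no core variant (reference or repeat allele)")
        return cat.variant(gene, allele.core_variant).coord

    return abs(core_coord(star_a) - core_coord(star_b))


def function_class(cat: Catalog, gene: str, star: str) -> str:
    """Clinical function class of a star allele (pure catalog lookup)."""
    return cat.allele(gene, star).function_class
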