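"""File formats: FASTA/FASTQ for sequences and reads, a minimal phased VCF,
and small TSV/JSON/YAML helpers.

FASTA/FASTQ go through Biopython's ``SeqIO``. Simulated reads carry no real
base-quality model, so FASTQ is written with a constant Q30 quality.

The VCF writer emits a minimal VCF 4.2 single-sample file with a phased
``GT`` (``|`` separator) and a ``PS`` phase-set tag equal to the 1-based
coordinate of the first heterozygous site of each phase block. The reader
accepts exactly what the writer produces (plus arbitrary extra headers) and
reports malformed input with 1-based line numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phasing import HetSite, PhaseResult
from .simulate import SimRead, SimReadSet

__all__ = [
    "IOFormatError",
    "VcfSite",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "reads_to_fastq",
    "write_vcf",
    "read_vcf",
    "phase_result_to_vcf_sites",
    "load_json",
    "save_json",
    "load_yaml",
    "save_yaml",
]

FASTQ_QUALITY = 30  # constant placeholder quality for simulated reads

PathLike = Union[str, Path]


class IOFormatError(ValueError):
    """Malformed input file; carries the offending 1-based line number."""

    def __init__(self, path: PathLike, line_no: int, message: str) -> None:
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(path: PathLike, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def reads_to_fastq(reads: Iterable[SimRead]) -> list[SeqRecord]:
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
        rec.letter_annotations["phred_quality"] = [FASTQ_QUALITY] * len(read.sequence)
        records.append(rec)
    return records


def write_fastq(path: PathLike, readset: Union[SimReadSet, Iterable[SimRead]]) -> int:
    reads = readset.reads if isinstance(readset, SimReadSet) else list(readset)
    return SeqIO.write(reads_to_fastq(reads), str(path), "fastq")


def read_fastq(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")}


# ---------------------------------------------------------------------------
# minimal phased VCF


@dataclass(frozen=True)
class VcfSite:
    """One biallelic site with a single-sample diploid genotype.

    ``gt`` is (hapA allele, hapB allele) with 0=ref, 1=alt. ``phase_set`` is
    the PS tag (None for unphased genotypes, written with "/" instead of "|").
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gt: tuple[int, int]
    phase_set: Optional[int] = None
    var_id: str = "."


def write_vcf(path: PathLike, sites: Sequence[VcfSite], sample: str = "SAMPLE") -> None:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=pgxphase",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">',
    ]
    for chrom in sorted({s.chrom for s in sites}):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}")
    for s in sorted(sites, key=lambda s: (s.chrom, s.pos)):
        if s.phase_set is not None:
            gt = f"{s.gt[0]}|{s.gt[1]}"
            fmt, value = "GT:PS", f"{gt}:{s.phase_set}"
        else:
            fmt, value = "GT", f"{s.gt[0]}/{s.gt[1]}"
        lines.append(
            f"{s.chrom}\t{s.pos}\t{s.var_id}\t{s.ref}\t{s.alt}\t.\tPASS\t.\t{fmt}\t{value}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: PathLike) -> list[VcfSite]:
    sites: list[VcfSite] = []
    saw_header = False
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("##"):
            continue
        if line.startswith("#CHROM"):
            cols = line.split("\t")
            if len(cols) != 10:
                raise IOFormatError(path, line_no, "expected a single-sample VCF (10 columns)")
            saw_header = True
            continue
        if not saw_header:
            raise IOFormatError(path, line_no, "data line before #CHROM header")
        fields = line.split("\t")
        if len(fields) != 10:
            raise IOFormatError(path, line_no, f"expected 10 columns, found {len(fields)}")
        chrom, pos_s, var_id, ref, alt, _qual, _filt, _info, fmt, value = fields
        try:
            pos = int(pos_s)
        except ValueError:
            raise IOFormatError(path, line_no, f"POS is not an integer: {pos_s!r}") from None
        keys = fmt.split(":")
        vals = value.split(":")
        if len(keys) != len(vals) or "GT" not in keys:
            raise IOFormatError(path, line_no, f"FORMAT/sample mismatch or missing GT: {fmt!r}")
        fields_map = dict(zip(keys, vals))
        gt_s = fields_map["GT"]
        sep = "|" if "|" in gt_s else "/"
        parts = gt_s.split(sep)
        if len(parts) != 2 or not all(p in ("0", "1") for p in parts):
            raise IOFormatError(path, line_no, f"unsupported genotype {gt_s!r}")
        phase_set = None
        if sep == "|":
            if "PS" not in fields_map:
                raise IOFormatError(path, line_no, "phased genotype without PS tag")
            try:
                phase_set = int(fields_map["PS"])
            except ValueError:
                raise IOFormatError(
                    path, line_no, f"PS is not an integer: {fields_map['PS']!r}"
                ) from None
        sites.append(
            VcfSite(chrom, pos, ref, alt, (int(parts[0]), int(parts[1])), phase_set, var_id)
        )
    return sites


def phase_result_to_vcf_sites(
    result: PhaseResult,
    het_sites: Sequence[HetSite],
    chrom: str,
    hom_alt: Sequence[HetSite] = (),
) -> list[VcfSite]:
    """Render a phasing result (plus homozygous-alt sites) as VCF sites.

    ``het_sites`` lists the heterozygous sites in the index order the result
    was phased in. hapA carries the alt allele where the assignment is 1. The
    PS tag is the coordinate of the block's first site. Homozygous 1|1 sites
    get their own coordinate as PS.
    """
    block_ps = {}
    for block in result.blocks:
        ps = min(het_sites[i].coord for i in block)
        for i in block:
            block_ps[i] = ps
    sites = [
        VcfSite(
            chrom,
            s.coord,
            s.ref,
            s.alt,
            (result.assignment[i], 1 - result.assignment[i]),
            block_ps[i],
        )
        for i, s in enumerate(het_sites)
    ]
    sites.extend(VcfSite(chrom, s.coord, s.ref, s.alt, (1, 1), s.coord) for s in hom_alt)
    return sorted(sites, key=lambda s: s.pos)


# ---------------------------------------------------------------------------
# JSON / YAML helpers


def save_json(path: PathLike, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: PathLike):
    return json.loads(Path(path).read_text())


def save_yaml(path: PathLike, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def load_yaml(path: PathLike):
    return yaml.safe_load(Path(path).read_text())
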