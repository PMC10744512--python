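"""Star-allele haplotype and diplotype containers.

A *haplotype* is the ordered set of star components carried on one parental
chromosome, each with a copy multiplier (``*2 x 2`` means two tandem copies of
the *2 gene unit; ``*41,*68`` means a *41 gene copy in tandem with a *68
hybrid). A *diplotype* is the pair ``hapA/hapB``.

String grammar (both directions)::

    diplotype  = haplotype "/" haplotype
    haplotype  = component ("," component)*
    component  = star [("x" | "×") int]
    star       = "*" number [letter-suffix]      e.g. *4, *68, *4N

Unicode "×" is accepted on input; ASCII "x" is emitted. Canonical ordering is
deterministic: components within a haplotype sort by star number, haplotypes
sort by (lowest star number, fewer components, lower total copies, string).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["StarComponent", "Haplotype", "Diplotype", "parse_haplotype", "parse_diplotype", "star_sort_key"]

_STAR_RE = re.compile(r"^\*?(\d+)([A-Za-z]*)$")
_COMPONENT_RE = re.compile(r"^\s*(\*?\d+[A-Za-z]*)\s*(?:[x×]\s*(\d+))?\s*$")


def star_sort_key(name: str) -> tuple[int, str]:
    """Sort key for a star name: numeric part, then letter suffix (*4 < *4N < *5)."""
    m = _STAR_RE.match(name)
    if not m:
        raise ValueError(f"not a star-allele name: {name!r}")
    return int(m.group(1)), m.group(2)


@dataclass(frozen=True)
class StarComponent:
    """One star allele on a haplotype with its tandem copy count."""

    star: str
    copies: int = 1

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError(f"copies must be >= 1, got {self.copies}")
        star_sort_key(self.star)  # validates name
        if not self.star.startswith("*"):
            object.__setattr__(self, "star", "*" + self.star)

    def render(self) -> str:
        return self.star if self.copies == 1 else f"{self.star} x {self.copies}"


@dataclass(frozen=True)
class Haplotype:
    """Ordered star components on one parental allele."""

    components: tuple[StarComponent, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("haplotype must have at least one component")

    @property
    def stars(self) -> tuple[str, ...]:
        return tuple(c.star for c in self.components)

    @property
    def total_copies(self) -> int:
        return sum(c.copies for c in self.components)

    def sorted(self) -> "Haplotype":
        return Haplotype(tuple(sorted(self.components, key=lambda c: star_sort_key(c.star))))

    def render(self) -> str:
        return ",".join(c.render() for c in self.components)

    def sort_key(self):
        canon = self.sorted()
        lowest = min(star_sort_key(c.star) for c in canon.components)
        return (lowest, len(canon.components), canon.total_copies, canon.render())


@dataclass(frozen=True)
class Diplotype:
    """Pair of haplotypes at one gene, rendered ``hapA/hapB``."""

    gene: str
    hapA: Haplotype
    hapB: Haplotype

    def canonical(self) -> "Diplotype":
        a, b = self.hapA.sorted(), self.hapB.sorted()
        if b.sort_key() < a.sort_key():
            a, b = b, a
        return Diplotype(self.gene, a, b)

    def render(self) -> str:
        return f"{self.hapA.render()}/{self.hapB.render()}"

    @property
    def canonical_string(self) -> str:
        return self.canonical().render()

    def __eq__(self, other) -> bool:  # equality up to haplotype/component order
        if not isinstance(other, Diplotype):
            return NotImplemented
        c, d = self.canonical(), other.canonical()
        return (c.gene, c.hapA, c.hapB) == (d.gene, d.hapA, d.hapB)

    def __hash__(self) -> int:
        c = self.canonical()
        return hash((c.gene, c.hapA, c.hapB))


def parse_haplotype(text: str) -> Haplotype:
    parts = [p for p in text.strip().split(",") if p.strip()]
    if not parts:
        raise ValueError(f"empty haplotype string: {text!r}")
    comps = []
    for part in parts:
        m = _COMPONENT_RE.match(part)
        if not m:
            raise ValueError(f"cannot parse haplotype component {part!r} in {text!r}")
        comps.append(StarComponent(m.group(1), int(m.group(2)) if m.group(2) else 1))
    return Haplotype(tuple(comps))


def parse_diplotype(gene: str, text: str) -> Diplotype:
    halves = text.strip().split("/")
    if len(halves) != 2:
        raise ValueError(f"diplotype must be 'hapA/hapB': {text!r}")
    return Diplotype(gene, parse_haplotype(halves[0]), parse_haplotype(halves[1]))
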