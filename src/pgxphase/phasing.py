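"""Read-backed and statistical haplotype phasing, and phasing-error metrics.

Direct phasing solves the (unweighted) minimum error correction problem: find
the bipartition of het-site alleles into two haplotypes that minimizes the
number of base calls that must be flipped for every read to be consistent
with one of them. Blocks of sites connected by no common read are phased
independently; within a block the A/B labeling is fixed by convention
(haplotype A carries the reference allele at the block's first site).

Statistical phasing emulates population-frequency inference: within-block
phase is taken as given (short reads phase adjacent sites closer than the
read length) and the orientation of each block relative to the first is
chosen to maximize the product of population haplotype frequencies. This is a
behavioural model of frequency-driven phasing software, not a reimplementation
of any particular tool.

Error metrics follow the usual definitions: a switch error is an adjacent
in-block het-site pair whose relative phase disagrees with the truth; the
Hamming error is the number of mis-assigned sites minimized over a global A/B
relabeling of each block.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .catalog import Catalog
from .diplotypes import Diplotype, Haplotype, StarComponent

logger = logging.getLogger(__name__)

__all__ = [
    "HetSite",
    "ReadObservation",
    "PhaseResult",
    "PhaseErrorReport",
    "extract_observations",
    "phase_direct",
    "compute_phase_blocks",
    "phase_statistical",
    "phase_errors",
    "EXACT_SITE_LIMIT",
]

EXACT_SITE_LIMIT = 15  # exhaustive MEC search bound; greedy refinement beyond


@dataclass(frozen=True)
class HetSite:
    coord: int  # gene-frame, 1-based
    ref: str
    alt: str


@dataclass
class ReadObservation:
    """Alleles observed by one read (or read pair) at the het sites."""

    read_id: str
    alleles: dict[int, int]  # site index -> 0 (ref) | 1 (alt)

    @property
    def informative(self) -> bool:
        return len(self.alleles) >= 2


@dataclass
class PhaseResult:
    sites: list[int]  # het-site coords, sorted
    assignment: list[int]  # hapA allele per site (0 ref / 1 alt), block-relative
    blocks: list[list[int]]  # site indices, jointly phased
    mec_score: int
    method: str  # "direct" | "statistical" | "blockmodel"
    ambiguous_join: bool = False
    hap_labels: Optional[tuple[str, str]] = None  # statistical phasing only

    def block_of(self, site_index: int) -> int:
        for b, members in enumerate(self.blocks):
            if site_index in members:
                return b
        raise KeyError(site_index)


@dataclass(frozen=True)
class PhaseErrorReport:
    switch_errors: int
    hamming: int


# ---------------------------------------------------------------------------
# observation extraction


def extract_observations(
    readset, sites: Sequence[HetSite], merge_pairs: bool = True
) -> list[ReadObservation]:
    """Project reads onto the het sites, classifying each covered base.

    Reads carry true haplotype-frame coordinates; the read set's frame maps
    translate them into the gene frame (the translation an aligner would
    produce). Bases matching neither ref nor alt, and sites observed twice
    with conflicting alleles within one fragment, become missing. Reads
    covering no site are dropped (count logged). With ``merge_pairs`` false,
    paired mates stay separate rows — the per-read (rather than per-fragment)
    evidence model used by the phase-block emulation.
    """
    site_index = {s.coord: i for i, s in enumerate(sites)}
    rows: dict[str, ReadObservation] = {}
    n_empty = 0
    for read in readset.reads:
        key = (
            read.fragment_id
            if (merge_pairs and readset.regime.paired and read.fragment_id)
            else read.read_id
        )
        read_end = read.start + read.length - 1
        obs: dict[int, int] = {}
        conflicted: set[int] = set()
        for seg in readset.frame_maps[read.haplotype_of_origin]:
            if seg.source != "gene":
                continue
            lo = max(read.start, seg.hap_start)
            hi = min(read_end, seg.hap_end)
            if lo > hi:
                continue
            for site in sites:
                gpos = site.coord
                if not (seg.gene_start <= gpos <= seg.gene_start + seg.length - 1):
                    continue
                hap_pos = seg.hap_start + (gpos - seg.gene_start)
                if not (read.start <= hap_pos <= read_end):
                    continue
                base = read.sequence[hap_pos - read.start]
                allele = 0 if base == site.ref else 1 if base == site.alt else None
                idx = site_index[gpos]
                if allele is None:
                    conflicted.add(idx)
                elif idx in obs and obs[idx] != allele:
                    conflicted.add(idx)
                else:
                    obs[idx] = allele
        for idx in conflicted:
            obs.pop(idx, None)
        if not obs:
            n_empty += 1
            continue
        if key in rows:  # second mate of a pair
            prev = rows[key].alleles
            for idx, allele in obs.items():
                if idx in prev and prev[idx] != allele:
                    del prev[idx]
                else:
                    prev[idx] = allele
        else:
            rows[key] = ReadObservation(key, obs)
    if n_empty:
        logger.debug("dropped %d reads covering no het site", n_empty)
    return list(rows.values())


# ---------------------------------------------------------------------------
# direct (MEC) phasing


def _block_cost(rows: list[dict[int, int]], assignment: dict[int, int]) -> int:
    cost = 0
    for row in rows:
        d = sum(1 for i, a in row.items() if assignment[i] != a)
        cost += min(d, len(row) - d)
    return cost


def _solve_block_exact(members: list[int], rows: list[dict[int, int]]) -> tuple[dict[int, int], int]:
    k = len(members)
    best_assign: dict[int, int] = {}
    best_cost = None
    for mask in range(1 << (k - 1)):
        assignment = {members[0]: 0}
        for i in range(1, k):
            assignment[members[i]] = (mask >> (k - 1 - i)) & 1
        cost = _block_cost(rows, assignment)
        if best_cost is None or cost < best_cost:  # first hit wins: lexicographic tie-break
            best_cost, best_assign = cost, assignment
    return best_assign, int(best_cost or 0)


def _solve_block_greedy(members: list[int], rows: list[dict[int, int]]) -> tuple[dict[int, int], int]:
    """Spanning-tree seed on majority pairwise phase, then read-reassignment."""
    votes: dict[tuple[int, int], int] = {}  # (i, j) -> cis votes minus trans votes
    for row in rows:
        idxs = sorted(row)
        for i, j in itertools.combinations(idxs, 2):
            votes[(i, j)] = votes.get((i, j), 0) + (1 if row[i] == row[j] else -1)
    # maximum spanning tree over |votes|
    parent = {m: m for m in members}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = sorted(votes.items(), key=lambda kv: -abs(kv[1]))
    adj: dict[int, list[tuple[int, int]]] = {m: [] for m in members}
    for (i, j), v in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            rel = 0 if v >= 0 else 1  # 0 = same allele (cis)
            adj[i].append((j, rel))
            adj[j].append((i, rel))
    assignment = {members[0]: 0}
    stack = [members[0]]
    while stack:
        u = stack.pop()
        for v, rel in adj[u]:
            if v not in assignment:
                assignment[v] = assignment[u] ^ rel
                stack.append(v)
    for m in members:  # disconnected within block cannot happen, but stay safe
        assignment.setdefault(m, 0)

    for _ in range(20):
        groupA = [r for r in rows if sum(assignment[i] != a for i, a in r.items()) * 2 <= len(r)]
        groupB = [r for r in rows if r not in groupA]
        new_assign = {}
        for m in members:
            tally = 0
            for r in groupA:
                if m in r:
                    tally += 1 if r[m] == 1 else -1
            for r in groupB:
                if m in r:
                    tally += 1 if r[m] == 0 else -1  # B carries the complement
            new_assign[m] = 1 if tally > 0 else 0
        if new_assign[members[0]] == 1:
            new_assign = {m: 1 - a for m, a in new_assign.items()}
        if new_assign == assignment:
            break
        assignment = new_assign
    return assignment, _block_cost(rows, assignment)


def phase_direct(
    observations: Sequence[ReadObservation],
    n_sites: int,
    exact_limit: int = EXACT_SITE_LIMIT,
    force_greedy: bool = False,
) -> PhaseResult:
    """MEC phasing of het sites from read observations.

    Blocks are the connected components of the co-observation graph; each is
    solved exactly (exhaustive over the ``2^(k-1)`` assignments) for up to
    ``exact_limit`` sites, by spanning-tree seeding plus read-reassignment
    refinement beyond. With zero informative observations every site is its
    own block (warning logged).
    """
    informative = [o for o in observations if o.informative]
    n_dropped = len(observations) - len(informative)
    if n_dropped:
        logger.debug("dropped %d uninformative observations", n_dropped)
    if not informative and n_sites > 0:
        logger.info("no informative reads: all %d sites left unphased", n_sites)

    # connected components over sites
    parent = list(range(n_sites))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for o in informative:
        idxs = sorted(o.alleles)
        for j in idxs[1:]:
            ri, rj = find(idxs[0]), find(j)
            if ri != rj:
                parent[ri] = rj

    comp: dict[int, list[int]] = {}
    for i in range(n_sites):
        comp.setdefault(find(i), []).append(i)
    blocks = sorted((sorted(m) for m in comp.values()), key=lambda b: b[0])

    assignment = [0] * n_sites
    mec = 0
    rows_all = [o.alleles for o in observations]
    for members in blocks:
        if len(members) == 1:
            continue
        rows = [r for r in rows_all if any(i in r for i in members)]
        rows = [{i: a for i, a in r.items() if i in members} for r in rows]
        rows = [r for r in rows if r]
        if not force_greedy and len(members) <= exact_limit:
            block_assign, cost = _solve_block_exact(members, rows)
        else:
            block_assign, cost = _solve_block_greedy(members, rows)
        for i, a in block_assign.items():
            assignment[i] = a
        mec += cost
    return PhaseResult(sites=[], assignment=assignment, blocks=blocks, mec_score=mec, method="direct")


def recount_mec(result: PhaseResult, observations: Sequence[ReadObservation]) -> int:
    """Recount the corrections implied by a phasing (self-consistency check)."""
    total = 0
    for members in result.blocks:
        mset = set(members)
        assign = {i: result.assignment[i] for i in members}
        for o in observations:
            row = {i: a for i, a in o.alleles.items() if i in mset}
            if not row:
                continue
            d = sum(1 for i, a in row.items() if assign[i] != a)
            total += min(d, len(row) - d)
    return total


# ---------------------------------------------------------------------------
# phase-block model


def compute_phase_blocks(het_positions: Sequence[int], read_length: int) -> list[list[int]]:
    """Blocks attainable at a given read length.

    Adjacent heterozygous sites farther apart than the read length cannot be
    bridged by any single read, so a cut is introduced between them; sites
    closer than the read length are assumed phasable.
    """
    positions = list(het_positions)
    if positions != sorted(positions):
        raise ValueError("het positions must be sorted")
    blocks: list[list[int]] = []
    for pos in positions:
        if blocks and pos - blocks[-1][-1] <= read_length:
            blocks[-1].append(pos)
        else:
            blocks.append([pos])
    return blocks


# ---------------------------------------------------------------------------
# statistical phasing (population-frequency joins)


def haplotype_label(alt_coords: set[int], cat: Catalog, gene: str) -> str:
    """Star-composition label of a haplotype given its alt-carrying coords."""
    from .star_calling import assign_stars  # local to avoid import cycle in docs builds

    return ",".join(assign_stars(alt_coords, cat, gene))


def phase_statistical(
    blocks: list[list[tuple[int, int]]],
    hom_alt_coords: Sequence[int],
    cat: Catalog,
    gene: str,
    rng: Optional[np.random.Generator] = None,
) -> PhaseResult:
    """Join phase blocks by maximizing the product of haplotype frequencies.

    ``blocks``: per block, (coord, hapA allele) pairs — the within-block phase
    established by read evidence. The relative orientation of every block
    after the first is free; each choice induces two full haplotypes whose
    star-composition labels are scored against the population frequency table
    (floor frequency for unlisted haplotypes). Deterministic: ties are broken
    toward the canonically smaller diplotype and flagged as ambiguous joins;
    an rng may be supplied to randomize tie-breaks instead.
    """
    freq = cat.haplotype_frequencies.get(gene, {})
    floor = float(cat.config.get("statistical_phasing", {}).get("floor_frequency", 1e-3))
    ref_star = cat.reference_star(gene)

    def f(label: str) -> float:
        return freq.get(label if label else ref_star, floor)

    def labels_for(orientation: tuple[int, ...]) -> tuple[str, str, dict[int, int]]:
        hapA: set[int] = set(hom_alt_coords)
        hapB: set[int] = set(hom_alt_coords)
        assignment: dict[int, int] = {}
        for b, block in enumerate(blocks):
            flip = orientation[b]
            for coord, a in block:
                allele = a ^ flip
                assignment[coord] = allele
                if allele == 1:
                    hapA.add(coord)
                else:
                    hapB.add(coord)
        la = haplotype_label(hapA, cat, gene)
        lb = haplotype_label(hapB, cat, gene)
        return la, lb, assignment

    n_free = max(0, len(blocks) - 1)
    candidates = []
    for bits in itertools.product((0, 1), repeat=n_free):
        orientation = (0,) + bits
        la, lb, assignment = labels_for(orientation)
        score = f(la) * f(lb)
        dip = Diplotype(
            gene,
            Haplotype(tuple(StarComponent(s) for s in (la.split(",") if la else [ref_star]))),
            Haplotype(tuple(StarComponent(s) for s in (lb.split(",") if lb else [ref_star]))),
        )
        candidates.append((score, dip.canonical_string, (la, lb), assignment))

    best_score = max(c[0] for c in candidates)
    top = [c for c in candidates if abs(c[0] - best_score) <= 1e-12 * max(1.0, best_score)]
    distinct = sorted({c[1] for c in top})
    ambiguous = len(distinct) > 1
    if ambiguous and rng is not None:
        chosen_string = distinct[int(rng.integers(0, len(distinct)))]
        chosen = next(c for c in top if c[1] == chosen_string)
    else:
        chosen = min(top, key=lambda c: c[1])

    coords = sorted(c for block in blocks for c, _ in block)
    assignment = [chosen[3][c] for c in coords]
    return PhaseResult(
        sites=coords,
        assignment=assignment,
        blocks=[[coords.index(c) for c, _ in block] for block in blocks],
        mec_score=0,
        method="statistical",
        ambiguous_join=ambiguous,
        hap_labels=chosen[2],
    )


# ---------------------------------------------------------------------------
# error metrics


def phase_errors(predicted: PhaseResult, truth_assignment: dict[int, int], coords: Sequence[int]) -> PhaseErrorReport:
    """Switch and Hamming errors of a phasing against the truth.

    ``truth_assignment`` maps het-site coord to the true haplotype-A allele.
    Both metrics are invariant to a global A/B relabeling within each block.
    """
    coords = list(coords)
    if set(coords) != set(truth_assignment):
        raise ValueError("predicted and truth site sets differ")
    if len(predicted.assignment) != len(coords):
        raise ValueError("assignment length does not match site count")

    switch = 0
    hamming = 0
    for members in predicted.blocks:
        members = sorted(members, key=lambda i: coords[i])
        pred = [predicted.assignment[i] for i in members]
        true = [truth_assignment[coords[i]] for i in members]
        for a, b in zip(range(len(members) - 1), range(1, len(members))):
            pred_rel = pred[a] ^ pred[b]
            true_rel = true[a] ^ true[b]
            if pred_rel != true_rel:
                switch += 1
        mismatches = sum(1 for p, t in zip(pred, true) if p != t)
        hamming += min(mismatches, len(members) - mismatches)
    return PhaseErrorReport(switch_errors=switch, hamming=hamming)
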