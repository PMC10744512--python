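import numpy as np
import pytest

from pgxphase.diplotypes import parse_diplotype
from pgxphase.simulate import (
    CNTruth,
    RegimeConfig,
    materialize_haplotypes,
    simulate_depth_profile,
    simulate_reads,
    simulate_sample,
)


def _regime(cat, name, **over):
    return RegimeConfig.from_catalog(cat, name, **over)


def test_same_seed_is_deterministic(cat):
    dip = parse_diplotype("NAT2", "*4/*6,*13")
    a = simulate_sample(dip, cat, _regime(cat, "LRS"), np.random.default_rng(5))
    b = simulate_sample(dip, cat, _regime(cat, "LRS"), np.random.default_rng(5))
    assert [r.sequence for r in a[1].reads] == [r.sequence for r in b[1].reads]
    assert [r.read_id for r in a[1].reads] == [r.read_id for r in b[1].reads]


def test_zero_error_reads_are_exact_substrings(cat):
    dip = parse_diplotype("NAT2", "*4/*6,*13")
    truth, reads, _ = simulate_sample(
        dip, cat, _regime(cat, "LRS", error_rate=0.0), np.random.default_rng(0)
    )
    seqs = {"A": truth.hapA.sequence, "B": truth.hapB.sequence}
    for r in reads.reads:
        hap = seqs[r.haplotype_of_origin]
        assert hap[r.start - 1 : r.start - 1 + r.length] == r.sequence
        assert r.error_positions == ()


def test_error_rate_within_binomial_interval(cat):
    dip = parse_diplotype("NAT2", "*4/*4")
    regime = _regime(cat, "LRS", error_rate=0.01)
    _, reads, _ = simulate_sample(dip, cat, regime, np.random.default_rng(1))
    total = sum(r.length for r in reads.reads)
    errors = sum(len(r.error_positions) for r in reads.reads)
    rate = errors / total
    assert 0.007 < rate < 0.013  # >5 sigma around 0.01 at this base count


def test_mean_depth_within_ten_percent(cat):
    dip = parse_diplotype("NAT2", "*4/*4")
    for name in ("SRS", "LRS"):
        regime = _regime(cat, name)
        truth, reads, _ = simulate_sample(dip, cat, regime, np.random.default_rng(2))
        L = len(truth.hapA.sequence)
        cov = np.zeros(L)
        for r in reads.reads:
            cov[r.start - 1 : r.start - 1 + r.length] += 1
        assert abs(cov.mean() - regime.depth) / regime.depth < 0.10


def test_edge_positions_are_covered(cat):
    dip = parse_diplotype("NAT2", "*4/*4")
    regime = _regime(cat, "SRS")
    truth, reads, _ = simulate_sample(dip, cat, regime, np.random.default_rng(3))
    L = len(truth.hapA.sequence)
    cov = np.zeros(L)
    for r in reads.reads:
        cov[r.start - 1 : r.start - 1 + r.length] += 1
    # no systematic falloff: first and last base still see reasonable coverage
    assert cov[0] > regime.depth * 0.5
    assert cov[-1] > regime.depth * 0.5


def test_paired_reads_share_fragment_and_respect_geometry(cat):
    dip = parse_diplotype("NAT2", "*4/*4")
    regime = _regime(cat, "SRS")
    _, reads, _ = simulate_sample(dip, cat, regime, np.random.default_rng(4))
    by_frag = {}
    for r in reads.reads:
        assert r.fragment_id is not None
        by_frag.setdefault(r.fragment_id, []).append(r)
    assert any(len(v) == 2 for v in by_frag.values())
    for frag in by_frag.values():
        if len(frag) != 2:
            continue  # mate clipped away at the locus edge
        first, second = sorted(frag, key=lambda r: r.start)
        inner = second.start + second.length - first.start
        assert inner <= regime.fragment_length


def test_materialize_variant_matrix(cat):
    dip = parse_diplotype("NAT2", "*12/*6,*13,*12")
    truth = materialize_haplotypes(dip, cat)
    coord = {a.name: cat.variant("NAT2", a.core_variant).coord for a in cat.alleles_for("NAT2") if a.core_variant}
    assert truth.variant_matrix[coord["*12"]] == (1, 1)  # hom
    het = set(truth.het_coords)
    assert coord["*6"] in het and coord["*13"] in het
    assert coord["*5"] not in truth.variant_matrix or truth.variant_matrix[coord["*5"]] == (0, 0)


def test_cyp2d6_cn_truth(cat):
    truth = materialize_haplotypes(parse_diplotype("CYP2D6", "*2 x 2/*5"), cat)
    assert truth.cn == CNTruth(gene_copies=2, paralog_copies=2, hybrid_copies=0, deleted_alleles=1)
    truth = materialize_haplotypes(parse_diplotype("CYP2D6", "*1 x 2/*4,*68"), cat)
    assert truth.cn.gene_copies == 3
    assert truth.cn.hybrid_copies == 1


def test_depth_profile_noise_free_values(cat):
    regime = _regime(cat, "LRS")
    cn = CNTruth(gene_copies=3, paralog_copies=2, hybrid_copies=1, deleted_alleles=0)
    sig = simulate_depth_profile(cn, regime, np.random.default_rng(0), cv=0.0)
    assert sig.gene_ratio == pytest.approx(1.5)
    assert sig.hybrid_junction_reads == 15  # one copy at depth 30 -> depth/2 junction reads
    assert sig.deletion_junction_reads == 0


def test_deletion_junction_reads_only_under_long_reads(cat):
    cn = CNTruth(gene_copies=2, paralog_copies=2, hybrid_copies=0, deleted_alleles=1)
    lrs = simulate_depth_profile(cn, _regime(cat, "LRS"), np.random.default_rng(0), cv=0.0)
    srs = simulate_depth_profile(cn, _regime(cat, "SRS"), np.random.default_rng(0), cv=0.0)
    assert lrs.deletion_junction_reads == 15
    assert srs.deletion_junction_reads == 0


def test_deletion_haplotype_contributes_no_reads(cat):
    dip = parse_diplotype("CYP2D6", "*5/*17")
    truth, reads, _ = simulate_sample(dip, cat, _regime(cat, "LRS"), np.random.default_rng(0))
    labels = {r.haplotype_of_origin for r in reads.reads}
    deleted = "A" if len(truth.hapA.sequence) == 0 else "B"
    assert deleted not in labels
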