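"""Fusion calling: the four criteria, audit trail, truth recovery."""

from __future__ import annotations

import pytest

from isoscope import io as iio
from isoscope.fusion import call_fusions, fusion_gene_summary, FusionCandidate
from isoscope.isoforms import partition_split_reads
from isoscope.models import AnnGene, AnnTranscript, Annotation, SplicedAlignment


def _ann(genes):
    """genes: list of (id, chrom, start, end)."""
    out = {}
    for gid, chrom, s, e in genes:
        tx = AnnTranscript(f"{gid}.T1", gid, chrom, "+", ((s, e),))
        out[gid] = AnnGene(gid, chrom, "+", (s, e), (tx,))
    return Annotation(out)


def _aln(read_id, chrom, span, coverage):
    return SplicedAlignment(read_id, chrom, "+", (span,), 1.0, coverage)


class TestCriteria:
    def test_interchromosomal_pair_with_support_passes(self):
        ann = _ann([("A", "chr1", 1000, 3000), ("B", "chr2", 1000, 3000)])
        alns = {"r1": [_aln("r1", "chr1", (1000, 2500), 0.55), _aln("r1", "chr2", (1000, 2400), 0.449)]}
        cands = call_fusions(alns, ann, {("A", "B"): 3})
        assert cands[0].verdict and cands[0].failed_criteria == []
        assert cands[0].combined_coverage == pytest.approx(0.999)

    def test_nearby_genes_fail_distance(self):
        ann = _ann([("A", "chr1", 1000, 3000), ("B", "chr1", 11000, 13000)])  # 8 kb apart
        alns = {"r1": [_aln("r1", "chr1", (1000, 2500), 0.55), _aln("r1", "chr1", (11000, 12400), 0.449)]}
        cands = call_fusions(alns, ann, {("A", "B"): 3})
        assert not cands[0].verdict and cands[0].failed_criteria == ["distance"]

    def test_low_segment_coverage_fails(self):
        ann = _ann([("A", "chr1", 1000, 3000), ("B", "chr2", 1000, 3000)])
        alns = {"r1": [_aln("r1", "chr1", (1000, 2900), 0.95), _aln("r1", "chr2", (1000, 1200), 0.08)]}
        cands = call_fusions(alns, ann, {("A", "B"): 3})
        assert not cands[0].verdict and "segment_coverage" in cands[0].failed_criteria

    def test_missing_pe_support_fails(self):
        ann = _ann([("A", "chr1", 1000, 3000), ("B", "chr2", 1000, 3000)])
        alns = {"r1": [_aln("r1", "chr1", (1000, 2500), 0.55), _aln("r1", "chr2", (1000, 2400), 0.449)]}
        cands = call_fusions(alns, ann, {})
        assert not cands[0].verdict and cands[0].failed_criteria == ["pe_support"]

    def test_single_alignment_reads_are_not_candidates(self):
        ann = _ann([("A", "chr1", 1000, 3000)])
        assert call_fusions({"r1": [_aln("r1", "chr1", (1000, 2500), 0.99)]}, ann, {}) == []

    def test_every_rejected_read_carries_failed_criteria(self):
        ann = _ann([("A", "chr1", 1000, 3000), ("B", "chr1", 11000, 13000)])
        alns = {"r1": [_aln("r1", "chr1", (1000, 2000), 0.4), _aln("r1", "chr1", (11000, 12000), 0.4)]}
        cands = call_fusions(alns, ann, {})
        assert all(c.failed_criteria for c in cands if not c.verdict)


def brute_force_verdict(segs, ann, pe, min_distance=10_000, min_seg_cov=0.10,
                        min_total_cov=0.99, min_pe=2):
    """Direct evaluation of the four predicates for one read (oracle)."""
    genes = sorted({g for g, *_ in segs})
    if len(genes) < 2:
        return False
    per_gene = {g: sum(c for gg, c in ((s[0], s[1]) for s in segs) if gg == g) for g in genes}
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = ann.genes[genes[i]], ann.genes[genes[j]]
            if a.chrom == b.chrom:
                gap = max(b.span[0] - a.span[1], a.span[0] - b.span[1], 0)
                if gap < min_distance:
                    return False
    if any(per_gene[g] <= min_seg_cov for g in genes):
        return False
    if sum(c for _, c in ((s[0], s[1]) for s in segs)) <= min_total_cov:
        return False
    pairs = [tuple(sorted((genes[i], genes[j]))) for i in range(len(genes)) for j in range(i + 1, len(genes))]
    return min(pe.get(p, 0) for p in pairs) >= min_pe


def test_simulated_fusions_recovered_with_perfect_precision_recall(clean_sim):
    """Every ground-truth fusion read is called; no other read is.
    Verdicts also agree with a brute-force evaluator of the criteria."""
    t = clean_sim.truth
    _, split = partition_split_reads(iio.read_alignments(clean_sim.alignments_sam))
    pe_df = iio.read_tsv(clean_sim.pe_support_tsv)
    pe = {tuple(sorted((r.gene_a, r.gene_b))): int(r.pe_count) for r in pe_df.itertuples()}
    cands = call_fusions(split, clean_sim.annotation, pe)
    called = {c.read_id for c in cands if c.verdict}
    assert called == set(t.fusions)
    assert len(called) >= 10
    for c in cands:
        segs = [(g, cov) for g, _, _, cov in c.segments]
        assert c.verdict == brute_force_verdict(segs, clean_sim.annotation, pe), c.read_id


def test_threshold_monotonicity(clean_sim):
    """Tightening any threshold never adds a candidate."""
    _, split = partition_split_reads(iio.read_alignments(clean_sim.alignments_sam))
    pe_df = iio.read_tsv(clean_sim.pe_support_tsv)
    pe = {tuple(sorted((r.gene_a, r.gene_b))): int(r.pe_count) for r in pe_df.itertuples()}
    base = {c.read_id for c in call_fusions(split, clean_sim.annotation, pe) if c.verdict}
    tighter = [
        dict(min_distance=50_000), dict(min_seg_cov=0.3),
        dict(min_total_cov=0.999), dict(min_pe=10),
    ]
    for kw in tighter:
        sub = {c.read_id for c in call_fusions(split, clean_sim.annotation, pe, **kw) if c.verdict}
        assert sub <= base


def test_order_invariance(clean_sim):
    _, split = partition_split_reads(iio.read_alignments(clean_sim.alignments_sam))
    rev = dict(reversed(list(split.items())))
    a = [(c.read_id, c.verdict) for c in call_fusions(split, clean_sim.annotation, {})]
    b = [(c.read_id, c.verdict) for c in call_fusions(rev, clean_sim.annotation, {})]
    assert a == b


class TestSummary:
    def _cand(self, rid, genes, inter=True):
        segs = [(g, "chr1", (0, 100), 0.5) for g in genes]
        return FusionCandidate(rid, segs, None if inter else 20_000, 1.0, 3, True, [])

    def test_distinct_gene_union(self):
        cands = [
            self._cand("r1", ["A", "B"]), self._cand("r2", ["A", "C"]),
            self._cand("r3", ["D", "E"]),
        ]
        s = fusion_gene_summary(cands)
        assert s["n_fusion_events"] == 3
        assert s["n_distinct_genes"] == 5
        assert s["inter_chromosomal_fraction"] == 1.0

    def test_no_candidates(self):
        s = fusion_gene_summary([])
        assert s["n_fusion_events"] == 0 and s["n_distinct_genes"] == 0

    def test_summary_equals_independent_tally(self, clean_sim):
        _, split = partition_split_reads(iio.read_alignments(clean_sim.alignments_sam))
        pe_df = iio.read_tsv(clean_sim.pe_support_tsv)
        pe = {tuple(sorted((r.gene_a, r.gene_b))): int(r.pe_count) for r in pe_df.itertuples()}
        cands = call_fusions(split, clean_sim.annotation, pe)
        s = fusion_gene_summary(cands)
        hits = [c for c in cands if c.verdict]
        genes = set()
        for c in hits:
            genes.update(g for g, *_ in c.segments)
        assert s["n_fusion_events"] == len(hits)
        assert s["n_distinct_genes"] == len(genes)
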