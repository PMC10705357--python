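"""Collapse, degradation filter, retention rule, loci, novelty."""

from __future__ import annotations

import itertools
import random

import networkx as nx
import pytest

from isoscope import io as iio
from isoscope.isoforms import (
    apply_retention_filter,
    assign_loci,
    build_chain,
    call_novelty,
    collapse,
    filter_degraded,
    partition_split_reads,
    retention_filter,
)
from isoscope.models import (
    IsoformModel,
    SplicedAlignment,
    build_chain_from_blocks,
)


def _aln(read_id, blocks, chrom="chr1", strand="+", identity=1.0):
    return SplicedAlignment(read_id, chrom, strand, tuple(blocks), identity, 1.0)


class TestBuildChain:
    def test_introns_are_gaps_between_blocks(self):
        assert build_chain(_aln("r", [(100, 200), (300, 400)])) == ((200, 300),)

    def test_single_block_gives_empty_chain(self):
        assert build_chain(_aln("r", [(100, 400)])) == ()

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError):
            _aln("r", [(100, 300), (200, 400)])

    def test_chains_match_truth_on_simulated_alignments(self, default_sim, default_alignments):
        truth = default_sim.truth
        simple, _ = partition_split_reads(default_alignments)
        assert len(simple) > 200
        for a in simple:
            expect = build_chain_from_blocks(truth.reads[a.read_id].blocks)
            assert build_chain(a) == expect


class TestCollapse:
    def test_identical_chains_collapse_with_support(self):
        isos = collapse([_aln("a", [(0, 100), (200, 300)]), _aln("b", [(10, 100), (200, 280)])])
        assert len(isos) == 1
        assert isos[0].support == 2
        assert isos[0].span == (0, 300)

    def test_different_chains_stay_separate(self):
        isos = collapse(
            [_aln("a", [(0, 100), (200, 300)]), _aln("b", [(0, 100), (150, 300)])]
        )
        assert len(isos) == 2

    def test_matches_brute_force_chain_grouping(self, default_sim, default_alignments):
        """Collapsed multi-exon isoforms equal an independent grouping of
        reads by exact (chrom, strand, chain) key."""
        simple, _ = partition_split_reads(default_alignments)
        isos = collapse(simple)
        expected: dict[tuple, int] = {}
        for a in simple:
            chain = tuple((a.blocks[i][1], a.blocks[i + 1][0]) for i in range(len(a.blocks) - 1))
            if chain:
                key = (a.chrom, a.strand, chain)
                expected[key] = expected.get(key, 0) + 1
        got = {(i.chrom, i.strand, i.chain): i.support for i in isos if i.chain}
        assert got == expected

    def test_order_invariance(self, default_alignments):
        simple, _ = partition_split_reads(default_alignments)
        shuffled = simple[:]
        random.Random(9).shuffle(shuffled)
        a = [(i.id, i.chrom, i.strand, i.chain, i.span, i.support) for i in collapse(simple)]
        b = [(i.id, i.chrom, i.strand, i.chain, i.span, i.support) for i in collapse(shuffled)]
        assert a == b

    def test_idempotence(self, default_alignments):
        """Re-collapsing one representative read per isoform reproduces
        the isoform set (support resets to 1)."""
        simple, _ = partition_split_reads(default_alignments)
        first = collapse(simple)
        rep = [
            _aln(i.id, i.exons, i.chrom, i.strand) for i in first
        ]
        second = collapse(rep)
        assert {(i.chrom, i.strand, i.chain, i.span) for i in second} == {
            (i.chrom, i.strand, i.chain, i.span) for i in first
        }

    def test_support_conservation(self, default_alignments):
        simple, _ = partition_split_reads(default_alignments)
        isos = collapse(simple)
        assert sum(i.support for i in isos) == len(simple)

    def test_mono_exon_merge_by_three_prime_end(self):
        # ends within 50 and overlapping spans -> one isoform
        isos = collapse([_aln("a", [(0, 1000)]), _aln("b", [(100, 1030)])])
        assert len(isos) == 1 and isos[0].support == 2
        # ends far apart -> separate
        isos = collapse([_aln("a", [(0, 1000)]), _aln("b", [(100, 1200)])])
        assert len(isos) == 2


class TestFilterDegraded:
    def _iso(self, chain, span, strand="+", iid="x"):
        return IsoformModel(id=iid, chrom="chr1", strand=strand, chain=tuple(chain), span=span)

    def test_suffix_chain_with_covered_five_prime_removed(self):
        full = self._iso([(150, 200), (300, 400)], (100, 500), iid="full")
        deg = self._iso([(300, 400)], (250, 500), iid="deg")
        kept, removed = filter_degraded([full, deg])
        assert [i.id for i in removed] == ["deg"]

    def test_minus_strand_uses_genomic_prefix(self):
        full = self._iso([(150, 200), (300, 400)], (100, 500), strand="-", iid="full")
        deg = self._iso([(150, 200)], (100, 350), strand="-", iid="deg")
        kept, removed = filter_degraded([full, deg])
        assert [i.id for i in removed] == ["deg"]

    def test_equal_five_prime_start_is_not_degraded(self):
        # an intron-retention variant shares the transcript start: kept
        full = self._iso([(100, 200), (300, 400)], (0, 500), iid="full")
        irv = self._iso([(300, 400)], (0, 500), iid="ir")
        kept, removed = filter_degraded([full, irv])
        assert removed == []

    def test_mono_exon_isoforms_never_removed(self):
        full = self._iso([(150, 200)], (100, 500), iid="full")
        mono = self._iso([], (250, 450), iid="mono")
        _, removed = filter_degraded([full, mono])
        assert removed == []

    def test_removed_set_matches_truth_exactly(self, degraded_sim):
        """With 30% degraded reads at zero error, the removed isoforms are
        exactly those whose chains arise only from degraded reads."""
        t = degraded_sim.truth
        alns = iio.read_alignments(degraded_sim.alignments_sam)
        simple, _ = partition_split_reads(alns)
        isos = collapse(simple)
        kept, removed = filter_degraded(isos)
        true_chains = {
            (i.chrom, i.strand, i.chain)
            for g in t.genes.values()
            for i in g.isoforms
            if i.chain
        }
        degraded_only = set()
        for a in simple:
            key = (a.chrom, a.strand, build_chain(a))
            if key[2] and key not in true_chains:
                degraded_only.add(key)
        got = {(i.chrom, i.strand, i.chain) for i in removed}
        assert got == degraded_only
        assert {(i.chrom, i.strand, i.chain) for i in kept if i.chain} == true_chains


class TestRetentionFilter:
    def _iso(self, support, identity, js):
        return IsoformModel(
            id="x", chrom="chr1", strand="+", chain=tuple((i * 100 + 50, i * 100 + 80) for i in range(len(js))),
            span=(0, len(js) * 100 + 100), support=support, best_identity=identity,
            junction_support=tuple(js),
        )

    def test_two_reads_suffice(self):
        assert retention_filter(self._iso(2, 0.90, [False]))

    def test_single_read_above_identity_cut(self):
        assert retention_filter(self._iso(1, 0.995, [False]))
        assert not retention_filter(self._iso(1, 0.99, [False]))  # strict >

    def test_partial_junction_support_insufficient(self):
        assert not retention_filter(self._iso(1, 0.95, [True, False, True]))
        assert retention_filter(self._iso(1, 0.95, [True, True, True]))

    def test_matches_boolean_oracle_on_random_cases(self):
        rng = random.Random(7)
        for _ in range(1000):
            support = rng.randint(1, 3)
            identity = rng.uniform(0.9, 1.0)
            n_j = rng.randint(0, 4)
            js = [rng.random() < 0.5 for _ in range(n_j)]
            iso = self._iso(support, identity, js)
            expect = (
                support >= 2
                or (support == 1 and identity > 0.99)
                or (n_j > 0 and all(js))
            )
            assert retention_filter(iso) == expect


class TestAssignLoci:
    def _iso(self, span, iid, strand="+"):
        return IsoformModel(id=iid, chrom="chr1", strand=strand, chain=(), span=span)

    def test_ten_percent_overlap_keeps_two_loci(self):
        loci = assign_loci([self._iso((0, 1000), "a"), self._iso((900, 2000), "b")])
        assert len(loci) == 2

    def test_thirty_percent_overlap_merges(self):
        loci = assign_loci([self._iso((0, 1000), "a"), self._iso((700, 1700), "b")])
        assert len(loci) == 1

    def test_matches_networkx_connected_components(self, default_kept_isoforms):
        """Loci equal connected components of the pairwise >=20% overlap
        predicate computed independently with networkx."""
        kept, loci = default_kept_isoforms
        assert len(kept) >= 50
        g = nx.Graph()
        g.add_nodes_from(i.id for i in kept)
        for a, b in itertools.combinations(kept, 2):
            if a.chrom != b.chrom or a.strand != b.strand:
                continue
            ov = min(a.span[1], b.span[1]) - max(a.span[0], b.span[0])
            shorter = min(a.span[1] - a.span[0], b.span[1] - b.span[0])
            if ov > 0 and ov / shorter >= 0.2:
                g.add_edge(a.id, b.id)
        expected = {frozenset(c) for c in nx.connected_components(g)}
        got = {frozenset(l.isoform_ids) for l in loci}
        assert got == expected


class TestNovelty:
    def test_known_and_novel_against_simulation(self, default_sim, default_kept_isoforms):
        """Withheld and strand-distinct noncoding genes surface as novel
        loci; annotated base isoforms are known, variants novel."""
        kept, loci = default_kept_isoforms
        t = default_sim.truth
        expected_novel_genes = set(t.withheld)
        for g in t.genes.values():
            if g.coding:
                continue
            if g.placement == "intergenic" or g.strand != t.genes[g.host_id].strand:
                expected_novel_genes.add(g.id)
        assert sum(1 for l in loci if l.status == "novel") == len(expected_novel_genes)

        known_chains = {
            (tx.chrom, tx.strand, tx.chain) for tx in default_sim.annotation.transcripts()
        }
        for iso in kept:
            if iso.chain:
                assert (iso.status == "known") == (
                    (iso.chrom, iso.strand, iso.chain) in known_chains
                )

    def test_novel_locus_for_unannotated_region(self, default_sim):
        iso = IsoformModel(
            id="x", chrom="chrZZ", strand="+", chain=((100, 200),), span=(0, 300)
        )
        loci = assign_loci([iso])
        call_novelty(loci, [iso], default_sim.annotation)
        assert loci[0].status == "novel" and iso.status == "novel"
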