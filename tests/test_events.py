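"""AS event taxonomy: canonical patterns, fuzz behavior, oracle equivalence."""

from __future__ import annotations

import itertools

import pytest

from isoscope.events import EVENT_TYPES, classify_locus, classify_pair, summarize_events
from isoscope.models import IsoformModel, build_chain_from_blocks


def iso_from_exons(exons, iid="a", strand="+", locus="L1", chrom="chr1"):
    exons = tuple(exons)
    return IsoformModel(
        id=iid, chrom=chrom, strand=strand,
        chain=build_chain_from_blocks(exons),
        span=(exons[0][0], exons[-1][1]), locus_id=locus,
    )


# ------------------------------------------------------------------ oracle

def oracle_events(A: IsoformModel, B: IsoformModel, fuzz: int) -> set:
    """Independent interval-algebra evaluation of the five patterns.

    Written as plain nested loops over both role assignments; returns the
    set of (type, region) pairs.
    """
    found = set()
    for S, I in ((A, B), (B, A)):
        iex = I.exons
        # skipping: an intron of S containing complete internal exons of I
        for d, a in S.chain:
            ks = [k for k in range(1, len(iex) - 1) if d <= iex[k][0] and iex[k][1] <= a]
            if ks and ks == list(range(min(ks), max(ks) + 1)):
                dprime = iex[min(ks) - 1][1]
                aprime = iex[max(ks) + 1][0]
                delta = max(abs(d - dprime), abs(a - aprime))
                t = "SKIP" if len(ks) == 1 else "MSKIP"
                region = (iex[min(ks)][0], iex[max(ks)][1])
                if delta == 0:
                    found.add((t, region))
                elif delta <= fuzz:
                    found.add(("X" + t, region))
        # retention: an exon of S containing complete introns of I
        for ei, (s, e) in enumerate(S.exons):
            js = [j for j, (d, a) in enumerate(I.chain) if s <= d and a <= e]
            if js and js == list(range(min(js), max(js) + 1)):
                deltas = []
                if not (ei == 0 and min(js) == 0):
                    deltas.append(abs(s - iex[min(js)][0]))
                if not (ei == len(S.exons) - 1 and max(js) == len(I.chain) - 1):
                    deltas.append(abs(e - iex[max(js) + 1][1]))
                delta = max(deltas) if deltas else 0
                t = "IR" if len(js) == 1 else "MIR"
                region = (I.chain[min(js)][0], I.chain[max(js)][1])
                if delta == 0:
                    found.add((t, region))
                elif delta <= fuzz:
                    found.add(("X" + t, region))
    # alternative ends: overlapping intron pairs sharing (nearly) one boundary
    for ia in A.chain:
        for ib in B.chain:
            if ia == ib or ia[1] <= ib[0] or ib[1] <= ia[0]:
                continue
            if any(ia[0] <= s and e <= ia[1] for s, e in B.exons):
                continue
            if any(ib[0] <= s and e <= ib[1] for s, e in A.exons):
                continue
            dd, da = abs(ia[0] - ib[0]), abs(ia[1] - ib[1])
            if (dd == 0) != (da == 0):
                region = (
                    (min(ia[1], ib[1]), max(ia[1], ib[1])) if dd == 0
                    else (min(ia[0], ib[0]), max(ia[0], ib[0]))
                )
                found.add(("AE", region))
            elif dd > 0 and da > 0 and min(dd, da) <= fuzz:
                region = (
                    (min(ia[0], ib[0]), max(ia[0], ib[0])) if dd > da
                    else (min(ia[1], ib[1]), max(ia[1], ib[1]))
                )
                found.add(("XAE", region))
    return found


# ------------------------------------------------------------------ canonical cases

class TestCanonicalPatterns:
    def test_exon_skipping(self):
        A = iso_from_exons([(0, 100), (200, 300), (400, 500)], "A")
        B = iso_from_exons([(0, 100), (400, 500)], "B")
        evs = classify_pair(A, B)
        assert [(e.type, e.region, e.n_exons_or_introns) for e in evs] == [
            ("SKIP", (200, 300), 1)
        ]

    def test_multiple_cassette_skipping(self):
        A = iso_from_exons([(0, 100), (200, 300), (400, 500), (600, 700)], "A")
        B = iso_from_exons([(0, 100), (600, 700)], "B")
        evs = classify_pair(A, B)
        assert [(e.type, e.n_exons_or_introns) for e in evs] == [("MSKIP", 2)]

    def test_intron_retention(self):
        A = iso_from_exons([(0, 100), (200, 300)], "A")
        B = iso_from_exons([(0, 300)], "B")
        evs = classify_pair(A, B)
        assert [(e.type, e.region) for e in evs] == [("IR", (100, 200))]

    def test_multiple_intron_retention(self):
        A = iso_from_exons([(0, 100), (200, 300), (400, 500)], "A")
        B = iso_from_exons([(0, 500)], "B")
        evs = classify_pair(A, B)
        assert [(e.type, e.n_exons_or_introns) for e in evs] == [("MIR", 2)]

    def test_alternative_exon_end(self):
        A = iso_from_exons([(0, 100), (200, 300)], "A")
        B = iso_from_exons([(0, 130), (200, 300)], "B")
        evs = classify_pair(A, B)
        assert [(e.type, e.region) for e in evs] == [("AE", (100, 130))]

    def test_shifted_skip_boundary_becomes_approximate(self):
        """The same skip pattern with a 4 bp flank shift is XSKIP at
        fuzz=10 and nothing at fuzz=0."""
        A = iso_from_exons([(0, 100), (200, 300), (400, 500)], "A")
        B = iso_from_exons([(0, 104), (400, 500)], "B")
        assert [e.type for e in classify_pair(A, B, fuzz=10)] == ["XSKIP"]
        assert classify_pair(A, B, fuzz=0) == []

    def test_different_loci_is_usage_error(self):
        A = iso_from_exons([(0, 100), (200, 300)], "A", locus="L1")
        B = iso_from_exons([(0, 300)], "B", locus="L2")
        with pytest.raises(ValueError):
            classify_pair(A, B)


# ------------------------------------------------------------------ properties

def _sim_pairs(default_sim):
    pairs = []
    for g in default_sim.truth.genes.values():
        isos = [
            iso_from_exons(i.exons, i.id, g.strand, g.id, g.chrom) for i in g.isoforms
        ]
        pairs.extend(itertools.combinations(isos, 2))
    return pairs


def test_matches_interval_algebra_oracle_on_simulated_pairs(default_sim):
    """Event multisets across every isoform pair of a simulated run equal
    the oracle's, at fuzz 0, 5 and 10."""
    pairs = _sim_pairs(default_sim)
    assert len(pairs) >= 20
    for fuzz in (0, 5, 10):
        for A, B in pairs:
            got = {(e.type, e.region) for e in classify_pair(A, B, fuzz)}
            assert got == oracle_events(A, B, fuzz), (A.id, B.id, fuzz)


def test_symmetry(default_sim):
    for A, B in _sim_pairs(default_sim):
        ab = sorted((e.type, e.region) for e in classify_pair(A, B))
        ba = sorted((e.type, e.region) for e in classify_pair(B, A))
        assert ab == ba


def test_no_approximate_types_at_fuzz_zero(default_sim):
    for A, B in _sim_pairs(default_sim):
        assert not any(e.type.startswith("X") for e in classify_pair(A, B, fuzz=0))


def test_locus_dedup_and_raw_counts(default_sim):
    g = next(g for g in default_sim.truth.genes.values() if len(g.isoforms) >= 3)
    isos = [iso_from_exons(i.exons, i.id, g.strand, g.id, g.chrom) for i in g.isoforms]
    dedup, raw = classify_locus(isos)
    assert len(dedup) <= len(raw)
    assert len({(e.type, e.region) for e in dedup}) == len(dedup)


class TestSummarizeEvents:
    def test_counts_equal_independent_tally(self, default_sim):
        events = []
        for g in default_sim.truth.genes.values():
            isos = [
                iso_from_exons(i.exons, i.id, g.strand, g.id, g.chrom) for i in g.isoforms
            ]
            events.extend(classify_locus(isos)[0])
        df = summarize_events(events)
        tally = {}
        for e in events:
            tally[e.type] = tally.get(e.type, 0) + 1
        for _, row in df.iterrows():
            assert row["count"] == tally.get(row["type"], 0)
        assert int(df["count"].sum()) == len(events)

    def test_empty_event_list_gives_zero_summary(self):
        df = summarize_events([])
        assert set(df["type"]) == set(EVENT_TYPES)
        assert df["count"].sum() == 0
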