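"""Collapse spliced alignments into isoform models, filter, group, annotate.

The collapse key for multi-exon reads is the junction chain: reads with
identical (chrom, strand, intron chain) become one isoform regardless of
their transcript end scatter. Mono-exon reads are merged into an isoform
when their spans overlap and their transcriptional 3' ends agree within a
tolerance (the 5' end is left free, consistent with the 5'-degradation
model). Downstream filters remove 5'-degraded isoforms (chain is a
3'-anchored suffix of a longer same-strand isoform) and isoforms lacking
read/identity/junction support; surviving isoforms are grouped into gene
loci by >=20% reciprocal-span overlap (fraction of the shorter span) and
compared with a reference annotation to call novel loci and isoforms.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from typing import Iterable, Sequence

from ._util import connected_components, span_overlap
from .models import (
    Annotation,
    Chain,
    GeneLocus,
    IsoformModel,
    SplicedAlignment,
    build_chain_from_blocks,
)

log = logging.getLogger(__name__)


def build_chain(aln: SplicedAlignment) -> Chain:
    """Introns are the gaps between consecutive aligned exon blocks."""
    return build_chain_from_blocks(aln.blocks)


def collapse(
    alns: Sequence[SplicedAlignment], mono_end_tol: int = 50
) -> list[IsoformModel]:
    """Group alignments into nonredundant isoform models.

    Multi-exon reads collapse on exact (chrom, strand, chain) identity;
    the isoform span is the maximal extent of its reads. Mono-exon reads
    on one (chrom, strand) merge transitively when pairwise their spans
    overlap and their 3' ends lie within ``mono_end_tol``. Isoform ids
    are assigned in sorted genomic order so output is independent of
    input order.
    """
    multi: dict[tuple, list[SplicedAlignment]] = defaultdict(list)
    mono: dict[tuple, list[SplicedAlignment]] = defaultdict(list)
    for a in alns:
        chain = build_chain(a)
        if chain:
            multi[(a.chrom, a.strand, chain)].append(a)
        else:
            mono[(a.chrom, a.strand)].append(a)

    isoforms: list[IsoformModel] = []
    for (chrom, strand, chain), group in multi.items():
        isoforms.append(
            IsoformModel(
                id="", chrom=chrom, strand=strand, chain=chain,
                span=(min(a.span[0] for a in group), max(a.span[1] for a in group)),
                support=len(group),
                best_identity=max(a.identity for a in group),
            )
        )
    for (chrom, strand), group in mono.items():
        group = sorted(group, key=lambda a: (a.span, a.read_id))
        end_of = (lambda a: a.span[1]) if strand == "+" else (lambda a: a.span[0])
        edges = []
        for i, j in itertools.combinations(range(len(group)), 2):
            if (
                abs(end_of(group[i]) - end_of(group[j])) <= mono_end_tol
                and span_overlap(group[i].span, group[j].span) > 0
            ):
                edges.append((i, j))
        labels = connected_components(len(group), edges)
        comps: dict[int, list[SplicedAlignment]] = defaultdict(list)
        for i, lab in enumerate(labels):
            comps[lab].append(group[i])
        for members in comps.values():
            isoforms.append(
                IsoformModel(
                    id="", chrom=chrom, strand=strand, chain=(),
                    span=(min(a.span[0] for a in members), max(a.span[1] for a in members)),
                    support=len(members),
                    best_identity=max(a.identity for a in members),
                )
            )
    isoforms.sort(key=lambda i: (i.chrom, i.span, i.strand, i.chain))
    for k, iso in enumerate(isoforms, 1):
        iso.id = f"I{k:06d}"
    return isoforms


def filter_degraded(isoforms: Sequence[IsoformModel]) -> tuple[list[IsoformModel], list[IsoformModel]]:
    """Remove 5'-degraded isoforms.

    A multi-exon isoform is removed when another same (chrom, strand)
    isoform exists whose chain contains the victim's chain as a strict
    3'-anchored suffix (genomic suffix on '+', genomic prefix on '-')
    and whose span strictly covers the victim's 5' end. Mono-exon
    isoforms are never removed here: an empty chain is trivially a
    suffix of every chain, and applying the rule to them would delete
    genuine single-exon genes nested inside other genes.
    """
    by_key: dict[tuple, list[IsoformModel]] = defaultdict(list)
    for iso in isoforms:
        by_key[(iso.chrom, iso.strand)].append(iso)
    kept, removed = [], []
    for iso in isoforms:
        if not iso.chain:
            kept.append(iso)
            continue
        victim = False
        for other in by_key[(iso.chrom, iso.strand)]:
            if other is iso or len(other.chain) <= len(iso.chain):
                continue
            if iso.strand == "+":
                suffix = other.chain[-len(iso.chain):] == iso.chain
                covers = other.span[0] < iso.span[0] <= other.span[1]
            else:
                suffix = other.chain[: len(iso.chain)] == iso.chain
                covers = other.span[0] <= iso.span[1] < other.span[1]
            if suffix and covers:
                victim = True
                break
        (removed if victim else kept).append(iso)
    return kept, removed


def retention_filter(iso: IsoformModel, pid_cut: float = 0.99) -> bool:
    """Keep an isoform when it has read, identity, or junction support.

    Keep iff support >= 2, or a single read aligned with identity above
    ``pid_cut``, or every intron has external junction evidence
    (short-read or annotation). Mono-exon isoforms have no junctions to
    support, so the junction clause is false for them.
    """
    if iso.support >= 2:
        return True
    if iso.support == 1 and iso.best_identity > pid_cut:
        return True
    return bool(iso.chain) and len(iso.junction_support) == len(iso.chain) and all(
        iso.junction_support
    )


def annotate_junction_support(
    isoforms: Iterable[IsoformModel],
    evidence: set[tuple[str, int, int]],
) -> None:
    """Fill per-intron support flags from a set of (chrom, donor, acceptor)."""
    for iso in isoforms:
        iso.junction_support = tuple((iso.chrom, d, a) in evidence for d, a in iso.chain)


def apply_retention_filter(
    isoforms: Sequence[IsoformModel], pid_cut: float = 0.99
) -> tuple[list[IsoformModel], list[IsoformModel]]:
    kept = [i for i in isoforms if retention_filter(i, pid_cut)]
    dropped = [i for i in isoforms if not retention_filter(i, pid_cut)]
    return kept, dropped


def _overlap_related(a: IsoformModel, b: IsoformModel, min_overlap: float) -> bool:
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    ov = span_overlap(a.span, b.span)
    shorter = min(a.span[1] - a.span[0], b.span[1] - b.span[0])
    return shorter > 0 and ov / shorter >= min_overlap


def assign_loci(
    isoforms: Sequence[IsoformModel], min_overlap: float = 0.2
) -> list[GeneLocus]:
    """Group isoforms into gene loci.

    Two isoforms are related when, on the same chrom and strand, their
    span overlap is at least ``min_overlap`` of the shorter span; loci
    are the connected components (transitive closure) of this relation.
    Mutates ``locus_id`` on the isoforms and returns loci in sorted
    genomic order.
    """
    isoforms = sorted(isoforms, key=lambda i: (i.chrom, i.span, i.strand, i.chain))
    # candidate pairs via per-(chrom,strand) sweep over sorted spans
    edges = []
    groups: dict[tuple, list[int]] = defaultdict(list)
    for idx, iso in enumerate(isoforms):
        groups[(iso.chrom, iso.strand)].append(idx)
    for idxs in groups.values():
        for pos, i in enumerate(idxs):
            for j in idxs[pos + 1:]:
                if isoforms[j].span[0] >= isoforms[i].span[1]:
                    break
                if _overlap_related(isoforms[i], isoforms[j], min_overlap):
                    edges.append((i, j))
    labels = connected_components(len(isoforms), edges)
    comps: dict[int, list[IsoformModel]] = defaultdict(list)
    for i, lab in enumerate(labels):
        comps[lab].append(isoforms[i])
    loci = []
    for members in comps.values():
        loci.append(
            GeneLocus(
                id="",
                chrom=members[0].chrom,
                strand=members[0].strand,
                span=(min(m.span[0] for m in members), max(m.span[1] for m in members)),
                isoform_ids=[m.id for m in members],
            )
        )
    loci.sort(key=lambda l: (l.chrom, l.span, l.strand))
    iso_by_id = {i.id: i for i in isoforms}
    for k, loc in enumerate(loci, 1):
        loc.id = f"L{k:05d}"
        for iid in loc.isoform_ids:
            iso_by_id[iid].locus_id = loc.id
    return loci


def call_novelty(
    loci: Sequence[GeneLocus],
    isoforms: Sequence[IsoformModel],
    annotation: Annotation,
    min_overlap: float = 0.2,
) -> None:
    """Label loci and isoforms known/novel against a reference annotation.

    A locus is known when some reference gene on the same strand overlaps
    it by >= ``min_overlap`` of the shorter span. An isoform is known
    when a reference transcript on the same chrom/strand has the exact
    same junction chain; mono-exon isoforms additionally require
    >= ``min_overlap`` span overlap with the matching mono-exon
    reference transcript, since an empty chain alone carries no
    positional information. Mutates ``status`` in place.
    """
    ref_by_cs: dict[tuple, list] = defaultdict(list)
    for g in annotation.genes.values():
        ref_by_cs[(g.chrom, g.strand)].append(g)
    tx_chains: dict[tuple, set[Chain]] = defaultdict(set)
    mono_tx: dict[tuple, list] = defaultdict(list)
    for t in annotation.transcripts():
        if t.chain:
            tx_chains[(t.chrom, t.strand)].add(t.chain)
        else:
            mono_tx[(t.chrom, t.strand)].append(t)

    for loc in loci:
        known = False
        for g in ref_by_cs[(loc.chrom, loc.strand)]:
            ov = span_overlap(loc.span, g.span)
            shorter = min(loc.span[1] - loc.span[0], g.span[1] - g.span[0])
            if shorter > 0 and ov / shorter >= min_overlap:
                known = True
                break
        loc.status = "known" if known else "novel"

    for iso in isoforms:
        if iso.chain:
            iso.status = (
                "known" if iso.chain in tx_chains[(iso.chrom, iso.strand)] else "novel"
            )
        else:
            known = False
            for t in mono_tx[(iso.chrom, iso.strand)]:
                ov = span_overlap(iso.span, t.span)
                shorter = min(iso.span[1] - iso.span[0], t.span[1] - t.span[0])
                if shorter > 0 and ov / shorter >= min_overlap:
                    known = True
                    break
            iso.status = "known" if known else "novel"


def partition_split_reads(
    alns: Sequence[SplicedAlignment],
) -> tuple[list[SplicedAlignment], dict[str, list[SplicedAlignment]]]:
    """Separate simple alignments from reads split across multiple records.

    Reads with more than one alignment record are fusion-transcript
    candidates and are excluded from isoform collapse (their partial
    segments would otherwise surface as spurious truncated isoforms).
    """
    by_read: dict[str, list[SplicedAlignment]] = defaultdict(list)
    for a in alns:
        by_read[a.read_id].append(a)
    simple = [g[0] for g in by_read.values() if len(g) == 1]
    split = {rid: g for rid, g in by_read.items() if len(g) > 1}
    return simple, split
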