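"""Fusion-transcript calling from multi-gene FLNC alignments.

A read is a fusion candidate when its alignment segments hit two or more
annotated genes and all four criteria hold: (a) every gene pair is at
least ``min_distance`` apart or on different chromosomes; (b) every
per-gene merged segment covers more than ``min_seg_cov`` of the read;
(c) combined coverage over all segments exceeds ``min_total_cov``; and
(d) paired-end short-read support across the fusion junction reaches
``min_pe``. Rejected multi-gene reads are kept in the candidate table
with the list of criteria they failed, for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._util import span_overlap
from .models import Annotation, SplicedAlignment

CRITERIA = ("distance", "segment_coverage", "total_coverage", "pe_support")


@dataclass
class FusionCandidate:
    read_id: str
    segments: list[tuple[str, str, tuple[int, int], float]]  # (gene, chrom, span, coverage)
    pairwise_gene_distance: int | None  # None = inter-chromosomal pair present only
    combined_coverage: float
    pe_support: int
    verdict: bool
    failed_criteria: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(sorted({s[0] for s in self.segments}))


def _assign_gene(aln: SplicedAlignment, ann: Annotation) -> str | None:
    """Annotated gene with the largest span overlap on the same chromosome."""
    best, best_ov = None, 0
    for g in ann.genes.values():
        if g.chrom != aln.chrom:
            continue
        ov = span_overlap(aln.span, g.span)
        if ov > best_ov:
            best, best_ov = g.id, ov
    return best


def _gene_distance(ann: Annotation, ga: str, gb: str) -> int | None:
    a, b = ann.genes[ga], ann.genes[gb]
    if a.chrom != b.chrom:
        return None
    if a.span[1] <= b.span[0]:
        return b.span[0] - a.span[1]
    if b.span[1] <= a.span[0]:
        return a.span[0] - b.span[1]
    return 0


def call_fusions(
    alignments_by_read: Mapping[str, Sequence[SplicedAlignment]],
    annotation: Annotation,
    pe_evidence: Mapping[tuple[str, str], int] | None = None,
    min_distance: int = 10_000,
    min_seg_cov: float = 0.10,
    min_total_cov: float = 0.99,
    min_pe: int = 2,
) -> list[FusionCandidate]:
    """Evaluate every multi-record read against the four fusion criteria.

    ``pe_evidence`` maps a sorted gene-id pair to the number of
    junction-spanning read pairs; missing pairs count 0. Reads with a
    single alignment record are not candidates and are excluded.
    """
    pe_evidence = pe_evidence or {}
    out: list[FusionCandidate] = []
    for read_id in sorted(alignments_by_read):
        alns = alignments_by_read[read_id]
        if len(alns) < 2:
            continue
        per_gene: dict[str, list[SplicedAlignment]] = {}
        for a in alns:
            gid = _assign_gene(a, annotation)
            if gid is not None:
                per_gene.setdefault(gid, []).append(a)
        segments = []
        for gid, group in sorted(per_gene.items()):
            cov = sum(a.read_coverage for a in group)
            span = (min(a.span[0] for a in group), max(a.span[1] for a in group))
            segments.append((gid, group[0].chrom, span, cov))
        combined = sum(a.read_coverage for a in alns)

        failed = []
        genes = [s[0] for s in segments]
        if len(genes) < 2:
            failed.append("distance")  # fewer than two annotated genes hit
            min_dist = None
        else:
            dists = []
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    d = _gene_distance(annotation, genes[i], genes[j])
                    if d is not None:
                        dists.append(d)
            min_dist = min(dists) if dists else None
            if dists and min(dists) < min_distance:
                failed.append("distance")
        if any(s[3] <= min_seg_cov for s in segments) or not segments:
            failed.append("segment_coverage")
        if combined <= min_total_cov:
            failed.append("total_coverage")
        pe = 0
        if len(genes) >= 2:
            pairs = [
                tuple(sorted((genes[i], genes[j])))
                for i in range(len(genes))
                for j in range(i + 1, len(genes))
            ]
            pe = min(pe_evidence.get(p, 0) for p in pairs)
        if pe < min_pe:
            failed.append("pe_support")
        out.append(
            FusionCandidate(
                read_id=read_id, segments=segments,
                pairwise_gene_distance=min_dist, combined_coverage=combined,
                pe_support=pe, verdict=not failed, failed_criteria=failed,
            )
        )
    return out


def fusion_gene_summary(candidates: Sequence[FusionCandidate]) -> dict:
    """Event/gene counts over verdict-true candidates.

    Reports both the read-level event count and the collapsed count of
    distinct unordered gene sets ("fusion genes"), the union of genes
    involved, and the inter-chromosomal fraction.
    """
    hits = [c for c in candidates if c.verdict]
    gene_sets = {c.gene_ids for c in hits}
    genes: set[str] = set()
    for c in hits:
        genes.update(c.gene_ids)
    inter = sum(1 for c in hits if c.pairwise_gene_distance is None)
    return {
        "n_fusion_events": len(hits),
        "n_fusion_gene_sets": len(gene_sets),
        "n_distinct_genes": len(genes),
        "inter_chromosomal_fraction": inter / len(hits) if hits else 0.0,
    }
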