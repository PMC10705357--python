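"""Alternative-polyadenylation site detection from FLNC 3' ends.

Per gene and strand, read 3' ends are grouped greedily: ends are scanned
in genomic order and an end joins the current cluster while it lies
within ``group_window`` (5 bp) of the cluster's representative — the
modal end position, ties resolved to the most 3'-distal position for the
gene's strand. Clusters supported by fewer than ``min_support`` (2)
reads are discarded; surviving clusters are accepted in descending
support order (ties most-3'-distal first), skipping any candidate within
``exclusion`` (15 bp) of an already accepted site.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .models import SplicedAlignment


@dataclass(frozen=True)
class ThreePrimeEnd:
    read_id: str
    gene_id: str
    position: int
    strand: str


@dataclass(frozen=True)
class ApaSite:
    gene_id: str
    position: int
    support: int
    rank: int


def _representative(positions: list[int], strand: str) -> int:
    cnt = Counter(positions)
    best = max(cnt.values())
    modes = [p for p, c in cnt.items() if c == best]
    return max(modes) if strand == "+" else min(modes)


def detect_apa(
    ends: Sequence[ThreePrimeEnd],
    group_window: int = 5,
    min_support: int = 2,
    exclusion: int = 15,
) -> list[ApaSite]:
    """Cluster one gene's 3' ends into supported polyadenylation sites.

    All ends must belong to one gene and strand. Returns accepted sites
    with their acceptance rank; any two sites are more than ``exclusion``
    bases apart.
    """
    if not ends:
        return []
    genes = {e.gene_id for e in ends}
    strands = {e.strand for e in ends}
    if len(genes) != 1 or len(strands) != 1:
        raise ValueError("detect_apa expects ends of a single gene and strand")
    gene = next(iter(genes))
    strand = next(iter(strands))

    ordered = sorted(e.position for e in ends)
    clusters: list[list[int]] = []
    for pos in ordered:
        if clusters and abs(pos - _representative(clusters[-1], strand)) <= group_window:
            clusters[-1].append(pos)
        else:
            clusters.append([pos])

    cands = [
        (_representative(c, strand), len(c)) for c in clusters if len(c) >= min_support
    ]
    # acceptance: descending support, ties most 3'-distal first
    distal = (lambda p: -p) if strand == "+" else (lambda p: p)
    cands.sort(key=lambda pc: (-pc[1], distal(pc[0])))
    accepted: list[ApaSite] = []
    for pos, sup in cands:
        if any(abs(pos - s.position) <= exclusion for s in accepted):
            continue
        accepted.append(ApaSite(gene_id=gene, position=pos, support=sup, rank=len(accepted) + 1))
    return accepted


def detect_apa_all(
    ends: Iterable[ThreePrimeEnd], **kwargs
) -> dict[str, list[ApaSite]]:
    """detect_apa per (gene, strand) group."""
    by_gene: dict[str, list[ThreePrimeEnd]] = {}
    for e in ends:
        by_gene.setdefault(e.gene_id, []).append(e)
    return {g: detect_apa(es, **kwargs) for g, es in sorted(by_gene.items())}


def apa_gene_stats(sites: Iterable[ApaSite]) -> pd.DataFrame:
    """Per-gene site counts plus dataset-level totals.

    Returns a frame with one row per gene (gene_id, n_sites) whose attrs
    carry ``n_sites_total``, ``n_genes`` and ``n_multi_apa_genes``.
    """
    df = pd.DataFrame(
        [{"gene_id": s.gene_id, "position": s.position, "support": s.support} for s in sites]
    )
    if df.empty:
        out = pd.DataFrame(columns=["gene_id", "n_sites"])
        out.attrs.update(n_sites_total=0, n_genes=0, n_multi_apa_genes=0)
        return out
    out = df.groupby("gene_id").size().rename("n_sites").reset_index()
    out.attrs.update(
        n_sites_total=int(len(df)),
        n_genes=int(len(out)),
        n_multi_apa_genes=int((out["n_sites"] > 1).sum()),
    )
    return out


def ends_from_alignments(
    alns: Iterable[SplicedAlignment],
    gene_spans: dict[str, tuple[str, str, tuple[int, int]]],
    slack: int = 10,
) -> list[ThreePrimeEnd]:
    """Extract transcriptional 3' ends and assign them to genes.

    ``gene_spans`` maps gene_id -> (chrom, strand, (start, end)). The 3'
    end of a '+' alignment is its last block end; of a '-' alignment its
    first block start (poly(A) tails are trimmed before alignment, so
    block termini are cleavage positions). An end is assigned to the
    smallest same-strand gene span containing it within ``slack`` bases
    (cleavage scatter can place an end just past the annotated gene
    boundary); unassigned ends are dropped.
    """
    out = []
    for a in alns:
        pos = a.blocks[-1][1] if a.strand == "+" else a.blocks[0][0]
        best = None
        for gid, (chrom, strand, (s, e)) in gene_spans.items():
            if chrom != a.chrom or strand != a.strand:
                continue
            if s - slack <= pos <= e + slack:
                size = e - s
                if best is None or size < best[1]:
                    best = (gid, size)
        if best:
            out.append(ThreePrimeEnd(a.read_id, best[0], pos, a.strand))
    return out
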