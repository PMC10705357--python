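"""Shared domain objects for the structural-annotation pipeline.

Coordinate convention: all in-memory coordinates are 0-based, half-open
``[start, end)`` on the forward genome strand. GFF3 I/O converts to the
1-based inclusive convention of that format. A transcript's *junction
chain* is the ordered tuple of intron ``(donor, acceptor)`` coordinate
pairs — the gaps between consecutive exon blocks — and is the identity
used to collapse reads into isoforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

Blocks = tuple[tuple[int, int], ...]
Chain = tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class SplicedAlignment:
    """A read's exon blocks on the genome.

    ``identity`` is alignment percent identity in [0, 1];
    ``read_coverage`` is the fraction of the read's bases that are aligned
    in this record (soft-clipped bases excluded).
    """

    read_id: str
    chrom: str
    strand: str
    blocks: Blocks
    identity: float = 1.0
    read_coverage: float = 1.0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev = None
        for s, e in self.blocks:
            if e <= s:
                raise ValueError(f"empty block ({s},{e}) in {self.read_id}")
            if prev is not None and s < prev:
                raise ValueError(f"overlapping/unsorted blocks in {self.read_id}")
            prev = e
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0,1]")
        if not 0.0 <= self.read_coverage <= 1.0:
            raise ValueError("read_coverage outside [0,1]")

    @property
    def span(self) -> tuple[int, int]:
        return (self.blocks[0][0], self.blocks[-1][1])


@dataclass
class IsoformModel:
    """A collapsed transcript model defined by its junction chain."""

    id: str
    chrom: str
    strand: str
    chain: Chain
    span: tuple[int, int]
    support: int = 1
    best_identity: float = 1.0
    junction_support: tuple[bool, ...] = ()
    status: Optional[str] = None  # "known" | "novel"
    locus_id: Optional[str] = None

    @property
    def exons(self) -> Blocks:
        """Exon blocks implied by span + chain."""
        if not self.chain:
            return (self.span,)
        out = []
        start = self.span[0]
        for d, a in self.chain:
            out.append((start, d))
            start = a
        out.append((start, self.span[1]))
        return tuple(out)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the transcriptional 3' terminus."""
        return self.span[1] if self.strand == "+" else self.span[0]

    @property
    def five_prime(self) -> int:
        return self.span[0] if self.strand == "+" else self.span[1]


@dataclass
class GeneLocus:
    """Strand-specific cluster of isoforms treated as one gene."""

    id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    isoform_ids: list[str] = field(default_factory=list)
    status: Optional[str] = None


@dataclass(frozen=True)
class AnnTranscript:
    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Blocks

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def chain(self) -> Chain:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class AnnGene:
    id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    transcripts: tuple[AnnTranscript, ...]


@dataclass
class Annotation:
    """Reference annotation: genes with transcript exon structures."""

    genes: dict[str, AnnGene]

    def transcripts(self):
        for g in self.genes.values():
            yield from g.transcripts

    def junction_set(self) -> set[tuple[str, int, int]]:
        out = set()
        for t in self.transcripts():
            for d, a in t.chain:
                out.add((t.chrom, d, a))
        return out


def build_chain_from_blocks(blocks: Blocks) -> Chain:
    return tuple((blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1))
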