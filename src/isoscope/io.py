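"""Format readers/writers shared by all pipeline stages.

FASTA goes through Biopython, SAM/BAM through pysam, GFF3 parsing through
gffutils; GFF3 output is written directly (gene/mRNA/exon features,
1-based inclusive coordinates per the format).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    AnnGene,
    AnnTranscript,
    Annotation,
    Blocks,
    GeneLocus,
    IsoformModel,
    SplicedAlignment,
)

COORD_HEADER = "# coordinates: GFF3/BED columns follow their format conventions; TSV coordinates are 0-based half-open"


# ---------------------------------------------------------------- FASTA

def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- GFF3

def _gff3_feature(chrom, source, ftype, start, end, strand, attrs) -> str:
    # internal half-open -> GFF3 1-based inclusive
    a = ";".join(f"{k}={v}" for k, v in attrs.items())
    return f"{chrom}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{a}"


def write_annotation_gff3(ann: Annotation, path: str | Path, source: str = "isoscope") -> None:
    lines = ["##gff-version 3"]
    for g in sorted(ann.genes.values(), key=lambda g: (g.chrom, g.span)):
        lines.append(
            _gff3_feature(g.chrom, source, "gene", g.span[0], g.span[1], g.strand, {"ID": g.id})
        )
        for t in g.transcripts:
            lines.append(
                _gff3_feature(
                    t.chrom, source, "mRNA", t.span[0], t.span[1], t.strand,
                    {"ID": t.id, "Parent": g.id},
                )
            )
            for i, (s, e) in enumerate(t.exons, 1):
                lines.append(
                    _gff3_feature(
                        t.chrom, source, "exon", s, e, t.strand,
                        {"ID": f"{t.id}.e{i}", "Parent": t.id},
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_isoforms_gff3(
    isoforms: Sequence[IsoformModel],
    loci: Sequence[GeneLocus],
    path: str | Path,
    source: str = "isoscope",
) -> None:
    """Isoform models as gene(locus)/transcript/exon features."""
    by_locus: dict[str, list[IsoformModel]] = {}
    for iso in isoforms:
        by_locus.setdefault(iso.locus_id or "NA", []).append(iso)
    lines = ["##gff-version 3"]
    for loc in sorted(loci, key=lambda l: (l.chrom, l.span)):
        attrs = {"ID": loc.id}
        if loc.status:
            attrs["status"] = loc.status
        lines.append(
            _gff3_feature(loc.chrom, source, "gene", loc.span[0], loc.span[1], loc.strand, attrs)
        )
        for iso in sorted(by_locus.get(loc.id, []), key=lambda i: i.span):
            attrs = {"ID": iso.id, "Parent": loc.id, "support": iso.support}
            if iso.status:
                attrs["status"] = iso.status
            lines.append(
                _gff3_feature(
                    iso.chrom, source, "transcript", iso.span[0], iso.span[1], iso.strand, attrs
                )
            )
            for i, (s, e) in enumerate(iso.exons, 1):
                lines.append(
                    _gff3_feature(
                        iso.chrom, source, "exon", s, e, iso.strand,
                        {"ID": f"{iso.id}.e{i}", "Parent": iso.id},
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation(path: str | Path) -> Annotation:
    """Parse a GFF3 annotation into gene/transcript exon structures.

    Transcripts missing a strand are skipped with a warning, as are
    transcript features with no exon children.
    """
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except gffutils.exceptions.EmptyInputError:
        return Annotation(genes={})
    genes: dict[str, AnnGene] = {}
    for g in db.features_of_type("gene"):
        txs = []
        for t in db.children(g, level=1):
            if t.featuretype not in ("mRNA", "transcript"):
                continue
            if t.strand not in "+-":
                import warnings

                warnings.warn(f"transcript {t.id} has no strand; skipped")
                continue
            exons = sorted((e.start - 1, e.end) for e in db.children(t, featuretype="exon"))
            if not exons:
                continue
            txs.append(
                AnnTranscript(
                    id=t.id, gene_id=g.id, chrom=t.seqid, strand=t.strand, exons=tuple(exons)
                )
            )
        if g.strand not in "+-":
            continue
        genes[g.id] = AnnGene(
            id=g.id,
            chrom=g.seqid,
            strand=g.strand,
            span=(g.start - 1, g.end),
            transcripts=tuple(txs),
        )
    return Annotation(genes=genes)


# ---------------------------------------------------------------- SAM

def sam_header(chrom_lengths: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()],
        }
    )


def write_sam(
    path: str | Path,
    chrom_lengths: dict[str, int],
    records: Iterable[pysam.AlignedSegment],
) -> None:
    with pysam.AlignmentFile(str(path), "w", header=sam_header(chrom_lengths)) as fh:
        for rec in records:
            fh.write(rec)


def read_alignments(path: str | Path) -> list[SplicedAlignment]:
    """SAM/BAM records -> SplicedAlignment, merging nothing.

    Identity is derived from the NM tag when present (1 - NM/aligned);
    read_coverage from aligned query bases over the full read length
    (soft clips included in the denominator).
    """
    out = []
    save = pysam.set_verbosity(0)
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            blocks = _merge_adjacent(rec.get_blocks())
            read_len = rec.infer_read_length() or rec.query_length
            aligned = rec.query_alignment_length
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            ident = 1.0 - nm / aligned if aligned else 0.0
            out.append(
                SplicedAlignment(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    strand="-" if rec.is_reverse else "+",
                    blocks=tuple(blocks),
                    identity=max(0.0, ident),
                    read_coverage=aligned / read_len if read_len else 0.0,
                )
            )
    pysam.set_verbosity(save)
    return out


def _merge_adjacent(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    # pysam emits one block per M run; merge blocks split by I/D, not by N
    merged: list[list[int]] = []
    for s, e in blocks:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(b) for b in merged]


# ---------------------------------------------------------------- TSV / BED

def write_tsv(df: pd.DataFrame, path: str | Path, comment: str | None = COORD_HEADER) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(comment + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_bed6(rows: Iterable[tuple], path: str | Path) -> None:
    """rows: (chrom, start, end, name, score, strand), half-open starts."""
    with open(path, "w") as fh:
        for chrom, s, e, name, score, strand in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score}\t{strand}\n")


def file_sha256(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
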