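"""Seeded generator of a toy genome, annotation, FLNC reads and alignments.

The generator emulates the structure of a size-fractionated, two-sex
full-length cDNA sequencing experiment: multi-exon gene models with
isoform variants that realize the five exact alternative-splicing
patterns (SKIP, MSKIP, IR, MIR, AE); reads carrying a 5' primer, a
poly(A) tail and a reverse-complemented 3' primer; 5'-degraded copies;
3'-end scatter around per-gene polyadenylation sites; inter-chromosomal
(and occasional same-chromosome, >=10 kb) fusion chimeras; noncoding
transcripts placed in defined positional configurations (intergenic,
intronic, sense, antisense, other); and optional uniform per-base
substitution error.

Every run is fully determined by (seed, config): per-stage child RNGs are
derived from a single root ``numpy.random.SeedSequence`` so adding a
stage never perturbs earlier ones, and identical inputs give
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from . import io as iio
from ._util import revcomp
from .models import Annotation, AnnGene, AnnTranscript, Blocks, build_chain_from_blocks

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_PRIMER_5P = "AAGCAGTGGTATCAACGCAGAGTACATGGG"
DEFAULT_PRIMER_3P = "GTACTCTGCGTTGATACCACTGCTTAGATC"

AS_OPS = ("skip", "mskip", "ir", "mir", "ae")
PLACEMENTS = ("intergenic", "intronic", "sense", "antisense", "other")


class SimConfigError(ValueError):
    """Raised when a SimConfig field is out of its documented domain."""


@dataclass(frozen=True)
class SimConfig:
    seed: int = 1
    n_chroms: int = 3
    chrom_len: int = 150_000
    n_genes: int = 30
    isoforms_per_gene: tuple[int, int] = (2, 4)
    exons_per_isoform: tuple[int, int] = (4, 8)
    frac_degraded_reads: float = 0.15
    frac_fusion_reads: float = 0.02
    frac_artifact_reads: float = 0.05
    apa_sites_per_gene: tuple[int, int] = (1, 3)
    end_scatter_sd: float = 2.0
    per_base_error: float = 0.0
    polya_len: tuple[int, int] = (20, 40)
    primer_5p: str = DEFAULT_PRIMER_5P
    primer_3p: str = DEFAULT_PRIMER_3P
    reads_per_isoform: tuple[int, int] = (2, 6)
    frac_noncoding_genes: float = 0.2
    frac_withheld_genes: float = 0.25

    def validate(self) -> None:
        for name in (
            "frac_degraded_reads",
            "frac_fusion_reads",
            "frac_artifact_reads",
            "per_base_error",
            "frac_noncoding_genes",
            "frac_withheld_genes",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0,1], got {v}")
        for name in (
            "isoforms_per_gene",
            "exons_per_isoform",
            "apa_sites_per_gene",
            "polya_len",
            "reads_per_isoform",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise SimConfigError(f"{name} must satisfy 0 <= min <= max, got ({lo},{hi})")
        for name in ("n_chroms", "chrom_len", "n_genes"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if not self.primer_5p or not self.primer_3p:
            raise SimConfigError("primer_5p / primer_3p must be non-empty")


@dataclass
class TrueIsoform:
    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Blocks
    op: str  # "base" or one of AS_OPS

    @property
    def chain(self):
        return build_chain_from_blocks(self.exons)


@dataclass
class SimGene:
    id: str
    chrom: str
    strand: str
    exons: Blocks  # base structure
    sex: str
    coding: bool
    placement: str = "intergenic"
    host_id: str | None = None  # coding gene a noncoding gene was placed against
    isoforms: list[TrueIsoform] = field(default_factory=list)
    apa_sites: list[int] = field(default_factory=list)

    @property
    def span(self):
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class SimRead:
    id: str
    gene_id: str
    isoform_id: str
    chrom: str
    strand: str
    blocks: Blocks  # genomic exon blocks of the aligned (trimmed) read
    category: str  # full-length | degraded | fusion | artifact
    subtype: str = ""
    library: str = ""
    # fusion reads carry a second segment
    blocks2: Blocks | None = None
    chrom2: str | None = None
    strand2: str | None = None
    gene2_id: str | None = None


@dataclass
class GroundTruth:
    genes: dict[str, SimGene]
    reads: dict[str, SimRead]
    fusions: dict[str, tuple[str, str]]
    withheld: set[str]
    as_ops_emitted: set[str]

    @property
    def noncoding_genes(self) -> set[str]:
        return {g.id for g in self.genes.values() if not g.coding}


@dataclass
class SimResult:
    config: SimConfig
    outdir: Path
    genome: dict[str, str]
    annotation: Annotation
    truth: GroundTruth
    genome_fa: Path
    annotation_gff3: Path
    reads_fa: Path
    alignments_sam: Path
    pe_support_tsv: Path
    evidence_tsv: Path


# ------------------------------------------------------------------ helpers

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode("ascii")


def _rint(rng, lo, hi):
    return int(rng.integers(lo, hi + 1))


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Uniform substitutions; returns (sequence, n_substitutions)."""
    if rate <= 0 or not seq:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode(), len(hits)


def _spliced_seq(genome: dict[str, str], chrom: str, blocks: Blocks, strand: str) -> str:
    s = "".join(genome[chrom][a:b] for a, b in blocks)
    return s if strand == "+" else revcomp(s)


# ------------------------------------------------------------------ layout

def _make_gene_structure(rng, cfg: SimConfig, chrom: str, start: int, gid: str, coding: bool) -> SimGene:
    n_ex = _rint(rng, *cfg.exons_per_isoform)
    exons = []
    pos = start
    for i in range(n_ex):
        last = i == n_ex - 1
        ex_len = _rint(rng, 300, 500) if last or i == 0 else _rint(rng, 100, 300)
        exons.append((pos, pos + ex_len))
        pos += ex_len
        if not last:
            pos += _rint(rng, 200, 700)
    return SimGene(
        id=gid, chrom=chrom, strand=rng.choice(["+", "-"]), exons=tuple(exons),
        sex=rng.choice(["F", "M"]), coding=coding,
    )


def _layout_genes(rng, cfg: SimConfig) -> list[SimGene]:
    n_nc = int(round(cfg.frac_noncoding_genes * cfg.n_genes))
    n_cd = cfg.n_genes - n_nc
    genes: list[SimGene] = []
    cursors = {f"chr{i+1}": 1000 for i in range(cfg.n_chroms)}
    order = list(cursors)
    ci = 0
    for k in range(n_cd):
        placed = False
        for _ in range(len(order)):
            chrom = order[ci % len(order)]
            g = _make_gene_structure(rng, cfg, chrom, cursors[chrom], f"G{k+1:04d}", True)
            if g.span[1] + 1000 <= cfg.chrom_len:
                cursors[chrom] = g.span[1] + _rint(rng, 3000, 6000)
                genes.append(g)
                placed = True
                ci += 1
                break
            ci += 1
        if not placed:
            raise SimConfigError(
                "chrom_len too small for n_genes with the configured gene sizes"
            )
    # noncoding genes: cycle through positional placements
    hosts = [g for g in genes if g.coding and len(g.exons) >= 3]
    for k in range(n_nc):
        gid = f"N{k+1:04d}"
        placement = PLACEMENTS[k % len(PLACEMENTS)]
        g = _place_noncoding(rng, cfg, gid, placement, hosts, cursors, order, ci)
        ci += 1
        genes.append(g)
    return genes


def _place_noncoding(rng, cfg, gid, placement, hosts, cursors, order, ci) -> SimGene:
    if placement != "intergenic" and not hosts:
        placement = "intergenic"
    if placement == "intergenic":
        for _ in range(len(order)):
            chrom = order[ci % len(order)]
            start = cursors[chrom]
            length = _rint(rng, 400, 1200)
            if start + length + 1000 <= cfg.chrom_len:
                cursors[chrom] = start + length + _rint(rng, 3000, 6000)
                return SimGene(
                    id=gid, chrom=chrom, strand=rng.choice(["+", "-"]),
                    exons=((start, start + length),), sex=rng.choice(["F", "M"]),
                    coding=False, placement="intergenic",
                )
            ci += 1
        raise SimConfigError("chrom_len too small to place noncoding genes")
    host = hosts[int(rng.integers(len(hosts)))]
    introns = build_chain_from_blocks(host.exons)
    if placement == "intronic":
        # fully inside the widest host intron
        d, a = max(introns, key=lambda iv: iv[1] - iv[0])
        room = a - d - 40
        if room < 150:
            return _place_noncoding(rng, cfg, gid, "intergenic", hosts, cursors, order, ci)
        length = min(_rint(rng, 250, 450), room)
        start = d + 20
        return SimGene(
            id=gid, chrom=host.chrom, strand=rng.choice(["+", "-"]),
            exons=((start, start + length),), sex=rng.choice(["F", "M"]),
            coding=False, placement="intronic", host_id=host.id,
        )
    if placement in ("sense", "antisense"):
        ex = host.exons[len(host.exons) // 2]
        start = max(ex[0] - 60, host.span[0])
        length = _rint(rng, 280, 420)
        strand = host.strand if placement == "sense" else ("-" if host.strand == "+" else "+")
        return SimGene(
            id=gid, chrom=host.chrom, strand=strand,
            exons=((start, start + length),), sex=rng.choice(["F", "M"]),
            coding=False, placement=placement, host_id=host.id,
        )
    # "other": two exons in adjacent host introns, own intron spanning a host exon
    if len(introns) < 2:
        # host too simple; fall back to intergenic
        return _place_noncoding(rng, cfg, gid, "intergenic", hosts, cursors, order, ci)
    i = len(introns) // 2
    d1, a1 = introns[i]
    d2, a2 = introns[i + 1]
    e1 = (d1 + 15, min(d1 + 15 + _rint(rng, 100, 160), a1 - 15))
    e2 = (d2 + 15, min(d2 + 15 + _rint(rng, 100, 160), a2 - 15))
    strand = rng.choice(["+", "-"])
    return SimGene(
        id=gid, chrom=host.chrom, strand=strand, exons=(e1, e2),
        sex=rng.choice(["F", "M"]), coding=False, placement="other", host_id=host.id,
    )


# ------------------------------------------------------------------ isoforms

def _variant_exons(rng, exons: Blocks, op: str) -> Blocks | None:
    n = len(exons)
    ex = list(exons)
    if op == "skip" and n >= 3:
        i = _rint(rng, 1, n - 2)
        return tuple(ex[:i] + ex[i + 1:])
    if op == "mskip" and n >= 4:
        i = _rint(rng, 1, n - 3)
        return tuple(ex[:i] + ex[i + 2:])
    if op == "ir" and n >= 2:
        i = _rint(rng, 0, n - 2)
        merged = (ex[i][0], ex[i + 1][1])
        return tuple(ex[:i] + [merged] + ex[i + 2:])
    if op == "mir" and n >= 3:
        i = _rint(rng, 0, n - 3)
        merged = (ex[i][0], ex[i + 2][1])
        return tuple(ex[:i] + [merged] + ex[i + 3:])
    if op == "ae" and n >= 2:
        # shift one donor (exon end) inward/outward; acceptor stays shared
        i = _rint(rng, 0, n - 2)
        delta = int(rng.choice([-1, 1])) * _rint(rng, 15, 40)
        s, e = ex[i]
        new_e = e + delta
        intron_len = ex[i + 1][0] - new_e
        if new_e - s < 50 or intron_len < 50:
            new_e = e - abs(delta)
            if new_e - s < 50:
                return None
        ex[i] = (s, new_e)
        return tuple(ex)
    return None


def _build_isoforms(rng, cfg: SimConfig, genes: list[SimGene]) -> set[str]:
    emitted: set[str] = set()
    gi = 0
    for g in genes:
        base = TrueIsoform(f"{g.id}.I1", g.id, g.chrom, g.strand, g.exons, "base")
        g.isoforms = [base]
        if not g.coding:
            continue
        k = _rint(rng, *cfg.isoforms_per_gene)
        seen = {base.chain}
        j = 2
        for v in range(k - 1):
            op = AS_OPS[(gi + v) % len(AS_OPS)]
            for _ in range(6):  # resample target if duplicate chain
                ex = _variant_exons(rng, g.exons, op)
                if ex is None:
                    break
                iso = TrueIsoform(f"{g.id}.I{j}", g.id, g.chrom, g.strand, ex, op)
                if iso.chain not in seen:
                    seen.add(iso.chain)
                    g.isoforms.append(iso)
                    emitted.add(op)
                    j += 1
                    break
        gi += 1
    return emitted


def _assign_apa(rng, cfg: SimConfig, genes: list[SimGene]) -> None:
    spacing = 40
    for g in genes:
        term = g.exons[-1] if g.strand == "+" else g.exons[0]
        room = (term[1] - term[0]) - 60
        kmax = max(1, min(cfg.apa_sites_per_gene[1], room // spacing + 1))
        k = min(_rint(rng, *cfg.apa_sites_per_gene), kmax)
        if g.strand == "+":
            g.apa_sites = [term[1] - spacing * i for i in range(k)]
        else:
            g.apa_sites = [term[0] + spacing * i for i in range(k)]


# ------------------------------------------------------------------ reads

def _truncate_to_site(iso: TrueIsoform, strand: str, end: int) -> Blocks:
    ex = list(iso.exons)
    if strand == "+":
        s, _ = ex[-1]
        ex[-1] = (s, max(end, s + 20))
    else:
        _, e = ex[0]
        ex[0] = (min(end, e - 20), e)
    return tuple(ex)


def _make_reads(rng, cfg: SimConfig, genes: list[SimGene]) -> list[SimRead]:
    reads: list[SimRead] = []
    counter = 0
    for g in genes:
        site_i = 0
        for iso in g.isoforms:
            for _ in range(_rint(rng, *cfg.reads_per_isoform)):
                site = g.apa_sites[site_i % len(g.apa_sites)]
                site_i += 1
                scatter = int(round(rng.normal(0.0, cfg.end_scatter_sd)))
                blocks = _truncate_to_site(iso, g.strand, site + scatter)
                counter += 1
                reads.append(
                    SimRead(
                        id=f"r{counter:06d}", gene_id=g.id, isoform_id=iso.id,
                        chrom=g.chrom, strand=g.strand, blocks=blocks,
                        category="full-length",
                    )
                )
    return reads


def implant_degradation(read: SimRead, rng: np.random.Generator, min_exons: int = 3) -> SimRead | None:
    """Return a 5'-degraded copy of ``read``, or None when not applicable.

    The degraded copy starts inside an internal exon so that its junction
    chain is a strict, 3'-anchored suffix of the source chain (strand
    aware); the poly(A)-proximal structure is untouched. Reads with fewer
    than ``min_exons`` exons are skipped (no intron would remain).
    """
    ex = list(read.blocks)
    n = len(ex)
    if n < min_exons:
        return None
    if read.strand == "+":
        j = _rint(rng, 1, n - 2)
        s, e = ex[j]
        cut = _rint(rng, s + 10, e - 10)
        new_blocks = tuple([(cut, e)] + ex[j + 1:])
    else:
        j = _rint(rng, 1, n - 2)  # exons dropped from the genomic right
        keep = n - 1 - j
        s, e = ex[keep]
        cut = _rint(rng, s + 10, e - 10)
        new_blocks = tuple(ex[:keep] + [(s, cut)])
    return dataclasses.replace(
        read, id=read.id + "d", blocks=new_blocks, category="degraded", subtype="5p_trim"
    )


def _cut_transcript(iso: TrueIsoform, strand: str, take_5p: bool) -> Blocks:
    """Roughly half of a transcript, cut at an exon boundary."""
    ex = list(iso.exons)
    n = len(ex)
    half = max(1, n // 2)
    if strand == "+":
        return tuple(ex[:half]) if take_5p else tuple(ex[half:])
    # transcript 5' is the genomic right for minus-strand genes
    return tuple(ex[n - half:]) if take_5p else tuple(ex[: n - half])


def _make_fusions(rng, cfg, genes, n_base: int, counter: int,
                  exclude: set[str] = frozenset()) -> list[SimRead]:
    # partners must be annotated genes: fusion criteria require gene hits
    coding = [g for g in genes if g.coding and g.isoforms and g.id not in exclude]
    n_fus = int(round(cfg.frac_fusion_reads * n_base))
    out = []
    if len(coding) < 2:
        return out
    for k in range(n_fus):
        same_chrom = rng.random() < 0.2
        pair = None
        for _ in range(50):
            a, b = rng.choice(len(coding), size=2, replace=False)
            ga, gb = coding[int(a)], coding[int(b)]
            if same_chrom:
                if ga.chrom == gb.chrom and _gene_distance(ga, gb) >= 10_000:
                    pair = (ga, gb)
                    break
            elif ga.chrom != gb.chrom:
                pair = (ga, gb)
                break
        if pair is None:
            continue
        ga, gb = pair
        counter += 1
        out.append(
            SimRead(
                id=f"r{counter:06d}f", gene_id=ga.id, isoform_id=ga.isoforms[0].id,
                chrom=ga.chrom, strand=ga.strand,
                blocks=_cut_transcript(ga.isoforms[0], ga.strand, take_5p=True),
                category="fusion", subtype="inter" if ga.chrom != gb.chrom else "intra",
                gene2_id=gb.id, chrom2=gb.chrom, strand2=gb.strand,
                blocks2=_cut_transcript(gb.isoforms[0], gb.strand, take_5p=False),
            )
        )
    return out


def _gene_distance(a: SimGene, b: SimGene) -> int:
    if a.span[1] <= b.span[0]:
        return b.span[0] - a.span[1]
    if b.span[1] <= a.span[0]:
        return a.span[0] - b.span[1]
    return 0


ARTIFACT_TYPES = ("no5p", "no3p", "nopolya", "internal_primer")


def _make_artifacts(rng, cfg, base_reads: list[SimRead], counter: int) -> list[SimRead]:
    n_art = int(round(cfg.frac_artifact_reads * len(base_reads)))
    out = []
    for k in range(n_art):
        src = base_reads[int(rng.integers(len(base_reads)))]
        sub = ARTIFACT_TYPES[k % len(ARTIFACT_TYPES)]
        counter += 1
        r = dataclasses.replace(src, id=f"r{counter:06d}a", category="artifact", subtype=sub)
        if sub == "internal_primer":
            other = base_reads[int(rng.integers(len(base_reads)))]
            r.gene2_id = other.gene_id
            r.chrom2 = other.chrom
            r.strand2 = other.strand
            r.blocks2 = other.blocks
        out.append(r)
    return out


def translate_evidence(evidence_df, truth: "GroundTruth", isoforms) -> "object":
    """Re-key a truth-isoform evidence table onto detected isoform models.

    Detected isoforms are matched to true isoforms by exact
    (chrom, strand, junction chain) for multi-exon models and by best
    span overlap for mono-exon models; unmatched detected isoforms get
    no row (treated as no-call downstream).
    """
    import pandas as pd

    from ._util import span_overlap

    ev = evidence_df.set_index("isoform_id")
    by_chain: dict[tuple, str] = {}
    mono: list[tuple[str, str, str, tuple[int, int]]] = []
    for g in truth.genes.values():
        for iso in g.isoforms:
            if iso.chain:
                by_chain[(iso.chrom, iso.strand, iso.chain)] = iso.id
            else:
                mono.append((iso.id, iso.chrom, iso.strand, (iso.exons[0][0], iso.exons[-1][1])))
    rows = []
    for det in isoforms:
        tid = None
        if det.chain:
            tid = by_chain.get((det.chrom, det.strand, det.chain))
        else:
            best = 0
            for iid, chrom, strand, span in mono:
                if chrom == det.chrom and strand == det.strand:
                    ov = span_overlap(span, det.span)
                    if ov > best:
                        best, tid = ov, iid
        if tid is not None and tid in ev.index:
            row = ev.loc[tid].to_dict()
            row["isoform_id"] = det.id
            rows.append(row)
    cols = ["isoform_id"] + [c for c in evidence_df.columns if c != "isoform_id"]
    return pd.DataFrame(rows, columns=cols)


# ------------------------------------------------------------------ sequence & SAM assembly

def _read_sequence(rng, cfg, genome, read: SimRead) -> tuple[str, list[tuple[str, int]]]:
    """Full read sequence (with primers/poly(A)) and per-segment (seq, nm).

    Returns the FASTA sequence plus the erroneous transcript segment(s)
    used for SAM records so that FASTA and SAM carry identical bases.
    """
    t1 = _spliced_seq(genome, read.chrom, read.blocks, read.strand)
    t1e, nm1 = _apply_errors(rng, t1, cfg.per_base_error)
    segs = [(t1e, nm1)]
    insert = t1e
    if read.blocks2 is not None and read.category == "fusion":
        t2 = _spliced_seq(genome, read.chrom2, read.blocks2, read.strand2)
        t2e, nm2 = _apply_errors(rng, t2, cfg.per_base_error)
        segs.append((t2e, nm2))
        insert = t1e + t2e
    tail = "A" * _rint(rng, *cfg.polya_len)
    p5, _ = _apply_errors(rng, cfg.primer_5p, cfg.per_base_error)
    p3, _ = _apply_errors(rng, revcomp(cfg.primer_3p), cfg.per_base_error)
    sub = read.subtype
    if read.category == "artifact":
        if sub == "no5p":
            p5 = ""
        elif sub == "no3p":
            p3 = ""
        elif sub == "nopolya":
            tail = ""
        elif sub == "internal_primer":
            t2 = _spliced_seq(genome, read.chrom2, read.blocks2, read.strand2)
            t2e, _ = _apply_errors(rng, t2, cfg.per_base_error)
            insert = t1e + revcomp(cfg.primer_3p) + cfg.primer_5p + t2e
    full = p5 + insert + tail + p3
    if rng.random() < 0.3:  # strand of the sequenced molecule is arbitrary
        full = revcomp(full)
    return full, segs


def _sam_record(header, read_id, chrom, strand, blocks, seq_err, nm,
                q_start, q_end, read_len, supplementary=False) -> pysam.AlignedSegment:
    """One SAM record; seq_err is the aligned (trimmed) segment in transcript
    orientation, q_start/q_end its interval on the trimmed read."""
    a = pysam.AlignedSegment(header)
    a.query_name = read_id
    a.reference_name = chrom
    a.reference_start = blocks[0][0]
    a.mapping_quality = 60
    flag = 0
    if strand == "-":
        flag |= 16
    if supplementary:
        flag |= 2048
    a.flag = flag
    cig = []
    lead = q_start if strand == "+" else read_len - q_end
    tail = read_len - q_end if strand == "+" else q_start
    if lead:
        cig.append((4, lead))
    for i, (s, e) in enumerate(blocks):
        if i:
            cig.append((3, s - blocks[i - 1][1]))
        cig.append((0, e - s))
    if tail:
        cig.append((4, tail))
    a.cigartuples = cig
    genome_oriented = seq_err if strand == "+" else revcomp(seq_err)
    a.query_sequence = ("N" * lead) + genome_oriented + ("N" * tail)
    a.set_tag("NM", int(nm))
    return a


# ------------------------------------------------------------------ main entry

def simulate(config: SimConfig, outdir: str | Path) -> SimResult:
    """Run the generator; writes all files under ``outdir`` and returns them."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    (s_genome, s_layout, s_iso, s_apa, s_reads, s_deg, s_fus, s_art, s_seq,
     s_withheld, s_evid) = [np.random.default_rng(c) for c in ss.spawn(11)]

    genome = {f"chr{i+1}": _rand_seq(s_genome, config.chrom_len) for i in range(config.n_chroms)}

    genes = _layout_genes(s_layout, config) if config.n_genes > 0 else []
    as_ops = _build_isoforms(s_iso, config, genes)
    _assign_apa(s_apa, config, genes)

    base_reads = _make_reads(s_reads, config, genes)

    degraded: list[SimRead] = []
    n_deg = int(round(config.frac_degraded_reads * len(base_reads)))
    eligible = [r for r in base_reads if len(r.blocks) >= 3]
    if eligible and n_deg:
        idx = s_deg.choice(len(eligible), size=min(n_deg, len(eligible)), replace=False)
        for i in sorted(int(x) for x in idx):
            d = implant_degradation(eligible[i], s_deg)
            if d is not None:
                degraded.append(d)

    # reference annotation: base isoform of each retained coding gene;
    # withheld genes are chosen before fusion reads so fusion partners
    # can be restricted to annotated genes
    hosts_in_use = {g.host_id for g in genes if g.host_id}
    coding_ids = [g.id for g in genes if g.coding and g.id not in hosts_in_use]
    n_hold = min(int(round(config.frac_withheld_genes * len(coding_ids))), len(coding_ids))
    withheld = set()
    if n_hold:
        withheld = {
            coding_ids[int(i)]
            for i in s_withheld.choice(len(coding_ids), size=n_hold, replace=False)
        }

    fusions = _make_fusions(s_fus, config, genes, len(base_reads), len(base_reads),
                            exclude=withheld)
    artifacts = _make_artifacts(s_art, config, base_reads, len(base_reads) + len(fusions))

    all_reads = base_reads + degraded + fusions + artifacts

    gene_by_id = {g.id: g for g in genes}
    ann_genes = {}
    for g in genes:
        if not g.coding or g.id in withheld:
            continue
        base = g.isoforms[0]
        tx = AnnTranscript(
            id=f"{g.id}.T1", gene_id=g.id, chrom=g.chrom, strand=g.strand, exons=base.exons
        )
        ann_genes[g.id] = AnnGene(
            id=g.id, chrom=g.chrom, strand=g.strand, span=g.span, transcripts=(tx,)
        )
    annotation = Annotation(genes=ann_genes)

    # sequences, libraries, SAM records
    header = iio.sam_header({c: len(s) for c, s in genome.items()})
    fasta_records: list[tuple[str, str]] = []
    sam_records: list[pysam.AlignedSegment] = []
    for read in all_reads:
        full, segs = _read_sequence(s_seq, config, genome, read)
        fasta_records.append((read.id, full))
        tlen = sum(len(s) for s, _ in segs)
        read.library = f"{gene_by_id[read.gene_id].sex} {'0-2k' if tlen < 2000 else '2k+'}"
        if read.category == "artifact":
            continue  # artifacts are dropped before alignment in the real pipeline
        if read.category == "fusion":
            (s1, nm1), (s2, nm2) = segs
            sam_records.append(
                _sam_record(header, read.id, read.chrom, read.strand, read.blocks,
                            s1, nm1, 0, len(s1), tlen)
            )
            sam_records.append(
                _sam_record(header, read.id, read.chrom2, read.strand2, read.blocks2,
                            s2, nm2, len(s1), tlen, tlen, supplementary=True)
            )
        else:
            s1, nm1 = segs[0]
            sam_records.append(
                _sam_record(header, read.id, read.chrom, read.strand, read.blocks,
                            s1, nm1, 0, len(s1), tlen)
            )

    truth = GroundTruth(
        genes={g.id: g for g in genes},
        reads={r.id: r for r in all_reads},
        fusions={r.id: (r.gene_id, r.gene2_id) for r in fusions},
        withheld=withheld,
        as_ops_emitted=as_ops,
    )

    paths = _write_outputs(config, outdir, genome, annotation, fasta_records, sam_records, truth, s_evid)
    return SimResult(
        config=config, outdir=outdir, genome=genome, annotation=annotation, truth=truth, **paths
    )


def _write_outputs(config, outdir, genome, annotation, fasta_records, sam_records, truth, rng_ev):
    import pandas as pd

    genome_fa = outdir / "genome.fa"
    iio.write_fasta(genome.items(), genome_fa)
    annotation_gff3 = outdir / "annotation.gff3"
    iio.write_annotation_gff3(annotation, annotation_gff3)
    reads_fa = outdir / "reads.fa"
    iio.write_fasta(fasta_records, reads_fa)
    alignments_sam = outdir / "alignments.sam"
    iio.write_sam(alignments_sam, {c: len(s) for c, s in genome.items()}, sam_records)

    rc = pd.DataFrame(
        [
            {
                "read_id": r.id, "category": r.category, "subtype": r.subtype,
                "gene_id": r.gene_id, "isoform_id": r.isoform_id, "library": r.library,
            }
            for r in truth.reads.values()
        ]
    )
    iio.write_tsv(rc, outdir / "truth_read_class.tsv")

    iso_rows = []
    for g in truth.genes.values():
        for iso in g.isoforms:
            iso_rows.append(
                {
                    "gene_id": g.id, "isoform_id": iso.id, "chrom": iso.chrom,
                    "strand": iso.strand, "op": iso.op,
                    "exons": ",".join(f"{s}-{e}" for s, e in iso.exons),
                }
            )
    iio.write_tsv(pd.DataFrame(iso_rows), outdir / "truth_isoforms.tsv")

    apa_rows = [
        {"gene_id": g.id, "chrom": g.chrom, "strand": g.strand, "position": p}
        for g in truth.genes.values()
        for p in g.apa_sites
    ]
    iio.write_tsv(pd.DataFrame(apa_rows), outdir / "truth_apa.tsv")

    fus_rows = [
        {"read_id": rid, "gene_a": a, "gene_b": b}
        for rid, (a, b) in truth.fusions.items()
    ]
    iio.write_tsv(pd.DataFrame(fus_rows, columns=["read_id", "gene_a", "gene_b"]),
                  outdir / "truth_fusions.tsv")

    nc_rows = [
        {"gene_id": g.id, "placement": g.placement, "host_id": g.host_id or ""}
        for g in truth.genes.values()
        if not g.coding
    ]
    iio.write_tsv(pd.DataFrame(nc_rows, columns=["gene_id", "placement", "host_id"]),
                  outdir / "truth_noncoding.tsv")
    iio.write_tsv(pd.DataFrame({"gene_id": sorted(truth.withheld)}),
                  outdir / "truth_withheld.tsv")

    # PE support for every true fusion gene pair (synthesized short-read evidence)
    pe_rows = [
        {"gene_a": min(a, b), "gene_b": max(a, b), "pe_count": int(rng_ev.integers(3, 8))}
        for a, b in sorted(set(truth.fusions.values()))
    ]
    pe_support_tsv = outdir / "pe_support.tsv"
    iio.write_tsv(pd.DataFrame(pe_rows, columns=["gene_a", "gene_b", "pe_count"]), pe_support_tsv)

    # database-hit / coding-potential evidence per true isoform (synthetic)
    ev_rows = []
    for g in truth.genes.values():
        for iso in g.isoforms:
            coding = g.coding
            ev_rows.append(
                {
                    "isoform_id": iso.id,
                    "nr_hit": int(coding), "swissprot_hit": int(coding),
                    "cog_hit": int(coding and rng_ev.random() < 0.8),
                    "kog_hit": int(coding and rng_ev.random() < 0.8),
                    "cp_score": round(float(rng_ev.uniform(0.6, 0.99) if coding
                                            else rng_ev.uniform(0.0, 0.2)), 4),
                }
            )
    evidence_tsv = outdir / "evidence.tsv"
    iio.write_tsv(pd.DataFrame(ev_rows), evidence_tsv)

    (outdir / "sim_config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=1, sort_keys=True) + "\n"
    )
    return dict(
        genome_fa=genome_fa, annotation_gff3=annotation_gff3, reads_fa=reads_fa,
        alignments_sam=alignments_sam, pe_support_tsv=pe_support_tsv, evidence_tsv=evidence_tsv,
    )
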