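"""lncRNA candidate filtering and positional classification.

A transcript is a lncRNA candidate when it has no hit in any of the four
protein databases (NR, Swiss-Prot, COG, KOG), a coding-potential score
below the cutoff (default 0.364, a common published convention for
CPAT-style scores), and a length of at least 200 bases. Candidates are
classified against the annotation as intergenic, intronic, sense,
antisense or other.

Database searching and coding-potential model scoring are external;
their results arrive as an evidence table. ``longest_orf_fraction``
offers a crude built-in score (longest ORF length over transcript
length) for synthetic fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ._util import round_half_up, span_overlap
from .models import Annotation, IsoformModel

log = logging.getLogger(__name__)

HIT_COLUMNS = ("nr_hit", "swissprot_hit", "cog_hit", "kog_hit")
POSITIONAL_CLASSES = ("intergenic", "intronic", "sense", "antisense", "other")


@dataclass(frozen=True)
class LncRnaCandidate:
    isoform_id: str
    length: int
    positional_class: str | None = None


def filter_lncrna(
    isoforms: Sequence[IsoformModel],
    evidence: pd.DataFrame,
    cp_cutoff: float = 0.364,
    min_length: int = 200,
) -> list[LncRnaCandidate]:
    """Apply the hit/coding-potential/length cascade.

    ``evidence`` columns: isoform_id, nr_hit, swissprot_hit, cog_hit,
    kog_hit (0/1), cp_score (float) — or a boolean ``coding_call``
    column that bypasses the score. Isoforms without an evidence row are
    excluded with a warning (no-call).
    """
    ev = evidence.set_index("isoform_id")
    out = []
    for iso in isoforms:
        if iso.id not in ev.index:
            log.warning("isoform %s has no evidence row; excluded (no-call)", iso.id)
            continue
        row = ev.loc[iso.id]
        if any(bool(row.get(c, 0)) for c in HIT_COLUMNS):
            continue
        if "coding_call" in ev.columns:
            if bool(row["coding_call"]):
                continue
        elif float(row["cp_score"]) >= cp_cutoff:
            continue
        if iso.length < min_length:
            continue
        out.append(LncRnaCandidate(isoform_id=iso.id, length=iso.length))
    return out


def longest_orf_fraction(sequence: str) -> float:
    """Longest sense-strand ORF length (ATG..stop, any frame) over length."""
    seq = sequence.upper()
    n = len(seq)
    if n == 0:
        return 0.0
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if codon == "ATG" and start is None:
                start = i
            elif codon in stops and start is not None:
                best = max(best, i + 3 - start)
                start = None
    return best / n


def classify_position(iso: IsoformModel, annotation: Annotation) -> str:
    """Positional class of one transcript against the gene annotation.

    Precedence: intergenic (no gene-span overlap on either strand);
    intronic (entire span inside one intron of some transcript, either
    strand); sense (some exon of the transcript overlaps a same-strand
    annotated exon); antisense (exonic overlap on the opposite strand);
    other (any remaining partial-overlap configuration).
    """
    overlapping = [
        g for g in annotation.genes.values()
        if g.chrom == iso.chrom and span_overlap(iso.span, g.span) > 0
    ]
    if not overlapping:
        return "intergenic"
    for g in overlapping:
        for t in g.transcripts:
            for d, a in t.chain:
                if d <= iso.span[0] and iso.span[1] <= a:
                    return "intronic"
    for same_strand in (True, False):
        for g in overlapping:
            if (g.strand == iso.strand) != same_strand:
                continue
            for t in g.transcripts:
                for ex in t.exons:
                    if any(span_overlap(ex, ce) > 0 for ce in iso.exons):
                        return "sense" if same_strand else "antisense"
    return "other"


def classify_candidates(
    candidates: Iterable[LncRnaCandidate],
    isoforms_by_id: dict[str, IsoformModel],
    annotation: Annotation,
) -> list[LncRnaCandidate]:
    out = []
    for c in candidates:
        cls = classify_position(isoforms_by_id[c.isoform_id], annotation)
        out.append(LncRnaCandidate(c.isoform_id, c.length, cls))
    return out


def length_summary(
    candidates: Sequence[LncRnaCandidate],
    labels: dict[str, str] | None = None,
    bin_width: int = 500,
    bin_max: int = 3500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean candidate length per library label and a binned histogram.

    Returns (means, bins). Mean lengths are rounded half-up to integer
    bases; labels without candidates are reported with a missing mean.
    Bins are ``bin_width`` wide from 0 to ``bin_max`` with a final
    open-ended bin.
    """
    rows = [
        {
            "label": (labels or {}).get(c.isoform_id, "all"),
            "length": c.length,
        }
        for c in candidates
    ]
    df = pd.DataFrame(rows, columns=["label", "length"])
    if df.empty:
        means = pd.DataFrame(columns=["label", "mean_length_bp", "n"])
    else:
        means = (
            df.groupby("label")
            .agg(mean_length_bp=("length", "mean"), n=("length", "size"))
            .reset_index()
        )
        means["mean_length_bp"] = [round_half_up(m, 0) for m in means["mean_length_bp"]]
    edges = list(range(0, bin_max + 1, bin_width))
    labels_bins = [f"{lo}-{lo + bin_width}" for lo in edges[:-1]] + [f">{bin_max}"]
    counts = [0] * len(labels_bins)
    for L in df["length"]:
        idx = min(int(L) // bin_width, len(labels_bins) - 1)
        counts[idx] += 1
    bins = pd.DataFrame({"bin": labels_bins, "count": counts})
    return means, bins
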