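"""Classification of CCS reads into full-length / FLNC categories.

A read is *full length* (FL) when it carries a 5' primer, a 3' primer
and a poly(A) tail; it is *full-length non-chimeric* (FLNC) when it is
additionally free of internal primer hits. Primer matching is an
ungapped scan allowing a bounded number of mismatches (default 2 for
~30 nt primers); the poly(A) tail is the longest terminal window of at
least ``min_len`` bases whose A fraction meets ``min_purity``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import revcomp, round_half_up, seq_array

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CcsRead:
    id: str
    sequence: str
    n_passes: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id}: empty sequence")


@dataclass
class ReadClassification:
    read_id: str
    has_5p: bool
    has_3p: bool
    has_polya: bool
    is_chimeric: bool
    trimmed_sequence: str

    @property
    def is_fl(self) -> bool:
        return self.has_5p and self.has_3p and self.has_polya

    @property
    def is_flnc(self) -> bool:
        return self.is_fl and not self.is_chimeric


def detect_polya(sequence: str, min_len: int = 20, min_purity: float = 0.8) -> tuple[bool, int]:
    """Find a poly(A) tail at the 3' end of an (oriented) sequence.

    A window is a terminal (3'-anchored) suffix. The flag is true iff any
    suffix of length >= ``min_len`` has an A fraction >= ``min_purity``.
    The accepted tail is the qualifying suffix with the highest A
    fraction, ties resolved to the longest, so a pure tail is reported
    exactly. Returns ``(found, tail_start)``; ``tail_start`` indexes the
    leftmost base of the accepted tail, or -1 when none qualifies.
    """
    n = len(sequence)
    if n < min_len or min_len <= 0:
        return False, -1
    arr = seq_array(sequence) == ord("A")
    # counts[L] = number of A in the last L bases
    counts = np.concatenate(([0], np.cumsum(arr[::-1])))
    lengths = np.arange(n + 1)
    with np.errstate(invalid="ignore"):
        purity = np.where(lengths > 0, counts / np.maximum(lengths, 1), 0.0)
    ok = (purity >= min_purity) & (lengths >= min_len)
    if not ok.any():
        return False, -1
    cand = np.nonzero(ok)[0]
    best = int(cand[np.lexsort((cand, purity[cand]))[-1]])
    return True, n - best


def find_primer_matches(primer: str, seq: str, max_mismatch: int = 2) -> list[tuple[int, int]]:
    """Ungapped scan: all (start, n_mismatch) with n_mismatch <= max_mismatch."""
    m, n = len(primer), len(seq)
    if n < m:
        return []
    s = seq_array(seq)
    p = seq_array(primer)
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    mm = (windows != p).sum(axis=1)
    hits = np.nonzero(mm <= max_mismatch)[0]
    return [(int(i), int(mm[i])) for i in hits]


def _orient_score(seq, primer5, primer3, max_mismatch, end_window):
    """Terminal primer evidence for one orientation of a read."""
    n = len(seq)
    p5_hits = find_primer_matches(primer5, seq, max_mismatch)
    p3rc = revcomp(primer3)
    p3_hits = find_primer_matches(p3rc, seq, max_mismatch)
    term5 = [h for h in p5_hits if h[0] <= end_window]
    term3 = [h for h in p3_hits if h[0] + len(p3rc) >= n - end_window]
    score = (len(term5) > 0) + (len(term3) > 0)
    mm = min((h[1] for h in term5), default=max_mismatch + 1) + min(
        (h[1] for h in term3), default=max_mismatch + 1
    )
    return score, mm, term5, term3, p5_hits, p3_hits


def classify_read(
    read: CcsRead,
    primer_5p: str,
    primer_3p: str,
    min_polya: int = 20,
    polya_purity: float = 0.8,
    max_mismatch: int = 2,
    end_window: int = 100,
    internal_margin: int = 50,
) -> ReadClassification:
    """Orient a read, detect its three FL signals, flag chimeras, and trim.

    Orientation is chosen to place the 5' primer upstream; when both
    orientations score identically on terminal primer evidence the read
    is classified non-FL (ambiguous) and returned untrimmed. A chimera
    is any read with an extra primer hit at least ``internal_margin``
    bases away from both termini.
    """
    if not primer_5p or not primer_3p:
        raise ValueError("primer sequences must be non-empty")
    fwd = read.sequence.upper()
    rev = revcomp(fwd)
    sf = _orient_score(fwd, primer_5p, primer_3p, max_mismatch, end_window)
    sr = _orient_score(rev, primer_5p, primer_3p, max_mismatch, end_window)
    if (sf[0], -sf[1]) > (sr[0], -sr[1]):
        seq, sc = fwd, sf
    elif (sf[0], -sf[1]) < (sr[0], -sr[1]):
        seq, sc = rev, sr
    else:
        if sf[0] > 0:
            log.info("read %s: ambiguous orientation; classified non-FL", read.id)
            return ReadClassification(read.id, False, False, False, False, fwd)
        seq, sc = fwd, sf  # no primer evidence either way
    _, _, term5, term3, p5_hits, p3_hits = sc
    n = len(seq)
    has_5p = bool(term5)
    has_3p = bool(term3)
    five_end = max((h[0] + len(primer_5p) for h in term5), default=0)
    three_start = min((h[0] for h in term3), default=n)

    insert = seq[five_end:three_start]
    has_polya, tail_rel = detect_polya(insert, min_polya, polya_purity)
    polya_start = five_end + tail_rel if has_polya else three_start

    chimeric = False
    for start, plen in [(h[0], len(primer_5p)) for h in p5_hits] + [
        (h[0], len(primer_3p)) for h in p3_hits
    ]:
        if start >= internal_margin and start + plen <= n - internal_margin:
            # a primer body well inside the read, clear of both termini
            if not (start < five_end or start >= three_start):
                chimeric = True
                break
    trimmed = seq[five_end:polya_start]
    if not trimmed:
        trimmed = insert or seq
    return ReadClassification(read.id, has_5p, has_3p, has_polya, chimeric, trimmed)


def classify_reads(
    reads: Iterable[CcsRead],
    primer_5p: str,
    primer_3p: str,
    min_passes: int = 1,
    **kwargs,
) -> list[ReadClassification]:
    """Classify every read with at least ``min_passes`` CCS passes."""
    return [
        classify_read(r, primer_5p, primer_3p, **kwargs)
        for r in reads
        if r.n_passes >= min_passes
    ]


def summarize_libraries(
    classifications: Sequence[ReadClassification],
    library_map: Mapping[str, str],
) -> pd.DataFrame:
    """Per-library signal counts plus a pooled row, Table-2 style.

    Columns: library, n_ccs, n_5p, n_3p, n_polya, n_fl, n_flnc,
    mean_flnc_len, flnc_fraction_pct (pooled row only carries the
    dataset-wide FLNC percentage of all CCS reads).
    """
    rows = []
    for c in classifications:
        if c.read_id not in library_map:
            raise KeyError(f"read {c.read_id} has no library label")
        rows.append(
            {
                "library": library_map[c.read_id],
                "n_ccs": 1,
                "n_5p": int(c.has_5p),
                "n_3p": int(c.has_3p),
                "n_polya": int(c.has_polya),
                "n_fl": int(c.is_fl),
                "n_flnc": int(c.is_flnc),
                "flnc_len": len(c.trimmed_sequence) if c.is_flnc else np.nan,
            }
        )
    if not rows:
        log.warning("no reads to summarize; emitting all-zero pooled row")
        return pd.DataFrame(
            [
                {
                    "library": "ALL", "n_ccs": 0, "n_5p": 0, "n_3p": 0, "n_polya": 0,
                    "n_fl": 0, "n_flnc": 0, "mean_flnc_len": 0.0, "flnc_fraction_pct": 0.0,
                }
            ]
        )
    df = pd.DataFrame(rows)
    agg = df.groupby("library", sort=True).agg(
        n_ccs=("n_ccs", "sum"), n_5p=("n_5p", "sum"), n_3p=("n_3p", "sum"),
        n_polya=("n_polya", "sum"), n_fl=("n_fl", "sum"), n_flnc=("n_flnc", "sum"),
        mean_flnc_len=("flnc_len", "mean"),
    ).reset_index()
    pooled = {
        "library": "ALL",
        **{c: int(agg[c].sum()) for c in ("n_ccs", "n_5p", "n_3p", "n_polya", "n_fl", "n_flnc")},
        "mean_flnc_len": float(df["flnc_len"].mean()) if df["flnc_len"].notna().any() else 0.0,
    }
    out = pd.concat([agg, pd.DataFrame([pooled])], ignore_index=True)
    out["flnc_fraction_pct"] = [
        round_half_up(100.0 * f / c, 2) if c else 0.0
        for f, c in zip(out["n_flnc"], out["n_ccs"])
    ]
    return out
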