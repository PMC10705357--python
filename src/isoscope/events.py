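"""Alternative-splicing event classification between isoforms of one locus.

Ten categories: exact exon skipping (SKIP), multiple cassette skipping
(MSKIP), intron retention (IR), multiple intron retention (MIR), and
alternative exon ends (AE), plus the X-prefixed "approximate boundary"
variant of each, emitted instead of the exact type when the structural
pattern matches but a corresponding splice boundary differs by 1..fuzz
bases.

Pattern definitions (isoform pair A, B; all half-open genomic
coordinates):

* SKIP / MSKIP — one isoform has an intron (d, a) that fully contains
  one (SKIP) or >= 2 (MSKIP) complete internal exons of the other; the
  other isoform's flanking splice boundaries (exon end before, exon
  start after the skipped block) must equal d and a (exact) or lie
  within the fuzz (approximate).
* IR / MIR — one isoform has an exon that fully contains one (IR) or
  >= 2 (MIR) introns of the other; the spliced isoform's outer exon
  boundaries over the region must match the retaining exon's
  boundaries, except that boundaries which are transcript termini in
  both isoforms are unconstrained (transcript ends are cleavage
  positions, not splice sites).
* AE — a pair of overlapping introns sharing one boundary exactly while
  the other differs (alternative donor or acceptor); approximate when
  the nearly-shared boundary differs by 1..fuzz. Intron pairs in which
  either intron fully contains an exon of the other isoform are
  excluded (those are skipping patterns).

Events are symmetric in the pair and deduplicated per locus by
(type, region).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .models import IsoformModel

EVENT_TYPES = ("SKIP", "MSKIP", "IR", "MIR", "AE", "XSKIP", "XMSKIP", "XIR", "XMIR", "XAE")


@dataclass(frozen=True)
class AsEvent:
    type: str
    locus_id: str
    isoform_pair: tuple[str, str]
    region: tuple[int, int]
    n_exons_or_introns: int

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown AS event type {self.type}")


def _skip_events(spliced: IsoformModel, other: IsoformModel, fuzz: int):
    """Introns of ``spliced`` that skip complete internal exons of ``other``."""
    out = []
    oex = other.exons
    for d, a in spliced.chain:
        inside = [k for k, (s, e) in enumerate(oex) if s >= d and e <= a]
        if not inside:
            continue
        if inside[0] == 0 or inside[-1] == len(oex) - 1:
            continue  # terminal exons cannot be cassette exons
        if inside != list(range(inside[0], inside[-1] + 1)):
            continue
        d2 = oex[inside[0] - 1][1]  # other's donor flanking the block
        a2 = oex[inside[-1] + 1][0]
        delta = max(abs(d - d2), abs(a - a2))
        n = len(inside)
        base = "SKIP" if n == 1 else "MSKIP"
        region = (oex[inside[0]][0], oex[inside[-1]][1])
        if delta == 0:
            out.append((base, region, n))
        elif delta <= fuzz:
            out.append(("X" + base, region, n))
    return out


def _ir_events(retainer: IsoformModel, spliced: IsoformModel, fuzz: int):
    """Exons of ``retainer`` that retain complete introns of ``spliced``."""
    out = []
    sx = spliced.exons
    schain = spliced.chain
    for ei, (s, e) in enumerate(retainer.exons):
        inside = [k for k, (d, a) in enumerate(schain) if d >= s and a <= e]
        if not inside:
            continue
        if inside != list(range(inside[0], inside[-1] + 1)):
            continue
        s2 = sx[inside[0]][0]  # spliced outer exon boundaries over the region
        e2 = sx[inside[-1] + 1][1]
        deltas = []
        left_term = ei == 0 and inside[0] == 0
        right_term = ei == len(retainer.exons) - 1 and inside[-1] == len(schain) - 1
        if not left_term:
            deltas.append(abs(s - s2))
        if not right_term:
            deltas.append(abs(e - e2))
        delta = max(deltas, default=0)
        n = len(inside)
        base = "IR" if n == 1 else "MIR"
        region = (schain[inside[0]][0], schain[inside[-1]][1])
        if delta == 0:
            out.append((base, region, n))
        elif delta <= fuzz:
            out.append(("X" + base, region, n))
    return out


def _contains_exon(intron: tuple[int, int], iso: IsoformModel) -> bool:
    d, a = intron
    return any(s >= d and e <= a for s, e in iso.exons)


def _ae_events(a_iso: IsoformModel, b_iso: IsoformModel, fuzz: int):
    out = []
    for ia in a_iso.chain:
        for ib in b_iso.chain:
            if ia[1] <= ib[0] or ib[1] <= ia[0]:
                continue  # disjoint introns
            if ia == ib:
                continue
            if _contains_exon(ia, b_iso) or _contains_exon(ib, a_iso):
                continue
            dd, da = abs(ia[0] - ib[0]), abs(ia[1] - ib[1])
            if (dd == 0) != (da == 0):
                region = (
                    (min(ia[1], ib[1]), max(ia[1], ib[1]))
                    if dd == 0
                    else (min(ia[0], ib[0]), max(ia[0], ib[0]))
                )
                out.append(("AE", region, 1))
            elif dd and da and min(dd, da) <= fuzz:
                region = (
                    (min(ia[0], ib[0]), max(ia[0], ib[0]))
                    if dd > da
                    else (min(ia[1], ib[1]), max(ia[1], ib[1]))
                )
                out.append(("XAE", region, 1))
    return out


def classify_pair(
    isoA: IsoformModel, isoB: IsoformModel, fuzz: int = 10
) -> list[AsEvent]:
    """All AS events between two isoforms of the same locus.

    Symmetric: the result does not depend on argument order (events are
    detected in both directions and deduplicated on (type, region)).
    With ``fuzz=0`` no approximate (X) type is ever emitted.
    """
    if isoA.locus_id != isoB.locus_id:
        raise ValueError("classify_pair requires isoforms of the same locus")
    if fuzz < 0:
        raise ValueError("fuzz must be >= 0")
    raw = []
    raw += _skip_events(isoA, isoB, fuzz) + _skip_events(isoB, isoA, fuzz)
    raw += _ir_events(isoA, isoB, fuzz) + _ir_events(isoB, isoA, fuzz)
    raw += _ae_events(isoA, isoB, fuzz)
    pair = tuple(sorted((isoA.id, isoB.id)))
    seen = set()
    events = []
    for etype, region, n in raw:
        key = (etype, region)
        if key in seen:
            continue
        seen.add(key)
        events.append(
            AsEvent(
                type=etype, locus_id=isoA.locus_id or "", isoform_pair=pair,
                region=region, n_exons_or_introns=n,
            )
        )
    return events


def classify_locus(
    isoforms: Sequence[IsoformModel], fuzz: int = 10
) -> tuple[list[AsEvent], list[AsEvent]]:
    """AS events over all isoform pairs of one locus.

    Returns (deduplicated, raw): the deduplicated list keeps one event
    per (type, region) per locus; the raw list keeps one per pair for
    audit.
    """
    raw: list[AsEvent] = []
    for i in range(len(isoforms)):
        for j in range(i + 1, len(isoforms)):
            raw.extend(classify_pair(isoforms[i], isoforms[j], fuzz))
    seen = set()
    dedup = []
    for ev in raw:
        key = (ev.type, ev.region)
        if key not in seen:
            seen.add(key)
            dedup.append(ev)
    return dedup, raw


def summarize_events(
    events: Iterable[AsEvent],
    labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Counts per event type (and per library label when provided).

    ``labels`` maps isoform id -> library label; an event is attributed
    to the label of the first isoform of its pair that has one, else
    "all". Proportions are percentages to 2 decimals; the TOTAL row
    carries the grand total.
    """
    from ._util import round_half_up

    rows = []
    for ev in events:
        lab = "all"
        if labels:
            for iid in ev.isoform_pair:
                if iid in labels:
                    lab = labels[iid]
                    break
        rows.append({"type": ev.type, "library": lab})
    if not rows:
        df = pd.DataFrame({"type": list(EVENT_TYPES)})
        df["count"] = 0
        df["share_pct"] = 0.0
        return df
    df = pd.DataFrame(rows)
    if labels:
        counts = df.groupby(["type", "library"]).size().rename("count").reset_index()
    else:
        counts = (
            df.groupby("type").size().reindex(EVENT_TYPES, fill_value=0)
            .rename("count").reset_index()
        )
    total = int(counts["count"].sum())
    counts["share_pct"] = [
        round_half_up(100.0 * c / total, 2) if total else 0.0 for c in counts["count"]
    ]
    return counts
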