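"""Tabular summaries: library totals, category shares, length bins.

All percentages are rounded half-up to two decimals, matching how such
tables are conventionally printed. Bundled under ``data/`` are the
published summary tables of a P. sinensis full-length-transcriptome
sequencing study (library statistics, CCS read classification, AS event
category counts, KOG category counts, gene-locus length bins) so the
report stage can replay their arithmetic without the primary data.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Sequence

import pandas as pd

from ._util import round_half_up

log = logging.getLogger(__name__)

DATA_TABLES = (
    "table1_libraries",
    "table2_ccs_classification",
    "as_event_counts",
    "kog_categories",
    "locus_length_bins",
)


def load_table(name: str) -> pd.DataFrame:
    """Load a bundled summary table by name (see ``DATA_TABLES``)."""
    if name not in DATA_TABLES:
        raise KeyError(f"unknown bundled table {name!r}; available: {DATA_TABLES}")
    ref = resources.files("isoscope.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def aggregate_library_stats(
    per_library: pd.DataFrame, sum_columns: Sequence[str]
) -> pd.Series:
    """Column-wise totals for extensive quantities (bases, read counts).

    Intensive columns (means, N50) are left per-library and not
    aggregated. Raises on non-numeric cells, naming the row and column.
    """
    totals = {}
    for col in sum_columns:
        vals = pd.to_numeric(per_library[col], errors="coerce")
        if vals.isna().any():
            row = per_library.index[vals.isna()][0]
            raise ValueError(f"non-numeric cell at row {row!r}, column {col!r}")
        totals[col] = int(vals.sum()) if (vals == vals.round()).all() else float(vals.sum())
    return pd.Series(totals)


def category_shares(table: pd.DataFrame, label_col: str = "category", count_col: str = "count") -> pd.DataFrame:
    """Percentage share per category row, half-up to 2 decimals."""
    total = int(table[count_col].sum())
    if total == 0:
        log.warning("category table has zero total; empty shares")
        return pd.DataFrame(columns=[label_col, count_col, "share_pct"])
    out = table[[label_col, count_col]].copy()
    out["share_pct"] = [round_half_up(100.0 * c / total, 2) for c in out[count_col]]
    return out


def length_bin_shares(
    lengths: Sequence[int], edges: Sequence[int] = (1000, 2000, 3000)
) -> pd.DataFrame:
    """Counts and shares of lengths in (<e1, e1-e2, ..., >elast) bins."""
    edges = list(edges)
    labels = (
        [f"<{edges[0]}"]
        + [f"{edges[i]}-{edges[i + 1]}" for i in range(len(edges) - 1)]
        + [f">{edges[-1]}"]
    )
    counts = [0] * len(labels)
    for L in lengths:
        idx = 0
        while idx < len(edges) and L >= edges[idx]:
            idx += 1
        counts[idx] += 1
    df = pd.DataFrame({"bin": labels, "count": counts})
    total = sum(counts)
    df["share_pct"] = [
        round_half_up(100.0 * c / total, 2) if total else 0.0 for c in counts
    ]
    return df


def de_proportions(
    table: pd.DataFrame,
    status_col: str = "status",
    regulation_col: str = "regulation",
) -> pd.DataFrame:
    """Cross-tabulated percentages of status x regulation, 2 decimals.

    ``status`` must be known/novel, ``regulation`` up/down/ns; anything
    else is an error. Percentages are of the status-group size, so the
    up/down/ns shares of each status row sum to 100.
    """
    if table.empty:
        log.warning("empty DE table; empty proportions")
        return pd.DataFrame(columns=[status_col, regulation_col, "count", "pct"])
    bad = set(table[status_col]) - {"known", "novel"}
    bad |= set(table[regulation_col]) - {"up", "down", "ns"}
    if bad:
        raise ValueError(f"unknown status/regulation labels: {sorted(bad)}")
    out = (
        table.groupby([status_col, regulation_col]).size().rename("count").reset_index()
    )
    group_sizes = table.groupby(status_col).size()
    out["pct"] = [
        round_half_up(100.0 * c / group_sizes[s], 2)
        for s, c in zip(out[status_col], out["count"])
    ]
    return out
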