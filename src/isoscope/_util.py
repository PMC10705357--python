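"""Small shared helpers: sequence ops, rounding, graph components."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (half-up), matching printed tables.

    Python's built-in round() is banker's rounding; summary tables here are
    compared against values printed to fixed precision with half-up ties.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def connected_components(n: int, edges: Iterable[tuple[int, int]]) -> list[int]:
    """Component label per node for an undirected graph on ``n`` nodes."""
    edges = list(edges)
    if n == 0:
        return []
    if not edges:
        return list(range(n))
    rows = np.fromiter((e[0] for e in edges), dtype=np.int64, count=len(edges))
    cols = np.fromiter((e[1] for e in edges), dtype=np.int64, count=len(edges))
    data = np.ones(len(edges), dtype=np.int8)
    g = coo_matrix((data, (rows, cols)), shape=(n, n))
    _, labels = _cc(g, directed=False)
    return labels.tolist()


def span_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def blocks_length(blocks: Sequence[tuple[int, int]]) -> int:
    return sum(e - s for s, e in blocks)
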