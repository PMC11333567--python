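"""Anchor chaining with gap penalties, minimap2-style.

A seed match is an *anchor* ``(x, y, w)``: the end position of the match on
the reference (``x``), on the query (``y``), and its span ``w`` (the
matching intervals are ``[x-w+1, x]`` and ``[y-w+1, y]``).  Chaining finds
colinear runs of anchors by dynamic programming over anchors sorted by
reference position: the best chain score ending at anchor ``i`` is

    f(i) = max( max_{j < i admissible} { f(j) + a(j,i) - b(j,i) },  w_i )

where ``a(j,i) = min(min(y_i - y_j, x_i - x_j), w_i)`` is the length of the
newly matched region and ``b(j,i) = gap_penalty(l)`` penalizes the gap
difference ``l = (y_i - y_j) - (x_i - x_j)`` between the two coordinate
axes:

    gap_penalty(l) = 0.01 * w * |l| + 0.5 * log2 |l|     (0 when l = 0)

The log term is undefined at ``l = 0``; a zero gap must cost nothing, so
``gap_penalty(0) = 0`` by definition.  Predecessor scanning uses the usual
heuristics (gap bound on both axes, ``max_skip`` non-improving-step cutoff,
``max_iter`` scan cap); with those disabled the DP is exact and equals
brute-force enumeration of all increasing anchor subsequences.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass

import numpy as np

__all__ = ["Anchor", "ChainParams", "Chain", "gap_penalty", "chain_anchors",
           "mapping_quality"]


@dataclass(frozen=True)
class Anchor:
    """A seed match: reference end ``x``, query end ``y``, span ``w``."""

    x: int
    y: int
    w: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("anchor span must be positive")
        if self.x < self.w - 1 or self.y < self.w - 1:
            raise ValueError("anchor end precedes its own span")


@dataclass(frozen=True)
class ChainParams:
    """Chaining heuristics.

    ``max_gap`` bounds the gap between successive anchors on *both* axes
    (in events); ``max_skip`` is the non-improving predecessor cutoff and
    ``max_iter`` the absolute predecessor-scan cap, both as in minimap2.
    Chains scoring below ``min_score`` or with fewer than ``min_anchors``
    anchors are dropped.
    """

    max_gap: int = 500
    max_skip: int = 25
    max_iter: int = 5000
    min_score: float = 40.0
    min_anchors: int = 4

    def __post_init__(self) -> None:
        for name in ("max_gap", "max_skip", "max_iter", "min_score",
                     "min_anchors"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Chain:
    """An ordered, colinear subset of anchors with its DP score."""

    anchors: tuple[Anchor, ...]
    score: float
    strand: str = "+"
    mapq: int = 0
    is_primary: bool = False
    tname: str | None = None  # set by the mapper; None for bare chains

    @property
    def ref_interval(self) -> tuple[int, int]:
        """Half-open [start, end) on the reference axis (event coords)."""
        first, last = self.anchors[0], self.anchors[-1]
        return (first.x - first.w + 1, last.x + 1)

    @property
    def query_interval(self) -> tuple[int, int]:
        first, last = self.anchors[0], self.anchors[-1]
        return (first.y - first.w + 1, last.y + 1)

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def gap_penalty(l: int, w: int) -> float:
    """Gap cost between successive chained anchors; zero gap costs zero."""
    if l == 0:
        return 0.0
    al = abs(l)
    return 0.01 * w * al + 0.5 * math.log2(al)


def chain_anchors(anchors: list[Anchor],
                  cp: ChainParams | None = None) -> list[Chain]:
    """Chain same-strand anchors sorted by (x, y); returns chains sorted by
    descending score, each anchor assigned to at most one chain.

    Raises ``ValueError`` on unsorted input.
    """
    cp = cp or ChainParams()
    n = len(anchors)
    if n == 0:
        return []
    xs = np.fromiter((a.x for a in anchors), dtype=np.int64, count=n)
    ys = np.fromiter((a.y for a in anchors), dtype=np.int64, count=n)
    ws = np.fromiter((a.w for a in anchors), dtype=np.int64, count=n)
    keys = list(zip(xs.tolist(), ys.tolist()))
    if any(keys[i] > keys[i + 1] for i in range(n - 1)):
        raise ValueError("anchors must be sorted by (x, y)")
    strand = anchors[0].strand
    if any(a.strand != strand for a in anchors):
        raise ValueError("chain_anchors expects a single strand")

    f = ws.astype(np.float64).copy()
    pred = np.full(n, -1, dtype=np.int64)
    x_list = xs.tolist()
    y_list = ys.tolist()
    w_list = ws.tolist()
    f_list = f.tolist()
    pred_list = pred.tolist()
    for i in range(1, n):
        xi, yi, wi = x_list[i], y_list[i], w_list[i]
        lo = bisect_left(x_list, xi - cp.max_gap, 0, i)
        best = f_list[i]
        best_j = -1
        skipped = 0
        iters = 0
        for j in range(i - 1, lo - 1, -1):
            iters += 1
            if iters > cp.max_iter:
                break
            dx = xi - x_list[j]
            dy = yi - y_list[j]
            if dx <= 0 or dy <= 0 or dy > cp.max_gap:
                continue
            alpha = min(dx, dy, wi)
            sc = f_list[j] + alpha - gap_penalty(dy - dx, wi)
            if sc > best:
                best, best_j = sc, j
                skipped = 0
            else:
                skipped += 1
                if skipped > cp.max_skip:
                    break
        f_list[i] = best
        pred_list[i] = best_j

    # backtrack greedily from highest-scoring chain ends; each anchor
    # belongs to at most one reported chain
    order = sorted(range(n), key=lambda i: -f_list[i])
    used = [False] * n
    chains: list[Chain] = []
    for i in order:
        if used[i]:
            continue
        members: list[int] = []
        node = i
        stop_score = 0.0
        while node != -1:
            if used[node]:
                stop_score = f_list[node]  # prefix claimed by a better chain
                break
            members.append(node)
            node = pred_list[node]
        score = f_list[i] - stop_score
        for m in members:
            used[m] = True
        if score < cp.min_score or len(members) < cp.min_anchors:
            continue
        members.reverse()
        chains.append(Chain(
            anchors=tuple(anchors[m] for m in members),
            score=float(score),
            strand=strand,
        ))
    chains.sort(key=lambda c: -c.score)
    return chains


def mapping_quality(chains: list[Chain]) -> list[Chain]:
    """Assign mapping quality; the best chain is primary, the rest get 0.

    For the primary chain with score ``f1``, runner-up score ``f2`` (0 when
    absent) and anchor count ``m``::

        mapq = clamp(round(40 * (1 - f2/f1) * min(1, m/10) * ln f1), 0, 60)
    """
    if not chains:
        return []
    ranked = sorted(chains, key=lambda c: -c.score)
    f1 = ranked[0].score
    f2 = ranked[1].score if len(ranked) > 1 else 0.0
    m = ranked[0].n_anchors
    if f1 <= 0:
        q = 0
    else:
        q = round(40.0 * (1.0 - f2 / f1) * min(1.0, m / 10.0) * math.log(f1))
    for c in ranked:
        c.mapq = 0
        c.is_primary = False
    ranked[0].mapq = int(min(60, max(0, q)))
    ranked[0].is_primary = True
    return ranked
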