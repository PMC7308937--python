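"""Seed validation and the paged cluster-growing protocol.

Growing accretes unassigned objects onto a validated seed.  Candidates are
ranked by distance to the seed centroid and partitioned into pages
(default 50 objects).  Under the monotonicity assumption — if a page
matches the seed, all earlier pages do too — the boundary page b (the last
fully matching page) is located with a galloping phase (page probes 1, 2,
4, 8, ..., doubling the index) followed by binary search inside the
bracketed interval, so only O(log P) of the P pages are ever reviewed.

"Turtle mode" covers the case where the annotator removes individual
objects from a judged page instead of rejecting it wholesale: binary
search is then abandoned and every remaining candidate from that page on
is reviewed one by one until a run of consecutive rejections ends the
scan.  Speed is traded for an exact cluster border.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotator import AnnotatorContract
from .core import (
    DEFAULT_PAGE_SIZE,
    Cluster,
    Clock,
    EventLog,
    FeatureSet,
    ProcessState,
    StateError,
)

#: Default number of consecutive individual rejections that ends a turtle
#: scan — one page worth of objects.
DEFAULT_TURTLE_PATIENCE = 50


def arrange_dissimilar(members: list[str], features: FeatureSet) -> list[str]:
    """Order members so that consecutive items are maximally dissimilar.

    Greedy: start from the most distant pair, then repeatedly append the
    remaining member farthest from the last placed one.  The alternating
    contrast makes impurities stand out when a seed is displayed for
    validation.  Ties break by ascending object id, so the arrangement is
    deterministic.
    """
    ids = sorted(set(members))
    if not ids:
        return []
    if len(ids) == 1:
        return ids
    x = features.matrix(ids)
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
    # most distant pair, lexicographically smallest on ties
    best = (-1.0, len(ids), len(ids))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            cand = (d[i, j], -i, -j)
            if cand > best:
                best = cand
    i0, j0 = -best[1], -best[2]
    order = [i0, j0]
    remaining = [t for t in range(len(ids)) if t not in (i0, j0)]
    while remaining:
        last = order[-1]
        nxt = max(remaining, key=lambda t: (d[last, t], -t))
        order.append(nxt)
        remaining.remove(nxt)
    return [ids[t] for t in order]


def rank_candidates(
    centroid: np.ndarray, pool: set[str], features: FeatureSet
) -> list[str]:
    """Pool ids by ascending Euclidean distance to *centroid*.

    Ties break by ascending object id.  Pure function; an empty pool gives
    an empty list.
    """
    ids = sorted(pool)
    if not ids:
        return []
    dist = np.linalg.norm(features.matrix(ids) - np.asarray(centroid), axis=1)
    order = sorted(range(len(ids)), key=lambda i: (dist[i], ids[i]))
    return [ids[i] for i in order]


def validate_seed(
    cluster: Cluster,
    annotator: AnnotatorContract,
    state: ProcessState,
    log: EventLog | None = None,
    clock: Clock | None = None,
) -> bool:
    """Present a seed for validation; approve it or dissolve it.

    On approval the cluster is marked approved (and flagged when the
    annotator asks for preferred treatment).  On rejection the cluster is
    removed from the state and its members implicitly return to the
    unassigned pool.  Returns the approval decision.
    """
    if cluster.approved:
        raise StateError(f"cluster {cluster.cluster_id} already approved")
    accepted = annotator.judge_cluster(cluster.seed_members)
    if accepted:
        cluster.approved = True
        cluster.flagged = annotator.wants_flag(cluster.seed_members)
        action = "approve"
    else:
        state.clusters.remove(cluster)
        action = "reject"
    if log is not None:
        log.record(
            (clock or Clock()).now(), "validate", action, len(cluster.seed_members)
        )
    state.assert_conservation()
    return accepted


@dataclass
class GrowthSearchState:
    """Trace of one cluster's growth search (exposed for inspection/UI)."""

    pages: list[list[str]]
    judged: dict[int, bool] = field(default_factory=dict)  # page -> match
    phase: str = "galloping"  # galloping | binary | turtle | done
    interval: tuple[int, int] = (0, 0)  # (last match, first mismatch)
    boundary: int = 0  # last fully accepted page
    removed_ids: dict[int, set[str]] = field(default_factory=dict)
    accepted_ids: set[str] = field(default_factory=set)

    @property
    def n_pages(self) -> int:
        return len(self.pages)


def _paginate(ranked: list[str], page_size: int) -> list[list[str]]:
    return [ranked[i : i + page_size] for i in range(0, len(ranked), page_size)]


def grow_cluster(
    cluster: Cluster,
    pool: set[str],
    features: FeatureSet,
    annotator: AnnotatorContract,
    page_size: int = DEFAULT_PAGE_SIZE,
    turtle: bool = True,
    turtle_patience: int = DEFAULT_TURTLE_PATIENCE,
    growth_factor: int = 2,
    log: EventLog | None = None,
    clock: Clock | None = None,
) -> tuple[set[str], GrowthSearchState]:
    """Grow an approved cluster from the unassigned pool.

    Moves the accepted candidates (all objects of pages 1..b, minus
    individually removed ids, plus individually accepted ids from a turtle
    scan) from *pool* into ``cluster.grown_members``.  The pool set is
    mutated in place and also returned inside the result tuple's search
    state for convenience.

    Returns ``(accepted_ids, search_state)``.
    """
    if not cluster.approved:
        raise StateError(f"cluster {cluster.cluster_id} not approved")
    if growth_factor < 2:
        raise StateError("growth_factor must be >= 2")
    clock = clock or Clock()

    ranked = rank_candidates(cluster.centroid, pool, features)
    state = GrowthSearchState(pages=_paginate(ranked, page_size))
    if not ranked:
        state.phase = "done"
        return set(), state
    P = state.n_pages
    modal = annotator.modal_label(cluster.seed_members)

    def judge(pnum: int):
        page = state.pages[pnum - 1]
        res = annotator.judge_page(page, modal)
        state.judged[pnum] = res.match
        if log is not None:
            log.record(clock.now(), "grow", "judge_page", len(page))
        return res

    turtle_at: int | None = None  # page where individual review starts

    # -- galloping: bracket the boundary with exponentially spaced probes --
    g, f = 0, 0  # last matching / first mismatching probe
    p = 1
    while True:
        res = judge(p)
        if res.match:
            g = p
            if p >= P:
                state.boundary = P
                break
            p = min(p * growth_factor, P)
        else:
            if turtle and len(res.offending_ids) < len(state.pages[p - 1]):
                turtle_at = p
            f = p
            break

    # -- binary search for the last matching page inside (g, f) --
    if f and turtle_at is None:
        state.phase = "binary"
        lo, hi = g, f  # invariant: lo matches (or 0), hi mismatches
        while hi - lo > 1:
            state.interval = (lo, hi)
            mid = (lo + hi) // 2
            res = judge(mid)
            if res.match:
                lo = mid
            else:
                if turtle and len(res.offending_ids) < len(state.pages[mid - 1]):
                    turtle_at = mid
                    break
                hi = mid
        state.boundary = lo
        state.interval = (lo, hi)

    accepted: set[str] = set()
    if turtle_at is not None:
        # Individual review of everything from the triggering page on;
        # earlier pages are accepted under the monotonicity assumption.
        state.phase = "turtle"
        state.boundary = turtle_at - 1
        for pnum in range(1, turtle_at):
            accepted.update(state.pages[pnum - 1])
        consecutive_rejects = 0
        start = (turtle_at - 1) * page_size
        for pos, oid in enumerate(ranked[start:], start=start):
            ok = annotator.judge_object(oid, modal)
            if log is not None:
                log.record(clock.now(), "grow", "judge_object", 1)
            if ok:
                accepted.add(oid)
                consecutive_rejects = 0
            else:
                pnum = pos // page_size + 1
                state.removed_ids.setdefault(pnum, set()).add(oid)
                consecutive_rejects += 1
                if consecutive_rejects >= turtle_patience:
                    break
    else:
        for pnum in range(1, state.boundary + 1):
            accepted.update(state.pages[pnum - 1])

    state.phase = "done"
    state.accepted_ids = accepted
    cluster.grown_members.update(accepted)
    pool.difference_update(accepted)
    if log is not None:
        log.record(clock.now(), "grow", "grow_cluster", len(accepted))
    return accepted, state


def max_page_judgments(n_pages: int) -> int:
    """Worst-case page reviews for a monotone annotator over *n_pages*.

    Galloping needs at most ``ceil(log2 P) + 1`` probes and binary search
    at most ``ceil(log2 P) + 1`` more, so ``2 * ceil(log2(P + 1)) + 2`` is
    a safe bound.
    """
    if n_pages <= 0:
        return 0
    return 2 * math.ceil(math.log2(n_pages + 1)) + 2
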