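"""Independent reference implementations used as oracles in tests.

These deliberately avoid the code paths they check: the UPGMA reference is
a naive O(n^3) agglomeration over an explicit distance matrix, and the
linear page scan reviews every page in order instead of searching.
"""

from __future__ import annotations

import numpy as np


def brute_force_upgma(dist: np.ndarray, ids: list[str]):
    """Naive UPGMA: repeatedly merge the closest pair of groups.

    ``dist`` is a full symmetric matrix over the leaves in ``ids``.
    Between-group distance is the size-weighted (arithmetic over all leaf
    pairs) average; ties break by the lexicographically smallest pair of
    sorted-leaf-set representatives.  Returns a list of merge records
    ``(height, frozenset_of_leaf_ids)`` in merge order, heights = half the
    merge distance (ultrametric leaf-to-root convention).
    """
    groups: list[tuple[frozenset, int]] = [(frozenset([i]), 1) for i in ids]
    d = {
        (frozenset([a]), frozenset([b])): dist[i, j]
        for i, a in enumerate(ids)
        for j, b in enumerate(ids)
        if i < j
    }

    def dget(x, y):
        return d.get((x, y), d.get((y, x)))

    merges = []
    while len(groups) > 1:
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                gi, gj = groups[i][0], groups[j][0]
                key = (dget(gi, gj), tuple(sorted((min(gi), min(gj)))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (_dist_key, _), i, j = best[0], best[1], best[2]
        (gi, ni), (gj, nj) = groups[i], groups[j]
        merged = gi | gj
        merges.append((dget(gi, gj) / 2.0, merged))
        rest = [g for t, g in enumerate(groups) if t not in (i, j)]
        for g, _n in rest:
            d[(merged, g)] = (ni * dget(gi, g) + nj * dget(gj, g)) / (ni + nj)
        groups = [(g, n) for g, n in groups if g not in (gi, gj)]
        groups.append((merged, ni + nj))
    return merges


def tree_merges(tree):
    """Extract ``(height, frozenset_of_cluster_ids)`` merge records from a
    built hierarchy, sorted the same way as the brute-force output."""

    def leafset(node):
        return frozenset(
            cl.cluster_id for n in node.walk() for cl in n.clusters
        )

    records = [
        (n.height, leafset(n)) for n in tree.nodes() if not n.is_leaf()
    ]
    return sorted(records, key=lambda r: (r[0], tuple(sorted(r[1]))))


def linear_page_scan(pages, annotator, modal):
    """Reference growing protocol: review every page in order, stop at the
    first mismatching page.  Returns the accepted id set."""
    accepted: set[str] = set()
    for page in pages:
        res = annotator.judge_page(page, modal)
        if not res.match:
            break
        accepted.update(page)
    return accepted


def paginate(ranked, page_size):
    return [ranked[i : i + page_size] for i in range(0, len(ranked), page_size)]
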