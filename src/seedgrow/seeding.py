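"""Density-based extraction of cluster seeds from the unassigned pool.

Seeds are the densest cores of feature-space regions, found with HDBSCAN*
at neighborhood size k = 1 and a minimum cluster size m that shrinks from
iteration to iteration (default schedule 128, 64, 32, 16, 8, 4).  A large
m first extracts the biggest coherent groups; as the pool empties, smaller
m values expose increasingly rare classes.  HDBSCAN* rejects most objects
as noise, which is exactly what makes the surviving seeds pure enough to
validate at a glance.
"""

from __future__ import annotations

from sklearn.cluster import HDBSCAN

from .core import Cluster, FeatureSet, ProcessState, ValidationError


def seed_clusters(
    features: FeatureSet,
    m: int,
    k: int = 1,
    cluster_selection_method: str = "eom",
    id_prefix: str = "c",
) -> list[Cluster]:
    """Extract disjoint cluster seeds of at least *m* members.

    Parameters
    ----------
    features:
        The feature rows of the current unassigned pool only.
    m:
        Minimum cluster size (HDBSCAN* ``min_cluster_size``), >= 2.
    k:
        Neighborhood size (HDBSCAN* ``min_samples``); the engine default
        is 1, which makes core distances nearest-neighbor distances and
        keeps seeds tight.
    cluster_selection_method:
        ``"eom"`` (excess of mass, default) or ``"leaf"``.
    id_prefix:
        Prepended to the generated cluster ids.

    Returns unapproved clusters ordered by decreasing seed size (ties by
    smallest member id) and numbered in that order.  Fewer pool objects
    than *m* yields an empty list, not an error.  The result is a pure
    function of the inputs.
    """
    if m < 2:
        raise ValidationError("minimum cluster size m must be >= 2")
    if len(features) < m:
        return []
    labels = HDBSCAN(
        min_cluster_size=int(m),
        min_samples=int(k),
        cluster_selection_method=cluster_selection_method,
        copy=True,
    ).fit_predict(features.features)

    groups: dict[int, list[str]] = {}
    for oid, lab in zip(features.object_ids, labels):
        if lab >= 0:
            groups.setdefault(int(lab), []).append(oid)

    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), min(ms)))
    clusters = [
        Cluster.from_seed(f"{id_prefix}{i:04d}", members, features)
        for i, members in enumerate(ordered, 1)
    ]
    for c in clusters:
        if len(c.seed_members) < m:
            raise ValidationError(
                f"seed {c.cluster_id} smaller than m={m}"
            )  # pragma: no cover - guards the backend contract
    return clusters


def next_iteration(state: ProcessState, features: FeatureSet) -> ProcessState:
    """Advance to the next schedule entry and seed the current pool.

    Appends the new (unapproved) seeds to ``state.clusters``.  When the
    schedule is exhausted the state is marked done and the remaining pool
    becomes the *residual objects*; no exception is raised.
    """
    if state.done:
        return state
    if state.iteration > len(state.m_schedule):
        state.done = True
        return state
    pool = sorted(state.unassigned())
    if not pool:
        state.done = True
        return state
    m = state.current_m
    seeds = seed_clusters(
        features.subset(pool), m, k=state.k, id_prefix=f"i{state.iteration}c"
    )
    state.clusters.extend(seeds)
    state.iteration += 1
    if state.iteration > len(state.m_schedule):
        state.done = True
    state.assert_conservation()
    return state
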