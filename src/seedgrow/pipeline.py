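"""End-to-end orchestration: seed → validate → grow, iterated over a
shrinking minimum-cluster-size schedule, then hierarchy building, naming
and label flattening.

The run is fully deterministic given the feature set, a deterministic
annotator and the configuration, and the partition invariant (each object
in exactly one of pool / one cluster) is asserted after every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from collections import Counter

from .annotator import AnnotatorContract
from .core import (
    DEFAULT_M_SCHEDULE,
    DEFAULT_PAGE_SIZE,
    Clock,
    Cluster,
    EventLog,
    FeatureSet,
    LabelTable,
    ProcessState,
    SimulatedClock,
)
from .growth import DEFAULT_TURTLE_PATIENCE, grow_cluster, validate_seed
from .hierarchy import (
    HierarchyTree,
    build_hierarchy,
    flatten_labels,
    merge_nodes,
    name_node,
)
from .seeding import seed_clusters


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of a full annotation run."""

    m_schedule: tuple[int, ...] = DEFAULT_M_SCHEDULE
    k: int = 1
    page_size: int = DEFAULT_PAGE_SIZE
    turtle: bool = True
    turtle_patience: int = DEFAULT_TURTLE_PATIENCE
    growth_factor: int = 2
    rng_seed: int = 0
    stop_when_no_seeds: bool = False  # optional early-stop rule
    cluster_selection_method: str = "eom"


@dataclass
class RunResult:
    """Everything a full run produces."""

    labels: LabelTable
    tree: HierarchyTree | None
    state: ProcessState
    log: EventLog
    residual_ids: set[str]
    seed_history: list[tuple[int, str, frozenset]] = field(default_factory=list)
    iterations_run: int = 0
    conservation_checks: int = 0

    @property
    def clusters(self) -> list[Cluster]:
        return self.state.clusters

    @property
    def residual_fraction(self) -> float:
        return len(self.residual_ids) / max(len(self.state.all_ids), 1)


def _growth_order(clusters: list[Cluster]) -> list[Cluster]:
    # flagged clusters get preferred treatment, then larger seeds first
    return sorted(
        clusters,
        key=lambda c: (not c.flagged, -len(c.seed_members), c.cluster_id),
    )


def run_full(
    features: FeatureSet,
    annotator: AnnotatorContract,
    config: RunConfig = RunConfig(),
    namer=None,
    clock: Clock | None = None,
) -> RunResult:
    """Run the complete annotation process on *features*.

    For each m in the schedule: seed the unassigned pool, present the new
    seeds for validation in descending size order, then grow every
    approved cluster (flagged first, then descending seed size).  After
    the schedule, the surviving clusters are arranged in a UPGMA hierarchy
    and handed to *namer* (e.g. :func:`oracle_namer` bound to a truth
    table, or an interactive walk); flattening the named tree yields the
    output labeling.  Objects never assigned are the residuals.
    """
    clock = clock or SimulatedClock()
    state = ProcessState(
        all_ids=set(features.object_ids),
        m_schedule=config.m_schedule,
        k=config.k,
        page_size=config.page_size,
        rng_seed=config.rng_seed,
    )
    log = EventLog()
    seed_history: list[tuple[int, str, frozenset]] = []
    iterations = 0
    checks = 0

    def check() -> None:
        nonlocal checks
        state.assert_conservation()
        checks += 1

    if len(features) == 0:
        return RunResult(LabelTable(), None, state, log, set())

    for iteration, m in enumerate(config.m_schedule, start=1):
        state.iteration = iteration
        pool_ids = sorted(state.unassigned())
        if not pool_ids:
            break
        seeds = seed_clusters(
            features.subset(pool_ids),
            m,
            k=config.k,
            cluster_selection_method=config.cluster_selection_method,
            id_prefix=f"i{iteration}c",
        )
        iterations = iteration
        if not seeds:
            if config.stop_when_no_seeds:
                break
            continue
        for s in seeds:
            seed_history.append((iteration, s.cluster_id, frozenset(s.seed_members)))
        state.clusters.extend(seeds)
        check()

        # validation, largest seeds first
        approved: list[Cluster] = []
        for cl in sorted(seeds, key=lambda c: (-len(c.seed_members), c.cluster_id)):
            if validate_seed(cl, annotator, state, log=log, clock=clock):
                approved.append(cl)
        check()

        # growing
        pool = state.unassigned()
        for cl in _growth_order(approved):
            grow_cluster(
                cl,
                pool,
                features,
                annotator,
                page_size=config.page_size,
                turtle=config.turtle,
                turtle_patience=config.turtle_patience,
                growth_factor=config.growth_factor,
                log=log,
                clock=clock,
            )
            check()

    residuals = state.unassigned()
    state.done = True

    tree: HierarchyTree | None = None
    labels = LabelTable()
    if state.clusters:
        tree = build_hierarchy(state.clusters, features)
        if namer is not None:
            tree = namer(tree)
            named = sum(1 for n in tree.nodes() if n.name)
            log.record(clock.now(), "name", "name_nodes", named)
        labels = flatten_labels(tree)

        # propagate effective node names down to the clusters and keep the
        # state's cluster list in sync with the (possibly merged) tree
        def push_names(node, inherited):
            effective = node.name if node.name else inherited
            for cl in node.clusters:
                cl.name = effective
            for c in node.children:
                push_names(c, effective)

        push_names(tree.root, None)
        state.clusters = [cl for n in tree.nodes() for cl in n.clusters]
        check()

    return RunResult(
        labels=labels,
        tree=tree,
        state=state,
        log=log,
        residual_ids=residuals,
        seed_history=seed_history,
        iterations_run=iterations,
        conservation_checks=checks,
    )


def oracle_namer(truth: LabelTable):
    """Build a namer that labels leaves by their predominant truth label.

    Automates the naming walk for tests and benchmarks: every leaf gets
    the most frequent true label of its members (lexicographic on ties),
    then same-named sibling leaves are merged.  Returns a function
    ``tree -> tree`` suitable for :func:`run_full`'s *namer* argument.
    """

    def leaf_label(node) -> str | None:
        counts = Counter(
            truth[o]
            for cl in node.clusters
            for o in cl.members
            if o in truth
        )
        if not counts:
            return None
        top = max(counts.values())
        return min(l for l, c in counts.items() if c == top)

    def namer(tree: HierarchyTree) -> HierarchyTree:
        for leaf in tree.leaves():
            label = leaf_label(leaf)
            if label is not None:
                name_node(tree, leaf.node_id, label)
        # merge same-named sibling leaves, bottom-up
        changed = True
        while changed:
            changed = False
            for node in tree.nodes():
                by_name: dict[str, list] = {}
                for child in node.children:
                    if child.is_leaf() and child.name:
                        by_name.setdefault(child.name, []).append(child)
                for name, group in by_name.items():
                    if len(group) > 1:
                        merge_nodes(tree, [n.node_id for n in group])
                        changed = True
                        break
                if changed:
                    break
        return tree

    return namer
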