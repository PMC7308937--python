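"""Quantitative evaluation: precision by sampled review, labeling agreement,
correspondence matrices, throughput and class-recovery reporting.

Per-class precision is Pr_c = TP_c / (TP_c + FP_c), estimated by reviewing
a random sample of up to ``cap`` objects per class; macro precision is the
unweighted mean over classes and Pr10 the empirical 10th percentile of the
per-class values.  Two labelings of the same objects are compared with the
relative overlap |A∩B| / |A∪B| of their classes (the Jaccard index) and
with the predominant-label agreement: each result class is assigned the
reference label most frequent among its members and scored by the fraction
carrying it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .annotator import AnnotatorContract
from .core import EventLog, LabelTable, ValidationError, split_sessions


# ---------------------------------------------------------------------------
# Precision by sampled review
# ---------------------------------------------------------------------------


@dataclass
class ClassPrecision:
    label: str
    true_positives: int
    false_positives: int

    @property
    def sample_size(self) -> int:
        return self.true_positives + self.false_positives

    @property
    def precision(self) -> float:
        return self.true_positives / self.sample_size


@dataclass
class EvaluationReport:
    """Per-class and aggregate precision of one labeling."""

    per_class: dict[str, ClassPrecision]
    groups: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return len(self.per_class)

    @property
    def macro_precision(self) -> float:
        return float(
            np.mean([c.precision for c in self.per_class.values()])
        )

    @property
    def precision_p10(self) -> float:
        """Empirical 10th percentile of per-class precisions (linear
        interpolation)."""
        return float(
            np.percentile(
                [c.precision for c in self.per_class.values()], 10.0
            )
        )

    def group_summary(self) -> dict[str, dict[str, float]]:
        """Macro precision / Pr10 / N per category group."""
        out: dict[str, dict[str, float]] = {}
        for group, labels in self.groups.items():
            vals = [self.per_class[l].precision for l in labels]
            if not vals:
                continue
            out[group] = {
                "macro_precision": float(np.mean(vals)),
                "precision_p10": float(np.percentile(vals, 10.0)),
                "n_classes": len(vals),
            }
        return out

    def to_dict(self) -> dict:
        return {
            "macro_precision": self.macro_precision,
            "precision_p10": self.precision_p10,
            "n_classes": self.n_classes,
            "per_class": {
                l: {
                    "precision": c.precision,
                    "true_positives": c.true_positives,
                    "false_positives": c.false_positives,
                }
                for l, c in sorted(self.per_class.items())
            },
            "groups": self.group_summary(),
        }


def precision_by_review(
    labels: LabelTable,
    annotator: AnnotatorContract,
    cap: int = 500,
    rng_seed: int = 0,
    group_map: dict[str, str] | None = None,
) -> EvaluationReport:
    """Estimate per-class precision by reviewing random samples.

    From each class, min(cap, class size) objects are sampled without
    replacement and shown to the annotator; inliers count as true
    positives.  With ``cap`` at least the largest class size this is the
    exhaustive precision.  ``group_map`` optionally assigns classes to
    groups (e.g. living / non-living); unmapped classes fall into the
    group ``"excluded"``.
    """
    if not len(labels):
        raise ValidationError("empty label table")
    rng = np.random.default_rng(rng_seed)
    per_class: dict[str, ClassPrecision] = {}
    groups: dict[str, list[str]] = {}
    for label in labels.classes():
        members = labels.members_of(label)
        n = min(cap, len(members))
        sample = (
            members
            if n == len(members)
            else [members[i] for i in rng.choice(len(members), size=n, replace=False)]
        )
        tp = sum(annotator.judge_object(o, label) for o in sample)
        per_class[label] = ClassPrecision(label, tp, n - tp)
        if group_map is not None:
            groups.setdefault(group_map.get(label, "excluded"), []).append(label)
    return EvaluationReport(per_class, groups)


# ---------------------------------------------------------------------------
# Relative overlap and correspondence
# ---------------------------------------------------------------------------


def relative_overlap(set_a: set[str], set_b: set[str]) -> float:
    """|a∩b| / (|a| + |b| − |a∩b|); 0 when both sets are empty."""
    inter = len(set_a & set_b)
    union = len(set_a) + len(set_b) - inter
    return inter / union if union else 0.0


@dataclass
class CorrespondenceMatrix:
    """Cross-labeling comparison on the shared object set.

    ``overlap`` holds the relative overlap of every (A-class, B-class)
    pair; ``predominant`` maps each B-class to its most frequent A-label
    (lexicographic on ties, tie flagged) and ``agreement`` to the fraction
    of its shared members carrying that label.
    """

    overlap: pd.DataFrame  # rows: A classes, cols: B classes
    predominant: dict[str, str]
    agreement: dict[str, float]
    tied: set[str]
    n_shared: int

    @property
    def macro_agreement(self) -> float:
        return float(np.mean(list(self.agreement.values())))


def correspondence(
    labels_a: LabelTable, labels_b: LabelTable
) -> CorrespondenceMatrix:
    """Compare two labelings on their shared ids.

    B-classes with no shared member are excluded from the predominant-label
    agreement (they cannot be mapped to an A-class).
    """
    shared = sorted(set(labels_a) & set(labels_b))
    if not shared:
        raise ValidationError("the two labelings share no objects")
    a = pd.Series({o: labels_a[o] for o in shared})
    b = pd.Series({o: labels_b[o] for o in shared})
    a_classes, b_classes = sorted(a.unique()), sorted(b.unique())

    members_a = {c: set(a.index[a == c]) for c in a_classes}
    members_b = {c: set(b.index[b == c]) for c in b_classes}
    overlap = pd.DataFrame(
        [
            [relative_overlap(members_a[ca], members_b[cb]) for cb in b_classes]
            for ca in a_classes
        ],
        index=a_classes,
        columns=b_classes,
    )

    predominant: dict[str, str] = {}
    agreement: dict[str, float] = {}
    tied: set[str] = set()
    for cb in b_classes:
        counts = Counter(a[o] for o in members_b[cb])
        top = max(counts.values())
        winners = sorted(l for l, c in counts.items() if c == top)
        predominant[cb] = winners[0]
        if len(winners) > 1:
            tied.add(cb)
        agreement[cb] = top / len(members_b[cb])
    return CorrespondenceMatrix(overlap, predominant, agreement, tied, len(shared))


# ---------------------------------------------------------------------------
# Throughput
# ---------------------------------------------------------------------------


def throughput(
    log: EventLog, max_gap: float = 600.0
) -> dict[str, float | None]:
    """Objects handled per hour, per phase and overall.

    Work time is the sum of session durations (sessions split at breaks
    longer than *max_gap* seconds), not the wall-clock span.  A phase with
    zero accumulated duration has undefined throughput, reported as None;
    phases with no events are omitted.
    """
    if not len(log):
        raise ValidationError("empty event log")

    def rate(events: list) -> float | None:
        sub = EventLog(events)
        sessions = split_sessions(sub, max_gap)
        total_s = sum(s.duration for s in sessions)
        objects = sum(e.count for e in sub)
        return objects / (total_s / 3600.0) if total_s > 0 else None

    out: dict[str, float | None] = {}
    for phase in ("validate", "grow", "name"):
        events = [e for e in log if e.phase == phase]
        if events:
            out[phase] = rate(events)
    out["total"] = rate(list(log))
    return out


# ---------------------------------------------------------------------------
# Class recovery
# ---------------------------------------------------------------------------


@dataclass
class ClassRecovery:
    label: str
    final_size: int  # truth objects of this class that ended up clustered
    retrieved: bool  # predominant truth label of >= 1 named cluster
    first_seed_iteration: int | None  # first seed with >= 5% of final size
    indicator: bool


@dataclass
class RecoveryReport:
    per_class: dict[str, ClassRecovery]
    size_iteration_spearman: float | None

    @property
    def retrieved_classes(self) -> list[str]:
        return sorted(l for l, r in self.per_class.items() if r.retrieved)


def recovery_report(
    clusters: list,
    truth: LabelTable,
    indicator_classes: list[str],
    seed_history: list[tuple[int, str, frozenset]] | None = None,
    min_seed_fraction: float = 0.05,
) -> RecoveryReport:
    """Which truth classes the run recovered, and how early.

    A class counts as *retrieved* when it is the predominant truth label of
    at least one named cluster.  When *seed_history* — records of
    ``(iteration, cluster_id, seed member ids)`` — is given, each class is
    assigned the first iteration in which a seed predominantly of that
    class held at least ``min_seed_fraction`` of the class's final
    clustered size, and a Spearman rank correlation between class size and
    that iteration is reported (negative means larger classes were found
    earlier).  Noise is never a recoverable class.
    """
    from .core import NOISE_LABEL

    clustered: set[str] = set()
    predominant_of_named: set[str] = set()
    for cl in clusters:
        clustered |= cl.members
        if cl.name is not None:
            counts = Counter(truth[o] for o in cl.members if o in truth)
            if counts:
                top = max(counts.values())
                predominant_of_named.add(
                    min(l for l, c in counts.items() if c == top)
                )

    final_sizes: Counter = Counter(
        truth[o] for o in clustered if o in truth
    )

    first_seed: dict[str, int] = {}
    if seed_history:
        for iteration, _cid, members in sorted(seed_history):
            counts = Counter(truth[o] for o in members if o in truth)
            if not counts:
                continue
            top = max(counts.values())
            label = min(l for l, c in counts.items() if c == top)
            if label == NOISE_LABEL or label in first_seed:
                continue
            if top >= min_seed_fraction * max(final_sizes.get(label, 0), 1):
                first_seed[label] = iteration

    per_class: dict[str, ClassRecovery] = {}
    for label in truth.classes():
        if label == NOISE_LABEL:
            continue
        per_class[label] = ClassRecovery(
            label=label,
            final_size=final_sizes.get(label, 0),
            retrieved=label in predominant_of_named,
            first_seed_iteration=first_seed.get(label),
            indicator=label in indicator_classes,
        )

    sizes = [
        truth.class_sizes()[l]
        for l, r in per_class.items()
        if r.first_seed_iteration is not None
    ]
    iters = [
        r.first_seed_iteration
        for r in per_class.values()
        if r.first_seed_iteration is not None
    ]
    rho: float | None = None
    if len(sizes) >= 3 and len(set(iters)) > 1 and len(set(sizes)) > 1:
        rho = float(spearmanr(sizes, iters).statistic)
    return RecoveryReport(per_class, rho)
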