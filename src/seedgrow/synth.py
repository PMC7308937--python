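"""Synthetic long-tailed feature clouds and the ground-truth oracle annotator.

Real plankton-imaging collections have a severely imbalanced class
structure: a handful of detritus-like classes hold most of the objects
while rare taxa contribute only tens of images, with class sizes spanning
several orders of magnitude.  This module emulates that structure as a
Gaussian mixture in feature space — one isotropic component per class,
sizes drawn from a discrete power law — plus a diffuse uniform background
("noise") component, so that every stage of the annotation engine can be
exercised and measured against known ground truth without images, a GPU,
or a human.

A subset of the smallest classes can be designated *indicator classes*:
they are generated like any other class and the engine receives no
knowledge of them, but they are reported separately to test whether rare,
novel classes are retrieved by the process.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .annotator import AnnotatorContract, PageJudgment
from .core import (
    DEFAULT_DIM,
    NOISE_LABEL,
    FeatureSet,
    LabelTable,
    ValidationError,
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic feature-cloud generator.

    Parameters
    ----------
    n_classes:
        Number of Gaussian mixture components (real classes).
    total_objects:
        Total number of objects including background noise.
    dim:
        Feature dimensionality.
    size_exponent:
        Exponent ``a`` of the power law ``size_i ∝ i^-a`` over class ranks
        ``i = 1..n_classes``; larger values give a heavier head.  At
        ``a = 2`` and 50 classes, the top 10% of classes hold >80% of the
        class objects and sizes span several orders of magnitude once the
        total is large enough — the regime observed in expert-sorted
        underwater-camera collections.
    separation:
        Minimum pairwise distance between class centroids in units of the
        within-class RMS radius ``σ·sqrt(dim)`` — the typical distance of
        a member from its own centroid.  Scaling by the radius rather than
        the per-coordinate σ gives a fixed separation value the same
        degree of class overlap in any dimensionality (in high dimensions
        distances concentrate around σ·sqrt(dim), so per-coordinate units
        would make nominally "separated" classes touch).  Values ≥ ~3
        give essentially perfect separation.
    noise_fraction:
        Fraction of objects drawn uniformly over the bounding box of the
        class points and labeled ``"noise"``.
    indicator_class_count:
        The smallest classes, this many of them, are tagged as held-out
        indicator classes for novelty-retrieval reporting.
    rng_seed:
        Seed for all randomness; generation is fully reproducible.
    """

    n_classes: int
    total_objects: int
    dim: int = DEFAULT_DIM
    size_exponent: float = 1.5
    separation: float = 10.0
    noise_fraction: float = 0.0
    indicator_class_count: int = 0
    within_class_sigma: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValidationError("need at least one class")
        if self.total_objects < self.n_classes:
            raise ValidationError("fewer objects than classes")
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ValidationError("noise_fraction must be in [0, 1)")
        if self.size_exponent <= 0:
            raise ValidationError("size_exponent must be positive")
        if not 0 <= self.indicator_class_count <= self.n_classes:
            raise ValidationError("indicator_class_count out of range")


def power_law_sizes(n_classes: int, exponent: float, total: int) -> list[int]:
    """Class sizes ``∝ rank^-exponent`` scaled to sum to *total*, each ≥ 1.

    Deterministic largest-remainder rounding; sizes are returned in rank
    order (largest first).
    """
    if total < n_classes:
        raise ValidationError("total smaller than the number of classes")
    w = np.arange(1, n_classes + 1, dtype=float) ** (-exponent)
    raw = w / w.sum() * (total - n_classes)  # reserve 1 per class up front
    sizes = np.floor(raw).astype(int) + 1
    remainder = total - int(sizes.sum())
    # distribute leftover units by largest fractional part, rank as tie-break
    order = np.lexsort((np.arange(n_classes), -(raw - np.floor(raw))))
    for j in range(remainder):
        sizes[order[j % n_classes]] += 1
    assert sizes.sum() == total and (sizes >= 1).all()
    return [int(s) for s in sizes]


def _place_centroids(
    rng: np.random.Generator, n: int, dim: int, min_dist: float
) -> np.ndarray:
    """Rejection-sample centroids with pairwise distance >= min_dist."""
    # Box wide enough that random placement succeeds easily in any dim >= 2;
    # grows with n so dense requests stay feasible.
    box = 3.0 * min_dist * max(1.0, n ** (1.0 / max(dim, 1)))
    centroids = np.empty((n, dim))
    placed = 0
    for _ in range(1000 * n):
        cand = rng.uniform(0.0, box, size=dim)
        if placed == 0 or (
            np.linalg.norm(centroids[:placed] - cand, axis=1) >= min_dist
        ).all():
            centroids[placed] = cand
            placed += 1
            if placed == n:
                return centroids
    raise ValidationError(
        f"could not place {n} centroids at separation {min_dist} in dim {dim}"
    )


def generate_dataset(
    config: SynthConfig,
) -> tuple[FeatureSet, LabelTable, list[str]]:
    """Generate a feature cloud with ground-truth labels.

    Returns the feature set, the complete truth label table (noise objects
    labeled ``"noise"``) and the names of the indicator classes (the
    ``indicator_class_count`` smallest classes).

    Class names are ``class_01, class_02, ...`` in decreasing size order;
    object ids are ``obj_000000, ...`` with rows shuffled so that file
    order carries no class information.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_noise = int(round(config.noise_fraction * config.total_objects))
    n_class_objects = config.total_objects - n_noise
    sizes = power_law_sizes(config.n_classes, config.size_exponent, n_class_objects)

    sigma = config.within_class_sigma
    rms_radius = sigma * float(np.sqrt(config.dim))
    centroids = _place_centroids(
        rng, config.n_classes, config.dim, config.separation * rms_radius
    )

    names = [f"class_{i + 1:02d}" for i in range(config.n_classes)]
    rows: list[np.ndarray] = []
    labels: list[str] = []
    for name, size, c in zip(names, sizes, centroids):
        rows.append(c + rng.normal(0.0, sigma, size=(size, config.dim)))
        labels.extend([name] * size)

    points = np.vstack(rows)
    if n_noise:
        lo = points.min(axis=0) - sigma
        hi = points.max(axis=0) + sigma
        rows.append(rng.uniform(lo, hi, size=(n_noise, config.dim)))
        labels.extend([NOISE_LABEL] * n_noise)
        points = np.vstack([points, rows[-1]])

    perm = rng.permutation(config.total_objects)
    ids = [f"obj_{i:06d}" for i in range(config.total_objects)]
    feature_set = FeatureSet(ids, points[perm])
    truth = LabelTable({ids[i]: labels[perm[i]] for i in range(len(ids))})
    indicators = names[config.n_classes - config.indicator_class_count :]
    return feature_set, truth, list(indicators)


def benchmark_config(rng_seed: int = 0) -> SynthConfig:
    """The package's standard end-to-end benchmark conditions.

    30 well-separated classes, 20 000 objects, 2% uniform background noise
    and the two smallest classes (≈50 objects each under exponent 1.5) held
    out as indicators.
    """
    return SynthConfig(
        n_classes=30,
        total_objects=20_000,
        dim=DEFAULT_DIM,
        size_exponent=1.5,
        separation=10.0,
        noise_fraction=0.02,
        indicator_class_count=2,
        rng_seed=rng_seed,
    )


class OracleAnnotator(AnnotatorContract):
    """Deterministic annotator backed by a complete truth label table.

    Stands in for the human: a cluster is approved when the share of its
    modal true label reaches ``purity_threshold`` (boundary inclusive) and
    that label is not the reserved noise label; page and single-object
    judgments compare true labels against the seed's modal label, with
    noise objects always counting as mismatches.
    """

    def __init__(self, truth: LabelTable, purity_threshold: float = 0.90):
        if not 0.0 < purity_threshold <= 1.0:
            raise ValidationError("purity_threshold must be in (0, 1]")
        self.truth = truth
        self.purity_threshold = purity_threshold

    def _label(self, object_id: str) -> str:
        try:
            return self.truth[object_id]
        except KeyError:
            raise ValidationError(
                f"object {object_id!r} missing from truth table"
            ) from None

    def modal_label(self, members: Iterable[str]) -> str:
        ids = sorted(members)
        if not ids:
            raise ValidationError("modal label of an empty member set")
        counts = Counter(self._label(o) for o in ids)
        top = max(counts.values())
        return min(l for l, c in counts.items() if c == top)

    def judge_cluster(self, members: Iterable[str]) -> bool:
        ids = sorted(members)
        if not ids:
            raise ValidationError("judging an empty member set")
        counts = Counter(self._label(o) for o in ids)
        top = max(counts.values())
        label = min(l for l, c in counts.items() if c == top)
        if label == NOISE_LABEL:
            return False
        return top / len(ids) >= self.purity_threshold

    def judge_page(self, page: Sequence[str], seed_modal_label: str) -> PageJudgment:
        if not page:
            raise ValidationError("judging an empty page")
        bad = frozenset(
            o for o in page if self._label(o) != seed_modal_label
        )
        if bad:
            return PageJudgment(False, bad)
        return PageJudgment(True)

    def judge_object(self, object_id: str, seed_modal_label: str) -> bool:
        return self._label(object_id) == seed_modal_label
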