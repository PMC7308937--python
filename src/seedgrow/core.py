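"""Domain types, file IO and event logging shared by all pipeline stages.

The engine operates on a fixed universe of objects, each identified by a
string id and carrying a D-dimensional feature vector (typically the
32-dimensional embedding of an image produced by a convolutional feature
extractor).  Objects move between an *unassigned pool* and clusters; the
partition of the universe into pool + cluster member sets is an invariant
that is checked after every stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

#: Reserved label for background objects that belong to no real class.
NOISE_LABEL = "noise"

#: Reserved label assigned by label flattening when no ancestor is named.
UNNAMED_LABEL = "unnamed"

#: Default feature dimensionality (reduced deep-learning embedding).
DEFAULT_DIM = 32

#: Default shrinking minimum-cluster-size schedule, one entry per iteration.
DEFAULT_M_SCHEDULE = (128, 64, 32, 16, 8, 4)

#: Default number of candidate objects reviewed together during growing.
DEFAULT_PAGE_SIZE = 50


class SeedgrowError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(SeedgrowError):
    """Malformed input data (files, tables, configurations)."""


class StateError(SeedgrowError):
    """An operation was applied to an incompatible process state."""


# ---------------------------------------------------------------------------
# FeatureSet
# ---------------------------------------------------------------------------


class FeatureSet:
    """Ordered collection of objects with one feature row each.

    Parameters
    ----------
    object_ids:
        Unique string identifiers, one per row of *features*.
    features:
        Real matrix of shape ``(n_objects, dim)``; all values finite.
    """

    __slots__ = ("object_ids", "features", "_index")

    def __init__(self, object_ids: Iterable[str], features: np.ndarray):
        ids = [str(i) for i in object_ids]
        feats = np.asarray(features, dtype=np.float64)
        if feats.ndim != 2:
            raise ValidationError("features must be a 2-d matrix")
        if len(ids) != feats.shape[0]:
            raise ValidationError(
                f"{len(ids)} object ids but {feats.shape[0]} feature rows"
            )
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValidationError(f"duplicate object id {dup!r}")
        if not np.all(np.isfinite(feats)):
            raise ValidationError("non-finite feature values")
        self.object_ids: list[str] = ids
        self.features: np.ndarray = feats
        self._index: dict[str, int] = {o: i for i, o in enumerate(ids)}

    # -- basic container protocol ------------------------------------------

    def __len__(self) -> int:
        return len(self.object_ids)

    def __contains__(self, object_id: str) -> bool:
        return object_id in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self.object_ids)

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    def row(self, object_id: str) -> np.ndarray:
        """Feature vector of a single object."""
        return self.features[self._index[object_id]]

    def matrix(self, object_ids: Iterable[str]) -> np.ndarray:
        """Feature rows for *object_ids*, in the given order."""
        idx = [self._index[o] for o in object_ids]
        return self.features[idx]

    def subset(self, object_ids: Iterable[str]) -> "FeatureSet":
        """New FeatureSet restricted to *object_ids* (given order kept)."""
        ids = list(object_ids)
        return FeatureSet(ids, self.matrix(ids))

    def centroid(self, object_ids: Iterable[str]) -> np.ndarray:
        """Arithmetic mean of the feature rows of *object_ids*."""
        m = self.matrix(object_ids)
        if m.shape[0] == 0:
            raise ValidationError("centroid of an empty member set")
        return m.mean(axis=0)


# ---------------------------------------------------------------------------
# LabelTable
# ---------------------------------------------------------------------------


class LabelTable(Mapping[str, str]):
    """Partial mapping from object id to class name.

    Unlabeled objects are simply absent from the table.
    """

    def __init__(self, mapping: Mapping[str, str] | Iterable[tuple[str, str]] = ()):
        self._map: dict[str, str] = dict(mapping)

    def __getitem__(self, object_id: str) -> str:
        return self._map[object_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, LabelTable):
            return self._map == other._map
        return NotImplemented

    def classes(self) -> list[str]:
        """Sorted list of distinct class names."""
        return sorted(set(self._map.values()))

    def members_of(self, label: str) -> list[str]:
        """Sorted ids carrying *label*."""
        return sorted(o for o, l in self._map.items() if l == label)

    def class_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for l in self._map.values():
            sizes[l] = sizes.get(l, 0) + 1
        return sizes

    def to_series(self) -> pd.Series:
        return pd.Series(self._map, name="label")

    def check_covers(self, feature_set: FeatureSet) -> None:
        """Raise unless every keyed id appears in *feature_set*."""
        missing = [o for o in self._map if o not in feature_set]
        if missing:
            raise ValidationError(
                f"{len(missing)} labeled ids missing from feature set, "
                f"e.g. {missing[0]!r}"
            )


# ---------------------------------------------------------------------------
# Cluster
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    """A cluster seed plus the members accreted during growing.

    ``seed_members`` are the dense core found by density clustering; the
    centroid is always the mean of the *seed* rows and stays fixed while the
    cluster grows.  ``grown_members`` is disjoint from ``seed_members``.
    """

    cluster_id: str
    seed_members: set[str]
    centroid: np.ndarray
    grown_members: set[str] = field(default_factory=set)
    approved: bool = False
    flagged: bool = False
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.seed_members:
            raise ValidationError(f"cluster {self.cluster_id}: empty seed")
        overlap = self.seed_members & self.grown_members
        if overlap:
            raise ValidationError(
                f"cluster {self.cluster_id}: seed/grown overlap {sorted(overlap)[:3]}"
            )
        self.centroid = np.asarray(self.centroid, dtype=np.float64)

    @classmethod
    def from_seed(
        cls, cluster_id: str, seed_members: Iterable[str], features: FeatureSet
    ) -> "Cluster":
        members = set(seed_members)
        return cls(cluster_id, members, features.centroid(sorted(members)))

    @property
    def members(self) -> set[str]:
        return self.seed_members | self.grown_members

    def __len__(self) -> int:
        return len(self.seed_members) + len(self.grown_members)

    def full_centroid(self, features: FeatureSet) -> np.ndarray:
        """Mean feature vector over seed *and* grown members."""
        return features.centroid(sorted(self.members))


# ---------------------------------------------------------------------------
# ProcessState
# ---------------------------------------------------------------------------


@dataclass
class ProcessState:
    """Bookkeeping for one run of the iterative seed/validate/grow process.

    The unassigned pool is implicit: it is the set of universe ids that are
    in no cluster.  :meth:`unassigned` recomputes it so that the partition
    invariant (every object in exactly one place) is checkable at any time.
    """

    all_ids: set[str]
    m_schedule: tuple[int, ...] = DEFAULT_M_SCHEDULE
    k: int = 1
    page_size: int = DEFAULT_PAGE_SIZE
    clusters: list[Cluster] = field(default_factory=list)
    iteration: int = 1
    rng_seed: int = 0
    done: bool = False

    def __post_init__(self) -> None:
        sched = tuple(int(m) for m in self.m_schedule)
        if not sched or any(m < 2 for m in sched):
            raise ValidationError("m_schedule entries must be >= 2")
        if any(a <= b for a, b in zip(sched, sched[1:])):
            raise ValidationError("m_schedule must be strictly decreasing")
        self.m_schedule = sched
        if self.iteration < 1:
            raise ValidationError("iteration starts at 1")

    @property
    def current_m(self) -> int:
        return self.m_schedule[self.iteration - 1]

    def unassigned(self) -> set[str]:
        assigned: set[str] = set()
        for c in self.clusters:
            assigned |= c.members
        return self.all_ids - assigned

    def assert_conservation(self) -> None:
        """Every id in exactly one of: pool, or one cluster's member sets."""
        assigned: list[str] = []
        for c in self.clusters:
            assigned.extend(c.members)
        if len(assigned) != len(set(assigned)):
            raise StateError("object assigned to more than one cluster")
        stray = set(assigned) - self.all_ids
        if stray:
            raise StateError(f"clustered ids outside universe: {sorted(stray)[:3]}")
        if len(self.unassigned()) + len(assigned) != len(self.all_ids):
            raise StateError("partition conservation violated")


# ---------------------------------------------------------------------------
# Event log and sessions
# ---------------------------------------------------------------------------

PHASES = ("validate", "grow", "name")


@dataclass(frozen=True)
class Event:
    """One tracked annotator action."""

    timestamp: float  # seconds since the epoch (UTC)
    phase: str  # one of PHASES
    action: str
    count: int  # number of objects affected

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if self.count < 0:
            raise ValidationError("negative object count")


class EventLog:
    """Append-only ordered record of annotator actions."""

    def __init__(self, events: Iterable[Event] = ()):
        self.events: list[Event] = []
        for e in events:
            self.append(e)

    def append(self, event: Event) -> None:
        if self.events and event.timestamp < self.events[-1].timestamp:
            raise ValidationError("timestamps must be non-decreasing")
        self.events.append(event)

    def record(self, timestamp: float, phase: str, action: str, count: int) -> None:
        self.append(Event(timestamp, phase, action, count))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)


@dataclass(frozen=True)
class Session:
    """A contiguous work period with no internal break longer than max_gap."""

    events: tuple[Event, ...]

    @property
    def duration(self) -> float:
        """Seconds between first and last entry (0 for a single event)."""
        return self.events[-1].timestamp - self.events[0].timestamp

    @property
    def object_count(self) -> int:
        return sum(e.count for e in self.events)


def split_sessions(log: EventLog, max_gap: float = 600.0) -> list[Session]:
    """Split a log into sessions at breaks strictly longer than *max_gap* s.

    A gap of exactly *max_gap* does not split ("no breaks longer than" the
    gap reads as gaps up to and including it being allowed).  An empty log
    yields an empty list.
    """
    sessions: list[Session] = []
    current: list[Event] = []
    for e in log:
        if current and e.timestamp - current[-1].timestamp > max_gap:
            sessions.append(Session(tuple(current)))
            current = []
        current.append(e)
    if current:
        sessions.append(Session(tuple(current)))
    return sessions


class Clock:
    """Injectable time source; the default reads the wall clock."""

    def now(self) -> float:
        import time

        return time.time()


class SimulatedClock(Clock):
    """Deterministic clock that advances a fixed step per reading.

    Used by oracle-driven runs so that event logs (and hence throughput
    statistics) are reproducible.
    """

    def __init__(self, start: float = 0.0, step: float = 1.0):
        self.t = float(start)
        self.step = float(step)

    def now(self) -> float:
        t = self.t
        self.t += self.step
        return t


# ---------------------------------------------------------------------------
# File readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def load_features(path: str, expected_dim: int | None = None) -> FeatureSet:
    """Read a delimited feature table (TSV by default, CSV by extension).

    The header row must start with ``object_id`` followed by one column per
    feature dimension.  Row order is preserved.
    """
    df = pd.read_csv(
        path, sep=_sep_for(path), dtype={0: str}, float_precision="round_trip"
    )
    if df.shape[1] < 2 or df.columns[0] != "object_id":
        raise ValidationError(
            f"{path}: expected header 'object_id' plus feature columns"
        )
    ids = df["object_id"].tolist()
    dup = df["object_id"][df["object_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicate object id {dup.iloc[0]!r}")
    feat_cols = df.columns[1:]
    try:
        feats = df[feat_cols].astype(np.float64).to_numpy()
    except ValueError:
        for i, (_, r) in enumerate(df[feat_cols].iterrows()):
            if pd.to_numeric(r, errors="coerce").isna().any():
                raise ValidationError(
                    f"{path}: non-numeric feature value in row {i + 1} "
                    f"(object {ids[i]!r})"
                ) from None
        raise
    if not np.all(np.isfinite(feats)):
        bad = int(np.argwhere(~np.isfinite(feats).all(axis=1))[0][0])
        raise ValidationError(
            f"{path}: non-finite feature value in row {bad + 1} "
            f"(object {ids[bad]!r})"
        )
    if expected_dim is not None and feats.shape[1] != expected_dim:
        raise ValidationError(
            f"{path}: expected {expected_dim} feature columns, found {feats.shape[1]}"
        )
    return FeatureSet(ids, feats)


def write_features(feature_set: FeatureSet, path: str) -> None:
    """Write a feature table; exact inverse of :func:`load_features`."""
    df = pd.DataFrame(
        feature_set.features,
        columns=[f"f{i}" for i in range(feature_set.dim)],
    )
    df.insert(0, "object_id", feature_set.object_ids)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def load_labels(path: str) -> LabelTable:
    """Read a two-column (object_id, label) delimited table."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.empty and df.shape[1] == 0:
        return LabelTable()
    if df.shape[1] != 2:
        raise ValidationError(f"{path}: expected exactly two columns")
    mapping: dict[str, str] = {}
    for oid, label in zip(df.iloc[:, 0], df.iloc[:, 1]):
        oid, label = str(oid), str(label)
        if oid in mapping and mapping[oid] != label:
            raise ValidationError(
                f"{path}: conflicting labels for {oid!r}: "
                f"{mapping[oid]!r} vs {label!r}"
            )
        mapping[oid] = label
    return LabelTable(mapping)


def write_labels(table: LabelTable, path: str) -> None:
    """Write a label table; exact inverse of :func:`load_labels`."""
    df = pd.DataFrame(
        {"object_id": list(table), "label": [table[o] for o in table]}
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def _iso(ts: float) -> str:
    return datetime.fromtimestamp(ts, tz=timezone.utc).isoformat()


def write_event_log(log: EventLog, path: str) -> None:
    """Write the log as JSON lines (ISO-8601 timestamp, phase, action, count)."""
    with open(path, "w") as fh:
        for e in log:
            fh.write(
                json.dumps(
                    {
                        "timestamp": _iso(e.timestamp),
                        "phase": e.phase,
                        "action": e.action,
                        "count": e.count,
                    }
                )
                + "\n"
            )


def load_event_log(path: str) -> EventLog:
    log = EventLog()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            ts = datetime.fromisoformat(rec["timestamp"]).timestamp()
            log.record(ts, rec["phase"], rec["action"], int(rec["count"]))
    return log
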