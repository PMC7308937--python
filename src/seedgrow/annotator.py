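"""The annotator contract: the judgment interface the engine calls.

Every interactive decision of the process — "is this cluster seed pure?",
"does this page of candidates still match the seed?", "does this single
object belong?" — goes through an :class:`AnnotatorContract`.  The engine
itself never inspects ground truth; it only sees the answers.  Two
implementations ship with the package: a deterministic oracle backed by a
complete truth table (:class:`seedgrow.synth.OracleAnnotator`) and an
interactive console annotator for real use (:class:`ConsoleAnnotator`).
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass(frozen=True)
class PageJudgment:
    """Outcome of reviewing one page of growth candidates.

    ``match`` means every object on the page belongs with the seed.  On a
    mismatch, ``offending_ids`` lists the objects that do not belong; it is
    never empty when ``match`` is False.
    """

    match: bool
    offending_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.match and not self.offending_ids:
            raise ValueError("mismatch requires at least one offending id")
        if self.match and self.offending_ids:
            raise ValueError("match must carry no offending ids")


class AnnotatorContract(ABC):
    """Judgment interface standing in for the human in front of the GUI."""

    @abstractmethod
    def modal_label(self, members: Iterable[str]) -> str:
        """The annotator's working identity for a seed (its visual class).

        For the oracle this is the most frequent true label among the seed
        members; an interactive annotator may return any stable token.
        """

    @abstractmethod
    def judge_cluster(self, members: Iterable[str]) -> bool:
        """True iff the member set reads as one homogeneous class."""

    @abstractmethod
    def judge_page(self, page: Sequence[str], seed_modal_label: str) -> PageJudgment:
        """Judge whether a whole candidate page still matches the seed."""

    @abstractmethod
    def judge_object(self, object_id: str, seed_modal_label: str) -> bool:
        """Judge a single candidate object against the seed."""

    def wants_flag(self, members: Iterable[str]) -> bool:
        """Whether a validated cluster should get preferred growth treatment."""
        return False


class ConsoleAnnotator(AnnotatorContract):
    """Interactive annotator that asks questions on the terminal.

    Object ids are shown in place of images, so this is mainly useful for
    demonstrations and for data whose ids are meaningful.
    """

    def __init__(self, echo=None, prompt=None):
        import click

        self._echo = echo or click.echo
        self._prompt = prompt or click.confirm

    def modal_label(self, members: Iterable[str]) -> str:
        return "seed:" + min(members)

    def judge_cluster(self, members: Iterable[str]) -> bool:
        ids = sorted(members)
        self._echo(f"Cluster seed with {len(ids)} members: {', '.join(ids[:20])}"
                   + (" ..." if len(ids) > 20 else ""))
        return self._prompt("Is this cluster homogeneous (approve)?")

    def judge_page(self, page: Sequence[str], seed_modal_label: str) -> PageJudgment:
        self._echo(f"Candidate page ({len(page)} objects) for {seed_modal_label}:")
        self._echo(", ".join(page))
        if self._prompt("Does the whole page match the seed?"):
            return PageJudgment(True)
        bad = [o for o in page if not self._prompt(f"  keep {o}?")]
        if not bad:  # user contradicted themselves; treat as match
            return PageJudgment(True)
        return PageJudgment(False, frozenset(bad))

    def judge_object(self, object_id: str, seed_modal_label: str) -> bool:
        return self._prompt(f"Does {object_id} match {seed_modal_label}?")


@dataclass
class CountingAnnotator(AnnotatorContract):
    """Wrapper that counts judgments made through an inner annotator."""

    inner: AnnotatorContract
    page_judgments: int = 0
    object_judgments: int = 0
    cluster_judgments: int = 0
    judged_pages: list = field(default_factory=list)

    def modal_label(self, members):
        return self.inner.modal_label(members)

    def judge_cluster(self, members):
        self.cluster_judgments += 1
        return self.inner.judge_cluster(members)

    def judge_page(self, page, seed_modal_label):
        self.page_judgments += 1
        self.judged_pages.append(list(page))
        return self.inner.judge_page(page, seed_modal_label)

    def judge_object(self, object_id, seed_modal_label):
        self.object_judgments += 1
        return self.inner.judge_object(object_id, seed_modal_label)

    def wants_flag(self, members):
        return self.inner.wants_flag(members)
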