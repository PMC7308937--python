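import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedgrow import (
    Cluster,
    EventLog,
    FeatureSet,
    LabelTable,
    OracleAnnotator,
    correspondence,
    precision_by_review,
    recovery_report,
    relative_overlap,
    throughput,
)
from seedgrow.core import ValidationError


class TestPrecisionByReview:
    def test_perfect_labeling(self):
        truth = LabelTable({f"o{i}": f"c{i % 3}" for i in range(30)})
        rep = precision_by_review(truth, OracleAnnotator(truth))
        assert rep.macro_precision == 1.0
        assert all(c.precision == 1.0 for c in rep.per_class.values())

    def test_hand_counted_fractions(self):
        # class "a": 3 of 4 inliers -> 0.75; class "b": perfect -> 1.0
        truth = LabelTable({"o1": "a", "o2": "a", "o3": "a", "o4": "z",
                            "o5": "b", "o6": "b"})
        labels = LabelTable({"o1": "a", "o2": "a", "o3": "a", "o4": "a",
                             "o5": "b", "o6": "b"})
        rep = precision_by_review(labels, OracleAnnotator(truth))
        assert rep.per_class["a"].precision == 0.75
        assert rep.per_class["a"].true_positives == 3
        assert rep.macro_precision == pytest.approx((0.75 + 1.0) / 2)

    def test_macro_is_mean_of_class_precisions(self):
        truth = LabelTable({"o1": "a", "o2": "z", "o3": "b", "o4": "b"})
        labels = LabelTable({"o1": "a", "o2": "a", "o3": "b", "o4": "b"})
        rep = precision_by_review(labels, OracleAnnotator(truth))
        assert rep.macro_precision == pytest.approx(0.75)  # mean(0.5, 1.0)

    def test_big_cap_equals_exhaustive(self):
        rng = np.random.default_rng(0)
        truth = LabelTable({f"o{i}": f"c{rng.integers(4)}" for i in range(200)})
        labels = LabelTable(
            {o: (l if rng.random() > 0.3 else "c0") for o, l in truth.items()}
        )
        oracle = OracleAnnotator(truth)
        rep = precision_by_review(labels, oracle, cap=10_000)
        for label, cp in rep.per_class.items():
            members = labels.members_of(label)
            exact = sum(truth[o] == label for o in members) / len(members)
            assert cp.precision == pytest.approx(exact)

    def test_macro_unweighted_under_class_duplication(self):
        truth = LabelTable({"o1": "a", "o2": "z", "o3": "b"})
        labels = LabelTable({"o1": "a", "o2": "a", "o3": "b"})
        base = precision_by_review(labels, OracleAnnotator(truth)).macro_precision
        # duplicate class b's objects: per-class precisions unchanged
        truth2 = LabelTable(dict(truth) | {f"d{i}": "b" for i in range(10)})
        labels2 = LabelTable(dict(labels) | {f"d{i}": "b" for i in range(10)})
        dup = precision_by_review(labels2, OracleAnnotator(truth2)).macro_precision
        assert dup == pytest.approx(base)

    def test_group_breakdown(self):
        truth = LabelTable({"o1": "a", "o2": "b", "o3": "c"})
        rep = precision_by_review(
            truth, OracleAnnotator(truth),
            group_map={"a": "living", "b": "non-living"},
        )
        groups = rep.group_summary()
        assert set(groups) == {"living", "non-living", "excluded"}
        assert groups["excluded"]["n_classes"] == 1

    def test_sampling_is_seeded(self):
        truth = LabelTable({f"o{i}": "a" for i in range(100)})
        labels = LabelTable({f"o{i}": "a" for i in range(100)})
        r1 = precision_by_review(labels, OracleAnnotator(truth), cap=10, rng_seed=5)
        r2 = precision_by_review(labels, OracleAnnotator(truth), cap=10, rng_seed=5)
        assert r1.per_class["a"].sample_size == r2.per_class["a"].sample_size == 10


class TestRelativeOverlap:
    def test_identity(self):
        assert relative_overlap({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert relative_overlap({"a"}, {"b"}) == 0.0

    def test_hand_arithmetic(self):
        a = {"1", "2", "3", "4"}
        b = {"3", "4", "5", "6", "7", "8"}
        assert relative_overlap(a, b) == pytest.approx(2 / 8)

    def test_both_empty_convention(self):
        assert relative_overlap(set(), set()) == 0.0

    @given(
        a=st.sets(st.integers(0, 30), max_size=20),
        b=st.sets(st.integers(0, 30), max_size=20),
    )
    @settings(deadline=None, max_examples=100)
    def test_symmetric_and_bounded(self, a, b):
        a, b = {str(x) for x in a}, {str(x) for x in b}
        v = relative_overlap(a, b)
        assert v == relative_overlap(b, a)
        assert 0.0 <= v <= 1.0


class TestCorrespondence:
    def test_identity_labeling(self):
        labels = LabelTable({f"o{i}": f"c{i % 3}" for i in range(12)})
        m = correspondence(labels, labels)
        assert m.macro_agreement == 1.0
        np.testing.assert_allclose(np.diag(m.overlap.to_numpy()), 1.0)
        assert all(m.predominant[c] == c for c in m.predominant)

    def test_predominant_and_agreement(self):
        # one B-class holding 7 X-objects and 3 Y-objects
        a = LabelTable({f"o{i}": ("X" if i < 7 else "Y") for i in range(10)})
        b = LabelTable({f"o{i}": "B1" for i in range(10)})
        m = correspondence(a, b)
        assert m.predominant["B1"] == "X"
        assert m.agreement["B1"] == pytest.approx(0.7)

    def test_unshared_b_class_excluded(self):
        a = LabelTable({"o1": "X"})
        b = LabelTable({"o1": "B1", "o2": "B2"})  # B2 shares nothing
        m = correspondence(a, b)
        assert set(m.agreement) == {"B1"}

    def test_overlap_transposes(self):
        a = LabelTable({"o1": "X", "o2": "X", "o3": "Y"})
        b = LabelTable({"o1": "P", "o2": "Q", "o3": "Q"})
        m_ab, m_ba = correspondence(a, b), correspondence(b, a)
        np.testing.assert_allclose(
            m_ab.overlap.to_numpy(), m_ba.overlap.to_numpy().T
        )

    def test_zero_shared_objects_error(self):
        with pytest.raises(ValidationError):
            correspondence(LabelTable({"o1": "X"}), LabelTable({"o2": "Y"}))


class TestThroughput:
    def _log(self, entries):
        log = EventLog()
        for t, phase, count in entries:
            log.record(float(t), phase, "act", count)
        return log

    def test_simple_rate(self):
        # 100 objects over a 30-minute session -> 200 objects/hour
        log = self._log([(0, "validate", 40), (600, "validate", 0),
                         (1200, "validate", 0), (1800, "validate", 60)])
        assert throughput(log)["validate"] == pytest.approx(200.0)

    def test_gap_split_sums_durations(self):
        # sessions of 5 min and 0 min: only 300 s of work time counts
        log = self._log([(0, "grow", 50), (300, "grow", 30), (1200, "grow", 20)])
        assert throughput(log)["grow"] == pytest.approx(100 / (300 / 3600))

    def test_absent_phase_omitted(self):
        log = self._log([(0, "validate", 10), (60, "validate", 10)])
        assert "grow" not in throughput(log)

    def test_zero_duration_undefined(self):
        log = self._log([(0, "name", 10)])
        assert throughput(log)["name"] is None

    def test_empty_log_error(self):
        with pytest.raises(ValidationError):
            throughput(EventLog())


class TestRecoveryReport:
    def _clusters(self, assignments, features):
        out = []
        for cid, (members, name) in assignments.items():
            c = Cluster.from_seed(cid, members, features)
            c.name = name
            out.append(c)
        return out

    def test_absent_class_not_retrieved(self):
        fs = FeatureSet(["o1", "o2", "o3"], np.zeros((3, 2)))
        truth = LabelTable({"o1": "a", "o2": "a", "o3": "rare"})
        clusters = self._clusters({"c1": (["o1", "o2"], "a")}, fs)
        rep = recovery_report(clusters, truth, [])
        assert rep.per_class["a"].retrieved
        assert not rep.per_class["rare"].retrieved

    def test_predominant_label_defines_retrieval(self):
        fs = FeatureSet([f"o{i}" for i in range(10)], np.zeros((10, 2)))
        truth = LabelTable(
            {f"o{i}": ("x" if i < 7 else "y") for i in range(10)}
        )
        clusters = self._clusters({"c1": ([f"o{i}" for i in range(10)], "x")}, fs)
        rep = recovery_report(clusters, truth, [])
        assert rep.per_class["x"].retrieved and not rep.per_class["y"].retrieved

    def test_singleton_class_below_m_cannot_be_retrieved(self):
        # pigeonhole: a 1-object class can never form a seed of size >= 4
        fs = FeatureSet(["o1", "o2", "o3", "o4", "o5"], np.zeros((5, 2)))
        truth = LabelTable({f"o{i}": "big" for i in range(1, 5)} | {"o5": "solo"})
        clusters = self._clusters({"c1": (["o1", "o2", "o3", "o4"], "big")}, fs)
        rep = recovery_report(
            clusters, truth, [],
            seed_history=[(1, "c1", frozenset(["o1", "o2", "o3", "o4"]))],
        )
        assert not rep.per_class["solo"].retrieved
        assert rep.per_class["solo"].first_seed_iteration is None

    def test_spearman_sign_for_size_ordered_discovery(self):
        fs = FeatureSet([f"o{i}" for i in range(60)], np.zeros((60, 2)))
        sizes = {"a": 30, "b": 20, "c": 10}
        mapping, i = {}, 0
        for label, n in sizes.items():
            for _ in range(n):
                mapping[f"o{i}"] = label
                i += 1
        truth = LabelTable(mapping)
        clusters = self._clusters(
            {
                "c1": (truth.members_of("a"), "a"),
                "c2": (truth.members_of("b"), "b"),
                "c3": (truth.members_of("c"), "c"),
            },
            fs,
        )
        history = [
            (1, "c1", frozenset(truth.members_of("a"))),
            (2, "c2", frozenset(truth.members_of("b"))),
            (3, "c3", frozenset(truth.members_of("c"))),
        ]
        rep = recovery_report(clusters, truth, [], seed_history=history)
        assert rep.size_iteration_spearman == pytest.approx(-1.0)
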