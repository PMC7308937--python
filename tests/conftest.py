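from __future__ import annotations

import numpy as np
import pytest

from seedgrow import (
    FeatureSet,
    LabelTable,
    OracleAnnotator,
    RunConfig,
    benchmark_config,
    generate_dataset,
    oracle_namer,
    run_full,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_features():
    """Five objects on a line in 2-d; handy for rank/arrange checks."""
    ids = ["a", "b", "c", "d", "e"]
    feats = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [10.0, 0.0], [11.0, 0.0]])
    return FeatureSet(ids, feats)


def make_line_dataset(n_match: int, n_other: int, page_size: int = 50):
    """Seed at the origin of a 1-d line, candidates at x = 1, 2, 3, ...

    The first *n_match* candidates share the seed's label "X", the rest
    are "Y", so page judgments against a distance ranking are monotone
    with the boundary after n_match objects.  Returns (features, truth,
    seed_ids, candidate_ids).
    """
    seed_ids = [f"s{i:03d}" for i in range(10)]
    cand_ids = [f"c{i:04d}" for i in range(n_match + n_other)]
    xs = [0.0] * len(seed_ids) + [float(i + 1) for i in range(len(cand_ids))]
    features = FeatureSet(seed_ids + cand_ids, np.array(xs)[:, None])
    truth = LabelTable(
        {s: "X" for s in seed_ids}
        | {c: ("X" if i < n_match else "Y") for i, c in enumerate(cand_ids)}
    )
    return features, truth, seed_ids, cand_ids


@pytest.fixture(scope="session")
def benchmark_run():
    """One full oracle-driven run under the standard benchmark conditions
    (30 classes, 20 000 objects, 2% noise, schedule 128..4, seed 0).

    Session-scoped: several end-to-end tests measure different properties
    of the same run.
    """
    features, truth, indicators = generate_dataset(benchmark_config(0))
    result = run_full(
        features,
        OracleAnnotator(truth),
        RunConfig(),
        namer=oracle_namer(truth),
    )
    return {
        "features": features,
        "truth": truth,
        "indicators": indicators,
        "result": result,
    }
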