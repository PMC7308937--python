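# Methods

This note records the model behind `seedgrow`, the parameters that matter,
what the synthetic data does and does not emulate, and the places where the
design was genuinely open.

## Process model

The engine assumes a feature space in which Euclidean distance is a proxy
for visual similarity (the contract of a well-trained deep feature
extractor; dimensionality D, default 32).  All stages share one invariant:
the object universe is always partitioned into the unassigned pool plus
pairwise-disjoint cluster member sets.  The partition is re-derived and
asserted after every seeding, validation, growth and naming stage; a
violation raises immediately rather than corrupting downstream results.

Annotation proceeds in iterations over a strictly decreasing minimum
cluster size schedule, default (128, 64, 32, 16, 8, 4).  Large m first
extracts the biggest coherent groups, keeping the number of clusters to
validate small while most of the data is still unassigned; small m later
exposes rare classes from the shrunken pool.  The schedule's exhaustion is
the stop rule; an optional early stop (no validated seeds in an iteration)
is available but off by default, since a fruitless iteration at large m
says little about smaller m.

### Seeding

Seeds come from HDBSCAN\* with `min_samples = k = 1` and
`min_cluster_size = m` (scikit-learn implementation), excess-of-mass
cluster selection.  HDBSCAN\* labels most of a diffuse pool as noise and
returns only dense cores — exactly the behavior that makes seeds pure
enough to validate wholesale.  The selection method is configurable
(`eom`/`leaf`); `eom` is the algorithm's default.  Distances are Euclidean
throughout the engine (seeding, ranking, hierarchy); nothing in the design
depends on another metric, and a consistent metric keeps the growth
monotonicity assumption coherent with the seeding geometry.

Seeding is deterministic given its input; the engine's `rng_seed` exists
for components that sample (synthetic generation, precision review).

### Validation

The annotator contract reduces validation to one judgment per seed:
homogeneous or not.  The oracle implementation approves a member set when
its modal true label reaches the purity threshold (default 0.90, boundary
inclusive — 9 of 10 passes) and that label is not the reserved `"noise"`
label.  0.90 mirrors the high purity that density cores exhibit in
practice while tolerating the occasional straggler; it is a parameter, not
a constant.  Rejected seeds dissolve back into the pool and their objects
remain available to later iterations.  For display-oriented annotators,
`arrange_dissimilar` orders a seed greedily: start from the most distant
pair, then repeatedly append the member farthest from the last placed one
(ties by id).  The greedy order is not the exact max–min-adjacent-distance
optimum — it guarantees alternation across any strong two-group split,
which is what makes contamination visible.

### Growing

Candidates are ranked by ascending distance to the *seed* centroid (ties
by object id) and cut into pages of 50.  The centroid stays fixed while
the cluster grows: a running centroid would drift toward whatever was
accepted first and silently change the question the annotator is
answering mid-search; the alternative is available behind a flag.

The boundary page b (last fully matching page) is found in two phases:
galloping probes at pages 1, 2, 4, …, doubling the page index and capped
at P, bracket the boundary between the last matching and first
mismatching probe; binary search then closes the bracket.  Pages before
the last matching probe are never re-judged — that is precisely the
monotonicity assumption, and the protocol is only claimed correct for
monotone annotators.  For such annotators the accepted set equals a
linear page-by-page scan's (verified over 200 random boundaries in the
acceptance suite) and the number of page judgments is at most
2·⌈log2(P+1)⌉ + 2.  When every page matches, the probe count is exactly
⌈log2 P⌉ + 1 (probes 1, 2, 4, …, then P itself when P is not a power of
two).

Turtle mode: when a judged page comes back with *individual* removals
(mismatch whose offending set is a proper subset of the page), page-level
search stops, pages before the triggering page are accepted under the
monotonicity assumption, and every candidate from that page on is judged
one by one.  Two aspects are underdetermined in interactive practice and
fixed here as defaults: the scan ends after 50 consecutive individual
rejections (one page worth — the annotator has seen a full page of
non-members), and earlier skipped pages are not re-examined.  Both are
configurable (`turtle_patience`; `turtle=False` disables the mode and
treats partial mismatches as whole-page rejections).

Growth order: flagged clusters first (preferred treatment), then
descending seed size, then id — a concrete, deterministic policy for a
preference that interactive use leaves to the user.

### Hierarchy and naming

Final clusters are arranged by UPGMA (average linkage) over the pairwise
Euclidean distances of their centroids, computed over **all** members
(seed + grown): the hierarchy organizes the end-of-process clusters, so it
should reflect their final composition rather than their historical cores.
Heights follow the ultrametric convention — a merge at average distance d
sits at height d/2, leaves at 0 — so two clusters at distance d join at
d/2.  scipy's `linkage(method="average")` does the agglomeration; input
clusters are pre-sorted by id so its index-order tie handling is
deterministic, and the whole construction is checked against a naive O(n³)
UPGMA in the test and acceptance suites (merge composition and heights to
1e−9).  Only UPGMA is implemented; the linkage argument is an enum with a
single value by design.

Tree edits preserve the object multiset: merging requires the nodes to
share a parent or be nested under one of them (anything else must be moved
first), moving refuses cycles, names are free-form nonempty strings.
Flattening assigns each object the name of the nearest named node from its
cluster's node up to the root, with the reserved label `"unnamed"` as the
fallback for fully unnamed paths — this makes partially named trees
well-defined instead of erroring.  Residual objects are absent from the
output table.  The `oracle_namer` used in tests and benchmarks names each
leaf by its predominant true label and merges same-named siblings,
emulating the leaves-to-root naming walk deterministically.

## Synthetic data

`generate_dataset` draws one isotropic Gaussian component per class in
D dimensions, class sizes from a discrete power law (size ∝ rank^−a,
largest-remainder rounding, every class nonempty), plus a uniform
background component over the bounding box labeled `"noise"`.  Defaults:
a = 1.5, σ = 1, 2% noise in the benchmark preset.  At a = 2 and 50
classes the top 10% of classes hold more than 80% of the objects — the
severe imbalance regime of expert-sorted underwater-imaging collections;
with totals in the 10⁵–10⁶ range the sizes span several orders of
magnitude.  The *indicator classes* are simply the smallest
`indicator_class_count` classes, reported by name to the evaluation layer
only — the engine never learns which classes are indicators.

`separation` is the minimum pairwise centroid distance in units of the
within-class RMS radius σ√D (the typical member-to-centroid distance).
The unit matters: in high dimensions distances concentrate around σ√D, so
a separation expressed in per-coordinate σ units would describe wildly
different overlap regimes at D = 2 and D = 32 — at D = 32, 10σ-spaced
unit-σ blobs actually touch.  In RMS-radius units, separation ≥ ~3 is
effectively perfect separation at any D, and the generator's documented
monotonicity property (distance ranking from a pure seed puts all
same-class candidates first) holds as stated.

The standard benchmark (`benchmark_config`): 30 classes, 20 000 objects,
D = 32, a = 1.5 (smallest classes ≈ 50 objects), separation 10, 2% noise,
2 indicator classes.  Problem sizes are chosen so the complete end-to-end
run takes seconds on one CPU while every mechanism (multi-iteration
seeding, rejection, growth boundaries, noise handling, late retrieval of
rare classes) is exercised.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: anisotropic or multi-modal classes, transitional
objects between classes (decaying organisms), label noise in the ground
truth, annotator inconsistency or fatigue (the oracle is deterministic; an
error-injecting annotator is an extension point of the contract, not
implemented behavior), and feature spaces whose distances are a poor
similarity proxy.  Benchmark results are parameter-recovery checks, not
predictions of human annotation throughput or accuracy.

An instructive benchmark artifact: occasionally a rare class's density
core attracts a few peripheral noise points, its seed then fails the 0.90
purity bar in every iteration, and the class ends unretrieved with its
objects residual.  This is faithful engine behavior under a strict purity
regime (the acceptance bar of ≥ 28/30 retrieved classes allows for it),
not a defect.

## Evaluation conventions

- Precision review samples min(cap, class size) objects per class without
  replacement (cap default 500); with cap ≥ class size it equals
  exhaustive precision.
- Pr10 is the empirical 10th percentile of per-class precisions with
  linear interpolation (numpy's default percentile method).
- Predominant-label ties break lexicographically and are flagged in the
  correspondence result; reference-side classes sharing no object with the
  comparison labeling are excluded from macro agreement.
- Session splitting uses strict inequality: a break of exactly the
  maximum allowed gap (default 10 min) does not end a session.  Throughput
  divides objects affected by summed session durations, per phase and
  overall; zero accumulated duration yields an undefined (None) rate.
- A class counts as *retrieved* when it is the predominant true label of
  at least one named cluster; its discovery iteration is the first
  iteration in which a seed predominantly of that class held ≥ 5% of the
  class's final clustered size.  The size-vs-discovery association is
  reported as a Spearman rank correlation (negative = larger found
  earlier).

## Numerical and degenerate-input choices

- Feature files are TSV with an `object_id` header column (CSV accepted by
  extension); floats are written at 17 significant digits and re-read with
  round-trip parsing, so write∘load is exact.
- Duplicate ids, non-finite features, conflicting duplicate labels and
  dimension mismatches are hard errors naming the offender.
- Seeding with fewer pool objects than m returns an empty seed list, not
  an error; growing with an empty candidate pool is a no-op; an empty
  feature set yields an empty run result.
- All ordering ties (candidate ranking, seed ordering, UPGMA merges,
  modal labels) break by lexicographic id, making every stage
  deterministic under a deterministic annotator; oracle-driven runs use a
  simulated clock (one tick per logged action) so event logs are
  reproducible too.

## Known limitations

Single-process, in-memory engine: no database persistence, no concurrent
annotators, no image handling.  Seeding cost is dominated by HDBSCAN\* on
the current pool (run once per iteration).  Classes smaller than the final
schedule entry m_min can never form a seed (pigeonhole) and are reported
as unretrieved rather than invented.  The console annotator shows object
ids, not images, so interactive use is only meaningful where ids are
interpretable; the intended production path is to implement the annotator
contract against a real display.
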