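# Methods

This note documents the models, conventions and numerical choices behind
`placentaml`, in the order the pipeline uses them.

## Labeling model

Each compound may carry three kinds of placental-transfer evidence, ranked
by reliability: the in vivo fetal:maternal concentration ratio (F/M,
dimensionless, measured at delivery), the Clearance Index from ex vivo
placental perfusion (CI, dimensionless), and a curated literature call.
The rules are:

| evidence | rule | label |
|---|---|---|
| F/M present | F/M ≤ 0.15 | NC |
| | F/M ≥ 0.3 | C |
| | 0.15 < F/M < 0.3 | EXCLUDED (dubious band) |
| else, CI present | CI > 0.80 | C |
| else, literature present | as stated | C or NC |
| no evidence | | UNLABELABLE |

Boundary values are inclusive for F/M (0.15 → NC, 0.3 → C) and strict for
CI (exactly 0.80 does not label). In vivo evidence always wins: a compound
with F/M in the excluded band is excluded even if a high CI is available
(this case is logged, since the evidence conflicts), and a CI at or below
0.80 never labels a compound NC on its own — there is no NC-by-CI rule, so
such compounds fall through to the literature. The crossing class C is the
large majority (~86% in the reference dataset) and is fixed as the negative
class at dataset build time; NC is the positive class everywhere
downstream.

## Descriptors

Full descriptor generation (thousands of physicochemical, electrotopological
and substructure-count features) belongs to external tools; the package
treats descriptor tables as opaque non-negative numeric CSV input, making
the pipeline tool-agnostic. Two operations are native:

**Rare-feature filter.** A fingerprint-count feature "matches" a compound
when its value there is strictly positive; features matched by fewer than 3
compounds (configurable) are dropped. The filter is label-free, so applying
it before the cross-validation split leaks nothing. It is idempotent, and
at `min_matches=1` removes exactly the all-zero columns.

**SMARTS counts.** The four final-model Klekota–Roth count descriptors are
computed from SMILES with RDKit. Two matches are distinct iff their sets of
matched heavy atoms differ; automorphic re-orderings of the same atom set
are deduplicated. This convention is isolated in one function
(`count_smarts_matches`) so it can be revisited; it is the natural reading
of a substructure *count*, but external fingerprint software does not
document its exact uniquification and may differ on highly symmetric
molecules. Patterns are matched against a kekulized copy of the molecule
(aromatic flags cleared), because the patterns are written Kekulé-style
with explicit single/double ring bonds and would otherwise never match
aromatic rings. Structures are used as given; no protonation-state
adjustment is performed (a log notice is the only trace of this).

## Evaluation metrics

With NC positive, false positives are crossing compounds predicted as
non-crossing — the mistake a prenatal-safety filter must avoid. The working
score is F_β with β = 1/2, the precision-weighted harmonic mean. Policy for
zero denominators: precision and recall are *undefined* (serialized as
null) rather than zero, because an undefined precision on an all-negative
prediction is informative in reports; only inside optimization (GA fitness,
model ranking) does an undefined score collapse to 0 so that candidates are
totally ordered. Averages across folds skip undefined entries and report
how many folds were defined.

The PR curve is computed at every distinct score threshold (thresholds
descending, recall non-decreasing), and average precision is the finite sum
Σ Pₙ(Rₙ−Rₙ₋₁) with R₀ = 0 — identical to the standard step-wise AP, which
the tests verify against an independent implementation. The classification
threshold on the predicted NC probability defaults to 0.5, with the
boundary inclusive (probability exactly at the threshold predicts NC; a
side had to be chosen and is documented here and in the code).

## Cross-validation

Stratified 5-fold with shuffling, seeded; per-fold class counts deviate
from perfect stratification by at most one compound (213 C / 35 NC splits
into folds of 42–43 C and exactly 7 NC). Partition k tests on fold k and
trains on the rest, so each compound trains four times and tests once.
Assignments serialize to CSV so a published split can be reloaded verbatim.

## Genetic algorithm

Individuals are ordered tuples of six distinct descriptor names (order
matters only for crossover; ranking compares sets). Fitness is the training
F₁/₂ of the configured classifier fit and evaluated on the same training
rows — no inner validation split; the GA is an optimizer, and honesty is
restored by the outer cross-validation. Fitness evaluations are memoized on
the feature set. Degenerate evaluations (e.g. an all-zero subset, on which
the SVD-based LDA solver cannot fit) score 0, the same as any model that
never predicts the positive class.

Defaults: population 1,000, offspring 500 (= population/2, enforced),
199 iterations, mutation probability 0.2, restart period 50 keeping the top
10, diversity fraction 1/3, individual size 6. Per iteration:

1. record the best individual;
2. form offspring by crossing random pairs (uniform with replacement) from
   the top half: the child takes positions 1–3 from one parent and
   positions 4–6 from the other, duplicates replaced by uniform pool draws.
   The complementary-halves rule makes every gene position transmissible —
   under a first-three-plus-first-three rule the back half of every
   individual would be dead cargo, which measurably slows the assembly of
   complementary informative features;
3. mutate each child with probability 0.2: the child becomes a copy of the
   current best individual with two uniformly chosen positions overwritten
   by random pool features (re-drawn on collision) — a local search around
   the incumbent. The alternative semantics (randomize two positions of the
   child itself) is available as `mutation_strategy="child"` for
   sensitivity analysis;
4. children replace the bottom half unconditionally; one third of the top
   half — never the best individual — is replaced by fresh random
   individuals (strong probes survive the re-rank and reproduce next
   generation); every 50 iterations the population is regenerated from
   scratch keeping the top 10.

Elitism (the best individual is exempt from injection and kept through
restarts) guarantees the recorded best fitness is non-decreasing across all
iterations. Ranking ties break by lexicographic feature set, making runs
bit-reproducible for a fixed seed. On saturated toy problems (many subsets
tied at fitness 1.0) this deterministic tie-break means all partitions can
converge to the same lexicographically-smallest winner; that is an artifact
of saturation, not of the selection signal.

## Selection protocol

One GA per partition, on its four training folds only (per-partition GA
seeds are derived deterministically from the protocol seed via a seed
sequence). The common set collects descriptors appearing in ≥ 2 of the five
partition winners — the threshold is inferred from the reference results,
where every retained common feature recurs at least twice. A fresh
classifier restricted to the common set is fit per partition and scored on
its test fold; fold averages are unweighted arithmetic means (fold sizes
differ by at most one). An empty common set is a reported null result, not
an error.

**Importance.** Repeated runs are grouped by initial condition (same
conditions, changed split, changed initial population, …). Per group a
descriptor earns 0 (absent from all the group's common sets), ½ (present
in exactly one) or 1 (present in more than one); the importance is the sum
over groups divided by the maximum achievable sum (½ per single-run group
plus 1 per multi-run group — 7.5 for the canonical design of one initial
run plus seven five-run groups). Computing the normalizer from the group
structure lets the scheme generalize to any grouping.

**Robustness.** A fixed common set can be re-evaluated over many fresh
splits (default 100, seeds derived from one master seed), yielding the
spread of train/test F₁/₂ as a stability report.

## Classifier back-ends

scikit-learn estimators behind one interface: LDA (SVD solver, pooled
covariance, class-frequency priors — a priors switch is exposed via
hyperparameters), logistic regression (L2, C = 1), random forest (100
trees, seeded), RBF-SVM (C = 1, Platt-calibrated probabilities).
Hyperparameters beyond these conventional defaults are deliberately not
tuned, and every report embeds the spec so comparisons are reproducible.
Fingerprint counts are used raw; standardization is available as an option
but off by default. One caveat documented for LDA: the SVD solver discards
discriminant directions with exactly zero within-class variance, so a
perfect binary indicator feature with no within-class variation at all is
ignored rather than exploited — irrelevant for real count data, which
always varies, but visible on constructed toys.

The threshold probe builds artificial samples holding every model feature
at a baseline (default 0) while sweeping one feature through a range,
reports the predicted label per value, and identifies the single decision
flip if there is exactly one.

## Synthetic data generator

The generator emulates the study conditions: 248 compounds, exactly 35 NC
(~14%), 760 features (the post-filter scale), sparse non-negative integer
counts. Background features are i.i.d. zero-inflated counts independent of
the label: zero with probability 0.92, else 1 + Poisson(0.7). At this
sparsity a feature's expected support is ~20 of 248 compounds, so the
preset comfortably survives the rare-feature filter, while the matrix is
~92% zeros like real fingerprint-count tables.

Four planted features carry the signal in the shape the real final model
learned — a count threshold. Each NC compound is assigned one planted
feature (round-robin) whose count is raised to cut + Poisson(1) with
cut = 2; elsewhere planted columns are truncated strictly below the cut,
except that each C compound leaks an elevated count in each planted column
with probability 0.01. The round-robin assignment makes the planted
features *complementary*: each marks only a quarter of the NC class, so no
single descriptor suffices and a selector must assemble all four — the
structure that makes common-feature extraction meaningful. The leak bounds
attainable precision below 1, mimicking the irreducible misclassifications
of the real data.

What the generator does not emulate: correlated descriptors (real
fingerprint counts co-occur within chemical families), any relationship
between features and actual chemistry, and label noise. Passing recovery
tests therefore demonstrates that the protocol can find sparse complementary
count signals at the study's sample size and imbalance — not that it would
recover the specific published descriptors from the real compound table.

## Problem sizes used in tests

The validation suite exercises the full 199-iteration schedule (with both
restarts) on a 40-compound, 25-feature problem at population 40; GA-vs-
exhaustive-search equivalence on a 10-feature pool (210 possible
individuals, 5 seeds); and planted-feature recovery on the full 248 × 760
preset for 10 seeds at a reduced GA budget (population 200, 50 iterations),
requiring ≥ 3 of 4 planted descriptors in the common set for ≥ 8 seeds.
These sizes keep the whole suite at a few minutes while covering every
moving part at the study's data scale.

## Known limitations

- The SMARTS-count uniquification convention is validated against
  exhaustive enumeration, not against external fingerprint software, whose
  convention is undocumented; symmetric molecules may differ.
- Compounds with F/M in the excluded band and a high CI are excluded by
  F/M priority; the alternative (trusting CI) is defensible and the case is
  logged.
- GA fitness is training-set fitness by design; reported generalization
  comes only from the outer cross-validation of the common set.
- With `SVC`, probability calibration uses Platt scaling on small folds and
  can be noisy; SVM is a comparator, not the primary family.
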