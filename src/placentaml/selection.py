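"""The full feature-selection protocol: GA per CV partition, common features.

Feature selection happens inside cross-validation: the data is split first,
then one GA runs per partition on its training folds only. The features
shared between the five partition winners (multiplicity >= 2) form the
"common set"; a fresh classifier restricted to that set is then trained per
partition and scored on its test fold. A "run" is one pass of this
select-then-evaluate procedure.

Robustness of a common set is probed two ways: re-evaluating it over many
fresh CV splits, and re-running the whole selection under varied initial
conditions and scoring how consistently each descriptor reappears across the
common sets (the 0 / 1/2 / 1 partial-score importance scheme).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import modeling
from .ga import GAConfig, evolve
from .metrics import average_precision, confusion, f_beta, pr_curve, precision_recall_fpr
from .modeling import ClassifierSpec
from .validation import FoldAssignment, partitions, stratified_split

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PartitionSolution:
    """Best GA individual found on one partition's training folds."""

    partition_index: int
    best_features: tuple[str, ...]
    train_f_half: float


@dataclass(frozen=True)
class CommonFeatureSet:
    """Features shared by >= min_multiplicity partition solutions."""

    features: tuple[str, ...]
    multiplicities: Mapping[str, int]

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class SelectionResult:
    solutions: list[PartitionSolution]
    common: Optional[CommonFeatureSet]
    evaluation: Optional[dict]
    fold_seed: int
    ga_seeds: list[int]

    def to_json_dict(self) -> dict:
        return {
            "partition_solutions": [
                {
                    "partition": s.partition_index,
                    "features": list(s.best_features),
                    "train_f_half": s.train_f_half,
                }
                for s in self.solutions
            ],
            "common_features": list(self.common.features) if self.common else None,
            "multiplicities": dict(self.common.multiplicities) if self.common else None,
            "evaluation": self.evaluation,
            "seeds": {"fold_seed": self.fold_seed, "ga_seeds": self.ga_seeds},
        }


def common_features(
    solutions: Sequence[PartitionSolution | Sequence[str]],
    min_multiplicity: int = 2,
) -> CommonFeatureSet:
    """Features appearing in at least *min_multiplicity* of the solutions.

    Multiplicity counts the number of solutions *containing* the feature;
    order of solutions is irrelevant.
    """
    if len(solutions) < 2:
        raise ValueError("need at least two solutions to share features")
    sets = [
        frozenset(s.best_features) if isinstance(s, PartitionSolution) else frozenset(s)
        for s in solutions
    ]
    counts = Counter(f for s in sets for f in s)
    kept = {f: c for f, c in counts.items() if c >= min_multiplicity}
    return CommonFeatureSet(
        features=tuple(sorted(kept)), multiplicities=dict(sorted(kept.items()))
    )


def _fold_metrics(conf, scores=None, y_true=None) -> dict:
    p, r, fpr = precision_recall_fpr(conf)
    fh = f_beta(conf, 0.5) if (p is not None and r is not None) else None
    out = {
        "tp": conf.tp, "fp": conf.fp, "fn": conf.fn, "tn": conf.tn,
        "precision": p, "recall": r, "fpr": fpr, "f_half": fh,
    }
    if scores is not None and np.sum(np.asarray(y_true, dtype=object) == "NC") > 0:
        out["average_precision"] = average_precision(pr_curve(scores, y_true))
    else:
        out["average_precision"] = None
    return out


def _mean_defined(values: list[Optional[float]]) -> tuple[Optional[float], int]:
    defined = [v for v in values if v is not None]
    return (float(np.mean(defined)) if defined else None, len(defined))


def evaluate_common_set(
    common: CommonFeatureSet,
    parts: Sequence[tuple[Sequence[str], Sequence[str]]],
    descriptor_table: pd.DataFrame,
    labels: pd.Series,
    classifier_spec: ClassifierSpec,
) -> dict:
    """Fit the common set per partition and score each held-out test fold.

    Per-fold undefined metrics (zero-denominator precision or recall)
    propagate as null; averages are unweighted arithmetic means over the
    defined folds, with the count of defined folds reported.
    """
    if len(common) == 0:
        raise ValueError("common feature set is empty")
    cols = list(common.features)
    per_fold = []
    for k, (train_ids, test_ids) in enumerate(parts, start=1):
        Xtr = descriptor_table.loc[list(train_ids), cols]
        Xte = descriptor_table.loc[list(test_ids), cols]
        ytr = labels.loc[list(train_ids)].to_numpy(dtype=object)
        yte = labels.loc[list(test_ids)].to_numpy(dtype=object)
        model = modeling.fit(classifier_spec, Xtr, ytr)
        pred = modeling.predict(model, Xte)
        conf = confusion(yte, pred["predicted_label"].to_numpy())
        fold = {"partition": k}
        fold.update(_fold_metrics(conf, pred["probability_NC"].to_numpy(), yte))
        fold["train_f_half"] = model.training_summary["train_f_half"]
        per_fold.append(fold)

    averaged = {}
    for key in ("f_half", "precision", "recall", "average_precision", "train_f_half"):
        mean, n_def = _mean_defined([f[key] for f in per_fold])
        averaged[key] = mean
        averaged[f"n_defined_{key}"] = n_def
    return {"per_fold": per_fold, "averaged": averaged, "features": cols}


def run_protocol(
    labels: pd.Series,
    descriptor_table: pd.DataFrame,
    classifier_spec: ClassifierSpec,
    ga_config: GAConfig,
    fold_seed: int = 0,
    n_folds: int = 5,
    min_multiplicity: int = 2,
    assignment: Optional[FoldAssignment] = None,
) -> SelectionResult:
    """One full "run": split, GA per partition, common set, evaluation.

    The GA sees only training-fold rows; test folds enter only in the final
    evaluation of the common set. An empty common set yields a null result
    (``common=None``), not an exception. Passing a precomputed *assignment*
    (e.g. a published split) bypasses the random split.
    """
    missing = [cid for cid in labels.index if cid not in descriptor_table.index]
    if missing:
        raise ValueError(f"descriptor table lacks compounds: {missing[:5]}...")
    if assignment is None:
        assignment = stratified_split(labels, n_folds=n_folds, seed=fold_seed)
    parts = partitions(assignment)
    pool = [str(c) for c in descriptor_table.columns]
    ga_seeds = [
        int(s) for s in
        np.random.SeedSequence(ga_config.seed).generate_state(n_folds) % (2**31)
    ]
    solutions = []
    for k, (train_ids, _) in enumerate(parts, start=1):
        Xtr = descriptor_table.loc[list(train_ids)]
        ytr = labels.loc[list(train_ids)].to_numpy(dtype=object)
        cfg = GAConfig(
            population_size=ga_config.population_size,
            n_iterations=ga_config.n_iterations,
            mutation_prob=ga_config.mutation_prob,
            restart_period=ga_config.restart_period,
            restart_elite=ga_config.restart_elite,
            diversity_fraction=ga_config.diversity_fraction,
            individual_size=ga_config.individual_size,
            mutation_strategy=ga_config.mutation_strategy,
            seed=ga_seeds[k - 1],
        )
        trace = evolve(Xtr, ytr, pool, classifier_spec, cfg)
        solutions.append(
            PartitionSolution(
                partition_index=k,
                best_features=trace.best.features,
                train_f_half=trace.best.fitness,
            )
        )
        logger.info(
            "partition %d: best train F_1/2 = %.3f with %s",
            k, trace.best.fitness, trace.best.features,
        )
    common = common_features(solutions, min_multiplicity)
    if len(common) == 0:
        logger.warning("no features shared between partition solutions (null result)")
        return SelectionResult(solutions, None, None, fold_seed, ga_seeds)
    evaluation = evaluate_common_set(
        common, parts, descriptor_table, labels, classifier_spec
    )
    return SelectionResult(solutions, common, evaluation, fold_seed, ga_seeds)


@dataclass
class RunLedger:
    """Common sets from repeated runs, grouped by initial condition.

    ``groups`` maps a group id (e.g. "initial run", "change in CV split 1") to
    the list of common feature sets its runs produced. The presence mark of a
    feature in a group is "absent", "once" (exactly one run) or "multiple".
    """

    groups: dict[str, list[frozenset]] = field(default_factory=dict)

    def add(self, group: str, common_set: Sequence[str]) -> None:
        self.groups.setdefault(group, []).append(frozenset(common_set))

    def features(self) -> list[str]:
        return sorted({f for runs in self.groups.values() for s in runs for f in s})

    def mark(self, feature: str, group: str) -> str:
        n = sum(1 for s in self.groups[group] if feature in s)
        return "absent" if n == 0 else ("once" if n == 1 else "multiple")

    def marks_frame(self) -> pd.DataFrame:
        feats = self.features()
        return pd.DataFrame(
            {g: [self.mark(f, g) for f in feats] for g in self.groups}, index=feats
        )


_PARTIAL = {"absent": 0.0, "once": 0.5, "multiple": 1.0}


def feature_importance(
    ledger: RunLedger, features: Optional[Sequence[str]] = None
) -> pd.Series:
    """Normalized consistency score per feature across run groups.

    Each group contributes a partial score of 0 (feature absent from its
    runs), 1/2 (present in exactly one run) or 1 (present in more than one).
    The normalizer is the maximum achievable sum: 1/2 for a single-run group
    plus 1 per multi-run group (7.5 for the canonical eight-group design of
    one initial run plus seven five-run variation groups). *features*
    restricts or extends the scored names (a feature absent everywhere
    scores 0).
    """
    if not ledger.groups:
        raise ValueError("empty run ledger")
    normalizer = sum(1.0 if len(runs) > 1 else 0.5 for runs in ledger.groups.values())
    feats = list(features) if features is not None else ledger.features()
    scores = {
        f: sum(_PARTIAL[ledger.mark(f, g)] for g in ledger.groups) / normalizer
        for f in feats
    }
    return pd.Series(scores, name="importance").sort_values(ascending=False)


def robustness_over_splits(
    common: CommonFeatureSet,
    labels: pd.Series,
    descriptor_table: pd.DataFrame,
    classifier_spec: ClassifierSpec,
    n_splits: int = 100,
    seed: int = 0,
    n_folds: int = 5,
) -> pd.DataFrame:
    """Re-evaluate a fixed common set over many fresh CV splits.

    Returns one row per split with the averaged train and test F_1/2; the
    summary mean/std live in ``attrs["summary"]``.
    """
    split_seeds = np.random.SeedSequence(seed).generate_state(n_splits) % (2**31)
    rows = []
    for i, s in enumerate(split_seeds):
        assignment = stratified_split(labels, n_folds=n_folds, seed=int(s))
        report = evaluate_common_set(
            common, partitions(assignment), descriptor_table, labels, classifier_spec
        )
        rows.append(
            {
                "split": i,
                "seed": int(s),
                "train_f_half": report["averaged"]["train_f_half"],
                "test_f_half": report["averaged"]["f_half"],
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["summary"] = {
        "train_mean": float(df["train_f_half"].mean()),
        "train_std": float(df["train_f_half"].std(ddof=1)) if len(df) > 1 else 0.0,
        "test_mean": float(df["test_f_half"].dropna().mean()),
        "test_std": float(df["test_f_half"].dropna().std(ddof=1)) if len(df) > 1 else 0.0,
    }
    return df


class CommonFeatureSelectorCV(BaseEstimator, TransformerMixin):
    """scikit-learn transformer running the whole selection protocol.

    ``fit(X, y)`` performs the stratified split, one GA per partition, and
    common-feature extraction; ``transform`` projects a table onto the common
    set. Fitted attributes: ``partition_solutions_``, ``common_features_``,
    ``multiplicities_``, ``report_``.
    """

    def __init__(
        self,
        classifier_spec: Optional[ClassifierSpec] = None,
        ga_config: Optional[GAConfig] = None,
        n_folds: int = 5,
        fold_seed: int = 0,
        min_multiplicity: int = 2,
    ):
        self.classifier_spec = classifier_spec
        self.ga_config = ga_config
        self.n_folds = n_folds
        self.fold_seed = fold_seed
        self.min_multiplicity = min_multiplicity

    def fit(self, X: pd.DataFrame, y) -> "CommonFeatureSelectorCV":
        X = pd.DataFrame(X)
        labels = pd.Series(np.asarray(y, dtype=object), index=X.index)
        result = run_protocol(
            labels,
            X,
            self.classifier_spec or ClassifierSpec(),
            self.ga_config or GAConfig(),
            fold_seed=self.fold_seed,
            n_folds=self.n_folds,
            min_multiplicity=self.min_multiplicity,
        )
        self.result_ = result
        self.partition_solutions_ = result.solutions
        self.common_features_ = list(result.common.features) if result.common else []
        self.multiplicities_ = dict(result.common.multiplicities) if result.common else {}
        self.report_ = result.evaluation
        return self

    def transform(self, X) -> pd.DataFrame:
        if not self.common_features_:
            raise ValueError("no common features were found (null result)")
        return pd.DataFrame(X).loc[:, self.common_features_]


__all__ = [
    "PartitionSolution",
    "CommonFeatureSet",
    "SelectionResult",
    "RunLedger",
    "common_features",
    "evaluate_common_set",
    "run_protocol",
    "feature_importance",
    "robustness_over_splits",
    "CommonFeatureSelectorCV",
]
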