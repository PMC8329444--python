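"""Selection protocol: common features, evaluation, importance, robustness."""

import json
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from placentaml import synthetic
from placentaml.ga import GAConfig
from placentaml.modeling import ClassifierSpec
from placentaml.selection import (
    CommonFeatureSelectorCV,
    CommonFeatureSet,
    RunLedger,
    common_features,
    evaluate_common_set,
    feature_importance,
    robustness_over_splits,
    run_protocol,
)
from placentaml.validation import partitions, stratified_split

SMALL_GA = GAConfig(population_size=40, n_iterations=15, restart_period=8,
                    restart_elite=4, seed=0)
LDA = ClassifierSpec()


def test_common_features_identical_solutions():
    sets = [("a", "b", "c", "d", "e", "f")] * 5
    common = common_features(sets)
    assert set(common.features) == set("abcdef")
    assert all(m == 5 for m in common.multiplicities.values())


def test_common_features_disjoint_solutions_empty():
    sets = [tuple(f"p{k}_{j}" for j in range(6)) for k in range(5)]
    common = common_features(sets)
    assert len(common) == 0


def test_common_features_matches_brute_force_count(rng):
    pool = [f"f{j}" for j in range(30)]
    sets = [tuple(rng.choice(pool, 6, replace=False)) for _ in range(5)]
    common = common_features(sets)
    counts = Counter(f for s in sets for f in set(s))
    expected = {f: c for f, c in counts.items() if c >= 2}
    assert dict(common.multiplicities) == dict(sorted(expected.items()))


def test_common_features_order_invariant(rng):
    pool = [f"f{j}" for j in range(15)]
    sets = [tuple(rng.choice(pool, 6, replace=False)) for _ in range(5)]
    a = common_features(sets)
    b = common_features(sets[::-1])
    assert a == b


def test_common_features_needs_two_solutions():
    with pytest.raises(ValueError):
        common_features([("a", "b")])


def _protocol_data(seed=0, **kw):
    spec = synthetic.SyntheticSpec(
        n_compounds=80, n_features=30, prevalence_nc=0.25, n_planted=2,
        leak_prob=0.0, seed=seed, **kw,
    )
    return synthetic.generate(spec)


def test_evaluate_common_set_separable_data_scores_one():
    table, labels, truth = _protocol_data()
    assignment = stratified_split(labels, seed=3)
    common = CommonFeatureSet(
        features=tuple(truth["planted_features"]),
        multiplicities={f: 5 for f in truth["planted_features"]},
    )
    report = evaluate_common_set(common, partitions(assignment), table, labels, LDA)
    assert report["averaged"]["f_half"] == pytest.approx(1.0)
    assert report["averaged"]["n_defined_f_half"] == 5


def test_evaluate_common_set_averages_match_manual_mean():
    table, labels, _ = _protocol_data(seed=5, background_nonzero_prob=0.3)
    assignment = stratified_split(labels, seed=1)
    common = common_features(
        [tuple(table.columns[:6])] * 5  # arbitrary fixed six features
    )
    report = evaluate_common_set(common, partitions(assignment), table, labels, LDA)
    for key in ("f_half", "precision", "recall"):
        vals = [f[key] for f in report["per_fold"] if f[key] is not None]
        expect = float(np.mean(vals)) if vals else None
        assert report["averaged"][key] == (
            pytest.approx(expect) if expect is not None else None
        )


def test_evaluate_common_set_undefined_folds_propagate():
    # all-zero descriptors: every fold predicts C only -> precision undefined
    ids = [f"m{i}" for i in range(40)]
    table = pd.DataFrame(0.0, index=ids, columns=["a", "b"])
    labels = pd.Series(["NC"] * 10 + ["C"] * 30, index=ids, dtype=object)
    assignment = stratified_split(labels, seed=0)
    common = CommonFeatureSet(features=("a", "b"), multiplicities={"a": 5, "b": 5})
    report = evaluate_common_set(
        common, partitions(assignment), table, labels, ClassifierSpec(family="LR")
    )
    assert all(f["f_half"] is None for f in report["per_fold"])
    assert report["averaged"]["f_half"] is None
    assert report["averaged"]["n_defined_f_half"] == 0
    assert all(f["recall"] == 0.0 for f in report["per_fold"])


def test_run_protocol_end_to_end_recovers_signal_and_is_deterministic():
    table, labels, truth = _protocol_data(seed=11)
    res1 = run_protocol(labels, table, LDA, SMALL_GA, fold_seed=2)
    res2 = run_protocol(labels, table, LDA, SMALL_GA, fold_seed=2)
    assert res1.to_json_dict() == res2.to_json_dict()
    assert len(res1.solutions) == 5
    assert all(len(s.best_features) == 6 for s in res1.solutions)
    assert res1.common is not None
    assert set(truth["planted_features"]) <= set(res1.common.features)
    assert json.dumps(res1.to_json_dict())  # serializable
    # the evaluation carries per-fold and averaged metrics
    assert len(res1.evaluation["per_fold"]) == 5
    assert res1.evaluation["averaged"]["f_half"] is not None


def test_run_protocol_ignores_test_fold_labels():
    """Scrambling test-fold labels must not change the selected features."""
    table, labels, _ = _protocol_data(seed=21)
    assignment = stratified_split(labels, seed=4)
    res = run_protocol(labels, table, LDA, SMALL_GA, assignment=assignment)

    # each partition's GA sees only its 4 training folds, so scrambling that
    # partition's test-fold labels must leave its solution unchanged
    rng = np.random.default_rng(0)
    for k, (train_ids, test_ids) in enumerate(partitions(assignment), start=1):
        sc = labels.copy()
        vals = sc.loc[test_ids].to_numpy(dtype=object)
        rng.shuffle(vals)
        sc.loc[test_ids] = vals
        res_k = run_protocol(sc, table, LDA, SMALL_GA, assignment=assignment)
        assert (
            res_k.solutions[k - 1].best_features == res.solutions[k - 1].best_features
        )


def test_run_protocol_null_result_when_nothing_shared(rng):
    # pure noise, tiny GA: a null common set must be reported, not raised
    ids = [f"m{i}" for i in range(50)]
    table = pd.DataFrame(
        rng.poisson(1.0, size=(50, 40)).astype(float),
        index=ids, columns=[f"n{j}" for j in range(40)],
    )
    labels = pd.Series(["NC"] * 10 + ["C"] * 40, index=ids, dtype=object)
    cfg = GAConfig(population_size=10, n_iterations=1, restart_elite=2, seed=0)
    res = run_protocol(labels, table, LDA, cfg, fold_seed=0)
    if res.common is None:  # noise may still share features by chance
        assert res.evaluation is None
    else:
        assert res.evaluation is not None


def test_run_protocol_requires_descriptor_coverage():
    table, labels, _ = _protocol_data()
    with pytest.raises(ValueError, match="lacks"):
        run_protocol(labels, table.iloc[:-5], LDA, SMALL_GA)


# ---------------------------------------------------------------------------
# importance scoring

def _ledger_from_marks(marks: dict, group_sizes: dict) -> RunLedger:
    ledger = RunLedger()
    for g, n_runs in group_sizes.items():
        ledger.groups[g] = [frozenset() for _ in range(n_runs)]
    for (feature, g), mark in marks.items():
        runs = ledger.groups[g]
        n_present = {"absent": 0, "once": 1, "multiple": 2}[mark]
        for i in range(n_present):
            runs[i] = runs[i] | {feature}
    return ledger


def test_feature_importance_partial_scores_and_normalizer():
    groups = {"initial": 1, "g2": 5, "g3": 5, "g4": 5}
    marks = {
        ("f1", "initial"): "once", ("f1", "g2"): "multiple",
        ("f1", "g3"): "multiple", ("f1", "g4"): "once",
        ("f2", "g2"): "once",
    }
    ledger = _ledger_from_marks(
        {k: v for k, v in marks.items()}, groups
    )
    imp = feature_importance(ledger)
    # normalizer = 0.5 + 1 + 1 + 1 = 3.5
    assert imp["f1"] == pytest.approx((0.5 + 1 + 1 + 0.5) / 3.5)
    assert imp["f2"] == pytest.approx(0.5 / 3.5)


def test_feature_importance_absent_everywhere_is_zero():
    ledger = RunLedger()
    ledger.add("g", ["a", "b"])
    ledger.add("g", ["a"])
    imp = feature_importance(ledger, features=["a", "b", "zz"])
    assert imp["zz"] == 0.0
    assert imp["a"] == pytest.approx(1.0)  # multiple in the only group
    assert imp["b"] == pytest.approx(0.5)


def test_feature_importance_empty_ledger_raises():
    with pytest.raises(ValueError):
        feature_importance(RunLedger())


def test_run_ledger_marks_frame():
    ledger = RunLedger()
    ledger.add("g1", ["a", "b"])
    ledger.add("g1", ["a"])
    ledger.add("g2", ["b"])
    frame = ledger.marks_frame()
    assert frame.loc["a", "g1"] == "multiple"
    assert frame.loc["b", "g1"] == "once"
    assert frame.loc["a", "g2"] == "absent"


# ---------------------------------------------------------------------------
# robustness over splits

def test_robustness_single_split_reduces_to_evaluate():
    table, labels, truth = _protocol_data(seed=9)
    common = CommonFeatureSet(
        features=tuple(truth["planted_features"]),
        multiplicities={f: 5 for f in truth["planted_features"]},
    )
    df = robustness_over_splits(common, labels, table, LDA, n_splits=1, seed=5)
    split_seed = int(df["seed"].iloc[0])
    assignment = stratified_split(labels, seed=split_seed)
    direct = evaluate_common_set(common, partitions(assignment), table, labels, LDA)
    assert df["test_f_half"].iloc[0] == pytest.approx(direct["averaged"]["f_half"])


def test_robustness_separable_data_all_splits_perfect():
    # one planted feature, zero leak: a 1-D threshold separates, so LDA is
    # perfect on every split
    spec = synthetic.SyntheticSpec(
        n_compounds=80, n_features=30, prevalence_nc=0.25, n_planted=1,
        leak_prob=0.0, seed=13,
    )
    table, labels, truth = synthetic.generate(spec)
    common = CommonFeatureSet(
        features=tuple(truth["planted_features"]),
        multiplicities={f: 5 for f in truth["planted_features"]},
    )
    df = robustness_over_splits(common, labels, table, LDA, n_splits=5, seed=2)
    assert (df["test_f_half"] == 1.0).all()
    summary = df.attrs["summary"]
    assert summary["test_mean"] == pytest.approx(df["test_f_half"].mean())
    assert summary["train_mean"] == pytest.approx(df["train_f_half"].mean())


def test_common_selector_cv_estimator():
    table, labels, truth = _protocol_data(seed=17)
    sel = CommonFeatureSelectorCV(ga_config=SMALL_GA, fold_seed=1)
    out = sel.fit_transform(table, labels)
    assert list(out.columns) == sel.common_features_
    assert set(truth["planted_features"]) <= set(sel.common_features_)
    assert sel.report_["averaged"]["f_half"] is not None
    assert sel.get_params()["fold_seed"] == 1
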