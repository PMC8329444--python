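"""Stratified 5-fold cross-validation bookkeeping.

With 248 compounds a single train/test split would report on ~50 samples, so
the protocol evaluates with stratified k-fold cross-validation instead: each
fold approximately preserves the ~86/14 C/NC class balance, and every sample
is used four times for training and once for testing. Partition k uses fold k
as the test set and the remaining folds as training data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from sklearn.model_selection import StratifiedKFold


class StratificationError(ValueError):
    """A class has fewer members than the requested number of folds."""


@dataclass(frozen=True)
class FoldAssignment:
    """Maps each compound_id to a fold index in 1..n_folds."""

    n_folds: int
    fold_of: dict[str, int]
    seed: int

    def fold_ids(self, k: int) -> list[str]:
        return [cid for cid, f in self.fold_of.items() if f == k]


def stratified_split(labels: pd.Series, n_folds: int = 5, seed: int = 0) -> FoldAssignment:
    """Randomly assign compounds to folds, preserving class proportions.

    ``labels`` is a Series of class labels indexed by compound_id. Per-fold
    class counts deviate from perfect stratification by at most one sample.
    Deterministic for a fixed seed.
    """
    counts = labels.value_counts()
    small = counts[counts < n_folds]
    if len(small):
        raise StratificationError(
            f"classes smaller than n_folds={n_folds}: {small.to_dict()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    ids = labels.index.to_numpy()
    fold_of: dict[str, int] = {}
    for k, (_, test_idx) in enumerate(skf.split(ids, labels.to_numpy()), start=1):
        for i in test_idx:
            fold_of[str(ids[i])] = k
    return FoldAssignment(n_folds=n_folds, fold_of=fold_of, seed=seed)


def partitions(assignment: FoldAssignment) -> list[tuple[list[str], list[str]]]:
    """The k (train_ids, test_ids) pairs: partition k tests on fold k."""
    out = []
    for k in range(1, assignment.n_folds + 1):
        test = assignment.fold_ids(k)
        train = [cid for cid, f in assignment.fold_of.items() if f != k]
        out.append((train, test))
    return out


def save_assignment(assignment: FoldAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {"compound_id": list(assignment.fold_of), "fold": list(assignment.fold_of.values())}
    ).to_csv(path, index=False)


def load_assignment(path: str | Path, seed: int = -1) -> FoldAssignment:
    """Load a published split verbatim (seed unknown unless supplied)."""
    df = pd.read_csv(path, dtype={"compound_id": str, "fold": int})
    fold_of = dict(zip(df["compound_id"], df["fold"]))
    return FoldAssignment(n_folds=int(df["fold"].max()), fold_of=fold_of, seed=seed)


__all__ = [
    "FoldAssignment",
    "StratificationError",
    "stratified_split",
    "partitions",
    "save_assignment",
    "load_assignment",
]
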