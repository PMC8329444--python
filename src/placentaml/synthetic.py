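"""Synthetic fingerprint-count datasets with planted informative features.

The generator emulates the shape of the real problem: a few hundred
compounds, ~86/14 C/NC class imbalance, and a sparse non-negative integer
descriptor matrix of fingerprint counts. Background features are label-free
draws from a zero-inflated count law (zero with high probability, else
1 + Poisson). A small set of *planted* features carries the class signal in
the form the final classifier learns on real data — a count threshold: each
NC compound is assigned one planted feature (round-robin) whose count is
raised to ``planted_cut + Poisson(planted_rate)``, while everywhere else the
planted columns stay strictly below the cut, except for a small leak
probability that plants elevated counts in C compounds (class overlap).

Because each planted feature marks only its share of the NC class, no single
feature suffices: a selector must assemble all of them, mirroring the
four-descriptor structure of the real final model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import NEGATIVE_LABEL, POSITIVE_LABEL


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset draw."""

    n_compounds: int = 248
    n_features: int = 760
    prevalence_nc: float = 35 / 248
    n_planted: int = 4
    planted_cut: int = 2
    planted_rate: float = 1.0
    leak_prob: float = 0.01
    background_nonzero_prob: float = 0.08
    background_rate: float = 0.7
    exact_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.prevalence_nc < 1):
            raise SpecError(f"prevalence_nc must be in (0, 1), got {self.prevalence_nc}")
        if self.n_planted > self.n_features:
            raise SpecError(
                f"cannot plant {self.n_planted} features among {self.n_features}"
            )
        if self.planted_cut < 1:
            raise SpecError("planted_cut must be >= 1")


def study_shape_preset(seed: int = 0) -> SyntheticSpec:
    """The study-shaped default: 248 compounds, 35 NC, 760 features, 4 planted."""
    return SyntheticSpec(seed=seed)


def _background(rng: np.random.Generator, shape, spec: SyntheticSpec) -> np.ndarray:
    nonzero = rng.random(shape) < spec.background_nonzero_prob
    counts = 1 + rng.poisson(spec.background_rate, size=shape)
    return np.where(nonzero, counts, 0)


def generate(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Draw one dataset: (descriptor table, C/NC labels, ground truth).

    Reproducible bit-for-bit under a fixed seed. The ground-truth record
    names the planted features and states the Bayes rule ("NC iff any planted
    count >= planted_cut", up to the configured leak).
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_compounds, spec.n_features

    if spec.exact_counts:
        n_nc = int(round(spec.prevalence_nc * n))
        is_nc = np.zeros(n, dtype=bool)
        is_nc[rng.choice(n, size=n_nc, replace=False)] = True
    else:
        is_nc = rng.random(n) < spec.prevalence_nc

    X = _background(rng, (n, m), spec)
    feature_names = [f"FPC{j + 1:04d}" for j in range(m)]
    planted_idx = np.sort(rng.choice(m, size=spec.n_planted, replace=False))
    planted_names = [feature_names[j] for j in planted_idx]

    if spec.n_planted:
        # planted columns: background truncated strictly below the cut ...
        sub = X[:, planted_idx]
        X[:, planted_idx] = np.minimum(sub, spec.planted_cut - 1)
        # ... each NC compound raised in its round-robin planted feature ...
        nc_rows = np.flatnonzero(is_nc)
        rng.shuffle(nc_rows)
        for i, row in enumerate(nc_rows):
            j = planted_idx[i % spec.n_planted]
            X[row, j] = spec.planted_cut + rng.poisson(spec.planted_rate)
        # ... and a small leak of elevated counts into the C class
        c_rows = np.flatnonzero(~is_nc)
        for j in planted_idx:
            leak = c_rows[rng.random(len(c_rows)) < spec.leak_prob]
            X[leak, j] = spec.planted_cut + rng.poisson(spec.planted_rate, size=len(leak))

    ids = [f"SYN{i + 1:05d}" for i in range(n)]
    table = pd.DataFrame(X, index=pd.Index(ids, name="compound_id"), columns=feature_names)
    labels = pd.Series(
        np.where(is_nc, POSITIVE_LABEL, NEGATIVE_LABEL).astype(object),
        index=table.index,
        name="assigned_label",
    )
    ground_truth = {
        "planted_features": planted_names,
        "bayes_rule": f"NC iff any planted count >= {spec.planted_cut}",
        "planted_cut": spec.planted_cut,
        "leak_prob": spec.leak_prob,
        "spec": asdict(spec),
    }
    return table, labels, ground_truth


def save_ground_truth(ground_truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ground_truth, indent=2))


__all__ = ["SyntheticSpec", "SpecError", "study_shape_preset", "generate", "save_ground_truth"]
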