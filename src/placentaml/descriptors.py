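"""Descriptor tables, the rare-feature filter, and SMARTS fingerprint counts.

The full descriptor generation (physicochemical properties, EState,
Klekota-Roth and substructure fingerprint counts, ~5.4k features) is the job
of external tools such as OpenBabel and PaDEL; this module ingests their
output as an opaque numeric CSV. What it computes natively are the four
Klekota-Roth fingerprint *counts* (KRFPC) of the final classifier, by SMARTS
substructure matching with RDKit.

Counting convention: two matches of a pattern are distinct iff their sets of
matched heavy atoms differ; automorphic re-orderings of the same atoms are
deduplicated. Patterns are written Kekulé-style (explicit single/double ring
bonds), so molecules are kekulized before matching — otherwise aromatic rings
would never match.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.base import BaseEstimator, TransformerMixin

from .labeling import FormatError

logger = logging.getLogger(__name__)


class StructureError(ValueError):
    """A SMILES or SMARTS string could not be parsed."""


@dataclass(frozen=True)
class SmartsDescriptor:
    """A named fingerprint-count descriptor backed by a SMARTS pattern."""

    name: str
    smarts: str

    def __post_init__(self) -> None:
        if Chem.MolFromSmarts(self.smarts) is None:
            raise StructureError(f"{self.name}: invalid SMARTS {self.smarts!r}")

    @property
    def pattern(self) -> Chem.Mol:
        return Chem.MolFromSmarts(self.smarts)


#: The four Klekota-Roth count descriptors of the final model, in model order.
FINAL_MODEL_DESCRIPTORS = (
    SmartsDescriptor("KRFPC435", "[#6]-[#7](-[!#1])-[#6]-[#6]-[!#1]"),
    SmartsDescriptor("KRFPC566", "[!#1]-[#6]-[#6]-1=[#6]-[#6]=[#6]-[#6]=[#6]-1"),
    SmartsDescriptor("KRFPC3948", "[#6]-[#7]-[#6]-[#6]-[#8]"),
    SmartsDescriptor("KRFPC4830", "[#8]-[#6]-[#6]-[#8]-[#6]=[#8]"),
)


def load_descriptor_table(path: str | Path) -> pd.DataFrame:
    """Read a descriptor CSV (first column compound_id, rest numeric).

    Returns a DataFrame indexed by compound_id with one numeric column per
    feature; duplicate compound ids or feature names are format errors, and
    negative fingerprint counts are tolerated but logged.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        header_row = next(csv.reader(fh), None)
    if not header_row:
        raise FormatError(f"{path}: empty header")
    names = header_row[1:]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"{path}: duplicated feature columns {dupes}")
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"{path}: duplicated compound ids {dupes}")
    if len(df) and df.isna().any().any():
        raise FormatError(f"{path}: missing cells in descriptor table")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric descriptor cell: {exc}") from exc
    if len(df) and (values < 0).any():
        logger.warning("%s: negative descriptor values present", path)
    return df.astype(float)


def feature_support(table: pd.DataFrame) -> pd.Series:
    """Per-feature number of compounds with a strictly positive value."""
    return (table > 0).sum(axis=0)


def filter_rare_features(
    table: pd.DataFrame, min_matches: int = 3
) -> tuple[pd.DataFrame, list[str]]:
    """Drop features matched by fewer than *min_matches* compounds.

    A feature "matches" a compound when its value there is strictly positive.
    Returns the filtered table (rows untouched) and the dropped names.
    """
    if min_matches < 1:
        raise ValueError(f"min_matches must be >= 1, got {min_matches}")
    support = feature_support(table)
    keep = support[support >= min_matches].index
    dropped = [c for c in table.columns if c not in set(keep)]
    if dropped:
        logger.info(
            "rare-feature filter: %d -> %d features (dropped %d with support < %d)",
            table.shape[1], len(keep), len(dropped), min_matches,
        )
    return table.loc[:, keep], dropped


class RareFeatureFilter(BaseEstimator, TransformerMixin):
    """Transformer view of the rare-feature filter (support >= min_matches).

    Fit learns which features survive on the fitted table; transform projects
    any table onto those features. The filter is label-free, so fitting it
    before a cross-validation split leaks nothing.
    """

    def __init__(self, min_matches: int = 3):
        self.min_matches = min_matches

    def fit(self, X: pd.DataFrame, y=None) -> "RareFeatureFilter":
        kept, dropped = filter_rare_features(X, self.min_matches)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.kept_features_ = list(kept.columns)
        self.dropped_features_ = dropped
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.kept_features_ if c not in X.columns]
        if missing:
            raise FormatError(f"table lacks fitted features: {missing[:5]}...")
        return X.loc[:, self.kept_features_]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.kept_features_, dtype=object)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparsable SMILES: {smiles!r}")
    return mol


def count_smarts_matches(smiles: str, descriptor: SmartsDescriptor) -> int:
    """Number of atom-set-distinct embeddings of the pattern in the molecule."""
    mol = _mol_from_smiles(smiles)
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    matches = kek.GetSubstructMatches(descriptor.pattern, uniquify=False, maxMatches=100000)
    return len({frozenset(m) for m in matches})


def featurize_final_model(smiles_list: Sequence[str]) -> pd.DataFrame:
    """Count the four final-model KRFPC descriptors for each SMILES.

    Returns an n x 4 table with columns in the fixed model order. Any
    unparsable SMILES aborts with the offending index.
    """
    rows = []
    for i, smi in enumerate(smiles_list):
        try:
            rows.append(
                [count_smarts_matches(smi, d) for d in FINAL_MODEL_DESCRIPTORS]
            )
        except StructureError as exc:
            raise StructureError(f"SMILES at index {i}: {exc}") from exc
    return pd.DataFrame(
        rows,
        columns=[d.name for d in FINAL_MODEL_DESCRIPTORS],
        index=pd.RangeIndex(len(rows)),
        dtype=int if rows else float,
    )


class SmartsCountFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer from SMILES sequences to SMARTS-count descriptor tables."""

    def __init__(self, descriptors: Iterable[SmartsDescriptor] = FINAL_MODEL_DESCRIPTORS):
        self.descriptors = descriptors

    def fit(self, X=None, y=None) -> "SmartsCountFeaturizer":
        self.descriptors_ = tuple(self.descriptors)
        return self

    def transform(self, X: Sequence[str]) -> pd.DataFrame:
        if not hasattr(self, "descriptors_"):
            self.fit()
        rows = [
            [count_smarts_matches(smi, d) for d in self.descriptors_] for smi in X
        ]
        return pd.DataFrame(rows, columns=[d.name for d in self.descriptors_])

    def get_feature_names_out(self, input_features=None):
        return np.asarray([d.name for d in tuple(self.descriptors)], dtype=object)


__all__ = [
    "SmartsDescriptor",
    "StructureError",
    "FINAL_MODEL_DESCRIPTORS",
    "load_descriptor_table",
    "feature_support",
    "filter_rare_features",
    "RareFeatureFilter",
    "count_smarts_matches",
    "featurize_final_model",
    "SmartsCountFeaturizer",
]
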