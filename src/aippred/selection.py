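"""Random-forest feature-importance estimation and cutoff-based feature sets.

The selection protocol scores every feature with a cross-validated
random-forest importance (FIS): within each cross-validation round a forest
is grown on the training fold with the per-node split-candidate count
(``mtry``) varied across the trees, and the Gini-impurity importances are
averaged over all trees of all rounds and renormalized to sum to one.
Candidate feature sets are then the features at or above each cutoff of a
fixed sweep; with the default sweep (floor 0.0005, cutoffs 0.0005..0.0039 in
steps of 0.0001) this yields 35 nested sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .exceptions import ParameterError
from .features import FeatureMatrix


@dataclass
class FISTable:
    """Per-feature importance scores; non-negative, summing to one."""

    feature_names: list[str]
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.feature_names) != self.scores.shape[0]:
            raise ParameterError("feature names and scores length mismatch")
        if np.any(self.scores < 0):
            raise ParameterError("FIS scores must be non-negative")
        total = self.scores.sum()
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ParameterError(f"FIS scores must sum to 1 (got {total})")

    def ranked(self) -> pd.DataFrame:
        """Features sorted by descending score (name ascending on ties)."""
        df = pd.DataFrame({"feature": self.feature_names, "fis": self.scores})
        return df.sort_values(
            ["fis", "feature"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)

    def write_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            for _, row in self.ranked().iterrows():
                fh.write(f"{row['feature']}\t{float(row['fis'])!r}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FISTable":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["feature", "fis"])
        return cls(list(df["feature"]), df["fis"].to_numpy(float))


@dataclass
class FeatureSet:
    """Features with FIS >= cutoff, in descending-importance order."""

    cutoff: float
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.feature_names:
            raise ParameterError(f"feature set at cutoff {self.cutoff} is empty")

    def __len__(self) -> int:
        return len(self.feature_names)


def _mtry_tree_allocation(n_trees: int, mtry_low: int, mtry_high: int,
                          n_features: int) -> list[tuple[int, int]]:
    # Partition the forest into sub-forests of (near-)equal size, one per
    # mtry value; the remainder goes to the smallest mtry values. mtry is
    # capped at the number of available features.
    mtry_values = [min(m, n_features) for m in range(mtry_low, mtry_high + 1)]
    mtry_values = sorted(set(mtry_values))
    base, rem = divmod(n_trees, len(mtry_values))
    alloc = []
    for j, m in enumerate(mtry_values):
        nt = base + (1 if j < rem else 0)
        if nt > 0:
            alloc.append((m, nt))
    if not alloc:
        raise ParameterError("n_trees too small for the mtry range")
    return alloc


def estimate_fis(
    matrix: FeatureMatrix,
    labels,
    folds: int = 5,
    n_trees: int = 10_000,
    mtry_low: int = 1,
    mtry_high: int = 50,
    seed: int = 0,
    repeats: int = 1,
) -> FISTable:
    """Cross-validated random-forest feature importance scores.

    For each of ``folds`` stratified CV rounds (optionally repeated with
    fresh partitions), a forest of ``n_trees`` trees is grown on the
    training fold, the per-node candidate count drawn per sub-forest
    uniformly over ``[mtry_low, mtry_high]``; impurity importances are
    averaged over all trees of all rounds (tree-count weighted) and
    renormalized to sum to one. Deterministic given ``seed``.
    """
    labels = np.asarray(labels, dtype=int)
    n, p = matrix.shape
    if labels.shape[0] != n:
        raise ParameterError("labels length does not match matrix rows")
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ParameterError("labels are constant; FIS requires both classes")
    if counts.min() < folds or n < folds:
        raise ParameterError("fewer class members than folds")
    if mtry_low < 1 or mtry_high < mtry_low:
        raise ParameterError("invalid mtry range")

    rng = np.random.default_rng(seed)
    alloc = _mtry_tree_allocation(n_trees, mtry_low, mtry_high, p)
    total_importance = np.zeros(p)
    total_trees = 0
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(seed + r) % (2**31))
        for train_idx, _ in skf.split(matrix.values, labels):
            fold_importance = np.zeros(p)
            fold_trees = 0
            for m, nt in alloc:
                rf = RandomForestClassifier(
                    n_estimators=nt,
                    max_features=m,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                    n_jobs=1,
                )
                rf.fit(matrix.values[train_idx], labels[train_idx])
                fold_importance += rf.feature_importances_ * nt
                fold_trees += nt
            total_importance += fold_importance / fold_trees
            total_trees += 1
    scores = total_importance / total_trees
    return FISTable(list(matrix.feature_names), scores / scores.sum())


def generate_feature_sets(
    fis: FISTable,
    cutoff_low: float = 0.0005,
    cutoff_high: float = 0.0039,
    step: float = 0.0001,
    floor: float = 0.0005,
) -> list[FeatureSet]:
    """Cutoff-thresholded candidate feature sets (nested by construction).

    Features with FIS below ``floor`` are dropped first; then one set is
    produced per cutoff in ``{low, low+step, ..., high}`` (integer-stepped to
    avoid floating-point drift in the set count), each containing the
    surviving features with FIS >= cutoff in descending-FIS order. With the
    defaults this is exactly 35 sets. A cutoff retaining zero features is
    skipped with a warning.
    """
    if step <= 0:
        raise ParameterError("step must be positive")
    if cutoff_low > cutoff_high:
        raise ParameterError("cutoff_low must be <= cutoff_high")
    ranked = fis.ranked()
    surviving = ranked[ranked["fis"] >= floor]
    n_steps = round((cutoff_high - cutoff_low) / step)
    sets: list[FeatureSet] = []
    for i in range(n_steps + 1):
        cutoff = cutoff_low + i * step
        names = list(surviving.loc[surviving["fis"] >= cutoff, "feature"])
        if not names:
            warnings.warn(f"cutoff {cutoff:.6g} retains no features; skipped")
            continue
        sets.append(FeatureSet(cutoff=cutoff, feature_names=names))
    return sets


def subset_matrix(matrix: FeatureMatrix, fset: FeatureSet) -> FeatureMatrix:
    """Column-subset of a feature matrix in feature-set order."""
    col_index = {name: i for i, name in enumerate(matrix.feature_names)}
    missing = [n for n in fset.feature_names if n not in col_index]
    if missing:
        raise ParameterError(f"features not in matrix: {missing}")
    cols = [col_index[n] for n in fset.feature_names]
    return FeatureMatrix(
        list(matrix.peptide_ids), list(fset.feature_names), matrix.values[:, cols]
    )
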