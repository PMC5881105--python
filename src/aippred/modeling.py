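"""Classifier training: grids, repeated CV, consensus parameters, bundles.

Four algorithm families are supported, mirroring the common choices for
peptide classification:

* ``RF``  — random forest (bootstrap sampling, Gini splits); tuned over
  ``ntree`` (trees), ``mtry`` (split-candidate features) and ``nsplit``
  (minimum samples to split a node).
* ``ERT`` — extremely randomized trees: same parameters, but each tree sees
  the entire training sample (no bootstrap) and split thresholds are drawn
  at random.
* ``SVM`` — RBF support vector machine with Platt-calibrated probabilities;
  tuned over ``cost`` and ``gamma``.
* ``KNN`` — k-nearest neighbours; the positive-class probability is the
  fraction of positive neighbours; tuned over ``k``.

Hyperparameters are chosen by grid search maximizing mean out-of-fold AUC
under a repeated stratified k-fold plan; the per-repeat winners are combined
by an element-wise median snapped back onto the grid ("consensus"
parameters). Class imbalance is handled only through the probability
cutoff, which is tuned on out-of-fold scores by maximizing MCC.
"""

from __future__ import annotations

import hashlib
import itertools
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import __version__ as _pkg_version
from .evaluation import roc_auc, threshold_metrics, confusion
from .exceptions import ConfigurationError, ParameterError, PipelineError
from .features import ENCODER_VERSION, FeatureMatrix, encode_dataset
from .selection import (FeatureSet, FISTable, estimate_fis,
                        generate_feature_sets, subset_matrix)
from .seqio import PeptideDataset, validate_sequence
from .exceptions import SequenceError

ALGORITHMS = ("RF", "ERT", "SVM", "KNN")

#: Tuning grids. The forest ``ntree`` grid steps by 20 from 50, which does
#: not land on 1000 exactly, so 1000 is appended as the final point.
NTREE_GRID = tuple(range(50, 1000, 20)) + (1000,)
MTRY_GRID = tuple(range(1, 8))
NSPLIT_GRID = tuple(range(2, 11))
COST_GRID = tuple(2.0**e for e in range(-5, 16, 2))
GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))
K_GRID = tuple(range(1, 32, 2))

_FOREST_FIELDS = ("ntree", "mtry", "nsplit")
_ALGO_FIELDS = {
    "RF": _FOREST_FIELDS,
    "ERT": _FOREST_FIELDS,
    "SVM": ("cost", "gamma"),
    "KNN": ("k",),
}


@dataclass(frozen=True)
class HyperParams:
    """Algorithm id plus the fields relevant to that algorithm."""

    algorithm: str
    ntree: int | None = None
    mtry: int | None = None
    nsplit: int | None = None
    cost: float | None = None
    gamma: float | None = None
    k: int | None = None

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ParameterError(f"unknown algorithm {self.algorithm!r}")
        relevant = _ALGO_FIELDS[self.algorithm]
        for name in ("ntree", "mtry", "nsplit", "cost", "gamma", "k"):
            value = getattr(self, name)
            if name in relevant and value is None:
                raise ParameterError(f"{self.algorithm} requires {name}")
            if name not in relevant and value is not None:
                raise ParameterError(f"{name} is not a {self.algorithm} parameter")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _ALGO_FIELDS[self.algorithm]}


def default_grid(algorithm: str) -> dict[str, tuple]:
    """The default tuning grid for one algorithm family."""
    if algorithm in ("RF", "ERT"):
        return {"ntree": NTREE_GRID, "mtry": MTRY_GRID, "nsplit": NSPLIT_GRID}
    if algorithm == "SVM":
        return {"cost": COST_GRID, "gamma": GAMMA_GRID}
    if algorithm == "KNN":
        return {"k": K_GRID}
    raise ParameterError(f"unknown algorithm {algorithm!r}")


@dataclass(frozen=True)
class CVPlan:
    """Repeated stratified k-fold plan; repeat r uses ``seed + r``."""

    folds: int = 5
    repeats: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if self.folds < 2:
            raise ParameterError("folds must be >= 2")
        if self.repeats < 1:
            raise ParameterError("repeats must be >= 1")


def make_folds(dataset_size: int, labels, plan: CVPlan) -> list[np.ndarray]:
    """Per-repeat fold assignment arrays (fold id per record).

    Stratified folds keep each fold's class proportions within one record of
    the global proportions. Deterministic given the plan's seed.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != dataset_size:
        raise ParameterError("labels length does not match dataset size")
    _, counts = np.unique(labels, return_counts=True)
    if len(counts) < 2 or counts.min() < plan.folds:
        raise ParameterError("each class needs at least as many members as folds")
    assignments = []
    for r in range(plan.repeats):
        skf = StratifiedKFold(
            n_splits=plan.folds, shuffle=True,
            random_state=int(plan.seed + r) % (2**31),
        )
        fold_of = np.empty(dataset_size, dtype=int)
        strat = labels if plan.stratified else np.zeros(dataset_size, dtype=int)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros(dataset_size), strat)):
            fold_of[test_idx] = f
        assignments.append(fold_of)
    return assignments


def build_estimator(params: HyperParams, seed: int, probability: bool = True):
    """Instantiate the scikit-learn estimator for a parameter set."""
    seed = int(seed) % (2**31)
    if params.algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=params.ntree, max_features=params.mtry,
            min_samples_split=params.nsplit, bootstrap=True,
            random_state=seed, n_jobs=1,
        )
    if params.algorithm == "ERT":
        # full training sample per tree (no bootstrap) + randomized splits
        return ExtraTreesClassifier(
            n_estimators=params.ntree, max_features=params.mtry,
            min_samples_split=params.nsplit, bootstrap=False,
            random_state=seed, n_jobs=1,
        )
    if params.algorithm == "SVM":
        if not probability:
            raise ConfigurationError(
                "SVM prediction requires probability calibration; "
                "construct the estimator with probability=True"
            )
        # probability=True fits a Platt sigmoid by internal CV on the
        # training data only, so calibration never sees held-out folds
        return SVC(C=params.cost, gamma=params.gamma, kernel="rbf",
                   probability=True, random_state=seed)
    if params.algorithm == "KNN":
        return KNeighborsClassifier(n_neighbors=params.k, weights="uniform")
    raise ParameterError(f"unknown algorithm {params.algorithm!r}")


def _positive_proba(estimator, values: np.ndarray) -> np.ndarray:
    col = list(estimator.classes_).index(1)
    return estimator.predict_proba(values)[:, col]


def _oof_probabilities(values, labels, params, fold_of, seed) -> np.ndarray:
    oof = np.empty(len(labels), dtype=float)
    for f in np.unique(fold_of):
        train = fold_of != f
        est = build_estimator(params, seed=seed + int(f))
        est.fit(values[train], labels[train])
        oof[~train] = _positive_proba(est, values[~train])
    return oof


def _grid_points(algorithm: str, grid: dict[str, Sequence]) -> list[HyperParams]:
    fields = _ALGO_FIELDS[algorithm]
    missing = [f for f in fields if f not in grid or not len(grid[f])]
    if missing:
        raise ParameterError(f"grid missing values for {missing}")
    points = []
    for combo in itertools.product(*(sorted(grid[f]) for f in fields)):
        points.append(HyperParams(algorithm, **dict(zip(fields, combo))))
    return points


@dataclass
class GridSearchResult:
    """Per-repeat grid-search winners and their CV metrics."""

    algorithm: str
    per_repeat_params: list[HyperParams]
    per_repeat_auc: list[float]
    per_repeat_oof: list[np.ndarray]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_repeat_auc))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.per_repeat_auc, ddof=1)) if len(
            self.per_repeat_auc) > 1 else 0.0


def grid_search(
    matrix: FeatureMatrix | np.ndarray,
    labels,
    algorithm: str,
    grid: dict[str, Sequence] | None = None,
    plan: CVPlan = CVPlan(),
) -> GridSearchResult:
    """Exhaustive grid search under repeated stratified cross-validation.

    For each repeat, returns the grid point maximizing the mean out-of-fold
    AUC across folds; ties go to the smaller parameter values (grid points
    are visited in ascending lexicographic order and only strict
    improvements replace the incumbent).
    """
    values = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix)
    labels = np.asarray(labels, dtype=int)
    if grid is None:
        grid = default_grid(algorithm)
    points = _grid_points(algorithm, grid)
    assignments = make_folds(len(labels), labels, plan)
    per_params, per_auc, per_oof = [], [], []
    for r, fold_of in enumerate(assignments):
        best_auc, best_params, best_oof = -np.inf, None, None
        for pt in points:
            oof = _oof_probabilities(values, labels, pt,
                                     fold_of, seed=plan.seed + 1000 * r)
            _, auc = roc_auc(oof, labels)
            if auc > best_auc:
                best_auc, best_params, best_oof = auc, pt, oof
        per_params.append(best_params)
        per_auc.append(best_auc)
        per_oof.append(best_oof)
    return GridSearchResult(algorithm, per_params, per_auc, per_oof)


def _snap_to_grid(value: float, grid_values: Sequence | None):
    if grid_values is None:
        return value
    best = min(sorted(grid_values), key=lambda g: (abs(g - value), g))
    return best


def consensus_params(
    per_repeat: Sequence[HyperParams], grid: dict[str, Sequence] | None = None
) -> HyperParams:
    """Element-wise median of per-repeat winners, snapped onto the grid.

    Even-count medians are the midpoint of the middle pair; when a grid is
    supplied the median is moved to the nearest grid point, ties toward the
    smaller value. Integer parameters are rounded to int.
    """
    if not per_repeat:
        raise ParameterError("consensus requires at least one repeat")
    algorithms = {p.algorithm for p in per_repeat}
    if len(algorithms) != 1:
        raise ParameterError(f"mixed algorithms in consensus: {sorted(algorithms)}")
    algorithm = per_repeat[0].algorithm
    out: dict[str, float] = {}
    for name in _ALGO_FIELDS[algorithm]:
        med = float(np.median([getattr(p, name) for p in per_repeat]))
        med = _snap_to_grid(med, grid.get(name) if grid else None)
        if name in ("ntree", "mtry", "nsplit", "k"):
            med = int(round(med))
        out[name] = med
    return HyperParams(algorithm, **out)


@dataclass
class ModelBundle:
    """A trained classifier plus everything needed to reapply it safely.

    Carries the algorithm id and tuned parameters, the selected feature
    names and encoder identity (prediction refuses to run on a different
    encoder version — silent feature misalignment is the main failure mode
    in this field), the tuned probability cutoff, the class order, and a
    fingerprint of the training matrix for leakage warnings.
    """

    algorithm: str
    params: HyperParams
    feature_names: list[str]
    probability_cutoff: float
    encoder: str
    encoder_version: str = ENCODER_VERSION
    class_order: tuple[int, int] = (0, 1)
    training_fingerprint: str = ""
    version: str = _pkg_version
    estimator: object | None = None

    def __post_init__(self):
        if not (0.0 < self.probability_cutoff < 1.0):
            raise ParameterError("probability cutoff must be in (0, 1)")
        if not self.feature_names:
            raise ParameterError("bundle requires a non-empty feature set")

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, cls):
            raise ConfigurationError(f"{path} is not a model bundle")
        return bundle

    def predict_proba(self, matrix: FeatureMatrix) -> np.ndarray:
        sub = subset_matrix(matrix, FeatureSet(cutoff=0.0,
                                               feature_names=self.feature_names))
        return _positive_proba(self.estimator, sub.values)


def fingerprint_matrix(matrix: FeatureMatrix) -> str:
    h = hashlib.sha256()
    h.update("\n".join(matrix.peptide_ids).encode())
    h.update("\n".join(matrix.feature_names).encode())
    h.update(np.ascontiguousarray(matrix.values).tobytes())
    return h.hexdigest()


def train_final(
    matrix: FeatureMatrix,
    labels,
    params: HyperParams,
    fset: FeatureSet,
    seed: int = 0,
    encoder: str = "dpc",
    probability_cutoff: float = 0.5,
) -> ModelBundle:
    """Fit the final model on the full matrix restricted to the feature set."""
    labels = np.asarray(labels, dtype=int)
    sub = subset_matrix(matrix, fset)
    est = build_estimator(params, seed=seed)
    est.fit(sub.values, labels)
    return ModelBundle(
        algorithm=params.algorithm,
        params=params,
        feature_names=list(fset.feature_names),
        probability_cutoff=probability_cutoff,
        encoder=encoder,
        training_fingerprint=fingerprint_matrix(sub),
        estimator=est,
    )


def tune_cutoff(oof_probabilities, labels, grid_step: float = 0.01) -> float:
    """Probability cutoff maximizing MCC of thresholded out-of-fold scores.

    The grid runs 0.01..0.99 (step ``grid_step``); among maximizers the
    cutoff closest to 0.5 wins, then the smaller one. If all scores are
    identical a warning is emitted and 0.5 returned.
    """
    scores = np.asarray(oof_probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ParameterError("scores and labels length mismatch")
    if np.any((scores < 0) | (scores > 1)):
        raise ParameterError("scores must lie in [0, 1]")
    if np.allclose(scores, scores[0]):
        warnings.warn("all scores identical; returning cutoff 0.5")
        return 0.5
    n_steps = round(0.98 / grid_step)
    best_mcc, best_cutoff = -np.inf, 0.5
    for i in range(n_steps + 1):
        cutoff = 0.01 + i * grid_step
        calls = (scores >= cutoff).astype(int)
        _, _, _, mcc = threshold_metrics(confusion(labels, calls))
        better = mcc > best_mcc + 1e-15
        tied = abs(mcc - best_mcc) <= 1e-15
        if better or (tied and (abs(cutoff - 0.5), cutoff)
                      < (abs(best_cutoff - 0.5), best_cutoff)):
            best_mcc, best_cutoff = max(mcc, best_mcc), cutoff
    return float(round(best_cutoff, 10))


def predict(bundle: ModelBundle, dataset: PeptideDataset) -> pd.DataFrame:
    """Per-record positive-class probability and class call.

    The call is positive iff probability >= the bundle's cutoff. Invalid
    sequences yield a per-record error message; other records are still
    processed. Output preserves input order.
    """
    if bundle.encoder_version != ENCODER_VERSION:
        raise ConfigurationError(
            f"bundle encoder version {bundle.encoder_version} != "
            f"installed {ENCODER_VERSION}; refusing to predict"
        )
    rows = []
    valid_records = []
    for rec in dataset:
        try:
            validate_sequence(rec.sequence, rec.id)
            valid_records.append(rec)
            rows.append({"id": rec.id, "error": ""})
        except SequenceError as exc:  # pragma: no cover - records prevalidated
            rows.append({"id": rec.id, "error": str(exc)})
    if valid_records:
        matrix = encode_dataset(PeptideDataset(valid_records), bundle.encoder)
        probs = bundle.predict_proba(matrix)
        prob_of = dict(zip(matrix.peptide_ids, probs))
    else:
        prob_of = {}
    out = []
    for row in rows:
        p = prob_of.get(row["id"])
        out.append({
            "id": row["id"],
            "probability": np.nan if p is None else float(p),
            "class": "" if p is None else int(p >= bundle.probability_cutoff),
            "cutoff_used": bundle.probability_cutoff,
            "error": row["error"],
        })
    return pd.DataFrame(out)


def train_test_split_dataset(
    dataset: PeptideDataset, test_fraction: float = 0.2, seed: int = 0,
    stratified: bool = True,
) -> tuple[PeptideDataset, PeptideDataset]:
    """Generic seeded train/test split of a labeled dataset."""
    if not (0.0 < test_fraction < 1.0):
        raise ParameterError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    if stratified and dataset.is_labeled():
        test_idx: list[int] = []
        labels = np.asarray(dataset.labels)
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            k = max(1, round(test_fraction * len(idx)))
            test_idx.extend(rng.permutation(idx)[:k].tolist())
        test_set = set(test_idx)
    else:
        k = max(1, round(test_fraction * n))
        test_set = set(rng.permutation(n)[:k].tolist())
    train_idx = [i for i in range(n) if i not in test_set]
    test_idx = [i for i in range(n) if i in test_set]
    return dataset.subset(train_idx), dataset.subset(test_idx)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Every tunable of the encode -> FIS -> sweep -> train pipeline."""

    encoder: str = "dpc"
    algorithm: str = "RF"
    # FIS estimation
    fis_trees: int = 10_000
    fis_mtry: tuple[int, int] = (1, 50)
    fis_folds: int = 5
    # cutoff sweep
    sweep_low: float = 0.0005
    sweep_high: float = 0.0039
    sweep_step: float = 0.0001
    sweep_floor: float = 0.0005
    # model tuning
    grid: dict | None = None
    folds: int = 5
    repeats: int = 10
    cutoff_grid_step: float = 0.01
    fast: bool = False
    seed: int = 0

    def config_hash(self) -> str:
        import json

        payload = {k: (sorted(v.items()) if isinstance(v, dict) else v)
                   for k, v in sorted(self.__dict__.items())}
        return hashlib.sha256(
            json.dumps(payload, default=str).encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Everything `run_pipeline` produces besides the bundle itself."""

    bundle: ModelBundle
    fis: FISTable
    sweep_report: pd.DataFrame
    selected: FeatureSet
    per_repeat_params: list[HyperParams]
    consensus: HyperParams
    oof_probabilities: np.ndarray
    cv_auc_mean: float
    cv_auc_sd: float


def run_pipeline(dataset: PeptideDataset, config: PipelineConfig) -> PipelineResult:
    """Encode, score features, sweep cutoffs, tune, and train the final model.

    Stages: (1) encode the labeled dataset; (2) estimate FIS with
    cross-validated forests; (3) generate the cutoff-swept candidate feature
    sets; (4) grid-search each set under repeated stratified CV and pick the
    set with the highest mean out-of-fold AUC (ties to the smaller set);
    (5) median-consensus the per-repeat parameter winners; (6) tune the
    probability cutoff on out-of-fold scores; (7) fit the final model on the
    full data. Emits a per-set sweep report (cutoff, n_features, mean AUC, sd).
    """
    if len(dataset) == 0:
        raise PipelineError("encode", "empty dataset")
    if not dataset.is_labeled():
        raise PipelineError("encode", "pipeline requires a fully labeled dataset")
    labels = np.asarray(dataset.labels, dtype=int)

    try:
        matrix = encode_dataset(dataset, config.encoder)
    except Exception as exc:
        raise PipelineError("encode", str(exc)) from exc

    try:
        fis = estimate_fis(
            matrix, labels, folds=config.fis_folds, n_trees=config.fis_trees,
            mtry_low=config.fis_mtry[0], mtry_high=config.fis_mtry[1],
            seed=config.seed,
        )
    except Exception as exc:
        raise PipelineError("fis", str(exc)) from exc

    try:
        fsets = generate_feature_sets(
            fis, cutoff_low=config.sweep_low, cutoff_high=config.sweep_high,
            step=config.sweep_step, floor=config.sweep_floor,
        )
        if not fsets:
            raise ParameterError("sweep produced no non-empty feature sets")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("sweep", str(exc)) from exc

    plan = CVPlan(folds=config.folds, repeats=config.repeats, seed=config.seed)
    grid = config.grid or default_grid(config.algorithm)

    shared_result: GridSearchResult | None = None
    if config.fast:
        # tune once on the full matrix, reuse the winners for every set
        shared_result = grid_search(matrix, labels, config.algorithm, grid, plan)

    rows = []
    per_set_results: list[GridSearchResult] = []
    try:
        for fset in fsets:
            sub = subset_matrix(matrix, fset)
            if config.fast:
                params = consensus_params(shared_result.per_repeat_params, grid)
                point_grid = {k: (v,) for k, v in params.as_dict().items()}
                gs = grid_search(sub, labels, config.algorithm, point_grid, plan)
            else:
                gs = grid_search(sub, labels, config.algorithm, grid, plan)
            per_set_results.append(gs)
            rows.append({
                "cutoff": fset.cutoff,
                "n_features": len(fset),
                "mean_auc": gs.mean_auc,
                "sd_auc": gs.sd_auc,
            })
    except Exception as exc:
        raise PipelineError("select", str(exc)) from exc
    report = pd.DataFrame(rows)

    best_i = max(
        range(len(fsets)),
        key=lambda i: (per_set_results[i].mean_auc, -len(fsets[i]),
                       fsets[i].cutoff),
    )
    best_set, best_gs = fsets[best_i], per_set_results[best_i]

    try:
        consensus = consensus_params(best_gs.per_repeat_params, grid)
        sub = subset_matrix(matrix, best_set)
        fold_of = make_folds(len(labels), labels,
                             CVPlan(folds=config.folds, repeats=1,
                                    seed=config.seed))[0]
        oof = _oof_probabilities(sub.values, labels, consensus, fold_of,
                                 seed=config.seed)
        cutoff = tune_cutoff(oof, labels, grid_step=config.cutoff_grid_step)
        bundle = train_final(matrix, labels, consensus, best_set,
                             seed=config.seed, encoder=config.encoder,
                             probability_cutoff=cutoff)
    except Exception as exc:
        raise PipelineError("final", str(exc)) from exc

    return PipelineResult(
        bundle=bundle, fis=fis, sweep_report=report, selected=best_set,
        per_repeat_params=list(best_gs.per_repeat_params), consensus=consensus,
        oof_probabilities=oof, cv_auc_mean=best_gs.mean_auc,
        cv_auc_sd=best_gs.sd_auc,
    )
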