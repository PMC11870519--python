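"""Hold-one-stressor-out random-forest classification of stress vs control.

For each stressor, all of its stress samples plus the control samples of
its batches form the test set, and a random-forest classifier of
stress/control is tuned (randomized search, stratified CV) and fit on
everything else, after SMOTE-balancing the training classes.  Per-gene
impurity importances from the six tuned forests are the feature signal:
the intersection of each model's top-N most important genes defines the
machine-learning core gene set, complementing the TN-ratio set
operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold

from .datatypes import (
    ConfigurationError,
    ExpressionMatrix,
    SampleMetadata,
    ValidationError,
)

DEFAULT_LADDER = (
    50, 100, 250, 500, 1000, 1500, 2000, 2500,
    3000, 4000, 5000, 6000, 7000, 8000, 10000, 15000,
)

DEFAULT_GRID = {
    "bootstrap": [True, False],
    "max_depth": [None, 5, 10, 20],
    "max_features": ["sqrt", "log2", 0.2],
    "min_samples_leaf": [1, 2, 4],
    "min_samples_split": [2, 5, 10],
    "n_estimators": [100, 200],
}


@dataclass
class RFConfig:
    """Hyperparameter search space and feature-selection settings."""

    param_grid: dict = field(default_factory=lambda: dict(DEFAULT_GRID))
    feature_ladder: tuple[int, ...] = DEFAULT_LADDER
    top_n: int = 6000
    smote_neighbors: int = 5
    n_search_iter: int = 20
    cv_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        ladder = tuple(self.feature_ladder)
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ConfigurationError("feature_ladder must be strictly increasing")
        if ladder and self.top_n > max(ladder) and self.top_n not in ladder:
            raise ConfigurationError(
                "top_n must be in the feature ladder or <= its maximum"
            )
        self.feature_ladder = ladder


@dataclass(frozen=True)
class HoldoutSplit:
    held_out_stressor: str
    train_samples: tuple[str, ...]
    test_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_samples) & set(self.test_samples):
            raise ValidationError("train and test samples overlap")


@dataclass
class ModelReport:
    split: str
    best_params: dict
    accuracy: float
    auc: float  # NaN when the test set is single-class
    f1: float
    importances: pd.Series  # per-gene, non-negative, sums to 1
    curve: pd.DataFrame | None = None


def _seed_ints(master: int, *key: int, n: int = 1) -> list[int]:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def make_holdout_splits(meta: SampleMetadata) -> list[HoldoutSplit]:
    """One split per stressor: its stress samples plus their batches' controls."""
    table = meta.table
    stressors = meta.stressors()
    if len(stressors) < 2:
        raise ValidationError("hold-one-stressor-out requires at least two stressors")
    splits = []
    all_samples = list(table.index)
    for stressor in stressors:
        stress_mask = (table["treatment"] == "stress") & (table["stressor"] == stressor)
        batches = set(table.loc[stress_mask, "batch"])
        control_mask = (table["treatment"] == "control") & table["batch"].isin(batches)
        if not control_mask.any():
            raise ValidationError(
                f"stressor {stressor!r} has no control samples in any of its batches"
            )
        test = tuple(s for s in all_samples if stress_mask[s] or control_mask[s])
        train = tuple(s for s in all_samples if s not in set(test))
        splits.append(
            HoldoutSplit(
                held_out_stressor=stressor, train_samples=train, test_samples=test
            )
        )
    return splits


def smote_upsample(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by interpolating synthetic minority samples (SMOTE).

    Each synthetic point is x + u * (nn - x) with u ~ Uniform(0, 1) and nn
    one of the k nearest minority neighbours of the base point x.
    Already-balanced input is returned unchanged.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE expects exactly two classes present")
    if counts[0] == counts[1]:
        return features, labels
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    X_min = features[labels == minority]
    if len(X_min) <= k:
        raise ValueError(
            f"minority class has {len(X_min)} samples; needs > k={k} "
            "(use a smaller smote_neighbors)"
        )
    # k nearest minority neighbours, excluding self
    d2 = ((X_min[:, None, :] - X_min[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn_idx = np.argsort(d2, axis=1, kind="stable")[:, :k]
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(X_min), size=n_needed)
    pick = rng.integers(0, k, size=n_needed)
    u = rng.uniform(size=n_needed)[:, None]
    x = X_min[base]
    nn = X_min[nn_idx[base, pick]]
    synthetic = x + u * (nn - x)
    X_out = np.vstack([features, synthetic])
    y_out = np.concatenate([labels, np.full(n_needed, minority, dtype=labels.dtype)])
    return X_out, y_out


def _labels_for(meta: SampleMetadata, samples: Sequence[str]) -> np.ndarray:
    return (meta.table.loc[list(samples), "treatment"] == "stress").to_numpy()


def train_and_tune(
    split: HoldoutSplit,
    m: ExpressionMatrix,
    meta: SampleMetadata,
    cfg: RFConfig,
    split_index: int = 0,
) -> ModelReport:
    """Tune, fit and evaluate one hold-one-stressor-out forest.

    SMOTE and the hyperparameter search see only the training samples;
    accuracy, AUC (stress-class probability) and F1 (stress positive) are
    computed on the untouched held-out set.
    """
    missing = sorted(
        (set(split.train_samples) | set(split.test_samples)) - set(m.sample_ids)
    )
    if missing:
        raise ValidationError(f"split references samples absent from matrix: {missing}")
    genes = m.gene_ids
    X_train = m.values[list(split.train_samples)].to_numpy().T
    y_train = _labels_for(meta, split.train_samples)
    X_test = m.values[list(split.test_samples)].to_numpy().T
    y_test = _labels_for(meta, split.test_samples)

    s_smote, s_rf, s_cv, s_search = _seed_ints(cfg.seed, split_index, n=4)
    X_bal, y_bal = smote_upsample(X_train, y_train, k=cfg.smote_neighbors, seed=s_smote)

    search = RandomizedSearchCV(
        RandomForestClassifier(random_state=s_rf, n_jobs=1),
        cfg.param_grid,
        n_iter=cfg.n_search_iter,
        cv=StratifiedKFold(cfg.cv_folds, shuffle=True, random_state=s_cv),
        scoring="roc_auc",
        random_state=s_search,
        n_jobs=1,
        refit=True,
    )
    search.fit(X_bal, y_bal)
    model = search.best_estimator_

    pred = model.predict(X_test)
    proba = model.predict_proba(X_test)[:, list(model.classes_).index(True)]
    accuracy = float(accuracy_score(y_test, pred))
    f1 = float(f1_score(y_test, pred, pos_label=True, zero_division=0))
    if len(np.unique(y_test)) < 2:
        warnings.warn(
            f"held-out set for {split.held_out_stressor} has one class; AUC undefined"
        )
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y_test, proba))

    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    importances = pd.Series(imp / total if total > 0 else imp, index=genes)
    return ModelReport(
        split=split.held_out_stressor,
        best_params=dict(search.best_params_),
        accuracy=accuracy,
        auc=auc,
        f1=f1,
        importances=importances,
    )


def _top_genes(importances: pd.Series, n: int) -> list[str]:
    # stable order: importance descending, gene id ascending at ties
    df = importances.rename_axis("gene").reset_index(name="importance")
    df = df.sort_values(["importance", "gene"], ascending=[False, True], kind="stable")
    return df["gene"].head(n).tolist()


def feature_selection_curve(
    split: HoldoutSplit,
    m: ExpressionMatrix,
    meta: SampleMetadata,
    cfg: RFConfig,
    importances: pd.Series,
    best_params: dict | None = None,
    split_index: int = 0,
) -> pd.DataFrame:
    """Refit on top-X feature subsets along the ladder; record test metrics."""
    if not cfg.feature_ladder:
        raise ValueError("feature ladder is empty")
    rows = []
    params = dict(best_params or {})
    y_train = _labels_for(meta, split.train_samples)
    y_test = _labels_for(meta, split.test_samples)
    for j, size in enumerate(cfg.feature_ladder):
        if size > m.n_genes:
            warnings.warn(
                f"ladder size {size} exceeds gene count {m.n_genes}; skipped"
            )
            continue
        top = _top_genes(importances, size)
        sub = m.values.loc[top]
        X_train = sub[list(split.train_samples)].to_numpy().T
        X_test = sub[list(split.test_samples)].to_numpy().T
        s_smote, s_rf = _seed_ints(cfg.seed, split_index, 1000 + j, n=2)
        X_bal, y_bal = smote_upsample(
            X_train, y_train, k=cfg.smote_neighbors, seed=s_smote
        )
        model = RandomForestClassifier(random_state=s_rf, n_jobs=1, **params)
        model.fit(X_bal, y_bal)
        pred = model.predict(X_test)
        proba = model.predict_proba(X_test)[:, list(model.classes_).index(True)]
        auc = (
            float(roc_auc_score(y_test, proba))
            if len(np.unique(y_test)) == 2
            else float("nan")
        )
        rows.append(
            {
                "n_features": size,
                "accuracy": float(accuracy_score(y_test, pred)),
                "auc": auc,
                "f1": float(f1_score(y_test, pred, pos_label=True, zero_division=0)),
            }
        )
    return pd.DataFrame(rows)


def rf_core_genes(reports: list[ModelReport], top_n: int) -> frozenset[str]:
    """Intersect each model's top-N most-important genes."""
    if len(reports) < 2:
        raise ValueError("need at least two model reports to intersect")
    sets = []
    for r in reports:
        if top_n > len(r.importances):
            raise ValueError(
                f"top_n={top_n} exceeds the {len(r.importances)} available genes"
            )
        sets.append(frozenset(_top_genes(r.importances, top_n)))
    return frozenset.intersection(*sets)
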