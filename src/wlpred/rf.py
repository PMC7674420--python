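"""Random-forest harness: repeated stratified shuffle-split k-fold CV with
fixed hyperparameters, metrics and Gini-importance reporting.

The classifier specification is deliberately rigid: 50 trees, Gini
impurity, all features eligible at every split, a minimum impurity
decrease of 0.01 per split and a fixed master seed.  One `ModelRun` is
produced per shuffle: every sample is scored exactly once out-of-fold,
metrics are computed on the pooled out-of-fold scores and reported
performance is the mean over shuffles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    n_shuffles: int = 50
    n_folds: int = 5
    n_trees: int = 50
    min_impurity_decrease: float = 0.01
    max_features: int | float | str | None = None  # None = all features per split
    seed: int = 42

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_impurity_decrease < 0:
            raise ValueError("min_impurity_decrease must be >= 0")

    def shuffle_seed(self, shuffle: int) -> int:
        """Deterministic per-shuffle seed derived from the master seed."""
        return int(np.random.SeedSequence([self.seed, shuffle]).generate_state(1)[0] % (2**31 - 1))


@dataclass
class MetricSet:
    roc_auc: float
    sensitivity: float
    specificity: float
    mcc: float
    ppv: float = float("nan")
    npv: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class ModelRun:
    """One trained model: a full k-fold pass for one shuffle."""

    label: str
    shuffle: int
    sample_ids: list
    oof_scores: np.ndarray
    y_true: np.ndarray
    selected_features: list[str]
    importances: dict[str, float]
    metrics: MetricSet = field(default=None)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; ties handled by midranks.

    Computed through the Mann-Whitney identity: the probability that a
    random positive outscores a random negative, counting ties as half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC undefined with a single class")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def classification_metrics(scores, labels, threshold: float = 0.5) -> MetricSet:
    """Confusion-matrix metrics at a score threshold (>= threshold -> positive).

    MCC is 0 by convention when any confusion-matrix margin is zero.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    npv = tn / (tn + fn) if (tn + fn) else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    try:
        auc = roc_auc(scores, labels)
    except ValueError:
        auc = float("nan")
    return MetricSet(roc_auc=auc, sensitivity=sens, specificity=spec, mcc=float(mcc), ppv=ppv, npv=npv)


def _make_forest(config: CVConfig, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        max_features=config.max_features,
        min_impurity_decrease=config.min_impurity_decrease,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def run_cv(
    X: pd.DataFrame,
    y,
    config: CVConfig | None = None,
    label: str = "model",
    n_shuffles: int | None = None,
    shuffle_indices=None,
) -> list[ModelRun]:
    """Repeated stratified k-fold cross-validation.

    Per shuffle: draw a stratified fold partition (seeded from the master
    seed and shuffle index), fit one forest per training fold and score the
    held-out fold with the forest's mean per-tree class-1 probability.
    Pooled out-of-fold scores give the shuffle's metrics; fold Gini
    importances are averaged.
    """
    config = config or CVConfig()
    y = np.asarray(y, dtype=int)
    if len(X) != len(y):
        raise ValueError("X and y must be aligned")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < config.n_folds:
        raise ValueError(
            f"minority class has {counts.min()} samples; cannot stratify into {config.n_folds} folds"
        )
    n_shuffles = config.n_shuffles if n_shuffles is None else n_shuffles
    if shuffle_indices is None:
        shuffle_indices = range(n_shuffles)
    features = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    runs = []
    for shuffle in shuffle_indices:
        seed = config.shuffle_seed(shuffle)
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=seed)
        oof = np.full(len(y), np.nan)
        imp = np.zeros(len(features))
        for fold, (tr, te) in enumerate(skf.split(Xv, y)):
            forest = _make_forest(config, seed=seed + fold)
            forest.fit(Xv[tr], y[tr])
            proba = forest.predict_proba(Xv[te])
            col = list(forest.classes_).index(1) if 1 in forest.classes_ else None
            oof[te] = proba[:, col] if col is not None else 0.0
            imp += forest.feature_importances_
        imp /= config.n_folds
        metrics = classification_metrics(oof, y)
        runs.append(
            ModelRun(
                label=label,
                shuffle=shuffle,
                sample_ids=list(X.index),
                oof_scores=oof,
                y_true=y.copy(),
                selected_features=features,
                importances=dict(zip(features, imp)),
                metrics=metrics,
            )
        )
    return runs


def mean_metrics(runs: list[ModelRun]) -> dict[str, float]:
    """Mean of each metric over the shuffles of a run set."""
    if not runs:
        raise ValueError("empty run set")
    keys = runs[0].metrics.as_dict().keys()
    return {k: float(np.nanmean([r.metrics.as_dict()[k] for r in runs])) for k in keys}


def importance_report(runs: list[ModelRun], min_freq: float = 0.15) -> pd.DataFrame:
    """Selection frequency and mean relative Gini importance across models.

    A feature's selection frequency is the fraction of trained models whose
    selected set contains it; its importance is the mean MDI over those
    models.  Features below ``min_freq`` are omitted.  The ``baseline``
    column holds the uniform-importance reference 1/M, with M the number of
    features in each model the feature appears in (averaged).
    """
    if not runs:
        raise ValueError("empty run set")
    labels = {r.label for r in runs}
    if len(labels) > 1:
        raise ValueError(f"runs mix data-combination labels: {sorted(labels)}")
    n_models = len(runs)
    counts: dict[str, int] = {}
    imp_sums: dict[str, float] = {}
    baseline_sums: dict[str, float] = {}
    for r in runs:
        m = len(r.selected_features)
        for f in r.selected_features:
            counts[f] = counts.get(f, 0) + 1
            imp_sums[f] = imp_sums.get(f, 0.0) + r.importances.get(f, 0.0)
            baseline_sums[f] = baseline_sums.get(f, 0.0) + (1.0 / m if m else 0.0)
    rows = []
    for f, c in counts.items():
        freq = c / n_models
        if freq < min_freq:
            continue
        rows.append((f, freq, imp_sums[f] / c, baseline_sums[f] / c))
    report = pd.DataFrame(rows, columns=["feature", "selection_frequency", "mean_importance", "baseline"])
    return report.sort_values("mean_importance", ascending=False, kind="mergesort").reset_index(drop=True)
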