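"""Label-permutation robustness tests and the distribution comparison used
to declare significance.

Three permutation modes are supported:

* ``retrain_fixed_features`` -- retrain on permuted labels using the feature
  set selected on the true labels;
* ``retrain_with_reselection`` -- rerun feature selection on the permuted
  labels before retraining (the most pessimistic check);
* ``evaluate_trained_on_shuffled`` -- keep the true-label out-of-fold scores
  and re-score them against permuted labels.

Every permutation preserves the class counts exactly.  The null ROC-AUC
distribution is compared to the true per-shuffle AUC distribution with a
two-sample test (t-test if both samples pass a Shapiro-Wilk gate, otherwise
Mann-Whitney U); an empirical-quantile p-value is emitted alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .rf import CVConfig, ModelRun, mean_metrics, roc_auc, run_cv
from .selection import forward_select

logger = logging.getLogger(__name__)

MODES = ("retrain_fixed_features", "retrain_with_reselection", "evaluate_trained_on_shuffled")


@dataclass
class PermutationResult:
    mode: str
    null_aucs: np.ndarray
    true_aucs: np.ndarray
    p_value: float
    p_empirical: float
    test_used: str
    details: dict = field(default_factory=dict)


def compare_distributions(a, b, normality_alpha: float = 0.05) -> tuple[float, str]:
    """Two-sided two-sample comparison with a normality gate.

    Both samples Gaussian by Shapiro-Wilk at ``normality_alpha`` -> unpaired
    t-test; otherwise Mann-Whitney U.  Identical constant samples are
    degenerate and return p = 1 by convention (logged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("both samples need >= 3 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        logger.info("identical constant samples: degenerate comparison, p = 1")
        return 1.0, "degenerate"
    gaussian = True
    for s in (a, b):
        if np.ptp(s) == 0:
            gaussian = False
            break
        if stats.shapiro(s).pvalue < normality_alpha:
            gaussian = False
            break
    if gaussian:
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.pvalue), "t-test"
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.pvalue), "mann-whitney"


def _permute_labels(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(len(y))
    return y[perm]


def permute_and_evaluate(
    X: pd.DataFrame,
    y,
    cv: CVConfig | None = None,
    mode: str = "retrain_fixed_features",
    n_perm: int = 50,
    seed: int = 0,
    reference_runs: list[ModelRun] | None = None,
    selected_features: list[str] | None = None,
    selection_kwargs: dict | None = None,
    perm_shuffles: int = 1,
    true_shuffles: int | None = None,
) -> PermutationResult:
    """Run one permutation-robustness setup.

    ``X`` holds the full feature frame (for the fixed-feature mode, the
    columns in ``selected_features``; for re-selection mode, the candidate
    pool).  ``reference_runs`` supplies the true-label models; if omitted
    they are fit here.  ``perm_shuffles`` / ``true_shuffles`` scale the CV
    repeats per permutation and for the reference fit.
    """
    cv = cv or CVConfig()
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    y = np.asarray(y, dtype=int)

    if mode == "retrain_fixed_features" and selected_features is None:
        if reference_runs is None:
            selected_features = list(X.columns)
        else:
            selected_features = reference_runs[0].selected_features
    if mode == "retrain_fixed_features":
        missing = [f for f in selected_features if f not in X.columns]
        if missing:
            raise ValueError(f"stored feature set absent from X: {missing}")

    if reference_runs is None:
        X_true = X[selected_features] if mode == "retrain_fixed_features" else X
        reference_runs = run_cv(X_true, y, cv, n_shuffles=true_shuffles or cv.n_shuffles)
    true_aucs = np.array([r.metrics.roc_auc for r in reference_runs])

    null_aucs = []
    for i in range(n_perm):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        y_perm = _permute_labels(y, rng)
        if mode == "retrain_fixed_features":
            runs = run_cv(X[selected_features], y_perm, cv, n_shuffles=perm_shuffles)
            null_aucs.extend(r.metrics.roc_auc for r in runs)
        elif mode == "retrain_with_reselection":
            kw = dict(selection_kwargs or {})
            always = kw.pop("always_in", None)
            trace = forward_select(X, always, y_perm, cv=cv, seed=seed + i, **kw)
            if trace.selected:
                X_sel = pd.concat([always, X[trace.selected]], axis=1) if always is not None else X[trace.selected]
            else:
                X_sel = always if always is not None else X.iloc[:, :1]
            runs = run_cv(X_sel, y_perm, cv, n_shuffles=perm_shuffles)
            null_aucs.extend(r.metrics.roc_auc for r in runs)
        else:  # evaluate_trained_on_shuffled
            for r in reference_runs[:perm_shuffles] or reference_runs:
                null_aucs.append(roc_auc(r.oof_scores, y_perm))
    null_aucs = np.asarray(null_aucs, dtype=float)

    p_value, test_used = compare_distributions(true_aucs, null_aucs)
    true_mean = float(true_aucs.mean())
    p_empirical = float((np.sum(null_aucs >= true_mean) + 1) / (null_aucs.size + 1))
    return PermutationResult(
        mode=mode,
        null_aucs=null_aucs,
        true_aucs=true_aucs,
        p_value=p_value,
        p_empirical=p_empirical,
        test_used=test_used,
        details={"n_perm": n_perm, "true_mean": true_mean, "null_mean": float(null_aucs.mean())},
    )


def plot_null_vs_true(result: PermutationResult, path) -> None:
    """Violin/strip plot of the null vs true AUC distributions (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.violinplot([result.null_aucs, result.true_aucs], showmeans=True)
    for i, sample in enumerate((result.null_aucs, result.true_aucs), start=1):
        jitter = np.random.default_rng(0).uniform(-0.06, 0.06, sample.size)
        ax.plot(np.full(sample.size, i) + jitter, sample, ".", alpha=0.4, color="k", ms=3)
    ax.set_xticks([1, 2], ["permuted", "true"])
    ax.set_ylabel("ROC-AUC")
    ax.set_title(f"{result.mode} (p = {result.p_value:.2g}, {result.test_used})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
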