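"""Wrapper feature selection: greedy forward selection with a shrinking
pool-removal schedule, and exhaustive small-subset search.

Forward selection scores every candidate by the cross-validated ROC-AUC of
the current set plus that candidate, adds the best candidate if it improves
the score, and then prunes the worst-scoring fraction of the remaining pool.
The pruned fraction starts at 0.4 and shrinks by 0.1 per iteration; below
0.1 the decrement becomes 0.01, and once the fraction rounds to zero
features exactly one is removed per iteration.  Tied best candidates are
first added jointly; if the joint set is no better, one tied candidate is
chosen at random and the others stay in the pool.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rf import CVConfig, mean_metrics, run_cv

logger = logging.getLogger(__name__)

TIE_TOL = 1e-6


@dataclass
class SelectionTrace:
    """Iteration-by-iteration record of a forward-selection run."""

    selected: list[str]
    always_in: list[str]
    iterations: list[dict] = field(default_factory=list)
    final_auc: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "selected": self.selected,
            "always_in": self.always_in,
            "final_auc": self.final_auc,
            "iterations": self.iterations,
        }


def _cv_auc(X: pd.DataFrame, y, cv: CVConfig, n_shuffles: int) -> float:
    runs = run_cv(X, y, cv, n_shuffles=n_shuffles)
    return mean_metrics(runs)["roc_auc"]


def forward_select(
    pool: pd.DataFrame,
    always_in: pd.DataFrame | None,
    y,
    cv: CVConfig | None = None,
    max_features: int | None = 8,
    frac: float = 0.4,
    step: float = 0.1,
    inner_shuffles: int = 5,
    seed: int = 0,
    scorer=None,
) -> SelectionTrace:
    """Greedy forward selection over ``pool`` with ``always_in`` fixed.

    ``max_features`` caps the number of *selected* features (``None`` =
    unlimited).  ``inner_shuffles`` controls how many CV shuffles score each
    candidate (reduced from the full protocol for tractability).  ``seed``
    drives random tie-breaking only; CV seeding comes from ``cv``.
    ``scorer`` optionally replaces the CV ROC-AUC evaluation with any
    ``f(X, y) -> float`` (used for schedule testing).
    """
    cv = cv or CVConfig()
    score_fn = scorer or (lambda X, yy: _cv_auc(X, yy, cv, inner_shuffles))
    if max_features is not None and max_features < 1:
        raise ValueError("max_features must be >= 1")
    if pool.shape[1] == 0:
        raise ValueError("candidate pool is empty")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=int)
    always_cols = list(always_in.columns) if always_in is not None else []
    base_X = always_in.copy() if always_in is not None else pd.DataFrame(index=pool.index)

    selected: list[str] = []
    remaining = list(pool.columns)
    if always_cols:
        best_auc = score_fn(base_X, y)
    else:
        best_auc = -np.inf
    trace = SelectionTrace(selected=[], always_in=always_cols)
    it = 0
    while remaining:
        if max_features is not None and len(selected) >= max_features:
            break
        it += 1
        current = pd.concat([base_X, pool[selected]], axis=1) if selected else base_X
        scores = {}
        for f in remaining:
            Xf = pd.concat([current, pool[[f]]], axis=1)
            scores[f] = score_fn(Xf, y)
        top = max(scores.values())
        record = {"iteration": it, "pool_size": len(remaining), "added": [], "removed": [], "auc": best_auc}
        improved = top > best_auc + TIE_TOL
        if improved:
            tied = [f for f in remaining if abs(scores[f] - top) <= TIE_TOL]
            if len(tied) > 1:
                X_all = pd.concat([current, pool[tied]], axis=1)
                auc_all = score_fn(X_all, y)
                if auc_all > top + TIE_TOL and (
                    max_features is None or len(selected) + len(tied) <= max_features
                ):
                    added = list(tied)
                    new_auc = auc_all
                else:
                    added = [tied[int(rng.integers(len(tied)))]]
                    new_auc = scores[added[0]]
            else:
                added = tied
                new_auc = top
            for f in added:
                selected.append(f)
                remaining.remove(f)
            best_auc = new_auc
            record["added"] = added
            record["auc"] = best_auc
        # prune the worst-scoring fraction; the fraction applies to the
        # pool size scanned this iteration, never exceeding what remains
        if remaining and improved:
            n_rm = int(np.floor(frac * record["pool_size"]))
            if n_rm == 0:
                n_rm = 1
            n_rm = min(n_rm, len(remaining))
            worst = sorted(remaining, key=lambda f: (scores[f], f))[:n_rm]
            for f in worst:
                remaining.remove(f)
            record["removed"] = worst
            frac = max(frac - step, 0.0)
            if frac < 0.1:
                step = 0.01
        trace.iterations.append(record)
        if not improved:
            break
    trace.selected = selected
    trace.final_auc = best_auc if np.isfinite(best_auc) else float("nan")
    return trace


def exhaustive_subsets(
    features: pd.DataFrame,
    y,
    sizes=(2, 3),
    cv: CVConfig | None = None,
    always_in: pd.DataFrame | None = None,
    inner_shuffles: int = 5,
    scorer=None,
) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Evaluate every feature subset of the given sizes by CV ROC-AUC.

    Returns the argmax subset and the full score table (subset, size, auc),
    sorted by AUC descending.
    """
    cv = cv or CVConfig()
    score_fn = scorer or (lambda X, yy: _cv_auc(X, yy, cv, inner_shuffles))
    cols = list(features.columns)
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes or sizes[0] < 1:
        raise ValueError("subset sizes must be positive")
    if len(cols) < max(sizes):
        raise ValueError(f"only {len(cols)} features for subsets of size {max(sizes)}")
    base = always_in if always_in is not None else pd.DataFrame(index=features.index)
    rows = []
    for size in sizes:
        for subset in itertools.combinations(cols, size):
            X = pd.concat([base, features[list(subset)]], axis=1)
            auc = score_fn(X, y)
            rows.append((subset, size, auc))
    table = pd.DataFrame(rows, columns=["subset", "size", "auc"])
    table = table.sort_values("auc", ascending=False, kind="mergesort").reset_index(drop=True)
    return tuple(table.iloc[0]["subset"]), table
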