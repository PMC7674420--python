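"""Confidence-gated ensembles of heterogeneous classifier runs.

Models (one per data combination per CV shuffle) are admitted to the
ensemble pool when their ROC-AUC strictly exceeds a threshold (0.62 by
default).  Each individual's admitted out-of-fold scores are aggregated by
one of four schemes:

* ``mean`` -- arithmetic mean of all scores;
* ``majority`` -- scores rounded to {0, 1}, majority class returned;
* ``confident_mean`` -- mean of the scores at or beyond the confidence band
  (s <= lower or s >= upper); excluded when none qualify;
* ``confident_majority`` -- rounding and majority vote over confident
  scores only; excluded when none qualify.

A threshold sweep reports sensitivity / specificity / PPV / NPV / MCC on
the non-excluded individuals at each classification threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rf import ModelRun, classification_metrics

logger = logging.getLogger(__name__)

METHODS = ("mean", "majority", "confident_mean", "confident_majority")
DEFAULT_BAND = (0.25, 0.75)
DEFAULT_AUC_THRESHOLD = 0.62


@dataclass(frozen=True)
class EnsembleConfig:
    auc_threshold: float = DEFAULT_AUC_THRESHOLD
    method: str = "confident_mean"
    band: tuple[float, float] = DEFAULT_BAND
    threshold_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))

    def __post_init__(self):
        lo, hi = self.band
        if not (0 < lo < hi < 1):
            raise ValueError("confidence band must satisfy 0 < lower < upper < 1")
        if self.method not in METHODS:
            raise ValueError(f"unknown scoring method {self.method!r}")


def admit_models(runs: list[ModelRun], auc_threshold: float = DEFAULT_AUC_THRESHOLD) -> list[ModelRun]:
    """Admit models whose ROC-AUC strictly exceeds the threshold."""
    admitted = [r for r in runs if r.metrics.roc_auc > auc_threshold]
    if not admitted:
        raise ValueError(
            f"no model exceeds ROC-AUC {auc_threshold}; lower the admission threshold"
        )
    logger.info("admitted %d of %d models at AUC > %s", len(admitted), len(runs), auc_threshold)
    return admitted


def ensemble_score(
    scores,
    method: str = "mean",
    band: tuple[float, float] = DEFAULT_BAND,
) -> float | None:
    """Aggregate one individual's per-model scores; ``None`` means excluded.

    Voting rounds s >= 0.5 to class 1; a tied vote yields 0.5 so the
    downstream classification threshold resolves it.
    """
    scores = np.asarray([s for s in np.atleast_1d(scores) if np.isfinite(s)], dtype=float)
    if scores.size == 0:
        return None
    if method == "mean":
        return float(scores.mean())
    if method == "majority":
        votes = (scores >= 0.5).astype(int)
        ones = votes.sum()
        if 2 * ones == votes.size:
            return 0.5
        return float(ones > votes.size / 2)
    lo, hi = band
    confident = scores[(scores <= lo) | (scores >= hi)]
    if confident.size == 0:
        return None
    if method == "confident_mean":
        return float(confident.mean())
    if method == "confident_majority":
        votes = (confident >= 0.5).astype(int)
        ones = votes.sum()
        if 2 * ones == votes.size:
            return 0.5
        return float(ones > votes.size / 2)
    raise ValueError(f"unknown scoring method {method!r}")


def collect_scores(runs: list[ModelRun]) -> pd.DataFrame:
    """Sample x model matrix of out-of-fold scores (NaN where no data)."""
    columns = {}
    for r in runs:
        columns[f"{r.label}#s{r.shuffle}"] = pd.Series(r.oof_scores, index=r.sample_ids)
    return pd.DataFrame(columns)


def ensemble_scores(
    runs: list[ModelRun],
    method: str = "mean",
    band: tuple[float, float] = DEFAULT_BAND,
) -> pd.DataFrame:
    """Aggregate scores for every individual covered by any admitted model.

    Returns a frame indexed by sample id with columns ``score`` (NaN when
    excluded), ``n_models`` (contributing model count) and ``excluded``.
    """
    matrix = collect_scores(runs)
    rows = []
    for sid, row in matrix.iterrows():
        vals = row.dropna().to_numpy()
        s = ensemble_score(vals, method=method, band=band) if vals.size else None
        rows.append((sid, np.nan if s is None else s, int(vals.size), s is None))
    out = pd.DataFrame(rows, columns=["sample_id", "score", "n_models", "excluded"]).set_index("sample_id")
    return out


def sweep_thresholds(
    scores: pd.DataFrame,
    labels: pd.Series,
    grid=None,
) -> pd.DataFrame:
    """Confusion metrics at each classification threshold.

    ``scores`` is the output of :func:`ensemble_scores`; ``labels`` maps
    sample id -> class (1 responder / 0 non-responder).  Score >= threshold
    predicts responder.  Excluded individuals are dropped; coverage (the
    retained fraction) is reported alongside.
    """
    if grid is None:
        grid = EnsembleConfig().threshold_grid
    kept = scores[~scores["excluded"]]
    if kept.empty:
        raise ValueError("all individuals are excluded under the current band")
    y = labels.reindex(kept.index).to_numpy(dtype=int)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("need >= 1 non-excluded individual per class")
    s = kept["score"].to_numpy(dtype=float)
    coverage = len(kept) / len(scores)
    rows = []
    for t in grid:
        m = classification_metrics(s, y, threshold=float(t))
        rows.append(
            {
                "threshold": float(t),
                "sensitivity": m.sensitivity,
                "ppv": m.ppv,
                "specificity": m.specificity,
                "npv": m.npv,
                "mcc": m.mcc,
                "n_evaluated": len(kept),
                "coverage": coverage,
            }
        )
    return pd.DataFrame(rows)
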