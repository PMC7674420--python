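"""Relative weight change and responder / non-responder class labels.

Each observation (one participant in one intervention period) is labelled
from its body weight before and after the period:

* ``delta_w = (w_after - w_before) / w_before`` (dimensionless fraction),
* any weight loss (``delta_w < 0``) -> responder (class 1),
* no change or gain (``delta_w >= 0``) -> non-responder (class 0),
* any missing or invalid weight -> excluded.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

RESPONDER = 1
NON_RESPONDER = 0
EXCLUDED = -1

CLASS_NAMES = {RESPONDER: "responder", NON_RESPONDER: "non_responder", EXCLUDED: "excluded"}


def relative_change(w_before: float, w_after: float) -> float:
    """Relative weight change ``(w_after - w_before) / w_before``.

    Non-positive or missing weights yield ``nan`` (a missing-value signal,
    not an exception), so callers can route such observations to exclusion.
    """
    if w_before is None or w_after is None:
        return math.nan
    w_before = float(w_before)
    w_after = float(w_after)
    if not math.isfinite(w_before) or not math.isfinite(w_after):
        return math.nan
    if w_before <= 0 or w_after <= 0:
        return math.nan
    return (w_after - w_before) / w_before


def classify_responder(delta_w: float) -> int:
    """Map a relative weight change to a class code.

    ``delta_w < 0`` -> :data:`RESPONDER`; ``delta_w >= 0`` ->
    :data:`NON_RESPONDER` (exactly-zero change counts as non-response);
    missing -> :data:`EXCLUDED`.
    """
    if delta_w is None or (isinstance(delta_w, float) and math.isnan(delta_w)):
        return EXCLUDED
    return RESPONDER if float(delta_w) < 0 else NON_RESPONDER


def label_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Label every observation of a cohort table.

    Parameters
    ----------
    cohort:
        Table with columns ``sample_id``, ``w_before`` and ``w_after``
        (missing ``w_after`` encoded as NaN).

    Returns
    -------
    DataFrame with columns ``sample_id``, ``delta_w``, ``label`` (int code)
    and ``class`` (human-readable name).
    """
    required = {"sample_id", "w_before", "w_after"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    delta = [relative_change(b, a) for b, a in zip(cohort["w_before"], cohort["w_after"])]
    codes = [classify_responder(d) for d in delta]
    return pd.DataFrame(
        {
            "sample_id": cohort["sample_id"].to_numpy(),
            "delta_w": np.asarray(delta, dtype=float),
            "label": np.asarray(codes, dtype=int),
            "class": [CLASS_NAMES[c] for c in codes],
        }
    )


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
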