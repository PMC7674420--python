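"""Postprandial time-series features: AUC and the volatility scores fluc1-3.

A postprandial series is a short, strictly-increasing time grid (five blood
time points at 0/30/60/120/180 min, or eight half-hourly breath-H2 points)
with possibly missing values.  Three volatility summaries are derived:

* ``fluc1`` -- mean absolute first difference of the min-max normalized
  series, ``sum(|x_i - x_{i-1}|) / len(x)``;
* ``fluc2`` -- the series is densified with a cubic spline (100 points),
  drawn onto a g x g binary raster (g in {10, 50}; value axis bounded by
  the cohort-wide marker min/max) and the occupied cells counted;
* ``fluc3`` -- same count restricted to cells lying in vertical runs of
  two or more consecutive occupied cells.

Missing-value policy: exactly one missing point is filled by interpolation;
two or more missing points make the series degenerate and all raster-based
representations are set to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d

logger = logging.getLogger(__name__)

BLOOD_TIMES_MIN = (0.0, 30.0, 60.0, 120.0, 180.0)
BREATH_TIMES_MIN = tuple(30.0 * i for i in range(8))
GRID_SIZES = (10, 50)


@dataclass(frozen=True)
class FlucFeatures:
    """Volatility summaries of one series at one grid size."""

    fluc1: float
    fluc2: int
    fluc3: int
    degenerate: bool = False

    def __post_init__(self):
        if self.fluc2 < 0 or self.fluc3 < 0:
            raise ValueError("occupancy counts must be non-negative")
        if self.fluc3 > self.fluc2:
            raise ValueError("fluc3 cannot exceed fluc2")


def fluc1(x) -> float:
    """Mean absolute consecutive difference: ``sum |x_i - x_{i-1}| / len(x)``.

    ``x`` must be a dense (no-missing) series of length >= 2, already
    normalized by the caller (see :func:`normalize_minmax`).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("fluc1 requires a 1-d series of length >= 2")
    if np.isnan(x).any():
        raise ValueError("fluc1 requires a dense series; apply fill_or_flag first")
    return float(np.abs(np.diff(x)).sum() / x.size)


def normalize_minmax(values, bounds: tuple[float, float]) -> np.ndarray:
    """Scale values into [0, 1] using cohort-wide marker bounds."""
    lo, hi = float(bounds[0]), float(bounds[1])
    if not hi > lo:
        raise ValueError("bounds must satisfy min < max")
    return (np.asarray(values, dtype=float) - lo) / (hi - lo)


def fill_or_flag(times, values) -> tuple[np.ndarray, np.ndarray, bool]:
    """Resolve missing points: fill one by interpolation, flag two or more.

    Returns ``(times, values, degenerate)``.  With exactly one missing value
    the gap is filled by interpolating the remaining points (cubic when at
    least four support points exist, else linear).  With two or more missing
    values the series is degenerate: raster representations are set to 0
    downstream and the returned values hold only the observed points.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size:
        raise ValueError("times and values must have equal length")
    if times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("need >= 2 strictly increasing time points")
    miss = ~np.isfinite(values)
    n_miss = int(miss.sum())
    if n_miss == 0:
        return times, values, False
    if n_miss >= 2 or n_miss == values.size:
        return times[~miss], values[~miss], True
    kind = "cubic" if (values.size - 1) >= 4 else "linear"
    f = interp1d(times[~miss], values[~miss], kind=kind, fill_value="extrapolate")
    filled = values.copy()
    filled[miss] = f(times[miss])
    return times, filled, False


def interpolate_dense(times, values, n_points: int = 100):
    """Cubic-spline interpolation onto ``n_points`` equally spaced times.

    Spans the observed time range and reproduces the observed points.
    Falls back to linear interpolation (logged) below four support points.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size or times.size < 2:
        raise ValueError("need >= 2 matching time/value points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.isnan(values).any():
        raise ValueError("dense interpolation requires a complete series")
    kind = "cubic"
    if times.size < 4:
        logger.debug("series has %d points; falling back to linear interpolation", times.size)
        kind = "linear"
    f = interp1d(times, values, kind=kind)
    t_dense = np.linspace(times[0], times[-1], n_points)
    return t_dense, f(t_dense)


def rasterize(t_dense, v_dense, g: int, y_bounds: tuple[float, float]) -> np.ndarray:
    """Binary image vector of a dense series on a g x g grid.

    The time axis is split into ``g`` equal bins over the series' own time
    span; the value axis into ``g`` equal bins over ``y_bounds`` (cohort-wide
    marker min/max).  A cell is 1 iff at least one point falls in it.  The
    vector is assembled column by column, each column bottom-to-top, length
    ``g * g``.  Interior bin edges belong to the upper bin; values outside
    ``y_bounds`` are clamped into the boundary cell (logged).
    """
    t = np.asarray(t_dense, dtype=float)
    v = np.asarray(v_dense, dtype=float)
    lo, hi = float(y_bounds[0]), float(y_bounds[1])
    if not hi > lo:
        raise ValueError("y_bounds must satisfy min < max")
    if g < 1:
        raise ValueError("grid size must be >= 1")
    t0, t1 = t[0], t[-1]
    if not t1 > t0:
        raise ValueError("time span must be positive")
    cols = np.floor((t - t0) / (t1 - t0) * g).astype(int)
    np.clip(cols, 0, g - 1, out=cols)
    if ((v < lo) | (v > hi)).any():
        logger.debug("values outside y_bounds clamped into boundary cells")
    rows = np.floor((v - lo) / (hi - lo) * g).astype(int)
    np.clip(rows, 0, g - 1, out=rows)
    image = np.zeros(g * g, dtype=np.int8)
    image[cols * g + rows] = 1
    return image


def fluc2(image) -> int:
    """Occupied-cell count: the sum of the binary image vector."""
    image = np.asarray(image)
    return int(image.sum())


def fluc3(image, g: int | None = None, cross_columns: bool = False) -> int:
    """Occupied cells lying in runs of >= 2 consecutive 1s.

    By default runs are confined within a column of the raster (the vector
    is column-major, so a run never crosses the seam between the top of one
    column and the bottom of the next).  ``cross_columns=True`` scans the
    concatenated vector as a whole instead.
    """
    image = np.asarray(image).astype(int)
    if g is None:
        g = int(round(np.sqrt(image.size)))
    if g * g != image.size:
        raise ValueError("image length must be a perfect square or g supplied")
    if cross_columns:
        segments = [image]
    else:
        segments = [image[c * g:(c + 1) * g] for c in range(image.size // g)]
    total = 0
    for seg in segments:
        run = 0
        for bit in seg:
            if bit:
                run += 1
            else:
                if run >= 2:
                    total += run
                run = 0
        if run >= 2:
            total += run
    return total


def auc_trapezoid(times, values) -> float:
    """Trapezoidal area under the curve over the observed time range."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise ValueError("AUC requires >= 2 points")
    if np.isnan(values).any():
        raise ValueError("AUC requires a complete series")
    return float(np.trapezoid(values, times))


def fluc_features(
    times,
    values,
    g: int,
    y_bounds: tuple[float, float],
    n_points: int = 100,
    cross_columns: bool = False,
) -> FlucFeatures:
    """Full volatility featurization of one raw series at one grid size."""
    t, v, degenerate = fill_or_flag(times, values)
    if degenerate:
        return FlucFeatures(fluc1=0.0, fluc2=0, fluc3=0, degenerate=True)
    f1 = fluc1(normalize_minmax(v, y_bounds))
    td, vd = interpolate_dense(t, v, n_points=n_points)
    image = rasterize(td, vd, g, y_bounds)
    return FlucFeatures(
        fluc1=f1,
        fluc2=fluc2(image),
        fluc3=fluc3(image, g=g, cross_columns=cross_columns),
    )


def marker_bounds(long_df: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Cohort-wide (min, max) per marker from a long-format table."""
    bounds = {}
    for marker, sub in long_df.groupby("marker"):
        v = sub["value"].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        lo, hi = float(v.min()), float(v.max())
        if hi == lo:  # degenerate marker: widen so rasterization stays defined
            hi = lo + 1.0
        bounds[marker] = (lo, hi)
    return bounds


def featurize_postprandial(
    long_df: pd.DataFrame,
    grid_sizes=GRID_SIZES,
    n_points: int = 100,
    cross_columns: bool = False,
) -> dict[str, pd.DataFrame]:
    """Featurize a long table (sample_id, marker, time_min, value).

    Returns one wide sample x feature frame per representation, keyed by
    block labels ``PostPranFluc1``, ``PostPranFluc2_<g>``, ``PostPranFluc3_<g>``
    and ``PostPranAUC``.
    """
    bounds = marker_bounds(long_df)
    rows: dict[str, dict[str, float]] = {}
    for (sid, marker), sub in long_df.groupby(["sample_id", "marker"], sort=True):
        sub = sub.sort_values("time_min")
        times = sub["time_min"].to_numpy(dtype=float)
        values = sub["value"].to_numpy(dtype=float)
        rec = rows.setdefault(sid, {})
        t, v, degenerate = fill_or_flag(times, values)
        if degenerate:
            rec[f"{marker}_fluc1"] = 0.0
            rec[f"{marker}_auc"] = 0.0
            for g in grid_sizes:
                rec[f"{marker}_fluc2_{g}"] = 0
                rec[f"{marker}_fluc3_{g}"] = 0
            continue
        rec[f"{marker}_fluc1"] = fluc1(normalize_minmax(v, bounds[marker]))
        rec[f"{marker}_auc"] = auc_trapezoid(t, v)
        td, vd = interpolate_dense(t, v, n_points=n_points)
        for g in grid_sizes:
            image = rasterize(td, vd, g, bounds[marker])
            rec[f"{marker}_fluc2_{g}"] = fluc2(image)
            rec[f"{marker}_fluc3_{g}"] = fluc3(image, g=g, cross_columns=cross_columns)
    wide = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    wide.index.name = "sample_id"
    out = {"PostPranFluc1": wide.filter(regex=r"_fluc1$"), "PostPranAUC": wide.filter(regex=r"_auc$")}
    for g in grid_sizes:
        out[f"PostPranFluc2_{g}"] = wide.filter(regex=rf"_fluc2_{g}$")
        out[f"PostPranFluc3_{g}"] = wide.filter(regex=rf"_fluc3_{g}$")
    return out
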