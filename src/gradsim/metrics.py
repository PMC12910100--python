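"""Prediction-accuracy metrics on the evaluation grid.

Three measures, each compared over the same 1000 equidistant grid points:

``multiple_r2``
    squared Pearson correlation between predicted and true responses.
    Affine-invariant: a prediction that is a scaled/shifted copy of the
    truth still scores 1, so it measures covariation, not match.
``chalcraft_ps``
    prediction success of the fixed identity model — the coefficient of
    determination of a regression of predicted on true forced through zero
    with slope one: ``1 - SSE / SST`` with ``SSE = sum((pred - true)^2)``
    and ``SST = sum((true - mean(true))^2)``.  Equals 1 only on exact
    match and may go negative (worse than predicting the true mean).
``neg_rmse``
    negative root mean square error, so that for all three measures larger
    is better; its magnitude grows linearly with the noise level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fitpredict import EvaluationGrid

__all__ = [
    "AccuracyScores",
    "multiple_r2",
    "chalcraft_ps",
    "neg_rmse",
    "score_grid",
]

METRIC_NAMES = ("r2_multiple", "chalcraft_ps", "neg_rmse")


@dataclass(frozen=True)
class AccuracyScores:
    r2_multiple: float
    chalcraft_ps: float
    neg_rmse: float


def multiple_r2(y_true, y_pred) -> float:
    """Squared Pearson correlation of predicted vs. true responses.

    A constant prediction (or constant truth) has undefined correlation and
    scores 0 by convention — this happens when a fit degenerates to a flat
    line, which is itself a failed prediction of any non-flat curve.
    """
    yt = np.asarray(y_true, float)
    yp = np.asarray(y_pred, float)
    dt = yt - yt.mean()
    dp = yp - yp.mean()
    sst = float(dt @ dt)
    ssp = float(dp @ dp)
    if sst <= 0.0 or ssp <= 0.0:
        return 0.0
    r = float(dt @ dp) / math.sqrt(sst * ssp)
    return min(r * r, 1.0)


def chalcraft_ps(y_true, y_pred, normalizer: str = "true_centered") -> float:
    """Prediction success of the through-origin, slope-one model.

    ``normalizer="true_centered"`` divides the squared mismatch by the sum
    of squared deviations of the truth from its mean, so PS=1 iff the
    prediction matches exactly and PS reads as the fraction of response
    variance matched.  ``"true_raw"`` divides by the raw sum of squares of
    the truth instead (kept for sensitivity checks).  A constant truth
    makes the centred normalizer undefined: NaN is returned.
    """
    yt = np.asarray(y_true, float)
    yp = np.asarray(y_pred, float)
    sse = float(np.sum((yp - yt) ** 2))
    if normalizer == "true_centered":
        d = yt - yt.mean()
        sst = float(d @ d)
    elif normalizer == "true_raw":
        sst = float(yt @ yt)
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    if sst <= 0.0:
        return float("nan")
    return 1.0 - sse / sst


def neg_rmse(y_true, y_pred) -> float:
    """Negative root mean square error (0 is perfect, more negative is worse)."""
    yt = np.asarray(y_true, float)
    yp = np.asarray(y_pred, float)
    return -math.sqrt(float(np.mean((yp - yt) ** 2)))


def score_grid(grid: EvaluationGrid, ps_normalizer: str = "true_centered") -> AccuracyScores:
    """All three accuracy measures for one evaluation grid."""
    return AccuracyScores(
        r2_multiple=multiple_r2(grid.y_true, grid.y_pred),
        chalcraft_ps=chalcraft_ps(grid.y_true, grid.y_pred, normalizer=ps_normalizer),
        neg_rmse=neg_rmse(grid.y_true, grid.y_pred),
    )
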