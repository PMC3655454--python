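"""Forecast evaluation: RMSE, result containers, baselines, comparisons.

The evaluation protocol is rolling one-step forecasting: each future point
is predicted from observed values up to the immediately preceding sample,
the forecaster is refit as the origin advances, and accuracy is the root
mean square error over the horizon.  Besides the sign-coerced and standard
AR forecasters this module supplies a nearest-neighbor analog baseline:
predict the successor of the historical window most similar to the current
trailing window, with a training span that grows as the origin advances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .signal_io import TimeSeries

__all__ = [
    "ForecastResult",
    "ModelSpec",
    "rmse",
    "nn_forecast",
    "compare_models",
]


def rmse(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean square error between two equal-length vectors."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1 or a.size == 0:
        raise ValueError(
            f"rmse needs equal-length nonempty vectors, got {a.shape} "
            f"and {p.shape}"
        )
    return float(np.sqrt(np.mean((a - p) ** 2)))


@dataclass
class ForecastResult:
    """Predictions over a horizon, with errors when actuals are known.

    ``origin`` is the 1-based absolute index of the first forecast step;
    ``errors`` is actual − predicted; ``rmse`` is present exactly when
    ``actual`` is.
    """

    origin: int
    horizon_n: int
    predicted: np.ndarray
    actual: Optional[np.ndarray] = None
    errors: Optional[np.ndarray] = field(default=None)
    rmse: Optional[float] = None
    model_descriptor: str = ""

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.horizon_n != self.predicted.size or self.horizon_n < 1:
            raise ValueError("horizon must equal the number of predictions")
        if self.actual is not None:
            self.actual = np.asarray(self.actual, dtype=float)
            if self.actual.size != self.horizon_n:
                raise ValueError("actual length must equal the horizon")
            if self.errors is None:
                self.errors = self.actual - self.predicted
            if self.rmse is None:
                self.rmse = rmse(self.actual, self.predicted)


def nn_forecast(
    x: TimeSeries,
    start: int,
    horizon: int,
    window_m: int = 5,
    train_end: Optional[int] = None,
) -> ForecastResult:
    """Rolling nearest-neighbor (analog) forecast.

    At each origin o the trailing observed window of length ``window_m``
    is compared (Euclidean distance) against every historical window whose
    successor lies inside the training span; the successor of the closest
    window is the prediction, earliest match winning ties.  The training
    span starts at ``train_end`` (default ``start`` − 1) and grows by one
    sample per step, mirroring how the observed series itself grows.
    """
    v = x.values
    n = v.size
    if train_end is None:
        train_end = start - 1
    if window_m < 1:
        raise ValueError("window_m must be positive")
    if train_end < window_m + 1:
        raise ValueError(
            f"training span (1..{train_end}) must cover at least "
            f"window_m + 1 = {window_m + 1} samples"
        )
    if start + horizon - 1 > n:
        raise ValueError(
            f"rolling forecast through index {start + horizon - 1} needs "
            f"observed values, but the series ends at {n}"
        )
    if start - 1 < window_m:
        raise ValueError("not enough trailing history for the query window")
    from numpy.lib.stride_tricks import sliding_window_view

    preds = np.empty(horizon)
    for k in range(horizon):
        origin = start + k
        limit = train_end + k  # successors up to this 1-based index
        query = v[origin - 1 - window_m : origin - 1]
        # candidate windows end at 1-based e = window_m .. limit-1
        ends = np.arange(window_m, limit)
        wins = sliding_window_view(v[: limit - 1], window_m)
        d2 = np.sum((wins - query) ** 2, axis=1)
        best = int(np.argmin(d2))  # argmin returns the earliest tie
        preds[k] = v[ends[best]]  # successor of the best window
    actual = v[start - 1 : start - 1 + horizon]
    return ForecastResult(
        origin=start,
        horizon_n=horizon,
        predicted=preds,
        actual=actual,
        model_descriptor=f"nn(m={window_m})",
    )


@dataclass(frozen=True)
class ModelSpec:
    """One row of a comparison: model kind plus its parameters.

    ``kind`` is ``"caar"`` (sign-coerced AR), ``"ar"`` (standard AR refit
    per origin) or ``"nn"`` (nearest neighbor).  ``order`` is the AR order
    p or, for nn, unused; ``window`` is the sign-fitting window W (caar),
    the training window (ar, None = all history to date) or the analog
    window m (nn).  ``method`` selects the standard-AR estimator: "yw"
    (Yule-Walker, the conventional choice) or "ls" (conditional least
    squares).
    """

    kind: str
    order: int = 5
    window: Optional[int] = None
    method: str = "yw"

    def descriptor(self) -> str:
        w = "" if self.window is None else f":w={self.window}"
        return f"{self.kind}:p={self.order}{w}"


def compare_models(
    x: TimeSeries,
    specs: Sequence[ModelSpec],
    start: int,
    horizon: int,
) -> pd.DataFrame:
    """Run each model spec over the same rolling split; one row per spec.

    Columns: model, order, window, start, horizon, rmse.  Deterministic
    row order (the spec order).  A failing spec raises with its descriptor
    named.
    """
    from . import models  # deferred: models imports this module

    rows = []
    for spec in specs:
        try:
            if spec.kind == "caar":
                res = models.caar_forecast(
                    x, start, horizon, spec.order, W=spec.window
                )
            elif spec.kind == "ar":
                res = models.ar_rolling_forecast(
                    x, start, horizon, spec.order,
                    train_window=spec.window, method=spec.method,
                )
            elif spec.kind == "nn":
                m = spec.window if spec.window is not None else spec.order
                res = nn_forecast(x, start, horizon, window_m=m)
            else:
                raise ValueError(f"unknown model kind {spec.kind!r}")
        except Exception as exc:
            raise type(exc)(f"model {spec.descriptor()}: {exc}") from exc
        rows.append(
            {
                "model": spec.kind,
                "order": spec.order,
                "window": spec.window,
                "start": start,
                "horizon": horizon,
                "rmse": res.rmse,
            }
        )
    return pd.DataFrame(
        rows, columns=["model", "order", "window", "start", "horizon", "rmse"]
    )
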