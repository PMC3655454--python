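"""Autoregressive forecasters: the standard AR(p) and the sign-coerced AR.

The standard model x_t = c + Σ φ_i x_{t−i} + ε_t is fit globally by
Yule-Walker or conditional least squares and serves as the baseline.  The
sign-coerced variant constrains every coefficient to ±1 with the first lag
fixed at +1:

    x_t = ĉ + Σ_i π_i x_{t−i},   π_i ∈ {−1, +1},  π_1 = +1,

and re-selects the sign vector at every forecast origin from a short
trailing window of one-step pairs: all 2^(p−1) admissible sign vectors are
scored by least squares (the intercept has a closed form per candidate —
the mean residual) and the RSS-minimal one is used for the next step.
Because only p + W trailing samples enter each fit, the method's cost per
step is constant in the series length, which is the point: it tracks
nonstationary, nonperiodic signals (the motivating case is seizure EEG)
where a globally fit AR goes stale.

All time indices in this module are 1-based and inclusive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from statsmodels.regression.linear_model import yule_walker

from .evaluation import ForecastResult
from .signal_io import TimeSeries

__all__ = [
    "ARModel",
    "SignVector",
    "CAARModel",
    "SignSelection",
    "fit_ar_yw",
    "fit_ar_ls",
    "ar_one_step",
    "ar_rolling_forecast",
    "select_signs",
    "caar_one_step",
    "caar_forecast",
]

#: refuse the exhaustive 2^(p-1) sign search above this order unless forced
MAX_SEARCH_ORDER = 20


@dataclass
class ARModel:
    """A fitted AR(p): coefficients, intercept and innovation variance."""

    order_p: int
    coeffs: np.ndarray
    intercept: float
    noise_var: float

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.size != self.order_p or self.order_p < 1:
            raise ValueError("coeffs length must equal the positive order p")
        if self.noise_var < 0:
            raise ValueError("noise_var must be non-negative")


@dataclass(frozen=True)
class SignVector:
    """A ±1 coefficient vector with the first entry pinned to +1."""

    signs: tuple

    def __post_init__(self) -> None:
        s = tuple(int(v) for v in self.signs)
        if not s or any(v not in (-1, 1) for v in s):
            raise ValueError("signs must be a non-empty ±1 vector")
        if s[0] != 1:
            raise ValueError("the first sign is pinned to +1")
        object.__setattr__(self, "signs", s)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.signs, dtype=float)

    def __len__(self) -> int:
        return len(self.signs)


@dataclass
class CAARModel:
    """Configuration of the sign-coerced forecaster.

    ``fit_window`` W is the number of trailing one-step pairs used to score
    sign candidates at each origin (default p, set at call sites).
    """

    order_p: int
    signs: SignVector
    intercept: float
    fit_window: int

    def __post_init__(self) -> None:
        if len(self.signs) != self.order_p:
            raise ValueError("sign vector length must equal the order")
        if self.fit_window < 1:
            raise ValueError("fit_window must be at least 1")


@dataclass
class SignSelection:
    """Outcome of one exhaustive sign search at a forecast origin."""

    signs: SignVector
    intercept: float
    rss: float


# ---------------------------------------------------------------------------
# standard AR


def _check_fit_input(v: np.ndarray, p: int) -> None:
    if p < 1:
        raise ValueError("order p must be a positive integer")
    if v.size < p + 2:
        raise ValueError(
            f"need at least p + 2 = {p + 2} samples to fit AR({p}), "
            f"got {v.size}"
        )
    if np.ptp(v) == 0:
        raise ValueError("constant series: sample variance is zero")


def fit_ar_yw(x: TimeSeries, p: int) -> ARModel:
    """Fit AR(p) by Yule-Walker from biased sample autocovariances.

    The intercept is set so the model mean equals the sample mean and the
    innovation variance comes from the Yule-Walker innovations identity.
    """
    v = x.values
    _check_fit_input(v, p)
    try:
        rho, sigma = yule_walker(v, order=p, method="mle", demean=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular autocovariance system for AR({p}): {exc}"
        ) from exc
    intercept = float(v.mean() * (1.0 - rho.sum()))
    return ARModel(
        order_p=p,
        coeffs=rho,
        intercept=intercept,
        noise_var=float(sigma**2),
    )


def fit_ar_ls(x: TimeSeries, p: int) -> ARModel:
    """Fit AR(p) by conditional least squares of x_t on (1, x_{t−1..t−p}).

    For large samples this agrees with the Yule-Walker estimate.
    """
    v = x.values
    _check_fit_input(v, p)
    rows = v.size - p
    if rows < p + 1:
        raise ValueError(
            f"only {rows} regression rows for {p + 1} parameters; "
            "series too short for least squares"
        )
    X = np.column_stack(
        [np.ones(rows)] + [v[p - i - 1 : v.size - i - 1] for i in range(p)]
    )
    y = v[p:]
    # min-norm solution: collinear designs (e.g. an exact ramp) still give
    # well-defined, residual-minimizing predictions
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = rows - (p + 1)
    noise_var = float(resid @ resid / dof) if dof > 0 else 0.0
    return ARModel(
        order_p=p, coeffs=coef[1:], intercept=float(coef[0]), noise_var=noise_var
    )


def ar_one_step(model: ARModel, history: Sequence[float]) -> float:
    """One-step forecast c + Σ φ_i x_{t−i} from the trailing history."""
    h = np.asarray(history, dtype=float)
    p = model.order_p
    if h.size < p:
        raise ValueError(f"history holds {h.size} samples but AR needs {p}")
    return float(model.intercept + model.coeffs @ h[-1 : -p - 1 : -1])


def ar_rolling_forecast(
    x: TimeSeries,
    start: int,
    horizon: int,
    p: int,
    train_window: Optional[int] = None,
    method: str = "yw",
) -> ForecastResult:
    """Rolling one-step AR baseline, refit at every origin.

    At origin o the model is refit on the trailing ``train_window``
    observed samples (default: all history to date, 1..o−1) and forecasts
    one step.  ``method`` is ``"yw"`` or ``"ls"``.
    """
    fit = {"yw": fit_ar_yw, "ls": fit_ar_ls}.get(method)
    if fit is None:
        raise ValueError(f"unknown AR fitting method {method!r}")
    v = x.values
    if start + horizon - 1 > v.size:
        raise ValueError("rolling AR forecast needs observed actuals")
    preds = np.empty(horizon)
    for k in range(horizon):
        origin = start + k
        lo = 0 if train_window is None else max(0, origin - 1 - train_window)
        hist = TimeSeries(v[lo : origin - 1])
        model = fit(hist, p)
        preds[k] = ar_one_step(model, hist.values)
    return ForecastResult(
        origin=start,
        horizon_n=horizon,
        predicted=preds,
        actual=v[start - 1 : start - 1 + horizon],
        model_descriptor=f"ar:p={p}:{method}",
    )


# ---------------------------------------------------------------------------
# sign-coerced AR


def _candidate_signs(p: int) -> np.ndarray:
    """All 2^(p−1) sign vectors with first entry +1, lexicographic,
    +1 ordered before −1 at every position."""
    if p == 1:
        return np.ones((1, 1))
    tails = np.array(
        list(itertools.product((1.0, -1.0), repeat=p - 1))
    )
    return np.column_stack([np.ones(tails.shape[0]), tails])


def select_signs(
    x: TimeSeries,
    t: int,
    p: int,
    W: Optional[int] = None,
    force: bool = False,
) -> SignSelection:
    """Exhaustive least-squares sign search at forecast origin ``t``.

    The W most recent one-step pairs before the origin — targets x_s with
    regressors (x_{s−1}, …, x_{s−p}) for s = t−W … t−1 — score every
    admissible sign vector π.  The intercept per candidate is the mean
    residual ĉ(π) = mean_s(x_s − Σ_i π_i x_{s−i}) and the winner minimizes
    the residual sum of squares, ties broken toward the lexicographically
    smaller sign vector (+1 before −1, leftmost lag first).

    ``W`` defaults to p.  Orders above 20 are refused unless ``force``
    (the search is exponential in p).
    """
    if p < 1:
        raise ValueError("order p must be a positive integer")
    if p > MAX_SEARCH_ORDER and not force:
        raise ValueError(
            f"p={p} implies {2 ** (p - 1)} sign candidates; pass force=True "
            "to run the exhaustive search anyway"
        )
    if W is None:
        W = p
    if W < 1:
        raise ValueError("fit window W must be at least 1")
    v = x.values
    earliest = t - W - p  # 1-based index of the oldest regressor sample
    if earliest < 1:
        raise ValueError(
            f"origin t={t} with p={p}, W={W} needs samples back to index "
            f"{earliest}; history starts at 1"
        )
    if t - 1 > v.size:
        raise ValueError(f"origin t={t} lies beyond the observed series")
    targets = v[t - W - 1 : t - 1]  # x_{t-W} .. x_{t-1}
    # R[w, i] = x_{s_w - i - 1} (1-based x_{s-i}), s_w = t-W+w
    R = np.column_stack(
        [v[t - W - i - 2 : t - i - 2] for i in range(p)]
    )
    cands = _candidate_signs(p)  # (K, p)
    resid0 = targets[:, None] - R @ cands.T  # (W, K)
    c = resid0.mean(axis=0)
    rss = np.sum((resid0 - c) ** 2, axis=0)
    k = int(np.argmin(rss))  # first minimum = lexicographic winner
    return SignSelection(
        signs=SignVector(tuple(int(s) for s in cands[k])),
        intercept=float(c[k]),
        rss=float(rss[k]),
    )


def caar_one_step(
    x: TimeSeries,
    t: int,
    p: int,
    W: Optional[int] = None,
    force: bool = False,
) -> float:
    """One-step sign-coerced forecast of x_t from x_{t−1} … x_{t−p}.

    Signs and intercept are re-selected at this origin; the sign vector
    may differ at every t.
    """
    sel = select_signs(x, t, p, W, force=force)
    v = x.values
    lags = v[t - 2 : t - 2 - p : -1] if t - 2 - p >= 0 else v[t - 2 :: -1]
    return float(sel.intercept + sel.signs.as_array() @ lags)


def caar_forecast(
    x: TimeSeries,
    start: int,
    horizon: int,
    p: int,
    W: Optional[int] = None,
    mode: str = "rolling",
    force: bool = False,
) -> ForecastResult:
    """Multi-step sign-coerced forecast from 1-based origin ``start``.

    ``rolling`` re-selects signs at each step from observed history only
    and therefore requires actuals through ``start + horizon − 1``;
    ``recursive`` uses observed values while they exist and feeds its own
    forecasts back once the series is exhausted (actuals, errors and RMSE
    then cover only the observed prefix of the horizon).
    """
    if mode not in ("rolling", "recursive"):
        raise ValueError(f"unknown mode {mode!r}")
    if horizon < 1:
        raise ValueError("horizon must be positive")
    n = len(x)
    last_needed = start + horizon - 1
    if mode == "rolling" and last_needed > n:
        raise ValueError(
            f"rolling mode needs observed values through index "
            f"{last_needed} but the series ends at {n}; use recursive mode "
            "to forecast beyond the data"
        )
    work = np.concatenate([x.values, np.full(max(0, last_needed - n), np.nan)])
    preds = np.empty(horizon)
    for k in range(horizon):
        origin = start + k
        hist = TimeSeries(work[: origin - 1])
        preds[k] = caar_one_step(hist, origin, p, W, force=force)
        if origin > n:  # beyond the data: feed the forecast back
            work[origin - 1] = preds[k]
    observed = min(horizon, max(0, n - start + 1))
    desc = f"caar:p={p}:w={W if W is not None else p}:{mode}"
    if observed == horizon:
        actual = x.values[start - 1 : start - 1 + horizon]
        return ForecastResult(start, horizon, preds, actual, model_descriptor=desc)
    # actuals incomplete: report predictions only
    return ForecastResult(start, horizon, preds, model_descriptor=desc)
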