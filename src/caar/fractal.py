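"""Box-counting fractal dimension and autoregressive order selection.

The number N_ε of grid cells of side ε needed to cover an object S scales
as N_ε(S) ≈ k·(1/ε)^d, so the dimension d is the slope of log N_ε against
log(1/ε) over the linear part of the plot.  Two objects are counted:

* the planar **graph** of a signal — the polyline {(t, x_t)}, t in raw
  1-based sample-index units, counted by segment–cell intersection;
* a **delay-coordinate phase space** — the point cloud of vectors
  V_t = [x_t, x_{t−τ}, …, x_{t−Lτ}], counted by cell occupancy.

The grid ladder doubles the cell side from 0.1 upward while it stays
within 10000, giving 17 sizes.  The autoregressive order of the
sign-coerced forecaster is chosen as the ceiling of the mean phase-space
slope over a collection of reference ("normal") signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np

from .signal_io import TimeSeries

__all__ = [
    "GridLadder",
    "BoxCountResult",
    "EmbeddingConfig",
    "PhaseSpace",
    "default_grid_ladder",
    "box_count_curve",
    "box_count_points",
    "fit_dimension",
    "embed_delay",
    "select_order",
]

MIN_FIT_POINTS = 5


@dataclass(frozen=True)
class GridLadder:
    """An ascending sequence of grid cell sides ε."""

    sizes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sizes", np.sort(np.asarray(self.sizes, dtype=float))
        )
        if self.sizes.size < MIN_FIT_POINTS:
            raise ValueError(
                f"a grid ladder needs at least {MIN_FIT_POINTS} sizes "
                "for a slope fit"
            )
        if not np.all(self.sizes > 0):
            raise ValueError("grid sizes must be positive")

    def __len__(self) -> int:
        return int(self.sizes.size)


def default_grid_ladder() -> GridLadder:
    """The standard ladder: ε = 0.1·2^k, k = 0…16 (0.1 up to 6553.6).

    Successive sizes differ by a factor of exactly 2 and every size stays
    at or below 10000.
    """
    return GridLadder(0.1 * 2.0 ** np.arange(17))


def custom_grid_ladder(
    smallest: float, largest: float, factor: float = 2.0
) -> GridLadder:
    """Geometric ladder from ``smallest`` up to at most ``largest``."""
    if smallest <= 0 or largest < smallest or factor <= 1:
        raise ValueError("need 0 < smallest <= largest and factor > 1")
    sizes = [smallest]
    while sizes[-1] * factor <= largest * (1 + 1e-12):
        sizes.append(sizes[-1] * factor)
    return GridLadder(np.array(sizes))


@dataclass
class BoxCountResult:
    """Counts over a ladder plus the fitted log-log slope.

    ``linear_range`` is a pair of inclusive indices into ``sizes`` marking
    the sub-range the slope was fitted on; ``slope`` is the dimension
    estimate d.
    """

    sizes: np.ndarray
    counts: np.ndarray
    log_inv_eps: np.ndarray
    log_counts: np.ndarray
    slope: float
    intercept: float
    linear_range: Tuple[int, int]
    r_squared: float


@dataclass(frozen=True)
class EmbeddingConfig:
    """Delay-coordinate embedding: delay ``tau`` samples, ``L`` extra lags.

    The embedding dimension is L + 1.
    """

    tau: int = 1
    L: int = 20

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be a positive integer")
        if self.L < 0:
            raise ValueError("L must be a non-negative integer")


@dataclass
class PhaseSpace:
    """Delay-coordinate vectors V_t = [x_t, x_{t-τ}, …, x_{t-Lτ}]."""

    vectors: np.ndarray  # shape (n - L·τ, L + 1)
    config: EmbeddingConfig


def embed_delay(x: TimeSeries, cfg: EmbeddingConfig) -> PhaseSpace:
    """Build the phase space of a series; one vector per valid t."""
    v = x.values
    n = v.size
    span = cfg.L * cfg.tau
    if span >= n:
        raise ValueError(
            f"embedding span L*tau = {span} must be below series length {n}"
        )
    cols = [v[span - j * cfg.tau : n - j * cfg.tau] for j in range(cfg.L + 1)]
    return PhaseSpace(vectors=np.column_stack(cols), config=cfg)


# ---------------------------------------------------------------------------
# counting


def _curve_count(t: np.ndarray, y: np.ndarray, eps: float) -> int:
    """Cells of side ``eps`` intersected by the polyline {(t_i, y_i)}.

    The grid is anchored at (min t, min y); a cell is counted when the
    polyline meets the closed cell.  Because t is strictly increasing and
    the polyline is a continuous function of t, the occupied cells in each
    ε-column form one contiguous run of rows, so the count is the sum of
    per-column row spans.  Columns are delimited by refining the polyline
    with its column-boundary crossings.
    """
    a, b = t[0], y.min()
    ncols = int(np.floor((t[-1] - a) / eps)) + 1
    # refine: evaluate y at every interior column boundary; boundary k
    # separates columns k and k+1 and belongs to both (closed cells)
    k = np.arange(1, ncols)
    bounds = a + eps * k
    keep = bounds < t[-1]
    bounds, k = bounds[keep], k[keep]
    yb = np.interp(bounds, t, y)

    idx_s = np.floor((t - a) / eps).astype(np.int64)
    np.clip(idx_s, 0, ncols - 1, out=idx_s)

    idx = np.concatenate([idx_s, k - 1, k])
    vals = np.concatenate([y, yb, yb])
    ymin = np.full(ncols, np.inf)
    ymax = np.full(ncols, -np.inf)
    np.minimum.at(ymin, idx, vals)
    np.maximum.at(ymax, idx, vals)
    used = np.isfinite(ymin)
    jlo = np.floor((ymin[used] - b) / eps).astype(np.int64)
    jhi = np.floor((ymax[used] - b) / eps).astype(np.int64)
    return int(np.sum(jhi - jlo + 1))


def _point_count(pts: np.ndarray, eps: float) -> int:
    """Occupied cells of side ``eps`` for a point cloud (half-open cells)."""
    anchored = pts - pts.min(axis=0)
    cells = np.floor(anchored / eps).astype(np.int64)
    return int(np.unique(cells, axis=0).shape[0])


def box_count_curve(
    x: TimeSeries,
    ladder: Optional[GridLadder] = None,
    range_policy: Union[str, Tuple[int, int]] = "auto",
    normalize: bool = False,
) -> BoxCountResult:
    """Box-count the planar graph of a signal and fit its dimension.

    Time is measured in raw sample-index units (1-based) and amplitude in
    raw signal units, so the default absolute ladder is meaningful against
    raw-amplitude recordings.  With ``normalize`` the curve is rescaled to
    a 4096×4096 box for unit-free use.  The fitted slope of a planar curve
    is expected in [1, 2]; values outside provoke a warning, not an error.
    """
    if ladder is None:
        ladder = default_grid_ladder()
    v = x.values
    if v.size < 2:
        raise ValueError("box-counting a curve needs at least 2 samples")
    t = np.arange(1, v.size + 1, dtype=float)
    if normalize:
        t = 1.0 + (t - t[0]) * (4095.0 / max(t[-1] - t[0], 1e-300))
        lo, hi = v.min(), v.max()
        v = (
            np.full_like(v, 1.0)
            if hi == lo
            else 1.0 + (v - lo) * (4095.0 / (hi - lo))
        )
    counts = np.array([_curve_count(t, v, e) for e in ladder.sizes])
    return _finish(ladder, counts, range_policy, curve=True)


def box_count_points(
    ps: PhaseSpace,
    ladder: Optional[GridLadder] = None,
    range_policy: Union[str, Tuple[int, int]] = "auto",
) -> BoxCountResult:
    """Box-count a phase-space point cloud and fit its dimension.

    Cells are half-open per axis and anchored at the per-axis minima, so
    each vector occupies exactly one hypercube.  Slopes above 2 are normal
    here — the cloud dimension grows with the embedding dimension.
    """
    if ladder is None:
        ladder = default_grid_ladder()
    pts = ps.vectors
    if pts.shape[0] < 2:
        raise ValueError("box-counting a point cloud needs at least 2 vectors")
    counts = np.array([_point_count(pts, e) for e in ladder.sizes])
    return _finish(ladder, counts, range_policy, curve=False)


def _finish(
    ladder: GridLadder,
    counts: np.ndarray,
    range_policy: Union[str, Tuple[int, int]],
    curve: bool,
) -> BoxCountResult:
    usable = counts >= 1
    if usable.sum() < MIN_FIT_POINTS:
        raise ValueError(
            f"only {int(usable.sum())} ladder sizes produced a count; "
            f"at least {MIN_FIT_POINTS} are required"
        )
    slope, intercept, rng, r2 = fit_dimension(
        ladder.sizes, counts, range_policy
    )
    if curve and not 1.0 - 0.15 <= slope <= 2.0 + 0.15:
        warnings.warn(
            f"curve dimension estimate {slope:.3f} outside the expected "
            "[1, 2] band for a planar graph",
            stacklevel=3,
        )
    return BoxCountResult(
        sizes=ladder.sizes,
        counts=counts,
        log_inv_eps=np.log(1.0 / ladder.sizes),
        log_counts=np.log(np.maximum(counts, 1)),
        slope=slope,
        intercept=intercept,
        linear_range=rng,
        r_squared=r2,
    )


def fit_dimension(
    sizes: Sequence[float],
    counts: Sequence[float],
    range_policy: Union[str, Tuple[int, int]] = "auto",
) -> Tuple[float, float, Tuple[int, int], float]:
    """OLS fit of log N_ε on log(1/ε); returns (slope, intercept, range, R²).

    ``range_policy``:

    * ``"full"`` — fit all points;
    * ``(i, j)`` — fit the inclusive index window i…j (must span ≥ 5);
    * ``"auto"`` — fit every contiguous window of ≥ 5 points and keep the
      one with maximal R², breaking ties toward the longer window and then
      toward smaller ε.  This formalizes excluding the flat shoulders that
      appear when cells are far smaller or far larger than the object.

    Windows whose log-counts are constant carry no scaling information and
    are skipped under ``auto``.
    """
    sizes = np.asarray(sizes, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if sizes.size != counts.size:
        raise ValueError("sizes and counts must have equal length")
    if sizes.size < MIN_FIT_POINTS:
        raise ValueError(f"need at least {MIN_FIT_POINTS} points")

    def ols(i: int, j: int) -> Tuple[float, float, float]:
        if np.any(counts[i : j + 1] < 1):
            raise ValueError(
                f"zero count inside fitted range [{i}, {j}]"
            )
        lx = np.log(1.0 / sizes[i : j + 1])
        ly = np.log(counts[i : j + 1])
        A = np.column_stack([lx, np.ones_like(lx)])
        coef, _, _, _ = np.linalg.lstsq(A, ly, rcond=None)
        resid = ly - A @ coef
        sst = float(np.sum((ly - ly.mean()) ** 2))
        ssr = float(resid @ resid)
        r2 = 1.0 - ssr / sst if sst > 0 else 0.0
        return float(coef[0]), float(coef[1]), r2

    m = sizes.size
    if isinstance(range_policy, tuple):
        i, j = range_policy
        if not (0 <= i <= j < m and j - i + 1 >= 2):
            raise ValueError(f"explicit range ({i}, {j}) invalid for {m} points")
        s, c, r2 = ols(i, j)
        return s, c, (i, j), r2
    if range_policy == "full":
        s, c, r2 = ols(0, m - 1)
        return s, c, (0, m - 1), r2
    if range_policy != "auto":
        raise ValueError(f"unknown range policy {range_policy!r}")

    best = None  # (r2, window length, -start index) maximized lexically
    best_fit = None
    for i in range(m):
        for j in range(i + MIN_FIT_POINTS - 1, m):
            win = counts[i : j + 1]
            if np.any(win < 1):
                continue
            ly = np.log(win)
            if np.ptp(ly) == 0:
                continue  # flat shoulder: no scaling information
            s, c, r2 = ols(i, j)
            # sizes ascend, so smaller start index = smaller ε
            key = (round(r2, 12), j - i + 1, -i)
            if best is None or key > best:
                best = key
                best_fit = (s, c, (i, j), r2)
    if best_fit is None:
        raise ValueError(
            "no contiguous window of 5+ positive, non-constant counts"
        )
    return best_fit


def select_order(
    signals: Iterable[TimeSeries],
    cfg: Optional[EmbeddingConfig] = None,
    ladder: Optional[GridLadder] = None,
) -> int:
    """Choose the AR order as ⌈mean phase-space dimension⌉ of the signals.

    Each reference signal is delay-embedded (default τ = 1, L = 20), its
    phase-space box-count slope estimated, the slopes averaged, and the
    ceiling returned (an integer average stays as is; the result is at
    least 1).  The caller decides which signals count as the "normal"
    reference collection.
    """
    if cfg is None:
        cfg = EmbeddingConfig()
    slopes = [
        box_count_points(embed_delay(s, cfg), ladder).slope for s in signals
    ]
    if not slopes:
        raise ValueError("select_order needs at least one signal")
    return max(1, int(np.ceil(np.mean(slopes))))
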