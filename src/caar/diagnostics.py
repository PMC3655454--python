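"""Signal characterization: cepstrum periodicity and lag-plot randomness.

Before fitting any forecaster it is worth knowing whether a signal carries
exploitable structure.  Two classical screens are provided:

* the **real cepstrum** — the inverse DFT of the log magnitude spectrum.
  A component of period q samples produces a harmonic comb in the
  spectrum whose regular spacing shows up as a cepstral peak at quefrency
  q; an aperiodic signal produces no outstanding peak.
* **lag plots** — the scatter of x_t against x_{t−L}.  Structure in the
  scatter (equivalently, large autocorrelation at lag L) marks the series
  as nonrandom and hence potentially predictable.

Peak significance and the randomness verdict are formalized here with
robust, scale-free thresholds (eyeballing the plots is the traditional
procedure); see the methods note for the calibration rationale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps
from scipy import stats

from .signal_io import TimeSeries

__all__ = [
    "CepstrumResult",
    "LagPlotData",
    "real_cepstrum",
    "lag_pairs",
    "randomness_verdict",
]

#: spectral magnitudes below this fraction of the maximum are floored
#: before the log, so exact spectral zeros do not produce -inf
SPECTRAL_FLOOR_REL = 1e-12

#: a cepstral peak is significant when it exceeds the band median by this
#: many robust standard deviations (normal-consistent MAD)
PEAK_MAD_MULTIPLIER = 5.0


@dataclass
class CepstrumResult:
    """Real cepstrum with detected periodicity peaks.

    ``quefrency`` is in samples; ``peaks`` holds (quefrency, value,
    prominence) triples sorted by descending prominence and restricted to
    the searched band; ``periodic`` is True iff some peak value exceeds
    ``threshold_used``.
    """

    quefrency: np.ndarray
    cepstrum: np.ndarray
    peaks: list
    periodic: bool
    threshold_used: float

    @property
    def fundamental(self) -> Optional[int]:
        """Quefrency of the most prominent peak, or None if no peak."""
        return int(self.peaks[0][0]) if self.peaks else None


@dataclass
class LagPlotData:
    """Scatter data of x_t versus x_{t-L} plus the lag-L autocorrelation."""

    lag: int
    pairs: np.ndarray  # shape (n - L, 2): columns (x_{t-L}, x_t)
    lag_autocorr: float


def real_cepstrum(
    x: TimeSeries,
    band: Optional[Tuple[int, int]] = None,
    window: bool = False,
) -> CepstrumResult:
    """Compute the real cepstrum and flag periodicity.

    The signal is mean-removed, optionally Hann-windowed (off by default),
    transformed, and the inverse DFT of the floored log magnitude spectrum
    is taken.  Peaks are searched inside ``band`` (1-based quefrency range,
    default 2 … n//2) and a peak is significant when its cepstral value
    exceeds median + 5 × MAD (MAD scaled to be a consistent estimator of a
    normal standard deviation) of the in-band cepstrum.

    Raises
    ------
    ValueError
        If the series is shorter than 8 samples or is constant (the log
        spectrum of an identically-zero signal is undefined).
    """
    v = x.values
    n = v.size
    if n < 8:
        raise ValueError("cepstrum needs at least 8 samples")
    v = v - v.mean()
    if not np.any(v):
        raise ValueError("constant signal: log spectrum undefined")
    if window:
        v = v * np.hanning(n)
    mag = np.abs(np.fft.rfft(v))
    floor = SPECTRAL_FLOOR_REL * mag.max()
    cep = np.fft.irfft(np.log(np.maximum(mag, floor)), n=n)
    quef = np.arange(n)

    lo, hi = band if band is not None else (2, n // 2)
    if not 1 <= lo < hi <= n - 1:
        raise ValueError(f"invalid quefrency band ({lo}, {hi}) for n={n}")
    seg = cep[lo : hi + 1]
    med = float(np.median(seg))
    mad = float(stats.median_abs_deviation(seg, scale="normal"))
    threshold = med + PEAK_MAD_MULTIPLIER * mad

    idx, props = sps.find_peaks(seg, prominence=0.0)
    # descending prominence, then descending value, then smaller quefrency:
    # an exactly periodic signal has equal rahmonic peaks at every multiple
    # of the period and the fundamental is the smallest of them.  Ranking
    # uses 10 relative digits so fp noise cannot break exact ties.
    peaks = [
        (int(lo + i), float(seg[i]), float(p))
        for i, p in zip(idx, props["prominences"])
    ]
    if peaks:
        scale = max(max(abs(v) for _, v, _ in peaks),
                    max(p for _, _, p in peaks), 1e-300)
        peaks.sort(
            key=lambda t: (-round(t[2] / scale, 10),
                           -round(t[1] / scale, 10), t[0])
        )
    periodic = any(val > threshold for _, val, _ in peaks)
    return CepstrumResult(
        quefrency=quef,
        cepstrum=cep,
        peaks=peaks,
        periodic=periodic,
        threshold_used=threshold,
    )


def lag_pairs(x: TimeSeries, L: int) -> LagPlotData:
    """Build the lag-L scatter (x_{t-L}, x_t) and its autocorrelation.

    The autocorrelation uses the biased (divide-by-n) estimator of the
    mean-centered series, which is bounded by 1 in magnitude.
    """
    v = x.values
    n = v.size
    if not 1 <= L < n:
        raise ValueError(f"lag {L} must satisfy 1 <= L < n={n}")
    pairs = np.column_stack([v[:-L], v[L:]])
    c = v - v.mean()
    denom = float(c @ c)
    if denom == 0.0:
        r = 0.0
    else:
        r = float(c[L:] @ c[:-L] / denom)
    return LagPlotData(lag=L, pairs=pairs, lag_autocorr=r)


def randomness_verdict(
    x: TimeSeries,
    lags: Sequence[int],
    threshold: Optional[float] = None,
) -> bool:
    """True ("random") iff |autocorrelation| < threshold at every lag.

    The default threshold is the usual 2/sqrt(n) white-noise band.  This is
    a formalization of reading a lag plot by eye: points smeared without
    linear structure correspond to in-band autocorrelations.
    """
    if not lags:
        raise ValueError("at least one lag is required")
    n = len(x)
    thr = 2.0 / np.sqrt(n) if threshold is None else float(threshold)
    return all(abs(lag_pairs(x, L).lag_autocorr) < thr for L in lags)
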