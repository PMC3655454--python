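"""Synthetic signal generators with known structure.

Everything downstream — the cepstrum diagnostics, the box-counting
dimension estimator, the sign-coerced forecaster — is exercised against
signals produced here, so each generator is a pure, seeded function whose
statistical properties are known in closed form:

* :func:`gen_ar` — a stationary AR(p) process (parameter-recovery fixture);
* :func:`gen_sine` — a noisy sinusoid (periodicity fixture);
* :func:`gen_random_walk` — the unit-root special case of AR(1);
* :func:`gen_weierstrass` — a deterministic curve whose graph has
  box-counting dimension exactly ``2 + ln(a)/ln(b)``;
* :func:`simulate_rc_process` — the random-coefficient autoregression in
  which every lag weight is an i.i.d. two-point ±θ draw;
* :func:`gen_sign_coerced_ar` — forward simulation of the sign-coerced
  AR recursion itself (coefficients constrained to ±1), used for
  identifiability and head-to-head forecasting studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .signal_io import TimeSeries

__all__ = [
    "RCSimConfig",
    "RCSimResult",
    "gen_ar",
    "gen_sine",
    "gen_random_walk",
    "gen_weierstrass",
    "gen_sign_coerced_ar",
    "simulate_rc_process",
]


def gen_ar(
    coeffs: Sequence[float],
    intercept: float = 0.0,
    noise_sd: float = 1.0,
    length: int = 1000,
    seed: int = 0,
    burn_in: int = 500,
    check_stationary: bool = True,
) -> TimeSeries:
    """Simulate an AR(p) process x_t = c + Σ φ_i x_{t-i} + ε_t.

    The process starts at its stationary mean c / (1 - Σφ) and the first
    ``burn_in`` samples are discarded so transients are washed out.

    Raises
    ------
    ValueError
        If ``check_stationary`` and any root of the characteristic
        polynomial lies on or outside the unit circle (the message reports
        the offending root modulus).
    """
    phi = np.asarray(coeffs, dtype=float)
    p = phi.size
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if length < 1:
        raise ValueError("length must be positive")
    if p and check_stationary:
        # roots of z^p - phi_1 z^{p-1} - ... - phi_p
        roots = np.roots(np.concatenate([[1.0], -phi]))
        worst = float(np.max(np.abs(roots))) if roots.size else 0.0
        if worst >= 1.0:
            raise ValueError(
                f"AR coefficients are nonstationary: characteristic root "
                f"modulus {worst:.6g} >= 1"
            )
    rng = np.random.default_rng(seed)
    n = length + burn_in
    eps = rng.normal(0.0, noise_sd, size=n)
    if p == 0:
        return TimeSeries(intercept + eps[burn_in:], label="ar0")
    phisum = float(phi.sum())
    mean = intercept / (1.0 - phisum) if abs(1.0 - phisum) > 1e-12 else 0.0
    x = np.empty(n + p)
    x[:p] = mean
    for t in range(p, n + p):
        x[t] = intercept + phi @ x[t - p : t][::-1] + eps[t - p]
    return TimeSeries(x[p + burn_in :], label=f"ar{p}")


def gen_sine(
    period_samples: float,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    length: int = 1000,
    seed: int = 0,
) -> TimeSeries:
    """x_t = amplitude * sin(2π t / period) + Gaussian noise, t = 1..length."""
    if period_samples < 2:
        raise ValueError(
            f"period_samples={period_samples} < 2 would alias at this rate"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = np.arange(1, length + 1, dtype=float)
    x = amplitude * np.sin(2.0 * np.pi * t / period_samples)
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0.0, noise_sd, size=length)
    return TimeSeries(x, label=f"sine{period_samples:g}")


def gen_random_walk(
    step_sd: float,
    drift: float = 0.0,
    length: int = 1000,
    seed: int = 0,
) -> TimeSeries:
    """Random walk x_t = x_{t-1} + drift + N(0, step_sd²), x_0 = 0."""
    if step_sd <= 0:
        raise ValueError("step_sd must be positive")
    if length < 1:
        raise ValueError("length must be positive")
    steps = drift + np.random.default_rng(seed).normal(0.0, step_sd, size=length)
    return TimeSeries(np.cumsum(steps), label="walk")


def gen_weierstrass(
    a: float,
    b: float,
    n_terms: Optional[int] = None,
    length: int = 4096,
) -> TimeSeries:
    """Sample the Weierstrass function W(t) = Σ_k a^k cos(b^k π t) on [0, 2].

    For 0 < a < 1, b > 1 and a·b > 1 the graph of W is a fractal with
    box-counting dimension 2 + ln(a)/ln(b).  ``n_terms`` defaults to the
    smallest k with a^k < 1e-6, so the truncation error is negligible
    against that dimension.  Deterministic (no seed).
    """
    if not 0 < a < 1:
        raise ValueError("a must lie in (0, 1)")
    if b <= 1:
        raise ValueError("b must exceed 1")
    if a * b <= 1:
        raise ValueError(
            f"a*b = {a * b:.6g} <= 1: the graph is rectifiable, not fractal"
        )
    if n_terms is None:
        n_terms = int(np.ceil(np.log(1e-6) / np.log(a)))
    if n_terms < 1:
        raise ValueError("n_terms must be positive")
    t = np.linspace(0.0, 2.0, length)
    k = np.arange(n_terms + 1)
    # sum smallest terms first for fp accuracy
    w = np.zeros(length)
    for kk in k[::-1]:
        w += a**kk * np.cos(b**kk * np.pi * t)
    return TimeSeries(w, label=f"weierstrass(a={a:g},b={b:g})")


def gen_sign_coerced_ar(
    signs: Sequence[int],
    intercept: float = 0.0,
    noise_sd: float = 0.1,
    length: int = 600,
    seed: int = 0,
) -> TimeSeries:
    """Simulate x_t = c + Σ s_i x_{t-i} + ε_t with fixed coefficients s_i = ±1.

    This is the data-generating counterpart of the sign-coerced AR
    forecaster: every coefficient has magnitude one and the first must be
    +1.  Such processes are never stationary (the characteristic roots have
    product modulus 1), so most sign patterns are explosive; patterns whose
    characteristic roots all sit on the unit circle — e.g. (+1, +1, −1) or
    (+1, −1, +1) at order 3 — grow only polynomially and are the usable
    simulation targets.  ``noise_sd`` = 0 gives a deterministic recursion
    from a small random initial condition, which is the exact-recovery
    fixture for the forecaster.
    """
    s = np.asarray(signs, dtype=float)
    if s.size < 1 or not np.all(np.isin(s, (-1.0, 1.0))):
        raise ValueError("signs must be a non-empty vector of +1/-1")
    if s[0] != 1.0:
        raise ValueError("first sign must be +1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    p = s.size
    rng = np.random.default_rng(seed)
    x = np.empty(length + p)
    x[:p] = rng.normal(0.0, 1.0, size=p)  # generic initial condition
    eps = (
        rng.normal(0.0, noise_sd, size=length)
        if noise_sd > 0
        else np.zeros(length)
    )
    for t in range(p, length + p):
        x[t] = intercept + s @ x[t - p : t][::-1] + eps[t - p]
    return TimeSeries(x[p:], label=f"scar{p}")


@dataclass(frozen=True)
class RCSimConfig:
    """Configuration of the cumulative random-coefficient process.

    Each lag of the recursion x_t = Σ_{i=1}^p φ_{ti} x_{t-i} + ε_t carries
    an independent two-point coefficient φ that equals ``+theta`` with
    probability ``alpha`` and ``-theta`` otherwise; the constraints
    0 ≤ θ < ∞ and 0 < α < 1 are enforced.  The seed fully determines the
    output.
    """

    theta: float
    alpha: float
    order_p: int = 1
    noise_sd: float = 1.0
    length: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.theta < np.inf:
            raise ValueError("theta must satisfy 0 <= theta < inf")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly in (0, 1)")
        if self.order_p < 1:
            raise ValueError("order_p must be a positive integer")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.length < 1:
            raise ValueError("length must be positive")


@dataclass
class RCSimResult:
    """Output of :func:`simulate_rc_process`.

    ``coefficients`` has shape (length, p): row t−1 holds the realized ±θ
    coefficients (φ_{t1} … φ_{tp}) that produced x_t, so oracle tests can
    reconstruct the recursion from noise and coefficients exactly.
    """

    series: TimeSeries
    coefficients: np.ndarray
    noise: np.ndarray

    def all_coefficients(self) -> np.ndarray:
        """All realized coefficient draws, flattened (for moment checks)."""
        return self.coefficients.ravel()


def simulate_rc_process(cfg: RCSimConfig) -> RCSimResult:
    """Simulate x_t = Σ_{i=1}^p φ_{ti} x_{t-i} + ε_t with i.i.d. two-point φ.

    A fresh coefficient vector is drawn at every time step, each entry +θ
    with probability α and −θ otherwise.  Unrolling the recursion shows
    every past noise term enters x_t with an accumulated ±θ^k weight, so
    with θ = 1 the process generalizes the random walk: each accumulated
    jump goes up or down according to the realized signs.  θ = 0
    degenerates to pure white noise.  The process starts from zeros.

    The realized coefficients and the noise sequence are returned alongside
    the series so tests can verify the recursion identity directly.
    """
    rng = np.random.default_rng(cfg.seed)
    p = cfg.order_p
    eps = rng.normal(0.0, cfg.noise_sd, size=cfg.length)
    coeffs = np.where(
        rng.random((cfg.length, p)) < cfg.alpha, cfg.theta, -cfg.theta
    )
    x = np.zeros(cfg.length + p)  # p zero pre-samples
    for t in range(cfg.length):
        x[t + p] = coeffs[t] @ x[t : t + p][::-1] + eps[t]
    return RCSimResult(
        series=TimeSeries(x[p:], label="rcproc"),
        coefficients=coeffs,
        noise=eps,
    )
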