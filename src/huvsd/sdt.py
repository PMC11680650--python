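"""Deterministic Gaussian signal-detection mathematics.

The unequal-variance signal detection (UVSD) model places a noise
distribution N(-d/2, sigma_n^2) and a signal distribution N(+d/2, sigma_s^2)
on a common latent decision axis.  A "Yes" response occurs whenever the
latent strength exceeds the criterion ``c``, measured as a deviation from
the midpoint between the two distribution means.  The noise standard
deviation is the unit of the axis (sigma_n = 1); the signal standard
deviation sigma_s is free, so the model can represent asymmetric ROCs.

This module implements the rate/parameter transforms, the bivariate-normal
moments of z-transformed hit and false-alarm rates implied by a population
of participants with independent normal sensitivity d_i and criterion c_i,
the closed-form moment estimator that inverts those moments, and the
z-ROC / ROC / AUC analytics.  Everything here is pure and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "IndividualParams",
    "PopulationParams",
    "RatePair",
    "MomentSummary",
    "MomentEstimationError",
    "rates_from_params",
    "params_from_rates",
    "moment_map",
    "moment_estimate",
    "empirical_moments",
    "corrected_rates",
    "zroc_line",
    "roc_curve",
    "auc",
]


@dataclass(frozen=True)
class IndividualParams:
    """Latent sensitivity and criterion of one participant.

    ``d`` is the distance between the signal and noise distribution means in
    noise-SD units; negative values represent below-chance responders.
    ``c`` is the response criterion, measured from the midpoint between the
    two means (0 = unbiased).
    """

    d: float
    c: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d) and math.isfinite(self.c)):
            raise ValueError("d and c must be finite")


@dataclass(frozen=True)
class PopulationParams:
    """Population-level parameters of the hierarchical SDT model.

    Sensitivity d_i ~ N(mu_d, sigma_d^2) and criterion c_i ~ N(mu_c,
    sigma_c^2) independently across participants; all participants share the
    signal SD ``sigma_s``.  The noise SD is the scale unit and is fixed at 1.
    """

    mu_d: float
    mu_c: float
    sigma_d: float
    sigma_c: float
    sigma_s: float
    sigma_n: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_d < 0 or self.sigma_c < 0:
            raise ValueError("population SDs cannot be negative")
        if self.sigma_s <= 0:
            raise ValueError("sigma_s must be positive")
        if self.sigma_n != 1.0:
            raise ValueError("the noise SD is the scale unit and must be 1")

    @property
    def lambda_d(self) -> float:
        """Precision of the sensitivity distribution."""
        return self.sigma_d**-2

    @property
    def lambda_c(self) -> float:
        """Precision of the criterion distribution."""
        return self.sigma_c**-2


@dataclass(frozen=True)
class RatePair:
    """A hit rate / false-alarm rate pair, strictly inside (0, 1)."""

    theta_h: float
    theta_f: float

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_h < 1.0 and 0.0 < self.theta_f < 1.0):
            raise ValueError("rates must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class MomentSummary:
    """First and second moments of z-transformed hit/false-alarm rates.

    Either model-implied (``n`` is None) or computed from data with the
    unbiased (n-1) variance/covariance convention.
    """

    mean_zh: float
    mean_zf: float
    var_zh: float
    var_zf: float
    cov_zhzf: float
    n: int | None = None

    def __post_init__(self) -> None:
        if self.var_zh < 0 or self.var_zf < 0:
            raise ValueError("variances must be non-negative")
        if self.cov_zhzf**2 > self.var_zh * self.var_zf * (1 + 1e-12):
            raise ValueError("covariance violates Cauchy-Schwarz")
        if self.n is not None and self.n < 2:
            raise ValueError("need at least 2 participants for moments")


class MomentEstimationError(ValueError):
    """Raised when the moment equations have no valid solution.

    Carries the name and value of the offending implied quantity.
    """

    def __init__(self, quantity: str, value: float):
        self.quantity = quantity
        self.value = value
        super().__init__(f"implied {quantity} = {value:.6g} is not positive")


def _check_scales(sigma_s: float, sigma_n: float) -> None:
    if sigma_s <= 0 or sigma_n <= 0:
        raise ValueError("sigma_s and sigma_n must be positive")


def rates_from_params(
    p: IndividualParams, sigma_s: float, sigma_n: float = 1.0
) -> RatePair:
    """Map (d, c) to the implied hit and false-alarm rates.

    theta_h = Phi((d/2 - c)/sigma_s), theta_f = Phi((-d/2 - c)/sigma_n):
    the areas beyond the criterion under the signal and noise distribution.
    """
    _check_scales(sigma_s, sigma_n)
    theta_h = ndtr((0.5 * p.d - p.c) / sigma_s)
    theta_f = ndtr((-0.5 * p.d - p.c) / sigma_n)
    return RatePair(float(theta_h), float(theta_f))


def params_from_rates(
    r: RatePair, sigma_s: float, sigma_n: float = 1.0
) -> IndividualParams:
    """Invert :func:`rates_from_params` for a rate pair in the open unit square.

    d = sigma_s z(theta_h) - sigma_n z(theta_f);
    c = -(sigma_s z(theta_h) + sigma_n z(theta_f)) / 2.

    Rates of exactly 0 or 1 are rejected (z would be infinite); any edge
    policy belongs to the caller — see :func:`corrected_rates`.
    """
    _check_scales(sigma_s, sigma_n)
    zh = ndtri(r.theta_h)
    zf = ndtri(r.theta_f)
    return IndividualParams(
        d=float(sigma_s * zh - sigma_n * zf),
        c=float(-0.5 * (sigma_s * zh + sigma_n * zf)),
    )


def moment_map(pop: PopulationParams) -> MomentSummary:
    """Model-implied moments of the z-transformed rates.

    With independent normal d_i and c_i, the pair (z(theta_h_i),
    z(theta_f_i)) is bivariate normal with

        mean_zh = (mu_d/2 - mu_c)/sigma_s      mean_zf = -mu_d/2 - mu_c
        var_zh  = (sigma_c^2 + sigma_d^2/4)/sigma_s^2
        var_zf  =  sigma_c^2 + sigma_d^2/4
        cov     = (sigma_c^2 - sigma_d^2/4)/sigma_s

    These five observable moments identify the five population parameters.
    """
    vc, vd = pop.sigma_c**2, pop.sigma_d**2
    return MomentSummary(
        mean_zh=(0.5 * pop.mu_d - pop.mu_c) / pop.sigma_s,
        mean_zf=-0.5 * pop.mu_d - pop.mu_c,
        var_zh=(vc + vd / 4.0) / pop.sigma_s**2,
        var_zf=vc + vd / 4.0,
        cov_zhzf=(vc - vd / 4.0) / pop.sigma_s,
    )


def moment_estimate(m: MomentSummary) -> PopulationParams:
    """Closed-form inversion of :func:`moment_map`.

    The signal SD is the square root of the variance ratio
    var[z(theta_f)] / var[z(theta_h)]; the remaining parameters follow by
    substitution.  Exact algebraic inverse on model-implied moments; on
    sample moments it is a consistent method-of-moments estimator.

    Raises
    ------
    MomentEstimationError
        If an implied variance is not positive (e.g. |cov| too large
        relative to the variances in noisy sample moments).
    """
    if m.var_zh <= 0:
        raise MomentEstimationError("var_zh", m.var_zh)
    sigma_s = math.sqrt(m.var_zf / m.var_zh)
    sigma_c2 = 0.5 * (m.var_zf + sigma_s * m.cov_zhzf)
    sigma_d2 = 2.0 * (m.var_zf - sigma_s * m.cov_zhzf)
    if sigma_c2 <= 0:
        raise MomentEstimationError("sigma_c^2", sigma_c2)
    if sigma_d2 <= 0:
        raise MomentEstimationError("sigma_d^2", sigma_d2)
    return PopulationParams(
        mu_d=sigma_s * m.mean_zh - m.mean_zf,
        mu_c=-0.5 * (sigma_s * m.mean_zh + m.mean_zf),
        sigma_d=math.sqrt(sigma_d2),
        sigma_c=math.sqrt(sigma_c2),
        sigma_s=sigma_s,
    )


def corrected_rates(
    h: np.ndarray, f: np.ndarray, s: np.ndarray, n: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Edge-stabilised empirical rates (h + 0.5)/(s + 1), (f + 0.5)/(n + 1).

    Keeps the z-transform finite when a participant scores 0 or all trials;
    used only by the moment estimator, never by the Bayesian model (whose
    rates are latent and need no correction).
    """
    h, f, s, n = (np.asarray(a, dtype=float) for a in (h, f, s, n))
    return (h + 0.5) / (s + 1.0), (f + 0.5) / (n + 1.0)


def empirical_moments(theta_h: np.ndarray, theta_f: np.ndarray) -> MomentSummary:
    """Sample moments of z-transformed rates, unbiased (n-1) convention."""
    zh = ndtri(np.asarray(theta_h, dtype=float))
    zf = ndtri(np.asarray(theta_f, dtype=float))
    if not (np.all(np.isfinite(zh)) and np.all(np.isfinite(zf))):
        raise ValueError("rates at 0 or 1: apply corrected_rates first")
    if zh.shape != zf.shape or zh.ndim != 1 or zh.size < 2:
        raise ValueError("need matching 1-d arrays with at least 2 entries")
    cov = np.cov(zh, zf, ddof=1)
    return MomentSummary(
        mean_zh=float(zh.mean()),
        mean_zf=float(zf.mean()),
        var_zh=float(cov[0, 0]),
        var_zf=float(cov[1, 1]),
        cov_zhzf=float(cov[0, 1]),
        n=zh.size,
    )


def zroc_line(mu_d: float, sigma_s: float) -> tuple[float, float]:
    """Slope and intercept of the z-ROC: z(theta_h) = z(theta_f)/sigma_s + mu_d/sigma_s.

    Returns ``(slope, intercept)`` with slope = 1/sigma_s and intercept =
    mu_d/sigma_s; the line crosses the x-axis at -mu_d.  A slope below 1
    diagnoses sigma_s > 1 (the classic asymmetric-ROC signature).
    """
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    return 1.0 / sigma_s, mu_d / sigma_s


def roc_curve(mu_d: float, sigma_s: float, grid: np.ndarray) -> np.ndarray:
    """ROC points (theta_f, theta_h) over a grid of false-alarm rates.

    theta_h = Phi((z(theta_f) + mu_d)/sigma_s); monotone nondecreasing.
    """
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise ValueError("grid values must lie strictly inside (0, 1)")
    theta_h = ndtr((ndtri(grid) + mu_d) / sigma_s)
    return np.column_stack([grid, theta_h])


def auc(mu_d: float, sigma_s: float) -> float:
    """Area under the ROC curve: Phi(mu_d / sqrt(1 + sigma_s^2)).

    The probability that a random signal draw exceeds an independent random
    noise draw; 0.5 at chance, approaching 1 as mu_d grows.
    """
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    return float(ndtr(mu_d / math.hypot(1.0, sigma_s)))
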