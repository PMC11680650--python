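"""Likelihood, priors, and joint log-posterior for the hierarchical models.

Three variants share one latent structure:

* ``huvsd``  — hierarchical unequal-variance model: five population
  parameters (mu_d, mu_c, lambda_d, lambda_c, sigma_s), noise SD fixed at 1.
* ``hevsd``  — equal-variance baseline: sigma_s pinned to 1.
* ``hevsd_expanded`` — the linearly expanded equal-variance model with
  auxiliary scale factors xi_d, xi_c in (0, 1) and per-participant
  deviations delta, so d_i = mu_d + xi_d * delta_d_i (and likewise for c).

The data are per-participant binomial counts: h_i hits out of s_i signal
trials and f_i false alarms out of n_i noise trials, with success
probabilities given by the Gaussian rate map of :mod:`huvsd.sdt`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import gammaln, ndtr, xlog1py, xlogy

__all__ = [
    "TrialCounts",
    "ModelSpec",
    "LatentState",
    "RATE_CLAMP",
    "counts_arrays",
    "rate_arrays",
    "binomial_loglik_terms",
    "log_likelihood",
    "log_prior",
    "log_posterior",
]

# Latent rates are clamped to [RATE_CLAMP, 1 - RATE_CLAMP] inside the
# likelihood so extreme latent states stay finite during early MCMC.
RATE_CLAMP = 1e-12

Variant = Literal["huvsd", "hevsd", "hevsd_expanded"]


@dataclass(frozen=True)
class TrialCounts:
    """Observed counts for one participant.

    ``h`` hits out of ``s`` signal trials, ``f`` false alarms out of ``n``
    noise trials.  Zero-trial rows are tolerated (they carry no likelihood
    information), which permits prior-only sampling runs.
    """

    participant_id: str | int
    h: int
    f: int
    s: int
    n: int

    def __post_init__(self) -> None:
        if self.s < 0 or self.n < 0:
            raise ValueError("trial totals cannot be negative")
        if not (0 <= self.h <= self.s):
            raise ValueError(f"need 0 <= h <= s, got h={self.h}, s={self.s}")
        if not (0 <= self.f <= self.n):
            raise ValueError(f"need 0 <= f <= n, got f={self.f}, n={self.n}")


@dataclass(frozen=True)
class ModelSpec:
    """Model variant plus hyperprior settings.

    Defaults follow the weakly-informative scheme of the hierarchical SDT
    literature: N(0, 1000) (variance 1000) on the population means,
    gamma(0.5, 0.5) on the precisions (gamma(0.1, 0.1) for the expanded
    equal-variance variant), and a normal prior on the signal *variance*
    sigma_s^2 centred on 1 — i.e. on equal variance — truncated to (0, inf).
    ``sigma_s2_scale_is_sd`` switches the truncated normal's second
    parameter from variance 2 (default) to SD 2.
    """

    variant: Variant = "huvsd"
    prior_mu_var: float = 1000.0
    prior_precision: tuple[float, float] | None = None  # (shape, rate)
    prior_sigma_s2: Literal["truncnorm", "gamma", "uniform"] = "truncnorm"
    sigma_s2_loc: float = 1.0
    sigma_s2_scale: float = 2.0
    sigma_s2_scale_is_sd: bool = False
    uniform_upper: float = 5.0

    def __post_init__(self) -> None:
        if self.variant not in ("huvsd", "hevsd", "hevsd_expanded"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.prior_precision is None:
            default = (0.1, 0.1) if self.variant == "hevsd_expanded" else (0.5, 0.5)
            object.__setattr__(self, "prior_precision", default)

    @property
    def equal_variance(self) -> bool:
        return self.variant != "huvsd"

    @property
    def expanded(self) -> bool:
        return self.variant == "hevsd_expanded"

    def sigma_s2_var(self) -> float:
        """Variance of the truncated-normal sigma_s^2 prior."""
        s = self.sigma_s2_scale
        return s * s if self.sigma_s2_scale_is_sd else s


@dataclass
class LatentState:
    """One point in the parameter space of a model variant.

    For the expanded variant, ``d`` and ``c`` are derived views that must
    satisfy d = mu_d + xi_d * delta_d (checked on construction via
    :meth:`from_expanded`).
    """

    d: np.ndarray
    c: np.ndarray
    mu_d: float
    mu_c: float
    lam_d: float
    lam_c: float
    sigma_s: float = 1.0
    xi_d: float | None = None
    xi_c: float | None = None
    delta_d: np.ndarray | None = field(default=None, repr=False)
    delta_c: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        if self.d.shape != self.c.shape:
            raise ValueError("d and c must have matching shapes")

    @classmethod
    def from_expanded(
        cls,
        delta_d: np.ndarray,
        delta_c: np.ndarray,
        mu_d: float,
        mu_c: float,
        lam_d: float,
        lam_c: float,
        xi_d: float,
        xi_c: float,
    ) -> "LatentState":
        delta_d = np.asarray(delta_d, dtype=float)
        delta_c = np.asarray(delta_c, dtype=float)
        return cls(
            d=mu_d + xi_d * delta_d,
            c=mu_c + xi_c * delta_c,
            mu_d=mu_d,
            mu_c=mu_c,
            lam_d=lam_d,
            lam_c=lam_c,
            sigma_s=1.0,
            xi_d=xi_d,
            xi_c=xi_c,
            delta_d=delta_d,
            delta_c=delta_c,
        )

    @property
    def n_participants(self) -> int:
        return self.d.size


def counts_arrays(
    counts: Sequence[TrialCounts],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack a count list into (h, f, s, n) integer arrays."""
    h = np.array([t.h for t in counts], dtype=float)
    f = np.array([t.f for t in counts], dtype=float)
    s = np.array([t.s for t in counts], dtype=float)
    n = np.array([t.n for t in counts], dtype=float)
    return h, f, s, n


def rate_arrays(
    d: np.ndarray, c: np.ndarray, sigma_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised rate map with the likelihood clamp applied."""
    theta_h = ndtr((0.5 * d - c) / sigma_s)
    theta_f = ndtr(-0.5 * d - c)
    lo, hi = RATE_CLAMP, 1.0 - RATE_CLAMP
    return np.clip(theta_h, lo, hi), np.clip(theta_f, lo, hi)


def binomial_loglik_terms(
    k: np.ndarray, m: np.ndarray, theta: np.ndarray, normalised: bool = True
) -> np.ndarray:
    """log Binomial(k | m, theta) elementwise; constants optional."""
    out = xlogy(k, theta) + xlog1py(m - k, -theta)
    if normalised:
        out = out + gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)
    return out


def log_likelihood(counts: Sequence[TrialCounts], state: LatentState) -> float:
    """Joint binomial log-likelihood of all hit and false-alarm counts."""
    h, f, s, n = counts_arrays(counts)
    if h.size != state.n_participants:
        raise ValueError(
            f"state has {state.n_participants} participants, data has {h.size}"
        )
    theta_h, theta_f = rate_arrays(state.d, state.c, state.sigma_s)
    ll = binomial_loglik_terms(h, s, theta_h) + binomial_loglik_terms(f, n, theta_f)
    return float(ll.sum())


def _norm_logpdf(x, mean, var):
    return -0.5 * (math.log(2.0 * math.pi * var) + (x - mean) ** 2 / var)


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    if x <= 0:
        return -math.inf
    return (
        shape * math.log(rate)
        - math.lgamma(shape)
        + (shape - 1.0) * math.log(x)
        - rate * x
    )


def log_sigma_s_prior(sigma_s: float, spec: ModelSpec) -> float:
    """Log prior density of sigma_s induced by the prior on sigma_s^2.

    The prior is placed on the signal variance v = sigma_s^2; the sampler
    works on sigma_s, so the change-of-variables Jacobian dv/d sigma_s =
    2 sigma_s is included.  The truncated normal's renormalisation constant
    is dropped (constant in the parameter).
    """
    if sigma_s <= 0:
        return -math.inf
    v = sigma_s * sigma_s
    if spec.prior_sigma_s2 == "truncnorm":
        lp = _norm_logpdf(v, spec.sigma_s2_loc, spec.sigma_s2_var())
    elif spec.prior_sigma_s2 == "gamma":
        lp = _gamma_logpdf(v, 0.5, 0.5)
    elif spec.prior_sigma_s2 == "uniform":
        if v >= spec.uniform_upper:
            return -math.inf
        lp = -math.log(spec.uniform_upper)
    else:  # pragma: no cover
        raise ValueError(spec.prior_sigma_s2)
    return lp + math.log(2.0 * sigma_s)


def log_prior(state: LatentState, spec: ModelSpec) -> float:
    """Joint log prior of the latent state under the given model variant.

    Returns -inf outside the support (non-positive precisions or sigma_s,
    xi outside (0, 1)).
    """
    if state.lam_d <= 0 or state.lam_c <= 0:
        return -math.inf
    a, b = spec.prior_precision
    lp = _norm_logpdf(state.mu_d, 0.0, spec.prior_mu_var)
    lp += _norm_logpdf(state.mu_c, 0.0, spec.prior_mu_var)
    lp += _gamma_logpdf(state.lam_d, a, b)
    lp += _gamma_logpdf(state.lam_c, a, b)

    if spec.expanded:
        if state.xi_d is None or state.xi_c is None or state.delta_d is None:
            raise ValueError("expanded variant requires xi and delta fields")
        if not (0.0 < state.xi_d < 1.0 and 0.0 < state.xi_c < 1.0):
            return -math.inf
        # xi ~ beta(1, 1): log density 0 on (0, 1)
        lp += float(_norm_logpdf(state.delta_d, 0.0, 1.0 / state.lam_d).sum())
        lp += float(_norm_logpdf(state.delta_c, 0.0, 1.0 / state.lam_c).sum())
        if abs(state.sigma_s - 1.0) > 1e-12:
            return -math.inf
        return lp

    lp += float(_norm_logpdf(state.d, state.mu_d, 1.0 / state.lam_d).sum())
    lp += float(_norm_logpdf(state.c, state.mu_c, 1.0 / state.lam_c).sum())
    if spec.variant == "huvsd":
        lp += log_sigma_s_prior(state.sigma_s, spec)
    elif abs(state.sigma_s - 1.0) > 1e-12:
        return -math.inf
    return lp


def log_posterior(
    counts: Sequence[TrialCounts], state: LatentState, spec: ModelSpec
) -> float:
    """log_likelihood + log_prior; -inf propagates from either term."""
    lp = log_prior(state, spec)
    if not math.isfinite(lp):
        return -math.inf
    return lp + log_likelihood(counts, state)
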