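"""Metropolis-within-Gibbs sampler with diagnostics and information criteria.

The posterior factorises conveniently: conditional on the individual
(d_i, c_i), the four population hyperparameters (mu_d, mu_c, lambda_d,
lambda_c) have conjugate normal/gamma full conditionals and are updated by
exact Gibbs draws.  The individual (d_i, c_i) pairs — whose full
conditionals involve the binomial likelihood — are updated by a joint
random-walk Metropolis step, vectorised across participants with a
per-participant proposal scale.  The signal SD sigma_s gets a scalar
adaptive random-walk step.  Proposal scales adapt by Robbins-Monro during
burn-in only (toward 0.23 acceptance for the bivariate block, 0.44 for
scalars) and are frozen afterwards, preserving detailed balance.

One master seed spawns independent per-chain bit streams, so results are
bit-reproducible given (data, spec, config).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, ndtr, xlog1py, xlogy

from .model import (
    ModelSpec,
    TrialCounts,
    counts_arrays,
    log_sigma_s_prior,
    RATE_CLAMP,
)
from .sdt import corrected_rates

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "conjugate_mu_posterior",
    "conjugate_lambda_posterior",
    "sample",
    "gelman_rubin",
    "split_rhat",
    "effective_sample_size",
    "dic",
    "waic",
    "pointwise_loglik",
    "summary",
    "draws_long_frame",
]

_TARGET_BLOCK = 0.23  # optimal-ish acceptance for a 2-d random-walk block
_TARGET_SCALAR = 0.44
_N_INTERWEAVE = 5  # repetitions of the likelihood-free sigma_s scale move
_N_DC_UPDATES = 2  # repetitions of the (d_i, c_i) block update per iteration


def conjugate_mu_posterior(
    values: np.ndarray, lam: float, prior_var: float
) -> tuple[float, float]:
    """Normal full conditional of a population mean.

    With x_i ~ N(mu, 1/lam) and mu ~ N(0, prior_var):
    precision = 1/prior_var + N lam, mean = lam * sum(x) / precision.
    Returns (mean, sd).
    """
    prec = 1.0 / prior_var + values.size * lam
    return lam * float(values.sum()) / prec, math.sqrt(1.0 / prec)


def conjugate_lambda_posterior(
    values: np.ndarray, mu: float, shape: float, rate: float
) -> tuple[float, float]:
    """Gamma full conditional of a precision.

    With x_i ~ N(mu, 1/lam) and lam ~ gamma(shape, rate):
    posterior shape = shape + N/2, rate = rate + sum((x - mu)^2)/2.
    Returns (shape, rate).
    """
    return shape + 0.5 * values.size, rate + 0.5 * float(((values - mu) ** 2).sum())


@dataclass(frozen=True)
class SamplerConfig:
    """Chain-management settings.

    Defaults mirror the simulation regime used throughout: 4 chains of
    10,000 iterations with the first 4,000 discarded as burn-in and the
    precisions lambda_d, lambda_c randomly initialised from their prior
    (clipped to [0.1, 100] so a heavy-tailed draw cannot strand a chain).
    """

    chains: int = 4
    iterations: int = 10_000
    burn_in: int = 4_000
    seed: int = 0
    init_jitter: float = 0.05
    lambda_init_clip: tuple[float, float] = (0.1, 100.0)

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")


@dataclass
class PosteriorSamples:
    """Post-burn-in draws of every parameter, indexed (chain, draw, param)."""

    names: list[str]
    draws: np.ndarray  # (chains, draws, n_params)
    variant: str
    n_participants: int
    acceptance: dict[str, float] = field(default_factory=dict)
    config: SamplerConfig | None = None

    def __post_init__(self) -> None:
        self._index = {name: i for i, name in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter as a (chains, draws) array."""
        return self.draws[:, :, self._index[name]]

    def posterior_mean(self, name: str) -> float:
        return float(self.get(name).mean())

    def posterior_sd(self, name: str) -> float:
        return float(self.get(name).std(ddof=1))

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.get(name), [a, 1.0 - a])
        return float(lo), float(hi)

    def individual_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Posterior-mean d_i and c_i vectors."""
        d = np.array([self.posterior_mean(f"d[{i}]") for i in range(self.n_participants)])
        c = np.array([self.posterior_mean(f"c[{i}]") for i in range(self.n_participants)])
        return d, c

    def _dc_sigma_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flattened (S, N) d and c draws plus (S,) sigma_s draws."""
        n = self.n_participants
        d_idx = [self._index[f"d[{i}]"] for i in range(n)]
        c_idx = [self._index[f"c[{i}]"] for i in range(n)]
        flat = self.draws.reshape(-1, self.draws.shape[2])
        return (
            flat[:, d_idx],
            flat[:, c_idx],
            flat[:, self._index["sigma_s"]],
        )


def _init_chain(
    rng: np.random.Generator,
    h: np.ndarray,
    f: np.ndarray,
    s: np.ndarray,
    n: np.ndarray,
    spec: ModelSpec,
    cfg: SamplerConfig,
) -> dict:
    """Data-informed start for (d, c); prior draws for the precisions."""
    a, b = spec.prior_precision
    lo, hi = cfg.lambda_init_clip
    lam_d = float(np.clip(rng.gamma(a, 1.0 / b), lo, hi))
    lam_c = float(np.clip(rng.gamma(a, 1.0 / b), lo, hi))
    th, tf = corrected_rates(h, f, s, n)
    from scipy.special import ndtri

    zh, zf = ndtri(th), ndtri(tf)
    d0 = zh - zf + cfg.init_jitter * rng.standard_normal(h.size)
    c0 = -0.5 * (zh + zf) + cfg.init_jitter * rng.standard_normal(h.size)
    sigma_s = 1.0
    if spec.variant == "huvsd":
        sigma_s = float(abs(1.0 + 0.1 * rng.standard_normal()))
    state = {
        "d": d0,
        "c": c0,
        "mu_d": float(d0.mean()) if d0.size else 0.0,
        "mu_c": float(c0.mean()) if c0.size else 0.0,
        "lam_d": lam_d,
        "lam_c": lam_c,
        "sigma_s": sigma_s,
    }
    if spec.expanded:
        state["xi_d"] = float(rng.uniform(0.3, 0.9))
        state["xi_c"] = float(rng.uniform(0.3, 0.9))
        state["delta_d"] = (d0 - state["mu_d"]) / state["xi_d"]
        state["delta_c"] = (c0 - state["mu_c"]) / state["xi_c"]
    return state


def _loglik_parts(d, c, sigma_s, h, f, s, n):
    """Unnormalised binomial log-likelihood, split into hit/FA parts."""
    lo, hi = RATE_CLAMP, 1.0 - RATE_CLAMP
    th = np.clip(ndtr((0.5 * d - c) / sigma_s), lo, hi)
    tf = np.clip(ndtr(-0.5 * d - c), lo, hi)
    llh = xlogy(h, th) + xlog1py(s - h, -th)
    llf = xlogy(f, tf) + xlog1py(n - f, -tf)
    return llh, llf


def _run_chain_plain(
    rng: np.random.Generator,
    h,
    f,
    s,
    n,
    spec: ModelSpec,
    cfg: SamplerConfig,
    store: np.ndarray,
) -> dict[str, float]:
    """hUVSD or plain hEVSD chain; fills ``store`` (draws, P) in place."""
    N = h.size
    st = _init_chain(rng, h, f, s, n, spec, cfg)
    d, c = st["d"], st["c"]
    mu_d, mu_c = st["mu_d"], st["mu_c"]
    lam_d, lam_c = st["lam_d"], st["lam_c"]
    sigma_s = st["sigma_s"]
    unequal = spec.variant == "huvsd"

    llh, llf = _loglik_parts(d, c, sigma_s, h, f, s, n)
    lp_sigma = log_sigma_s_prior(sigma_s, spec) if unequal else 0.0

    log_step = np.full(N, math.log(0.5))
    log_step_sig = math.log(0.1)
    log_step_scale = math.log(0.1)
    a_prec, b_prec = spec.prior_precision

    acc_block = 0.0
    acc_sigma = 0.0
    acc_scale = 0.0
    kept = 0

    for t in range(cfg.iterations):
        gamma = (t + 1) ** -0.6 if t < cfg.burn_in else 0.0

        if N:
            # --- joint RW Metropolis on (d_i, c_i), vectorised ---
            for _ in range(_N_DC_UPDATES):
                step = np.exp(log_step)
                dn = d + step * rng.standard_normal(N)
                cn = c + step * rng.standard_normal(N)
                llh_n, llf_n = _loglik_parts(dn, cn, sigma_s, h, f, s, n)
                dlp = (
                    llh_n
                    + llf_n
                    - llh
                    - llf
                    - 0.5 * lam_d * ((dn - mu_d) ** 2 - (d - mu_d) ** 2)
                    - 0.5 * lam_c * ((cn - mu_c) ** 2 - (c - mu_c) ** 2)
                )
                acc = np.log(rng.random(N)) < dlp
                d = np.where(acc, dn, d)
                c = np.where(acc, cn, c)
                llh = np.where(acc, llh_n, llh)
                llf = np.where(acc, llf_n, llf)
                if gamma:
                    log_step += gamma * (acc - _TARGET_BLOCK)

        # --- scalar adaptive RW on sigma_s (hUVSD only) ---
        if unequal:
            sig_n = sigma_s + math.exp(log_step_sig) * rng.standard_normal()
            accepted = False
            if sig_n > 0:
                lp_sig_n = log_sigma_s_prior(sig_n, spec)
                if N:
                    llh_n, _ = _loglik_parts(d, c, sig_n, h, f, s, n)
                    dll = float(llh_n.sum() - llh.sum())
                else:
                    dll = 0.0
                if math.log(rng.random()) < dll + lp_sig_n - lp_sigma:
                    sigma_s = sig_n
                    lp_sigma = lp_sig_n
                    if N:
                        llh = llh_n
                    accepted = True
            if gamma:
                log_step_sig += gamma * (accepted - _TARGET_SCALAR)

            # --- interweaving scale moves on sigma_s ---
            # Propose sigma_s in the (z_h, z_f) parameterisation, where the
            # likelihood is ancillary: holding each participant's latent
            # rates fixed, remap (d_i, c_i) deterministically.  Only the
            # hierarchical prior and the Jacobian sigma_s^N enter the
            # ratio, so sigma_s can take large steps that the conditional
            # random walk cannot.  The move is likelihood-free and cheap,
            # so it is repeated to decorrelate sigma_s faster.
            accepted_sc = False
            moved = False
            zh = (0.5 * d - c) / sigma_s
            zf = -0.5 * d - c
            for _ in range(_N_INTERWEAVE):
                sig_n = sigma_s + math.exp(log_step_scale) * rng.standard_normal()
                accepted_sc = False
                if sig_n > 0:
                    lp_sig_n = log_sigma_s_prior(sig_n, spec)
                    dn = sig_n * zh - zf
                    cn = -0.5 * (sig_n * zh + zf)
                    dlp = (
                        -0.5 * lam_d * float(((dn - mu_d) ** 2 - (d - mu_d) ** 2).sum())
                        - 0.5 * lam_c * float(((cn - mu_c) ** 2 - (c - mu_c) ** 2).sum())
                        + N * math.log(sig_n / sigma_s)
                        + lp_sig_n
                        - lp_sigma
                    )
                    if math.log(rng.random()) < dlp:
                        sigma_s = sig_n
                        lp_sigma = lp_sig_n
                        d, c = dn, cn
                        accepted_sc = True
                        moved = True
                if gamma:
                    log_step_scale += gamma * (accepted_sc - _TARGET_SCALAR)
            if moved:
                llh, llf = _loglik_parts(d, c, sigma_s, h, f, s, n)

        # --- exact Gibbs draws for the conjugate hyperparameters ---
        m, sd_ = conjugate_mu_posterior(d, lam_d, spec.prior_mu_var)
        mu_d = rng.normal(m, sd_)
        m, sd_ = conjugate_mu_posterior(c, lam_c, spec.prior_mu_var)
        mu_c = rng.normal(m, sd_)
        sh, rt = conjugate_lambda_posterior(d, mu_d, a_prec, b_prec)
        lam_d = rng.gamma(sh, 1.0 / rt)
        sh, rt = conjugate_lambda_posterior(c, mu_c, a_prec, b_prec)
        lam_c = rng.gamma(sh, 1.0 / rt)

        if t >= cfg.burn_in:
            row = store[kept]
            row[0] = mu_d
            row[1] = mu_c
            row[2] = lam_d
            row[3] = lam_c
            row[4] = sigma_s
            row[5 : 5 + N] = d
            row[5 + N : 5 + 2 * N] = c
            kept += 1
            if N:
                acc_block += float(acc.mean())
            if unequal:
                acc_sigma += accepted
                acc_scale += accepted_sc

    denom = max(kept, 1)
    return {
        "dc_block": acc_block / denom,
        "sigma_s": acc_sigma / denom,
        "sigma_s_scale": acc_scale / denom,
    }


def _run_chain_expanded(
    rng: np.random.Generator,
    h,
    f,
    s,
    n,
    spec: ModelSpec,
    cfg: SamplerConfig,
    store: np.ndarray,
) -> dict[str, float]:
    """Linearly expanded hEVSD chain: d_i = mu_d + xi_d * delta_d_i.

    mu and xi enter the likelihood directly here, so they get scalar
    adaptive Metropolis steps; only the precisions stay conjugate.
    """
    N = h.size
    st = _init_chain(rng, h, f, s, n, spec, cfg)
    delta_d, delta_c = st["delta_d"], st["delta_c"]
    mu_d, mu_c = st["mu_d"], st["mu_c"]
    lam_d, lam_c = st["lam_d"], st["lam_c"]
    xi_d, xi_c = st["xi_d"], st["xi_c"]

    def parts(dd, dc, md, mc, xd, xc):
        return _loglik_parts(md + xd * dd, mc + xc * dc, 1.0, h, f, s, n)

    llh, llf = parts(delta_d, delta_c, mu_d, mu_c, xi_d, xi_c)
    log_step = np.full(N, math.log(0.5))
    scalars = {"mu_d": math.log(0.2), "mu_c": math.log(0.2),
               "xi_d": math.log(0.2), "xi_c": math.log(0.2)}
    prior_prec_mu = 1.0 / spec.prior_mu_var
    a_prec, b_prec = spec.prior_precision
    acc_block = 0.0
    acc_scalar = {k: 0.0 for k in scalars}
    kept = 0

    for t in range(cfg.iterations):
        gamma = (t + 1) ** -0.6 if t < cfg.burn_in else 0.0

        if N:
            step = np.exp(log_step)
            ddn = delta_d + step * rng.standard_normal(N)
            dcn = delta_c + step * rng.standard_normal(N)
            llh_n, llf_n = parts(ddn, dcn, mu_d, mu_c, xi_d, xi_c)
            dlp = (
                llh_n + llf_n - llh - llf
                - 0.5 * lam_d * (ddn**2 - delta_d**2)
                - 0.5 * lam_c * (dcn**2 - delta_c**2)
            )
            acc = np.log(rng.random(N)) < dlp
            delta_d = np.where(acc, ddn, delta_d)
            delta_c = np.where(acc, dcn, delta_c)
            llh = np.where(acc, llh_n, llh)
            llf = np.where(acc, llf_n, llf)
            if gamma:
                log_step += gamma * (acc - _TARGET_BLOCK)

        # scalar Metropolis on mu_d, mu_c, xi_d, xi_c
        for name in ("mu_d", "mu_c", "xi_d", "xi_c"):
            cur = {"mu_d": mu_d, "mu_c": mu_c, "xi_d": xi_d, "xi_c": xi_c}
            prop = dict(cur)
            prop[name] = cur[name] + math.exp(scalars[name]) * rng.standard_normal()
            ok = True
            if name.startswith("xi") and not (0.0 < prop[name] < 1.0):
                ok = False
            accepted = False
            if ok:
                llh_n, llf_n = parts(
                    delta_d, delta_c, prop["mu_d"], prop["mu_c"],
                    prop["xi_d"], prop["xi_c"],
                )
                dlp = float((llh_n + llf_n - llh - llf).sum())
                if name.startswith("mu"):
                    dlp -= 0.5 * prior_prec_mu * (prop[name] ** 2 - cur[name] ** 2)
                if math.log(rng.random()) < dlp:
                    mu_d, mu_c = prop["mu_d"], prop["mu_c"]
                    xi_d, xi_c = prop["xi_d"], prop["xi_c"]
                    llh, llf = llh_n, llf_n
                    accepted = True
            if gamma:
                scalars[name] += gamma * (accepted - _TARGET_SCALAR)
            if t >= cfg.burn_in:
                acc_scalar[name] += accepted

        sh, rt = conjugate_lambda_posterior(delta_d, 0.0, a_prec, b_prec)
        lam_d = rng.gamma(sh, 1.0 / rt)
        sh, rt = conjugate_lambda_posterior(delta_c, 0.0, a_prec, b_prec)
        lam_c = rng.gamma(sh, 1.0 / rt)

        if t >= cfg.burn_in:
            row = store[kept]
            row[0] = mu_d
            row[1] = mu_c
            row[2] = lam_d
            row[3] = lam_c
            row[4] = 1.0
            row[5] = xi_d
            row[6] = xi_c
            row[7 : 7 + N] = mu_d + xi_d * delta_d
            row[7 + N : 7 + 2 * N] = mu_c + xi_c * delta_c
            kept += 1
            if N:
                acc_block += float(acc.mean())

    denom = max(kept, 1)
    out = {"dc_block": acc_block / denom}
    out.update({k: v / denom for k, v in acc_scalar.items()})
    return out


def sample(
    counts: Sequence[TrialCounts], spec: ModelSpec, cfg: SamplerConfig
) -> PosteriorSamples:
    """Draw from the posterior of the requested model variant.

    Deterministic given (counts, spec, cfg): the master seed spawns one
    independent stream per chain.  Non-convergence is never an error; check
    :func:`gelman_rubin` on the result.
    """
    h, f, s, n = counts_arrays(counts)
    N = h.size
    if spec.expanded:
        names = ["mu_d", "mu_c", "lam_d", "lam_c", "sigma_s", "xi_d", "xi_c"]
    else:
        names = ["mu_d", "mu_c", "lam_d", "lam_c", "sigma_s"]
    names += [f"d[{i}]" for i in range(N)] + [f"c[{i}]" for i in range(N)]

    kept = cfg.iterations - cfg.burn_in
    draws = np.empty((cfg.chains, kept, len(names)))
    seqs = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    acc_sums: dict[str, float] = {}
    runner = _run_chain_expanded if spec.expanded else _run_chain_plain
    for ch, seq in enumerate(seqs):
        rng = np.random.default_rng(seq)
        acc = runner(rng, h, f, s, n, spec, cfg, draws[ch])
        for k, v in acc.items():
            acc_sums[k] = acc_sums.get(k, 0.0) + v

    acceptance = {k: v / cfg.chains for k, v in acc_sums.items()}
    return PosteriorSamples(
        names=names,
        draws=draws,
        variant=spec.variant,
        n_participants=N,
        acceptance=acceptance,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# diagnostics


def split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of one parameter from a (chains, draws) array.

    Each chain is halved, giving 2m sequences; R-hat compares between- to
    within-sequence variance.  Identical constant chains return 1.0 by
    convention.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (chains >= 2, draws) array")
    if x.shape[1] < 10:
        raise ValueError("need at least 10 draws per chain")
    half = x.shape[1] // 2
    seqs = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, l = seqs.shape
    means = seqs.mean(axis=1)
    w = float(seqs.var(axis=1, ddof=1).mean())
    b = float(l * means.var(ddof=1))
    if w == 0.0:
        return 1.0 if b == 0.0 else math.inf
    var_plus = (l - 1) / l * w + b / l
    return math.sqrt(var_plus / w)


def gelman_rubin(samples: PosteriorSamples) -> dict[str, float]:
    """Split-R-hat for every stored parameter."""
    if samples.n_chains < 2:
        raise ValueError("R-hat requires at least 2 chains")
    return {name: split_rhat(samples.get(name)) for name in samples.names}


def effective_sample_size(samples: PosteriorSamples) -> dict[str, float]:
    """Bulk effective sample size per parameter (via arviz)."""
    import arviz as az

    out = {}
    for name in samples.names:
        x = samples.get(name)
        if np.allclose(x, x.flat[0]):
            out[name] = math.nan
            continue
        out[name] = float(az.ess(az.convert_to_dataset(x))["x"].values)
    return out


# ---------------------------------------------------------------------------
# information criteria


def _loglik_constant(h, f, s, n) -> float:
    c = gammaln(s + 1) - gammaln(h + 1) - gammaln(s - h + 1)
    c += gammaln(n + 1) - gammaln(f + 1) - gammaln(n - f + 1)
    return float(c.sum())


def _deviance_draws(counts, samples, chunk: int = 512) -> np.ndarray:
    """Full-data deviance -2 log L for every stored draw."""
    h, f, s, n = counts_arrays(counts)
    d, c, sig = samples._dc_sigma_arrays()
    const = _loglik_constant(h, f, s, n)
    out = np.empty(d.shape[0])
    for lo in range(0, d.shape[0], chunk):
        hi = lo + chunk
        llh, llf = _loglik_parts(
            d[lo:hi], c[lo:hi], sig[lo:hi, None], h, f, s, n
        )
        out[lo:hi] = -2.0 * ((llh + llf).sum(axis=1) + const)
    return out


def dic(
    counts: Sequence[TrialCounts],
    samples: PosteriorSamples,
    return_components: bool = False,
):
    """Deviance information criterion, DIC = Dbar + pD.

    The plug-in deviance is evaluated at the posterior means of the
    likelihood-level parameters (d_i, c_i, sigma_s); pD = Dbar - Dhat.
    """
    h, f, s, n = counts_arrays(counts)
    dev = _deviance_draws(counts, samples)
    dbar = float(dev.mean())
    d_mean, c_mean, sig = samples._dc_sigma_arrays()
    llh, llf = _loglik_parts(
        d_mean.mean(axis=0), c_mean.mean(axis=0), float(sig.mean()), h, f, s, n
    )
    dhat = -2.0 * (float((llh + llf).sum()) + _loglik_constant(h, f, s, n))
    p_d = dbar - dhat
    value = dbar + p_d
    if return_components:
        return {"dic": value, "pD": p_d, "Dbar": dbar, "Dhat": dhat}
    return value


def pointwise_loglik(
    counts: Sequence[TrialCounts], samples: PosteriorSamples
) -> np.ndarray:
    """Pointwise log-likelihood matrix, one column per participant x trial type.

    Columns 0..N-1 are the hit (signal-trial) terms, N..2N-1 the
    false-alarm (noise-trial) terms — the exact factorisation grain of the
    likelihood.  Shape (total draws, 2N).
    """
    h, f, s, n = counts_arrays(counts)
    d, c, sig = samples._dc_sigma_arrays()
    llh, llf = _loglik_parts(d, c, sig[:, None], h, f, s, n)
    llh = llh + (gammaln(s + 1) - gammaln(h + 1) - gammaln(s - h + 1))
    llf = llf + (gammaln(n + 1) - gammaln(f + 1) - gammaln(n - f + 1))
    return np.concatenate([llh, llf], axis=1)


def waic(
    counts: Sequence[TrialCounts],
    samples: PosteriorSamples,
    return_components: bool = False,
):
    """Widely applicable information criterion, -2 (lppd - p_waic)."""
    if samples.n_draws * samples.n_chains < 2:
        raise ValueError("WAIC needs at least 2 posterior draws")
    ll = pointwise_loglik(counts, samples)
    s_draws = ll.shape[0]
    lppd = float((logsumexp(ll, axis=0) - math.log(s_draws)).sum())
    p_waic = float(ll.var(axis=0, ddof=1).sum())
    value = -2.0 * (lppd - p_waic)
    if return_components:
        return {"waic": value, "lppd": lppd, "p_waic": p_waic}
    return value


# ---------------------------------------------------------------------------
# tabular export


def summary(samples: PosteriorSamples, population_only: bool = False) -> pd.DataFrame:
    """Per-parameter mean, SD, central 95% interval, median, R-hat and ESS.

    Adds derived rows for sigma_d and sigma_c (= lambda^{-1/2}).
    """
    rhat = gelman_rubin(samples) if samples.n_chains >= 2 else {}
    ess = effective_sample_size(samples) if samples.n_chains >= 2 else {}
    names = list(samples.names)
    if population_only:
        names = [n for n in names if "[" not in n]
    rows = []
    for name in names:
        x = samples.get(name).ravel()
        q = np.quantile(x, [0.025, 0.5, 0.975])
        rows.append(
            {
                "parameter": name,
                "mean": x.mean(),
                "sd": x.std(ddof=1),
                "q2.5": q[0],
                "median": q[1],
                "q97.5": q[2],
                "rhat": rhat.get(name, math.nan),
                "ess": ess.get(name, math.nan),
            }
        )
    for lam_name, sd_name in (("lam_d", "sigma_d"), ("lam_c", "sigma_c")):
        x = samples.get(lam_name).ravel() ** -0.5
        q = np.quantile(x, [0.025, 0.5, 0.975])
        rows.append(
            {
                "parameter": sd_name,
                "mean": x.mean(),
                "sd": x.std(ddof=1),
                "q2.5": q[0],
                "median": q[1],
                "q97.5": q[2],
                "rhat": rhat.get(lam_name, math.nan),
                "ess": ess.get(lam_name, math.nan),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def draws_long_frame(samples: PosteriorSamples) -> pd.DataFrame:
    """Long-format draws table: (chain, iteration, parameter, value)."""
    ch, it, p = samples.draws.shape
    chain = np.repeat(np.arange(ch), it * p)
    iteration = np.tile(np.repeat(np.arange(it), p), ch)
    parameter = np.tile(np.array(samples.names, dtype=object), ch * it)
    return pd.DataFrame(
        {
            "chain": chain,
            "iteration": iteration,
            "parameter": parameter,
            "value": samples.draws.ravel(),
        }
    )
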