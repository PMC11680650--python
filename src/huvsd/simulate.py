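"""Synthetic yes/no detection data from the hierarchical generative model.

The generator draws per-participant sensitivity d_i and criterion c_i from
a (by default independent) bivariate normal, maps them to hit and
false-alarm probabilities through the Gaussian rate transform, and draws
binomial counts.  No edge correction is ever applied: participants who
score 0 or all trials are kept verbatim, and downstream consumers must
cope.

Two assumption-violation modes are available for robustness studies:

* heterogeneous signal SD — each participant gets their own sigma_s_i drawn
  from Normal(sigma_s, 2 sigma_s^4 / n) truncated to positive values, the
  spread matching the standard error of a sample variance at sample size n;
* correlations — rho_dc between d_i and c_i, and rho_ds / rho_cs between
  d_i or c_i and the heterogeneous sigma_s_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .model import TrialCounts
from .sdt import PopulationParams

__all__ = ["SimulationConfig", "SyntheticDataset", "generate", "ladder"]


@dataclass(frozen=True)
class SimulationConfig:
    pop: PopulationParams
    n_participants: int
    signal_trials: int
    noise_trials: int
    seed: int = 0
    sigma_s_heterogeneity: bool = False
    rho_dc: float = 0.0
    rho_ds: float = 0.0
    rho_cs: float = 0.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if self.signal_trials < 0 or self.noise_trials < 0:
            raise ValueError("trial numbers cannot be negative")
        for name in ("rho_dc", "rho_ds", "rho_cs"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"{name} must lie in [-1, 1]")
        if (self.rho_ds or self.rho_cs) and not self.sigma_s_heterogeneity:
            raise ValueError(
                "correlations with sigma_s_i require sigma_s_heterogeneity"
            )
        if not np.all(np.linalg.eigvalsh(self._correlation_matrix()) > -1e-12):
            raise ValueError("correlation structure is not positive semi-definite")

    def _correlation_matrix(self) -> np.ndarray:
        return np.array(
            [
                [1.0, self.rho_dc, self.rho_ds],
                [self.rho_dc, 1.0, self.rho_cs],
                [self.rho_ds, self.rho_cs, 1.0],
            ]
        )

    @property
    def sigma_s_i_sd(self) -> float:
        """SD of the heterogeneous per-participant signal SD.

        Matched to the standard error of a sample variance at sample size
        n: var[sigma_s_i] = 2 sigma_s^4 / n.
        """
        return math.sqrt(2.0 * self.pop.sigma_s**4 / self.n_participants)


@dataclass
class SyntheticDataset:
    """Counts plus the generating truth (d_i, c_i, sigma_s_i, config)."""

    counts: list[TrialCounts]
    d: np.ndarray
    c: np.ndarray
    sigma_s_i: np.ndarray
    config: SimulationConfig

    @property
    def n_participants(self) -> int:
        return len(self.counts)

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [t.participant_id for t in self.counts],
                "hits": [t.h for t in self.counts],
                "false_alarms": [t.f for t in self.counts],
                "signal_trials": [t.s for t in self.counts],
                "noise_trials": [t.n for t in self.counts],
            }
        )

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [t.participant_id for t in self.counts],
                "d": self.d,
                "c": self.c,
                "sigma_s_i": self.sigma_s_i,
            }
        )

    def write(self, directory: str | Path) -> None:
        """Write counts, truth, and a key=value config sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.counts_frame().to_csv(directory / "counts.csv", index=False)
        self.truth_frame().to_csv(directory / "truth.csv", index=False)
        cfg, pop = self.config, self.config.pop
        lines = [
            f"mu_d={pop.mu_d!r}",
            f"mu_c={pop.mu_c!r}",
            f"sigma_d={pop.sigma_d!r}",
            f"sigma_c={pop.sigma_c!r}",
            f"sigma_s={pop.sigma_s!r}",
            f"n_participants={cfg.n_participants}",
            f"signal_trials={cfg.signal_trials}",
            f"noise_trials={cfg.noise_trials}",
            f"seed={cfg.seed}",
            f"sigma_s_heterogeneity={cfg.sigma_s_heterogeneity}",
            f"rho_dc={cfg.rho_dc!r}",
            f"rho_ds={cfg.rho_ds!r}",
            f"rho_cs={cfg.rho_cs!r}",
        ]
        (directory / "config.txt").write_text("\n".join(lines) + "\n")


def _draw_latents(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pop, n = cfg.pop, cfg.n_participants
    if not cfg.sigma_s_heterogeneity:
        cov = np.array(
            [
                [pop.sigma_d**2, cfg.rho_dc * pop.sigma_d * pop.sigma_c],
                [cfg.rho_dc * pop.sigma_d * pop.sigma_c, pop.sigma_c**2],
            ]
        )
        dc = rng.multivariate_normal([pop.mu_d, pop.mu_c], cov, size=n)
        return dc[:, 0], dc[:, 1], np.full(n, pop.sigma_s)

    sds = np.array([pop.sigma_d, pop.sigma_c, cfg.sigma_s_i_sd])
    cov = cfg._correlation_matrix() * np.outer(sds, sds)
    mean = np.array([pop.mu_d, pop.mu_c, pop.sigma_s])
    # rejection sampling keeps sigma_s_i positive; negative draws are
    # vanishingly rare at the regimes of interest, so the stated joint
    # moments are essentially intact
    out = np.empty((0, 3))
    while out.shape[0] < n:
        cand = rng.multivariate_normal(mean, cov, size=n)
        out = np.vstack([out, cand[cand[:, 2] > 0]])
    out = out[:n]
    return out[:, 0], out[:, 1], out[:, 2]


def generate(cfg: SimulationConfig) -> SyntheticDataset:
    """Draw one dataset from the generative model (reproducible by seed)."""
    rng = np.random.default_rng(cfg.seed)
    d, c, sig_i = _draw_latents(cfg, rng)
    theta_h = ndtr((0.5 * d - c) / sig_i)
    theta_f = ndtr((-0.5 * d - c) / cfg.pop.sigma_n)
    h = rng.binomial(cfg.signal_trials, theta_h)
    f = rng.binomial(cfg.noise_trials, theta_f)
    counts = [
        TrialCounts(
            participant_id=i,
            h=int(h[i]),
            f=int(f[i]),
            s=cfg.signal_trials,
            n=cfg.noise_trials,
        )
        for i in range(cfg.n_participants)
    ]
    return SyntheticDataset(counts=counts, d=d, c=c, sigma_s_i=sig_i, config=cfg)


def ladder(
    cfg_base: SimulationConfig, levels: list[tuple[int, int]]
) -> list[SyntheticDataset]:
    """One dataset per (n_participants, total_trials) level.

    Trials split evenly into signal and noise halves.  The heterogeneous
    sigma_s_i spread rescales automatically with each level's n.  Each
    level reuses the base seed, so a single-level ladder reproduces
    :func:`generate` exactly.
    """
    if not levels:
        raise ValueError("levels must be nonempty")
    out = []
    for n, k in levels:
        cfg = replace(
            cfg_base,
            n_participants=n,
            signal_trials=k // 2,
            noise_trials=k - k // 2,
        )
        out.append(generate(cfg))
    return out
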