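# Methods

## Model

Each participant i contributes two binomial observations: h_i hits out of
s_i signal trials and f_i false alarms out of n_i noise trials, with
success probabilities

    θ_i^h = Φ[(+d_i/2 − c_i)/σ_s],    θ_i^f = Φ[(−d_i/2 − c_i)/σ_n],

where Φ is the standard normal CDF, d_i is the distance between the
signal and noise distribution means, c_i the criterion measured from the
midpoint between them, σ_n = 1 fixes the scale of the latent axis, and
σ_s is the signal SD shared by all participants.  Individual parameters
are exchangeable normal draws, d_i ~ N(μ_d, λ_d⁻¹) and c_i ~ N(μ_c,
λ_c⁻¹), independent of each other.  The unequal-variance model (hUVSD)
has five population parameters (μ_d, μ_c, λ_d, λ_c, σ_s); the
equal-variance baseline (hEVSD) pins σ_s = 1; the expanded equal-variance
variant re-expresses d_i = μ_d + ξ_d δ_i^d with ξ_d, ξ_c ~ beta(1, 1) and
δ ~ N(0, λ⁻¹), a linear parameter expansion that historically eased
convergence of the four-parameter model.

Identifiability of σ_s from binary data rests on the bivariate normality
of the z-transformed rates across participants: var[z(θ^f)]/var[z(θ^h)]
→ σ_s² as the sample grows.  `sdt.moment_map` states all five implied
moments and `sdt.moment_estimate` inverts them in closed form; the
inversion is exact on model-implied moments (unit-tested to 1e-10) and a
consistent method-of-moments estimator on sample moments.  Any moment
summary satisfying the Cauchy–Schwarz inequality strictly inverts to a
valid population; the boundary (perfectly correlated z-rates) implies a
zero variance and raises `MomentEstimationError`.

## Priors

- μ_d, μ_c ~ N(0, 1000) (variance 1000, i.e. SD ≈ 31.6).  The literature
  this model descends from writes BUGS-style precision 0.001 and calls
  the variance "large", so the second argument is read as a variance.
- λ_d, λ_c ~ gamma(0.5, 0.5) (shape, rate) — the ν = 1 conjugate choice;
  the expanded equal-variance variant uses gamma(0.1, 0.1), and the plain
  hEVSD accepts either (default 0.5, 0.5 for comparability with hUVSD).
- σ_s² ~ N(1, 2) truncated to (0, ∞): centred on equal variance, so any
  estimated departure from σ_s = 1 is evidence in the data overwhelming a
  deliberately conservative prior.  Whether "2" is a variance or an SD is
  ambiguous in the source models; the variance reading is the default and
  `ModelSpec(sigma_s2_scale_is_sd=True)` switches to the SD reading.
  gamma(0.5, 0.5) and uniform(0, 5) alternatives are selectable; on
  well-sized samples all three give indistinguishable estimates.
- The sampler parameterises σ_s itself; the σ_s² prior is applied through
  the change of variables with its Jacobian 2σ_s (unit-tested by
  integrating the induced density).  The truncation constant is dropped
  as parameter-independent.
- Inside the likelihood, rates are clamped to [1e-12, 1 − 1e-12] so
  extreme latent excursions during early sampling stay finite; the clamp
  is far outside the region any realistic posterior visits.

## Sampler

Metropolis-within-Gibbs, vectorised across participants:

1. (d_i, c_i) — joint bivariate random-walk proposal per participant with
   a per-participant adaptive scale (target acceptance 0.23), two sweeps
   per iteration.  All participants update in parallel as numpy vector
   operations.
2. σ_s — a scalar adaptive random-walk step (target 0.44) against the
   full conditional, plus five repetitions of an *interweaving scale
   move*: σ_s is proposed while each participant's (z^h, z^f) pair — and
   hence the likelihood — is held fixed, with (d_i, c_i) remapped
   deterministically and the Jacobian σ_s^N entering the acceptance
   ratio.  σ_s is strongly coupled to the latent parameters, so the
   conditional step alone mixes poorly (split-R̂ ≈ 1.14 at 10,000
   iterations); the interweaving move, which only the hierarchical prior
   can resist, restores R̂ < 1.01.  It is likelihood-free and therefore
   cheap to repeat.
3. μ_d, μ_c, λ_d, λ_c — exact conjugate Gibbs draws
   (normal/gamma; closed forms exposed as `conjugate_mu_posterior` /
   `conjugate_lambda_posterior` and unit-tested against hand-derived
   formulas).
4. Expanded variant — μ and ξ enter the likelihood directly, so they get
   scalar adaptive Metropolis steps; δ pairs update as in (1) and the
   precisions stay conjugate.

Proposal scales adapt by Robbins–Monro (step t^−0.6) during burn-in only
and are frozen afterwards, preserving detailed balance of the retained
draws.  Defaults are 4 chains × 10,000 iterations with 4,000 burn-in.
λ_d, λ_c initialise from their prior (clipped to [0.1, 100] so a
heavy-tailed draw cannot strand a chain in the flat far tail), (d_i, c_i)
from edge-corrected empirical rates plus jitter, σ_s from |N(1, 0.1²)|.
One master seed spawns independent per-chain bit streams; identical
inputs give bit-identical draws.

Diagnostics: split-R̂ (each chain halved; identical constant chains
report 1.0 by convention) with the conventional 1.01 threshold, and bulk
ESS via arviz.  DIC uses the plug-in deviance at the posterior means of
the likelihood-level parameters (d_i, c_i, σ_s), matching the default
deviance-monitor focus of BUGS-family samplers; pD = D̄ − D̂.  WAIC's
pointwise unit is participant × trial type (the exact factorisation grain
of the likelihood, 2N terms) with the textbook ddof = 1 variance penalty
— arviz's ddof = 0 convention differs by p_waic/(S−1), which the
cross-check test accounts for explicitly.

## Synthetic data

`simulate.generate` draws (d_i, c_i) from the bivariate normal, maps them
through the rate transform, and draws binomial counts.  No edge
correction is applied at any point: participants scoring 0 or all trials
are kept verbatim (the Bayesian model needs no correction because the
rates are latent; only the closed-form moment estimator applies the
(h + ½)/(s + 1) stabilisation, and only to its own input).

Violation modes for robustness studies:

- heterogeneous signal SD: σ_s,i ~ N(σ_s, 2σ_s⁴/n) truncated to positive
  values by rejection, the spread matching the standard error of a sample
  variance at sample size n so that heterogeneity scales with what the
  data could resolve.  At the regimes of interest negative draws are
  vanishingly rare, so rejection leaves the stated moments essentially
  intact.
- correlations ρ_dc, ρ_ds, ρ_cs via a joint trivariate normal over
  (d_i, c_i, σ_s,i); requesting a σ_s,i correlation without
  heterogeneity, or a jointly non-PSD correlation matrix, is an error.

What the generator does *not* emulate: sequential dependencies between
trials, item-level random effects, non-Gaussian latent distributions, and
participant-varying noise SD.  Passing recovery tests therefore show that
the estimator works when its assumptions hold (and degrades as documented
when they are violated), not that real data satisfy those assumptions.

## Study conditions and the replication convention

The reference population for the simulation studies is μ_d = 2.0,
μ_c = −0.5, σ_d = 0.6, σ_c = 0.4, σ_s = 1.5 with n = 500 participants.
The generator-moment checks use 200 signal + 200 noise trials; at that
size the sample covariance of the z-rates has a Monte-Carlo SE of ≈ 0.008
around the model-implied 0.047.

For the parameter-recovery correlations a calibration subtlety matters.
The correlation between posterior-mean and generating individual
parameters is bounded above by the correlation achieved by the exact
posterior mean under the true generative model (computable by 2-D
quadrature, which the test suite uses as an oracle).  At 200 + 200 trials
that ceiling is r_d ≈ 0.949 / r_c ≈ 0.972; the reference values this
package reproduces (r_d ≈ 0.975, r_c ≈ 0.987, and r_d ≈ 0.977 for the
word-recognition replay) correspond to simulations with the *total* trial
number used as each binomial's size — 400 + 400 at the reference
population and 480 + 480 for the replay (the word-recognition experiment
itself had 240 targets and 240 foils).  The recovery and replay
experiments and `scripts/acceptance.py` therefore use k trials of each
type; both trial counts are explicit arguments everywhere, so either
convention is a one-line change.

Misspecification bias: fitting hEVSD to σ_s = 1.5 data underestimates
μ_d and overestimates μ_c, each by tens of posterior SDs at n = 500
(the criterion shifts by roughly half the sensitivity change); fitting
hUVSD to σ_s = 1 data recovers a σ_s interval containing 1.  Increasing
d–c correlation drives hUVSD estimates away from the truth (μ̂_d and
σ̂_s up, μ̂_c down) while leaving the hEVSD fit's constant bias
unchanged; the `run_robustness` runner exposes both sweeps.

## Numerical choices and limitations

- Sample moments use the unbiased (n − 1) convention throughout.
- The z-transform rejects rates of exactly 0 or 1 rather than silently
  correcting them; edge policy lives in one place (`corrected_rates`).
- Float precision bounds the rate/parameter round trip: beyond |z| ≈ 4.5
  the Gaussian tail loses the resolution needed for 1e-10 inversion, so
  property tests bound their ranges accordingly.
- Test-suite fits use shortened chains (the full 4 × 10,000 regime takes
  ≈ 20 s at n = 500 on one CPU and is used for the headline recovery
  fits; smoke tests use hundreds of iterations).
- The moment estimator requires every participant's corrected rates to be
  interior, and its finite-sample noise can place small samples near the
  Cauchy–Schwarz boundary where the implied variances degenerate; the
  Bayesian fit has no such failure mode and is the primary estimator.
- DIC's plug-in focus is a convention, not a theorem; other focus levels
  (e.g. population parameters only) give different pD.  Comparisons
  should hold the implementation fixed across models, as `fit_dataset`
  does.
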