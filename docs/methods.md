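# Methods

## The model

`trswitch` infers which subset of candidate transcription factors (TFs)
regulates a target gene, and the logic of that regulation, from dynamic
expression data observed under several experimental conditions.  The target
mRNA level M(t) in experiment k follows a linear ODE with piecewise-constant
transcription,

    dM/dt = tau(t) - delta * M(t),        t in [0, L_k],

where `delta` is a first-order degradation rate shared across experiments
and `tau(t)` jumps only when a regulator crosses its activation threshold.
Each regulator phi in the current set has a continuous activity curve
P_phi(t) per experiment (by default the GCV-smoothed mRNA profile) and one
threshold rho_phi shared across experiments; its binary activation state is
1 exactly where P_phi(t) >= rho_phi.  Every *observed* joint activation
state a_i of the set owns a single transcription rate tau_{a_i}, shared
across experiments and over time.  This cross-experiment consistency is
what identifies interactive logic (e.g. "A activates only while B is off"):
the same state must explain every time interval, in every condition, in
which it occurs.

For fixed thresholds and degradation rate the ODE solution is linear in the
initial conditions M_k(0) and the rates tau_{a_i}:

    M(t) = M(0) e^{-delta t} + sum_i tau_{a_i} e^{-delta t}
           * integral over [0, t] ∩ I_{a_i} of e^{delta u} du,

with I_{a_i} the interval union on which state a_i holds.  Observations are
Gaussian around M_k(t) with standard deviation sigma_k * v_k(t), where
v_k(t) = w_k(t)^(-psi_k), w_k is a fixed positive weight function (the
inverse of a smoothing-spline estimate of the target expression) and
psi_k in [0, 1] interpolates between homoscedastic noise (psi = 0) and
variance growing with the expression level (psi = 1).

## Inference

The regulator set, thresholds, degradation rate and noise parameters are
sampled by a reversible-jump MCMC.  Per iteration:

1. **Structure move** — move a threshold (truncated-normal proposal within
   the profile range), swap a regulator (new threshold uniform on the
   incoming profile's range), or add/remove a regulator (birth/death).
   Move probabilities follow the Green construction from the Poisson(lambda)
   prior on the set size: pi_B(nu) = c*min{1, lambda/(nu+1)},
   pi_D(nu) = c*min{1, nu/lambda}, with c maximized subject to
   pi_B + pi_D <= pi_BD (default 0.5); this satisfies the balance equation
   pi(nu) pi_B(nu) = pi(nu+1) pi_D(nu+1).  Where nu equals the number of
   candidates the swap move is impossible and its probability is folded
   into the threshold move — folding it in any other way silently biases
   the acceptance ratios (a flat-likelihood chain then fails to reproduce
   its own prior, which is exactly how this was caught; the prior-recovery
   test guards it).
2. **Degradation rate** — Gaussian random-walk Metropolis on delta
   (proposal sd 0.05, configurable); the design matrix is rebuilt because
   the integral factors depend on delta.
3. **Noise scales** — conjugate Gibbs draws of sigma_k^2 from scaled
   inverse-chi-square full conditionals.
4. **Variance exponents** — psi_k sampled by inverse-CDF on a 201-point
   grid over [0, 1] from its numerically evaluated full conditional.

All acceptance ratios use the *plug-in* likelihood: the linear coefficients
(M_k(0), tau_{a_i}) are estimated by weighted least squares and substituted
into the Gaussian likelihood rather than integrated out.  This is fast and
keeps trans-dimensional moves free of extra Jacobian terms (the only
dimension-changing quantities are thresholds with explicit proposal
densities), at the price of a mild overfitting bias: adding a regulator can
only decrease the residual sum of squares, so the size prior (small lambda,
default 0.15) carries real weight.

**Structure validity.** A proposal whose joint-state partition contains an
observed state with *no observation time* in any experiment is rejected.
Such states own a rate that no datum directly constrains; left in, they act
as nearly free parameters reachable by small threshold "flicker" around a
smoothed profile's plateau wiggles, and the sampler drifts into noise-fitting
structures.  Library calls outside the sampler fall back to the minimum-norm
least-squares solution and flag the fit instead.

## Priors

- Set size: Poisson(lambda), truncated to [1, nu_max] and renormalized
  (nu_max defaults to min(N, 8)).
- Regulator set given size: uniform over subsets, or informative with
  per-TF weights proportional to the *dynamic range* — the mean over
  experiments of the within-experiment level range, divided by the gene's
  mean absolute level.  The within-experiment range (rather than the joint
  range across experiments) means a gene that is constant in every
  condition has no dynamics even if its level differs between conditions;
  such a gene can only relabel experiments, not explain switches.  The
  normalizer over size-nu subsets is computed with elementary symmetric
  polynomials, so informative set priors stay exact for any N.
- Thresholds: uniform over the profile range R_phi, or informative with
  density proportional to the gradient-weighted traversal mass: each
  monotone crossing of a level band contributes mass proportional to
  |dP/dt| at the crossing.  A linear ramp gives a uniform density; a
  profile flat everywhere except one fast jump concentrates the density on
  the jumped band.  A 5% uniform floor keeps full support so that uniform
  threshold proposals are never auto-rejected.
- Degradation rate: Gamma with mean 0.345 and sd 0.1543 per hour
  (a roughly 2-hour mRNA half-life); shape/rate are solved from the
  mean/sd parameterization.
- Noise variances: scaled inverse-chi-square (0.001, 0.001), i.e. vague
  but conjugate.  psi_k: uniform on [0, 1].

The weight function w_k is normalized to geometric mean 1 per experiment
before exponentiation by psi_k.  Without this, v_k = w_k^(-psi) rescales
the likelihood by factors of order (expression level)^psi and the psi full
conditional degenerates into a proxy for the overall noise scale.

## Preprocessing

Candidate mRNA series are pooled over replicates (replicate values averaged
at shared times with proportional weights) and smoothed per experiment with
a generalized-cross-validated smoothing spline; the smoothed curve sampled
on a 121-point grid, treated as piecewise linear thereafter, is the default
regulator proxy ("identity" mode).  Affine, time-delay (edge-held) and
translation-ODE (dP/dt = k_tl M - delta_p P) proxies are available.  A wild
bootstrap with Mammen two-point weights provides a pointwise envelope
around each smoothed curve; it is diagnostic only — inference conditions on
the point-estimate curves.

## Synthetic studies

Both generators emit deterministic profiles Omega*h(t) (Omega = 1000) plus
i.i.d. Gaussian noise with sd Omega/20 = 50 units, observed at irregular
times (spacings uniform on [0.5, 1.5] time units), 4 replicates per
experiment sharing sampling times, values clipped at zero.  The target is
driven by a steep Hill gate of the regulator profiles (exponent 150 for the
two-experiment study, 50 for the SOC1 study), which the switch model
approximates closely; the ODE is integrated with an adaptive solver.

**Repressed activation** (two experiments, 10 h): f1 activates the target,
f2 suppresses that activation; the gate is
basal + amp * H(f1) * (1 - H(f2)) with basal rate 20 and active rate 120
units/h, so the target moves between steady states of roughly 60 and 400
units.  Confounders: f3 repeats f2's experiment-2 shape in both
experiments; f4 is constant low/high across experiments; f5 mirrors f2 with
transition times offset by +0.8/-0.7 h, a small sinusoidal wobble and 3x
observation noise (an exact mirror smoothed by GCV is likelihood-equivalent
to f2 and the study would be unidentifiable between them); f6 is f1
compressed into a smaller range (crossing times preserved), which the
informative set prior — but not the data — can distinguish from f1.

**SOC1 flowering-time network** (four conditions, 10 days): SOC1 requires
FT active with repressors FLC and SVP inactive; AGL24 and SOC1 itself
(positive feedback, threshold 400 units) multiply the open-gate rate
(floors 0.1 and 0.5).  Condition 1 is permissive: the gate opens when SVP
clears (day 4) and shuts when the FT pulse ends (day 8), with AGL24 (day 5)
and the self-feedback (~day 6) stepping the rate up inside the window.
Conditions 2-4 start *pre-induced* (SOC1 at 550 units, decaying) with FLC
high, SVP high and FT low respectively, so each repressor and FT is forced
into the regulator set by one condition, and "autoregulation alone" is
contradicted by the pre-induced decays.  The four non-regulator network
genes (FD, AP1, LFY, CO) have condition-invariant profiles, so any
regulatory role ascribed to them in the permissive condition is contradicted
elsewhere.  The scale of information in this study is deliberately modest:
the repressor/activator core {FLC, FT, SVP} is recovered essentially always,
while the AGL24 step and the self-feedback step ride on a handful of
observations in one condition, so the exact five-TF set is top-ranked only
in a subset of data realizations.  This is a property of the emulated
design, not of the sampler (see Limitations).

The generators' rate amplitudes and steepness constants were fixed during
design by one consideration: systematic discrepancies between the smooth
truth and the fitted switch model (Hill ramps, spline crossing-time error)
scale with the transcription-rate jump, while the noise floor is fixed, so
amplitudes were chosen to keep those discrepancies below the noise while
keeping state separations many standard errors wide.  With large amplitudes
the posterior spreads over supersets of the true set — extra regulators
whose thresholds carve out the mismatch regions — which manifests exactly
as an inflated P(nu = truth + 1).

## Numerical choices

- Closed-form ODE factors are computed in the shifted form
  e^{delta(min(r,t)-t)} - e^{delta(l-t)} (all exponents non-positive) to
  avoid overflow at large delta*t.
- Thresholds crossing detection is linear interpolation per knot segment of
  the piecewise-linear proxy; a value exactly at the threshold is active
  (state closed on the active side); segments shorter than 1e-12 time units
  are dropped when partitioning.
- Weighted least squares uses `numpy.linalg.lstsq` on the row-scaled
  design; rank-deficient systems return the minimum-norm solution with a
  warning.
- The psi grid likelihood reuses a precomputed (grid x observation) matrix
  of exp(-2 psi log w) per experiment, so the numerically evaluated full
  conditional costs one small matrix-vector product per iteration.
- Chain defaults: burn-in 10% of iterations, thinning chosen to retain at
  most 10,000 draws, threshold proposal sd 0.1 of the profile range.

## Problem sizes used in the shipped tests and reproduction script

The original studies ran 1M iterations; the test suite and the acceptance
script use 15k-150k iterations per chain and pool posterior summaries over
3-6 dataset replicates for study-level quantities.  Between-seed agreement
and prior-recovery diagnostics indicate the summaries are stable at these
sizes; set-recovery tests use ten 15k-iteration chains.

## Limitations

- The plug-in likelihood is not a marginal likelihood; model-size
  calibration leans on the Poisson prior.  A fully Bayesian linear-model
  marginalization would change the published algorithm and is deliberately
  not implemented.
- Posterior summaries on any *single* synthetic dataset inherit the
  realization noise of ~80-160 observations; probabilities of individual
  sets vary by +-0.1-0.2 across data seeds.  The generators emulate the
  described structure of the original studies, not their exact (unpublished)
  constants, so printed-probability comparisons are approximate by design.
- In the SOC1 emulation the exact five-TF set (including autoregulation) is
  the top-ranked model only in a minority of realizations; the recovered
  core is {FLC, FT, SVP} plus a realization-dependent subset of
  {AGL24, SOC1} or a near-equivalent gene.  Positive feedback is
  intrinsically hard for this model class: the target's own activation
  state can tautologically explain silence in any condition where the
  target stays low, and only pre-induced conditions break the tautology.
- Bootstrap uncertainty in the smoothed proxies does not propagate into the
  posterior; sensitivity can be assessed by re-running on bootstrap
  replicate curves.
- Expression scales must be comparable across experiments; no cross-platform
  normalization is attempted.
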