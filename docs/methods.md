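# Methods

`specdcm` estimates directed (effective) connectivity among brain regions
from resting-state fMRI by fitting a deterministic generative model of the
complex cross-spectral density of the observed BOLD series. This note
documents the model, its parameterisation and defaults, the numerical
scheme, the synthetic-data generator, and the design choices that were
genuinely open.

## Generative model

**Neuronal layer.** Each of `n` regions carries a scalar neuronal state;
the states evolve as a linear stochastic system

    dx/dt = A x + v(t),

where `A` (Hz) is the effective-connectivity Jacobian and `v(t)` are
endogenous neuronal fluctuations. `A[i, j]` is the coupling *from* region
`j` *to* region `i` (column = source); this convention matches the
matrix–vector action on the state and is stated here prominently because it
is easy to get wrong. Self-connections are parameterised as
`-0.5 * exp(lambda_i)` Hz: fixed at −0.5 Hz a priori and re-scaled through a
log parameter, so they are strictly negative for any finite `lambda_i` and
run-away excitation is impossible. The real parts of the eigenvalues of `A`
are the Lyapunov exponents of the system; `stability_analysis` checks that
all are negative (warning, not error, otherwise). Exogenous inputs are
supported in the parameterisation (`driving`) but are identically zero at
rest and are not estimated.

**Haemodynamic layer.** Each region's neuronal state drives a standard
balloon model: a vasodilatory signal `s`, and log-transformed blood flow,
venous volume and deoxyhemoglobin (log states keep the physical quantities
positive):

    ds/dt       = eps * x - kappa * s - gamma * (f - 1)
    d log f/dt  = s / f
    tau dv/dt   = f - v**(1/alpha)
    tau dq/dt   = f * E(f, E0)/E0 - v**(1/alpha) * q / v
    y           = V0 * (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v))

with `E(f, E0) = 1 - (1 - E0)**(1/f)`. Defaults: signal decay
`kappa = 0.64 s^-1`, autoregulation `gamma = 0.32 s^-1`, transit time
`tau = 2 s`, Grubb exponent `alpha = 0.32`, resting oxygen extraction
`E0 = 0.4`, resting venous volume `V0 = 4 %`, echo time 0.04 s, 3 T read-out
coefficients `k1 = 6.93 E0`, `k2 = 1.5`, `k3 = 0.6`. All constants are
config-overridable. Only the transit time and signal decay are free
(estimable) parameters, as per-region log-scaling factors with tight
shrinkage priors; freeing more would leave the inverse problem poorly
bounded.

**Neurovascular efficacy.** The drive of neuronal activity into the
vasodilatory signal carries an efficacy `eps` (default 1/16). With unit
efficacy, sustained unit neuronal activity would imply a steady-state flow
increase above 300 % and BOLD excursions of tens of percent — far outside
the canonical 30–40 % flow / 2–3 % BOLD response to strong sustained
activation — and, at the fluctuation amplitudes of the standard validation
protocol, would regularly drive the log-flow state into its finite-time
singularity (flow reaching zero in finite time, which no integrator can
cross). `eps = 1/16` restores the canonical response magnitudes; under the
standard protocol it yields resting fluctuations peaking near 2 % signal
change, with the observation noise (sd 0.125 %) a realistic minority share
of the measured variance.

**Spectral observation model.** Both noise processes get scale-free
spectral densities, `g_v(w) = alpha_v w^-beta_v` per region for the
neuronal fluctuations and `g_e(w) = alpha_e w^-beta_e` for observation
noise; amplitudes are region-specific, exponents shared (one neuronal, one
observational), all estimated as log-parameters so positivity holds by
construction. Passing the fluctuations through the transfer function of the
linearised full system,

    K(w) = dg/dx . (i 2 pi w I - J)^-1 . B,

gives the predicted cross-spectral density

    G_y(w) = K(w) diag(g_v(w)) K(w)^H + diag(g_e(w)),

the multi-region form of the scalar `|K|^2 g_v + g_e`; noise processes are
independent across regions and of each other (diagonal spectral matrices).
The base amplitudes (`1/4096` neuronal, one eighth of that observational)
are a unit calibration only: data are rescaled to the prior-predicted
overall power during inversion, so these constants fix units, not fit
quality. Spectra are two-sided densities per Hz evaluated on the positive
half-axis; the analysis grid is 32 evenly spaced bins from 1/128 Hz to the
Nyquist frequency.

## Data features

Observed series are detrended (mean + linear trend; no variance
normalisation by default) and a fourth-order multivariate autoregression is
fitted by ordinary least squares (tiny ridge fallback for rank-deficient
designs); its rational spectrum on the analysis grid is the smooth sample
CSD. Cross-covariance functions follow by an inverse Fourier transform over
the (Hermitian-extended) band.

The feature vector stacks, per frequency bin, the real upper triangle +
diagonal, then the imaginary strict upper triangle, then the flattened
cross-covariance block (±8 lags by default). Three details matter and were
all verified to matter empirically:

1. **Per-frequency whitening.** Raw densities span about four orders of
   magnitude across the band; under a single scalar noise precision only
   the few largest low-frequency values would carry any likelihood weight.
   Each frequency slab of the spectral block is therefore divided by the
   observed mean diagonal power at that frequency (a fixed transform shared
   by data and predictions).
2. **Unit calibration.** The log-precision hyperprior N(6, 1/128) implies a
   believed residual sd of `exp(-3) ~ 0.05`. Features are scaled so that
   this matches the first-order relative sampling sd of an order-p
   autoregressive spectral estimate, `sqrt(2 p n / T)`, anchored at the
   512-scan design point (a fixed unit convention — runs of all lengths are
   fitted in identical units, so longer runs help through cleaner features,
   not through a re-weighted likelihood).
3. **Three precision partitions.** Real spectra, imaginary spectra and
   cross-covariances each carry their own scalar log-precision
   hyperparameter. The imaginary cross-spectra — produced only by
   asymmetric between-region coupling, and an order of magnitude smaller
   than the autospectra — are the carriers of directionality; sharing a
   precision with the real block demonstrably degrades the resolution of
   reciprocal connections.

**MAR projection of predictions.** Model predictions pass through the same
bottleneck as the data: the predicted spectrum is evaluated on a fine
(128-point) grid over the full 1/128 Hz–Nyquist band, converted to
band-limited autocovariances, solved for the implied Yule–Walker MAR(4),
and that MAR's rational spectrum on the analysis grid is compared with the
data feature. Fitting "what the estimator would see" rather than the raw
spectrum removes the representation error of the order-4 family from the
residual; in validation runs it roughly halves the coupling RMS error.
Extending the projection band below 1/128 Hz degrades accuracy (the
power-law drive diverges as `w -> 0` while detrended data carry no such
power) and is deliberately not done.

## Inversion (variational Laplace)

The free energy

    F = ln p(y | mu, m) + ln p(mu | m) + (ln|Sigma| + P ln 2 pi)/2

is maximised over the posterior mean `mu` by a Gauss–Newton /
Levenberg–Marquardt ascent, with `Sigma` the curvature-based posterior
covariance and scalar log-precision hyperparameters updated by Newton steps
between parameter updates. Note the normaliser: with energies evaluated
*at* the mean the correct Gaussian-identity constant is `P ln 2pi`; the
textbook entropy form `(ln|Sigma| + P ln 2 pi e)/2` pairs with *expected*
energies, and the two coincide at a Gauss–Newton optimum. The
implementation reproduces the exact log evidence of a linear-Gaussian
problem to 1e-6, which pins the convention.

Numerical choices: prediction gradients by central finite differences with
per-coordinate step `1e-4 (1 + |theta|)`; LM damping starting at 1/32,
halved on acceptance, doubled on rejection, applied to the diagonal of the
curvature; initialisation at the prior mean (deterministic, no restarts);
convergence when `dF < 0.01` for three consecutive accepted steps, capped
at 64 iterations; steps are accepted only if F increases, and rejected
steps revert to the best state, so the accepted-F trace is non-decreasing
by construction. Non-finite predictions reject the step and raise damping.

Priors (all Gaussian, zero mean): extrinsic couplings variance 1/64,
self-connection log-scales 1/256, haemodynamic log-scales 1/256, noise
log-amplitudes and log-exponents 1/64; log-precision hyperprior N(6,
1/128) per partition. All exposed in `PriorSpec`.

## Synthetic data generator

The simulator emulates the standard validation protocol: a four-region
directed cyclic network (forward/lateral couplings +0.4, +0.2, +0.2, +0.1,
+0.3 Hz; backward couplings −0.3, −0.1, −0.1 Hz; self-connections −0.5 Hz),
512 scans at TR = 2 s. Endogenous fluctuations are AR(1) series with
coefficient 0.5, one draw per scan, each realisation rescaled to sample
sd 0.25, held constant over the TR and integrated through the nonlinear
neuronal + balloon system by fixed-step RK4 at TR/8; observation noise is
an independent AR(1) (same coefficient) at scan resolution, rescaled to sd
0.125 and added to the sampled BOLD. Scan-resolution generation (rather
than micro-time) follows the reference practice for this protocol; it is
also what makes the effective drive spectrum fall roughly as `1/f^0.9`
over the analysis band. An exact zero-order-hold propagator of the
linearised system is available (`method='linearised'`) and doubles as a
test oracle. Seeding is strict: identical spec and seed give bit-identical
output.

What the generator does *not* emulate: scanner drift, spikes, motion,
cardiac/respiratory nuisance, regionally heterogeneous haemodynamics,
nonstationarity, and measured-noise spectra beyond AR(1). Passing the
validation suite therefore demonstrates internal consistency of the method
under its intended noise model, not robustness to real-scanner artefacts.

## Group statistics

- `rms_error`: root mean squared deviation between true and estimated
  parameter vectors.
- `bpa`: precision-weighted (fixed-effects) Bayesian parameter averaging;
  by default the shared prior precision is counted once
  (`P_bpa = sum_i P_i - (k-1) P_0`), with flags for the uncorrected form
  and for diagonal (correlation-ignoring) averaging.
- `bmr_reduce` / `bmr_search`: analytic evidence and posterior for models
  whose priors shrink selected connections toward zero, without
  re-inversion; exhaustive search up to 12 switchable connections, greedy
  backward pruning beyond.
- `group_ttest`: per-connection two-sample t-tests on posterior means, with
  uncorrected (p = 0.05) and Bonferroni-corrected thresholds over the
  declared test count (16 for the four-region network, self-connections
  included in the count).

`run_experiment` orchestrates the five seeded protocols (face validity,
RMS vs run length, two-group difference, hyperprior sweep, sensitivity
sweep) and writes tidy CSV tables plus a JSON manifest recording every seed
and any deviation from the full-scale defaults.

## Problem sizes used in the shipped validation

The test suite and `scripts/acceptance.py` run the protocols at desk scale:
16 replications at 384 scans for the accuracy benchmark, 24 (script) or 12
(tests) subjects per group for the group-difference protocol, and single
512-scan runs for the signal-scale and shrinkage checks. Full-scale
settings (32 replications, the complete 128–1024 length ladder) remain the
experiment defaults and are reproducible through the CLI.

## Known limitations

- The power-law fluctuation model cannot represent the exact spectral shape
  of AR(1)-generated drives; the residual mismatch leaves a small
  network-dependent bias in coupling estimates. Its clearest consequence is
  in the two-group protocol: the maximum |BPA difference| across unaltered
  connections is typically 0.06–0.12 Hz rather than below 0.05 Hz (the
  altered connections are still recovered with the correct sign and
  approximate magnitude, and no or almost no unaltered connection survives
  the Bonferroni-corrected threshold).
- Single-run self-connection estimates are mildly biased toward weaker
  values (typically a 4–10 % shortfall against the true −0.5 Hz).
- The likelihood treats feature entries as conditionally independent given
  the partition precisions; the MAR-derived features are in truth smooth
  and strongly correlated across bins, so posterior variances should be
  read as calibrated approximations, not exact frequentist variances.
- Time-domain (generalised-filtering) inversion, state-dependent coupling,
  cross-region correlated noise and >32-node prior-mode reductions are out
  of scope.
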