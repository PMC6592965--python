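# Methods

This note documents the models, priors, algorithms and numerical choices
behind spectraldcm, and what the synthetic benchmarks do and do not
establish about real data.

## Neural-mass forward model

Four populations interact through sigmoid firing-rate coupling; each
population's mean depolarization obeys the second-order synaptic
convolution dynamics v̈_q = κ_q f_q − 2κ_q v̇_q − κ_q² v_q.  The drift
terms are

    f_1 = a14 σ(v4) − a11 σ(v1) + U
    f_2 = a23 σ(v3) − a22 σ(v2)
    f_3 = −a32 σ(v2) − a31 σ(v1) − a33 σ(v3) + a34 σ(v4)
    f_4 = −a41 σ(v1) − a44 σ(v4)

so populations (1, 4) form one negative-feedback loop and (3, 2) another,
with one-way couplings a31/a34 from the first into the second.  The firing
sigmoid σ(v) = 1/(1+e^{−r(v−η)}) − 1/(1+e^{rη}) is centred so σ(0) = 0:
the origin is then an exact fixed point of the unforced dynamics, which
makes the linearisation point analytic and lets the linearisation tests be
exact rather than approximate.  Slope r = 0.54 mV⁻¹ and inflection η = 0.

Units: rate constants are stored in ms⁻¹ and dynamics run on a millisecond
time axis; angular frequencies are rad/ms internally (ω = 2πf/1000).

Defaults (package choices, stated once and not revisited):

| parameter | default | rationale |
|---|---|---|
| κ (ms⁻¹) | (1/2, 1/35, 1/35, 1/2) | fast principal/interneuron pair (1, 4) and slow pair (2, 3) |
| a14, a41 | 2.0, 1.8 | gamma-band resonance of the fast loop (≈40 Hz) inside its stability margin |
| a23, a32 | 0.3, 0.25 | low-frequency resonance of the slow loop (≈4 Hz), stable |
| a11, a22, a33, a44 | 0.5, 0.5, 0.5, 0.2 | recurrent gain control |
| a31, a34 | 0.3, 0.6 | fast→slow cross-coupling |
| Lw | one row per channel, unit weight on the observed population | LFP proxies read depolarization |
| α_u, β_u | 0, 0 (log scale) | white + pink exogenous input |
| α_n, β_n | −4, −4 (log scale) | channel noise ≈ 2% of the input amplitude |

With a negative feedback loop of gain product g = a_qp·a_pq and shared
rate constant κ, the linearised poles sit at s = −κ + √(κσ′√g)·e^{±iπ/4},
so the resonance frequency cannot exceed κ/√2 without instability — the
slow pair can therefore only resonate below ≈5 Hz, and the low-frequency
"deep" spectrum is largely shaped by the 1/f input.

A fixed point for constant input is found by Newton iteration from the
origin (tolerance 1e-12, 100 iterations, error naming the diverging
population); the Jacobian has the block form [[0, I], [κ∘S − κ²I, −2κI]]
with S the signed gain matrix times σ′ at the fixed point.  The transfer
function T(ω) = C(iωI − J)⁻¹B (B injects input into the v̇ equations
scaled by κ; C reads depolarizations through Lw) requires all eigenvalues
of J to have negative real part and raises a stability error otherwise.
Predicted cross-spectra are g_lm = T_l g_u T_m† + g_n; the channel-noise
term is added to every element, not only the auto-spectra (see Open
choices below).

## Neural-field variant

Connection gains become spatial kernels α e^{−c|x|} with axonal delay
|x|/s.  Their Fourier transform 2α(c + iω/s)/((c + iω/s)² + k²) is
normalised by its DC value so that k = 0, ω = 0 recovers the point gain;
the per-mode Jacobian then depends on both wavenumber and frequency.
Cosine modes k_j = jπ/L on a bounded patch (L = 10 mm, 32 modes — converged
for the default lead-field dispersion) are summed under the Gaussian lead
field exp(−φ²k²/2) with population dipole weights Q = (0.2, 0, 0.2, 0.6);
population 2 carries no dipole and is treated as inhibitory, so its
efferent kernels (and all self-kernels) get negative sign in the default
(configurable) sign matrix.  Kernel decays are 0.6 mm⁻¹ off-diagonal and
2 mm⁻¹ on-diagonal; conduction speed 3 m/s; φ = √2/16 mm.  Kernel
amplitudes default to canonical-microcircuit values on a 10⁻³ scale (e.g.
α11 = 0.108): on a unit scale the slow loop would be linearly unstable at
k = 0 under this normalisation.  Stability is
checked mode-by-mode on the delay-free linearisation, with the offending
wavenumber named.  The kernel transform is validated only against direct
quadrature of its defining integral — the field model should be regarded
as a reconstruction whose spatial transfer detail is the package's own.

## Likelihood and variational Laplace

Real and imaginary parts of the upper-triangular cross-spectra are stacked
into one residual vector with isotropic Gaussian covariance exp(−λ)·I — a
single noise component; per-channel components and frequency-resolved
structure are out of scope.  The free energy is the Laplace bound

    F = ln p(y|μ, λ) + ln p(μ) + ½ ln|Σ| + (p/2) ln 2π,

with Σ the inverse Gauss–Newton curvature; for linear-Gaussian models this
equals the exact log evidence, which the suite checks to 1e-3 nats (and the
posterior to 1e-6).  Ascent alternates a damped Gauss–Newton parameter
step (Levenberg–Marquardt factor starting at 1/8, halved on acceptance,
×8 on rejection) with a bounded one-dimensional optimisation of λ under a
weakly informative N(0, 16) hyperprior (λ can be fixed for known noise,
in which case no hyperparameter terms enter F).  Steps that would lower F
are rejected, so the recorded trajectory is non-decreasing by
construction; convergence is declared when |ΔF| < 0.01 nats over four
consecutive accepted iterations, within a budget of 64 proposals.
Gradients and curvature use central finite differences (step 1e-4) on the
log-scaled parameters: the forward model is cheap and smooth, and the
scheme is fully deterministic — identical data and settings give
bit-identical results.

All positive parameters (rate constants, gains, observation weights) are
estimated as log-scalings of their template values, so Gaussian priors act
multiplicatively and positivity needs no constraints.  The default prior
on each free log-scaling is N(0, 1/16) (±25% scale changes at one SD).

## Bayesian model reduction and PEB

For Gaussian prior/posterior pairs, replacing the prior (μ0, P0) by a
reduced prior (μr, Pr) gives the reduced posterior precision
P* = Pq + Pr − P0 in closed form and the evidence change
ΔF = ln E_q[p_r(θ)/p_0(θ)], exact for any linear-Gaussian likelihood; an
indefinite P* raises an "incompatible reduction" error.  Switched-off
parameters use prior variance 1e-8 (not exactly zero) to keep precisions
finite.

The group model θ_i = (x_i ⊗ W)β + ε_i (W = I by default, covariate
columns mean-centred so the constant is the group mean) is fitted entirely
through reduction: each subject's contribution to the second-level free
energy, as a function of β, is an exact quadratic derived from its full
posterior, so q(β) is available in one step given the random-effect
log-precision γ; γ (one component, base precision 16, N(0, 16) hyperprior)
is then updated by damped Newton ascent on the profile free energy with the
same accept/reject monotonicity guarantee.  The β prior inherits the
subjects' first-level prior blockwise.  Model-space search scores on/off
combinations of group effects exhaustively up to 16 free effects; beyond
that a greedy backward pruning (switch off the effect whose removal costs
the least evidence) reduces the space first, since exhaustive enumeration
of 2³⁰ models is not literal.  Model probabilities are softmax-normalised
free energies; per-effect inclusion probabilities sum the probabilities of
models containing the effect; Bayesian model averaging moment-matches the
mixture of reduced posteriors.

## Laminar analyses

Current source density is the negative second spatial difference
−(v_{i−1} − 2v_i + v_{i+1})/Δz², which annihilates affine depth profiles
exactly.  Sink onset is detected by z-scoring each interior contact
against its pre-stimulus baseline and finding the earliest run of at least
5 consecutive samples below −z_thresh.  The persistence criterion is 5
samples; the default threshold is 3.5 SD, calibrated on the package's own
generator: with temporally correlated noise a 2-SD criterion false-alarms
on the large majority of noise-only records (22 contacts × 150 samples),
while 3.5 SD gave no false alarms in 60 records and still detects the
injected sink (z ≈ 6.5) within a few ms of onset.

Layer assignment treats the superficial/deep designation of a two-channel
recording as model comparison: the same model is inverted with the
channels as given and swapped, and ΔF is the assignment evidence.
Relabelling the input channels exchanges the two fits, so ΔF is
antisymmetric exactly.  Bipolar re-referencing, where appropriate, is the
caller's responsibility.

## Synthetic data: what it emulates, and what it does not

Generators add i.i.d. Gaussian noise (SD `noise_sd`, default 0.5) to the
stacked Re/Im spectra — exactly the inference model's likelihood.  Cohorts
draw subject parameters from the second-level linear model with
random-effect SD 0.1 on the log scale (≈10% parameter variability);
default cohort size 16; the planted covariate effect is 0.5 on the
log-scaled gains (≈65% per covariate SD), a strong but realistic phenotype
effect, placed on the a23/a32 connections (to and from the slow
interneuron population).  The group benchmark uses a winsorized
standard-normal covariate (|x| ≤ 1.8): because the slow loop sits close to
its stability margin by design, unbounded phenotype scores would
occasionally push a simulated subject into linear instability rather than
merely extreme spectra.  The laminar generator mirrors the two loops —
populations (1, 4) superficial with κ = 0.35 ms⁻¹ and raised loop gains
(gamma peak near 40 Hz), populations (3, 2) deep with κ = 1/35 ms⁻¹
(low-frequency response) — drives both principal populations with shared
input, and attenuates the pink input component (β_u = −4) so the
superficial gamma resonance is the band peak.  With identical mirrored
motifs and zero cross-gain the two channels are exact mirrors, giving the
symmetry checks in the suite.  The depth-LFP generator superposes a
ramped, depth-Gaussian sink (SD 1.5 contacts) on pink noise whose spectrum
is flattened below a low-frequency shoulder so baselines are stationary.

Because generator and likelihood match, passing benchmarks establish
internal correctness — calibration of the intervals, exactness of the
reductions, identifiability under the stated conditions — not robustness
to the mismatches of real recordings: non-Gaussian and
frequency-correlated spectral noise, model misspecification, volume
conduction, non-stationarity.  Frequency grids are 4–100 Hz (1 Hz for
forward checks, 2 Hz for fitting studies) to keep the suite and the
reproduction script desk-scale: the full test run takes well under a
minute and `scripts/acceptance.py` about ten seconds on one CPU.

On interval coverage: marginal 90% credible intervals measure ≈92% across
60 replicates (z-score SD ≈ 0.9, slightly conservative).  The recovery
benchmark counts a run as covered only when *both* gains lie inside their
intervals, so its expected pass rate is ≈0.85 per run and seed-to-seed
counts fluctuate binomially around 8.5/10.

## Open choices and limitations

- The channel-noise spectrum g_n is added to every cross-spectral element,
  matching the generative equation as stated; restricting it to
  auto-spectra would be a one-line change and would slightly lower
  off-diagonal noise floors.
- The noise covariance is a single scaled identity; real cross-spectral
  residuals are frequency-correlated.
- Which populations are "superficial pyramidal / deep pyramidal /
  interneuron" is a labelling convention carried by the observation
  weights and the laminar template, not an identification the model could
  make on its own.
- The field model's exact spatial transfer is validated against its own
  quadrature oracle only.
- PEB makes a single pass: empirical priors are not fed back to
  re-initialise first-level inversions.
- No time-domain (evoked-response) fitting, no conductance-based or
  compartmental dynamics, no MEG sensor geometry.
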