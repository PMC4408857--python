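# Methods

## Model

The package models a single-channel EEG-like signal as the output of two
coupled second-order oscillators, each combining a cubic (Duffing)
stiffness with van der Pol self-excited damping, driven by additive
white noise on the second oscillator:

    x1'' + (k1+k2) x1 - k2 x2 = -b1 x1^3 - b2 (x1-x2)^3 + eps1 x1' (1 - x1^2)
    x2'' - k2 x1 + k2 x2      =  b2 (x1-x2)^3 + eps2 x2' (1 - x2^2) + mu dW

`k1, k2` (1/s^2) set the two linear eigenfrequencies (up to `k = 1e4`,
i.e. ~16 Hz); `b1, b2` harden the resonances with amplitude; `eps1, eps2`
control self-excitation (limit-cycle) strength; `mu` is the intensity of
the Wiener-process excitation, which enters only the second oscillator's
velocity.  The simulated EEG channel is the velocity of the second
oscillator, the state component the noise drives directly.

### Integration

The system is integrated by explicit Euler-Maruyama.  The integration
step is not part of the model definition, so it is a numerical choice:
the default is 10 internal substeps per 125 Hz output sample
(h = 0.8 ms), with the internal trajectory decimated to the output rate.
At the largest admissible stiffness the angular frequency is ~100 rad/s,
so integrating directly on the 8 ms output grid would be marginally
stable for an explicit scheme; h = 0.8 ms keeps `omega*h` below 0.1.
`substeps` is configurable (`substeps=1` mirrors integration directly at
the sample rate).  Initial conditions default to the zero state and the
first 2 s are discarded as transient (configurable `burn_in`); both are
choices, since neither is fixed by the model.  A non-finite state aborts
the simulation with the step index; the fitter converts this into a
large objective penalty.

One caution documented by the convergence utility
(`convergence_check`): endpoint errors are measured against an
8x-refined *self* reference, so the order-1 signature is error ratios
7/3 and 3 between successive halvings (not the textbook factor 2, which
applies against the exact solution).

A structural property worth knowing: the van der Pol pumping acts on
whichever linear eigenmode has the larger participation of the strongly
self-excited oscillator.  With `eps1 >> eps2` the x1-heavy (higher)
eigenmode self-excites, so at stiffness ratios like `k1 ~ 7300,
k2 ~ 4500` the output is dominated by the ~19 Hz mode and is close to a
noisy limit cycle: amplitude-histogram (Shannon) entropy is high
(sinusoid-like bimodal histogram, ~2.2 nats) while sample entropy is low
(~0.3).  Noise-dominated regimes (small `eps`, large `mu`) produce the
opposite pattern.

## Features

Three per-block feature families (block = 40 s at 125 Hz, normalized to
unit SD before feature extraction):

* **Band powers** — Welch periodogram (2-s Hann windows, 50% overlap;
  0.5 Hz resolution resolves the 1 Hz wide lower-delta band), integrated
  over lower-delta (1-2 Hz), upper-delta (2-4), theta (4-8), alpha
  (8-13), lower-beta (13-20), upper-beta (20-30) and gamma (30-60),
  expressed as fractions of total 1-60 Hz power.  Band intervals are
  half-open `[lo, hi)` except gamma, closed at the 60 Hz hardware limit.
* **Shannon entropy** — histogram of the samples into 10 uniform bins
  spanning the observed range; natural logarithm, hence a maximum of
  ln 10 ~ 2.303 nats.  One value per block.
* **Sample entropy** — SampEn(m=2, r=0.25*sigma) with **Euclidean**
  template distance, implemented literally from the pair-counting
  definition: `U^q(r)` is the fraction of ordered template pairs among
  the first N-q starts within distance r, and
  SampEn = -ln(U^{m+1}/U^m).  The numba kernel is required to agree
  *bit-exactly* with an O(N^2) literal reference (tested).  The standard
  SampEn convention is a Chebyshev distance; Euclidean counts fewer
  matches at the same r and reads higher on broadband signals (a
  `metric="chebyshev"` switch supports cross-checks).  Zero
  (m+1)-matches yield `+inf` as a flagged sentinel.

All three families are scale-invariant (bins span the data range; r is
proportional to sigma), which is what makes the unit-SD normalization a
pure convention rather than a modeling step.

## Artifact stage

Eye/muscle artifacts are detected with the amplitude rule: flag samples
deviating more than 4.5 block standard deviations from the block mean
(sigma computed on the raw block, single pass; a two-pass robust variant
re-estimates sigma on the surviving samples, which corrects the
variance inflation the artifacts themselves cause).  Flagged samples are
reconstructed by iterative spectral gap filling: initialize gaps by
linear interpolation, then alternate between projecting onto the K
strongest Fourier components and restoring the known samples, until the
gap values change by less than a relative 1e-6 (at most 100
iterations).  K is chosen to retain 95% of the initialized signal's
spectral power, and the retained component *set* is fixed from that
initial spectrum: with a fixed support each iteration is an alternating
projection between a low-rank spectral subspace and data consistency,
whereas re-selecting the strongest components every iteration can
converge to a spiky solution that reproduces the artifact inside the
gap.  Blocks with >= 50% flagged samples are rejected as
artifact-dominated.

Because a smooth transient's sub-threshold shoulders stay in the data
and would anchor the repair to the artifact shape, the pipeline-level
`clean_block` dilates each detected segment (default 4 samples per
side) before repairing and iterates detect-dilate-repair (at most 3
passes; repairing lowers the block SD, which can push previously
sub-threshold samples over 4.5 sigma).  On surrogate blocks with
injected 8-sigma transients this leaves zero detector flags while
changing sample entropy by < 0.01 on average.

## Delay embedding

Average mutual information is estimated from a 20x20 uniform-bin joint
histogram spanning the series range, in bits (log2).  The embedding
delay is the first interior minimum of the AMI profile over lags up to
50 samples (0.4 s at 125 Hz, covering the slowest band's quarter
period), with the conventional fallback T=2 when no interior minimum
exists.  The default embedding dimension is 2 (matching two-dimensional
reconstructed phase plots); no false-nearest-neighbors selection is
implemented.

## Fitting

The objective matches the model output to a target feature vector:

    J(p) = sum_j (P_Ej - P_Oj)^2 + w1 |S_E - S_O| + w2 |SP_E - SP_O|

with w1 = w2 = 0.35 and the band sum over all seven bands by default (a
switch restricts it to the five hardware-reliable bands).  Model
features are averaged over `n_realizations` independent simulations per
evaluation (default 5); with `noise_mode="frozen"` one set of
realization seeds is reused for every evaluation (common random
numbers), giving a deterministic, optimizable landscape, while
`noise_mode="fresh"` redraws noise every evaluation, mirroring a
per-iteration redraw.  The objective is the plain sum of squared band
errors as written above (not a root-mean-square).

Feasibility box: `0 < k_i <= 1e4`, `0 < b_i <= k_i/2`,
`0 < eps_i <= k_i/3`, `0 <= mu <= 2`.  The search works in a log-scaled
unit cube — k log-uniform over [10, 1e4], b and eps log-uniform
fractions of their k-dependent caps (floor 1e-4 of the cap), mu linear —
so every search point is feasible by construction and uniform sampling
covers all scales.  The k >= 10 search floor (0.5 Hz) excludes only
dynamics below the measured band.  The multi-start search scores a
uniform candidate pool (default 200 points) once, then refines the best
`n_starts` candidates with bounded adaptive Nelder-Mead (<= `max_evals`
function evaluations per start, function tolerance 1e-4).  The pool size
is independent of `n_starts`, so start sets are nested and the best
objective is non-increasing in `n_starts` at fixed seed.  Blown-up or
out-of-bounds evaluations score a 1e6 penalty; penalized candidates are
never selected as starts.

Identifiability caveat: only feature-level recovery is claimed.  Targets
generated by the model at known feasible parameters are recovered to
J < 0.05 with per-band errors < 0.05, but different parameter vectors
can produce nearly identical feature vectors, so parameter-level
recovery is not asserted anywhere.

## Statistics

Per-parameter group comparisons use the two-sided unpaired t-test
(pooled variance; Welch behind a flag) and the two-sided Wilcoxon
rank-sum / Mann-Whitney test (exact enumeration when both n <= 10,
otherwise the tie-corrected normal approximation), each
Bonferroni-adjusted by 7 (one comparison per model parameter).  Power
analysis reports the minimum detectable mean difference
`(z_{1-alpha/2} + z_{power}) * s_pooled * sqrt(1/n_a + 1/n_b)` at
configurable alpha.

## Synthetic data

Surrogate blocks are Fourier-domain Gaussian processes: a white complex
spectrum is shaped by the square root of a target density composed of
seven flat band components plus a 1/f broadband floor (default 30% of
total power), restricted to 1-60 Hz, and normalized to unit SD.  The
expected fractional band powers equal the profile's fractions exactly;
per-block deviations shrink as duration grows.  Default condition
profiles are qualitative-shape choices: alpha-dominant for eyes-closed
controls, slightly theta-dominant for eyes-closed AD, flat
upper-delta-to-lower-beta for the eyes-open conditions.  The default
study-shaped dataset is 20 + 20 control blocks (EC/EO) and 10 + 10 AD
blocks of 40 s each.

What the surrogates do *not* emulate: amplitude non-stationarity,
transient oscillatory bursts, nonlinear phase structure, or any
deterministic dynamics — they are Gaussian by construction.  One
measurable consequence: their Euclidean sample entropy is high (~1.9 at
unit SD), whereas the oscillator model's reachable outputs top out
around ~1.2-1.5 (map obtained by scanning 300 random feasible parameter
sets).  Model fits to surrogate targets therefore carry an irreducible
sample-entropy error of roughly 0.7, i.e. an objective floor around
0.25-0.35, shared across conditions.  Passing fit tests on surrogates
demonstrates spectral matching and procedural correctness, not that the
model can reproduce every statistic of arbitrary broadband signals.

Artifact injection adds Hann-windowed transient bumps (default 3 per
block, 8 sigma, 12 samples) at non-overlapping uniform positions, with
the ground-truth mask returned for detector validation.

## Problem sizes in the test suite

Tests and the acceptance script scale simulation work to keep the suite
fast while preserving each scientific claim: published-value checks use
20 noise seeds of full 40-s blocks; fit-recovery uses 10-s objective
simulations (the self-match floor at the true parameters is J < 0.01,
so the shorter evaluations do not mask recovery); the study replica and
null-calibration runs use reduced group sizes, start counts and
evaluation budgets, stated in the tests themselves.

## Known limitations

* The published per-subject fits cannot be reproduced: the original
  recordings are unavailable, and the published group-mean parameters
  are means over per-block optima, which is not the same object as a fit
  to any one block.  Simulating at those mean parameters (the published
  parameter tables are used as simulation inputs) yields a nearly
  deterministic ~19 Hz limit cycle for the eyes-closed control means —
  beta-dominated, Shannon ~2.19, SampEn ~0.28 — rather than the
  alpha-dominant noisy output the study describes for its per-block
  fits.  The eigenmode-participation argument in the Model section shows
  this is a property of the equations at those parameter values, not of
  the integration accuracy (substep refinements from 2 to 80 per sample
  and both update orders give the same qualitative picture).
* Euclidean (not Chebyshev) sample entropy makes absolute SampEn values
  non-comparable to most published EEG SampEn numbers.
* The noisy objective makes `fresh` noise mode formally ill-posed as an
  optimization target; `frozen` is the default for that reason.
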