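# Methods

This note documents the models implemented in `perisaccade`, the
assumptions behind them, the synthetic data used to exercise them, and the
numerical choices a user should know about.

## The encoding model

A neuron's spiking on a trial is modelled as a conditionally Poisson point
process at 1 ms resolution with conditional intensity

    lambda(t) = f( sum_{x,y,tau} k_{x,y}(t,tau) s_{x,y}(t-tau)
                   + sum_tau h(tau) r(t-tau) + b(t) + b0 ),
    f(u) = rmax / (1 + e^{-u}),

where `s_{x,y}(t)` is the binary one-hot probe stimulus on the grid,
`r(t)` the binary spike train, `k_{x,y}(t,tau)` a *time-varying* stimulus
kernel per probe (time `t` is measured from saccade onset, latency `tau`
from stimulus onset), `h(tau) <= 0` a refractory post-spike kernel, `b(t)`
a stimulus-independent offset tracking saccade-locked baseline changes,
and `b0 = f^{-1}(r0)` pins the resting rate to the measured mean rate.
Because the kernels carry an explicit time-from-saccade axis, the model is
effectively a family of GLMs — one per millisecond — fitted jointly, which
is what lets it resolve modulations that evolve over tens of milliseconds
around a saccade.

All kernels are linear combinations of quadratic B-splines with simple
(non-repeated) knots, so a knot vector of length m yields m − 3 basis
functions.  "Order two" is taken to mean polynomial degree 2: this is the
only convention under which the four default knot grids (26 uniform delay
knots −13…162 ms; 159 uniform time knots −554…552 ms; 23 non-uniform
post-spike knots 1…176 ms; 77 uniform offset knots −570…570 ms) produce
their documented 23 / 156 / 20 / 74 basis functions.  Kernel values outside
the knot-supported span are defined as 0.  Bases are pre-evaluated on the
1 ms lattice and cached; kernels are realized by tensor contraction.

### Fitting

The point-process log-likelihood `LL = sum r log(lambda*Delta) -
lambda*Delta` is maximized by block coordinate ascent under a 35/30/35
train/validation/test split:

1. a *selection screen* first fits, for every stimulus-kernel coefficient
   in isolation (no history, no offset, baseline fixed at b0), a
   one-parameter MLE on each of `n_resamples` random 65 % subsets of the
   trials, and again with spike trains permuted across trials (the
   shuffled control, which preserves each train's autostructure).  A
   coefficient is retained when |mu − mu_ctrl| ≥ 1.5 sigma_ctrl; all
   others are frozen at zero.  The threshold is a fixed design constant;
   the screen's false-positive rate under a fully shuffled null is
   checked empirically in the tests.
2. the retained coefficients are then optimized block-wise — each probe's
   coefficients, then the post-spike block (parameterized as −eta² so the
   kernel stays non-positive), then the offset block — starting all
   parameters at 1e-6 so gradients are non-zero.  Within a block the
   training likelihood is climbed in small quasi-Newton micro-steps
   (L-BFGS with analytic gradients through the sigmoid chain rule), and
   the iterate actually kept is the one with the best *pooled
   train+validation* likelihood along that path (early stopping with a
   small patience, stop also when the relative RMS parameter change drops
   below 1 %).  Blocks cycle until the full parameter vector stops moving
   (relative RMS change < 1e-6) or a cycle cap is hit.
3. test trials are never touched during fitting; they back the held-out
   ΔLL/spk numbers.

`r0` is total spikes over total valid time; `rmax` is the maximum of the
spike trains smoothed with a Gaussian of FWHM 33 ms across trials (floored
at twice r0 so the sigmoid keeps headroom).  `lambda*Delta` is floored at
1e-12 inside logs.  The likelihood is optimized in natural log; reported
ΔLL/spk values are converted to bits.

The early-stopping-by-validation rule is the one genuinely open design
point: the fitting procedure maximizes on training data but accepts
progress by the pooled train+validation objective.  We track the
best-pooled iterate along the training ascent path rather than halting at
the first non-improving step, because the pooled objective is not monotone
along that path and single-dip halting systematically under-fits (shrunk
kernels), which parameter-recovery simulations made obvious.

## Source factorization

Fitted kernel fields are decomposed per (time, delay-bin) cell as

    khat_{x,y}(t,tau) = kfix_{x,y}(tau) + sum_sr G(x,y; phi_sr) + c

where `kfix` is the kernel's time average over the fixation period
([−400, −300] ms), each G is a spatial skew-Gaussian (amplitude, center,
spreads, orientation rho, two CDF skewness factors) tied to the RF, FF, or
ST probe, and c is a spatially uniform baseline (unconstrained scalar per
cell).  Because G and c are constant across the delays inside a bin,
minimizing the summed squared difference over (probes × in-bin delays)
is equivalent to fitting the spatial profile to the in-bin delay average
of `k − kfix`, which is how the residual is implemented.  Delay bins
default to the 28 boundaries {1, 20, 40, 50, 53, …, 145, 151} ms — dense
around the early (50–75 ms) and late (80–150 ms) response latencies.

Constraints: centers within one probe spacing (max-norm) of the nominal
source probe; spreads ≤ 2 probe spacings (≥ 0.05 to keep the profile
non-singular); |rho| ≤ 0.999; |skewness| ≤ 5.  The per-cell optimizer is
bounded trust-region least squares with three seeded starts (previous
bin's solution, nominal centers with unit spread, a perturbed variant);
bins are fitted in increasing delay so warm starts are well defined, and a
failed cell falls back to the previous bin's solution with a warning.
Reconstructed kernels are smoothed along delay with a 10 ms moving average
(shrinking windows at the edges so constants are preserved); stored phi
trajectories stay raw.

Knockouts null a source by replacing its parameters per (t, bin) with
independent seeded draws from that source's own fitted values at
fixation-period times, so its perisaccadic modulation disappears while its
fixation statistics survive.  The aggregate model is the element-wise mean
of the phi and c of several factorizations fitted to resampled kernel
fits (ten by default).

## Simulation and synthetic neurons

Spikes are sampled per bin as Bernoulli(min(lambda·Delta, 1)) at
Delta = 1 ms.  In simulated-history mode the generator signal is evaluated
without history once and then updated sequentially: each sampled spike
adds the post-spike kernel to the future generator, which is the standard
sequential self-history scheme for conditionally Poisson processes.

A synthetic neuron is a ground-truth kernel field built from the same
structure the factorized model assumes: a stationary fixation kernel (an
early response at the RF probe) plus skew-Gaussian sources gated in time
(each with an onset/offset epoch relative to the saccade and a response
latency band).  Latency tuning inside a band is a Gaussian bump by
default — a box profile is available, but sharp-edged boxes are not
representable by wide-knot spline bases and make recovery ceilings
misleading.  Stimuli are balanced pseudorandom probe conditions: each
cycle of `grid.size` conditions uses the cyclic shifts of a *fresh* seeded
permutation, giving exact position-by-location balance per cycle.
Refreshing the base permutation every cycle matters: reusing one
permutation makes the whole sequence deterministic given a single (probe,
time) observation, which destroys kernel identifiability.  Conditions are
tiled back-to-back so probes flash throughout the trial.  Trials default
to saccade-centered spans with a strong exponential refractory post-spike
kernel (−8 e^{−tau/3}).

What the generator does *not* emulate: eye-position jitter and saccade
duration variability, probe-onset timing error, adaptation and slow gain
drift, correlated population activity, and non-Poisson firing beyond
refractoriness.  Passing recovery tests therefore show the estimators are
correct under the model's own assumptions, not that real recordings meet
those assumptions.

## Effect statistics

RF = probe with the maximum fixation-period (−500…−100 ms) rate in the
early window (50–75 ms after stimulus onset).  FF = RF shifted by the
saccade vector rounded to probe units (half away from zero).  ST = the
probe among the 4×4 block centred on the saccade-target location with the
largest perisaccadic-minus-fixation late-window (80–150 ms) rate, with the
FF probe and its 8-neighborhood excluded.  Argmax ties break to the lowest
(row, col).

Saccadic suppression is a significant decrease of the early response to
RF probes flashed −30…0 ms before the saccade; FF/ST-remapping are
significant increases of the late response to FF/ST probes flashed
−50…0 ms before the saccade — all relative to fixation, alpha = 0.05
one-sided, no multiplicity adjustment.  Spike counts use the Wilcoxon
signed-rank test when arms pair by presentation order and fall back to the
rank-sum test for unequal arms (the common case, logged); model-predicted
rates always use the rank-sum test.  Display traces are smoothed with a
Gaussian of FWHM 13 ms; instantaneous-rate estimates from spikes use
FWHM 33 ms; responses are normalized by the grand mean (the mean of the
perisaccadic and fixation mean responses).  Prevalence masks mark, per
(time-from-saccade, latency) cell, a significant one-sided difference of
the stimulus-conditioned rate sample against the fixation sample at the
same latency; population maps average the binary masks × 100 %.

## Evaluation

ΔLL/spk compares a model's likelihood to a NULL model fixed at the average
firing rate, per spike, in bits; perisaccadic spikes live in [0, 150) ms,
fixation spikes in [−450, 0) ms.  Classification agreement between
data-based and model-based effect calls uses sensitivity, accuracy,
precision, GSP = sqrt(sensitivity × precision) and the F-measure with
alpha = 1/2; paired model comparisons use the one-tailed mid-p McNemar
test (p = P(X > b) + ½P(X = b), X ~ Bin(b+c, ½), small when the first
model wins more discordant pairs).  The perisaccadic-to-fixation ratio of
a model over a population is the slope of a zero-intercept IRLS regression
of perisaccadic on fixation ΔLL/spk with the 'fair' weight function
w = 1/(1 + |r|/(1.4 s)), s the MAD-based residual scale; the slope SE
comes from the final weighted fit.  Source contribution percentages
normalize a variant's ratio change by the full-model minus no-source gap.

## Detectability

Stimulus sequences (1000 by default; scaled down in tests) are pushed
through a fitted model with simulated spike history.  For each (probe, t,
latency) cell the AUC between stimulus-conditioned rates and their
shuffle-paired counterpart is computed through the Mann–Whitney rank-sum
identity (hence invariant to monotone rate transforms).  Significance
compares the observed AUC to 100 shuffle-vs-shuffle AUCs with a t-type
one-sample-versus-sample statistic at p < 1e-9 (1e-7 for population
neurons); comparing a single value against a null sample is our
interpretation of the published two-sample comparison.  Peak-detectability
traces take the max over latency (ties to the smallest latency), smooth I
and T over time with a 7 ms moving average, and report only significant
peaks with latency > 50 ms.  Population neurons average one source's
spacing-normalized parameters across qualifying neurons and zero the other
sources; suppression is excluded by default (too few qualifying neurons).

## Problem sizes used in the shipped tests

The recovery and calibration suites run on deliberately small
configurations chosen as this package's own test design: 3×3 probe grids,
600–900 ms trials, a few hundred trials per neuron, coarse time bases
(knot spacing 100–150 ms; PoU-covering spans), the default 150 ms delay
support with 14 ms delay knots, 10–20 screen resamples, and
detectability maps restricted to a few probes, times and latencies.  The
methods themselves default to the full-scale constants listed above.

### Identifiability under complete one-hot stimulation

When exactly one probe is on at every time bin, adding any function
g(t, τ) to *every* probe's kernel changes the generator signal by
Σ_τ g(t, τ), which the offset kernel (and b0) can absorb: the kernel
field is identified only up to a spatially-uniform component.  In
practice the selection screen's sparsity pins this freedom — most
off-source coefficients are frozen at zero, so the uniform direction is
not in the fitted parameter space.  Two further points matter for
recovery studies.  First, kernel *values* are only comparable between
models that share the same sigmoid constants: with a mismatched
(r0, rmax) pair the maximum-likelihood kernels are a warped (to first
order, rescaled) version of the generative ones even when the predicted
rates agree, so recovery fits fix r0 and rmax to the generative values
(both are documented as overridable).  Second, the block ascent
approaches the optimum gradually from its small initialization, and
stopping it early acts like ridge shrinkage on the kernels; recovery
configurations therefore allow enough block cycles for the parameter
vector to stop moving rather than capping cycles aggressively.

## Known limitations

* The block ascent has no convexity guarantee; different seeds can reach
  different (near-equivalent) optima.  The validation-guarded ascent is a
  regularizer, not a proof against overfitting at small trial counts.
* The screen's retention rule is marginal (one coefficient at a time) and
  knowingly admits correlated false positives; the joint fit is what
  shrinks them, and does so only with enough data.
* Per-cell factorization with 25 free parameters needs a grid of at least
  ~6×6 probes to be overdetermined; on smaller grids the recovered
  parameters are not unique even when the reconstruction is good.
* The knockout draw pool is the fitted fixation-period trajectory; very
  short fitted time grids can make that pool degenerate.
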