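# perisaccade

Time-varying Poisson GLMs for millisecond-resolution neural encoding
across saccadic eye movements.

## The problem

Visual neurons do not respond the same way around a rapid eye movement as
they do during fixation: shortly before a saccade the response to a
stimulus in the receptive field (RF) is suppressed, while stimuli at the
*future field* (FF — the RF translated by the saccade vector) and near the
saccade target (ST) start to evoke late responses they never evoke during
fixation.  These modulations unfold over a few tens of milliseconds, far
too fast for conventional time-invariant encoding models.  This package
implements, for experiments that flash single probes on a grid (7 ms
flashes, one probe on screen at a time, trials aligned to saccade onset),
a family of models that track the stimulus–response relationship
millisecond by millisecond and dissociate the modulatory sources behind
it.  It is aimed at systems neuroscientists modelling perisaccadic (or
other rapidly modulated) spiking data, and ships a synthetic-data
generator so the whole pipeline can be exercised and validated without
recordings.

## The models

**Sparse-variable GLM.**  The conditional intensity on a trial is

    λ(t) = f( Σ_{x,y,τ} k_{x,y}(t,τ) s_{x,y}(t−τ) + Σ_τ h(τ) r(t−τ) + b(t) + b0 ),
    f(u) = r_max / (1 + e^(−u)),

with time-varying stimulus kernels `k_{x,y}(t,τ)` per probe (t from
saccade onset, latency τ from stimulus onset), a non-positive post-spike
kernel `h`, an offset kernel `b(t)` for saccade-locked baseline changes,
and `b0 = f⁻¹(r0)`.  All kernels are quadratic B-spline expansions; the
kernel coefficients are screened against a shuffled-response control
(|μ − μ̄| ≥ 1.5 σ̄) and fitted by block coordinate ascent of the
point-process log-likelihood under a 35/30/35
train/validation/test split.

**Factorized model.**  Each fitted kernel field is decomposed per time and
delay bin into a fixation kernel (its average over −400…−300 ms) plus
three spatial skew-Gaussian sources tied to the RF, FF and ST probes and
a uniform baseline — a parsimonious description that lets single sources
be knocked out (replaced by their own fixation-period statistics) or
aggregated across resampled fits.

Downstream analyses: effect classification (suppression / FF-remapping /
ST-remapping, one-sided Wilcoxon tests at α = 0.05), held-out ΔLL/spk
versus a constant-rate NULL model, dichotomous data-vs-model agreement
(sensitivity, accuracy, precision, GSP, F-measure; mid-p McNemar),
robust perisaccadic-to-fixation performance ratios, prevalence maps and
ROC-based spatiotemporal detectability.  See `docs/methods.md` for the
full specification.

## Worked example

Simulate a neuron with a planted FF-remapping source, then classify its
effects from spike counts:

```python
import numpy as np
from perisaccade.experiment import ProbeGrid
from perisaccade.simulate import SourceSchedule, SyntheticNeuronSpec, \
    make_synthetic_neuron
from perisaccade.effects import EffectWindows, classify_from_trials, \
    estimate_locations

grid = ProbeGrid(n_rows=3, n_cols=3, origin=(-9.9, -3.3), dx=3.3, dy=3.3,
                 st=(-6.6, 0.0))
ff = SourceSchedule(center=(1, 0), amplitude=2.0, onset=-50, offset=30,
                    latency_band=(80, 150), sigma=(0.6, 0.6))
spec = SyntheticNeuronSpec(grid=grid, rf_loc=(1, 2), baseline_rate=10.0,
                           rmax=120.0, fixation_gain=0.8,
                           fixation_latency=(40, 100),
                           sources={"FF": ff},
                           trial_length=900, saccade_time=450)
data = make_synthetic_neuron(spec, n_trials=300, seed=7)

locs = estimate_locations(data.trials, saccade_vector_dva=(-6.6, 0.0))
print("locations:", locs)
for effect in ("suppression", "FF", "ST"):
    call = classify_from_trials(data.trials, effect, locs)
    print(f"{effect:12s} p={call.p_value:.2e} significant={call.significant}"
          f"  peri={call.peri_mean:.2f} fix={call.fix_mean:.2f}")
```

Output:

```
locations: {'RF': (1, 2), 'FF': (1, 0), 'ST': (1, 0)}
suppression  p=8.21e-01 significant=False  peri=0.71 fix=0.74
FF           p=1.08e-08 significant=True  peri=0.33 fix=0.11
ST           p=1.08e-08 significant=True  peri=0.33 fix=0.11
```

The planted FF source is detected (mean late-window count triples
perisaccadically, p ≈ 1e-8) while no suppression was planted and none is
called.  On this small grid the estimated ST probe coincides with the FF
probe's neighborhood remainder, so the ST call reads the same planted
source; on the full 9×9 paradigm grid the two are distinct.

A command-line pipeline mirrors the library
(`perisaccade simulate | fit-s | fit-f | aggregate | knockout | evaluate |
effects | detectability`); every run writes a provenance log with its
seed and config hash.

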