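"""Spike simulation and synthetic ground-truth neurons.

Spikes are drawn bin-by-bin as Bernoulli(min(lambda(t) * Delta, 1)) at
Delta = 1 ms, which matches the binning assumption that at most one spike
falls in a bin.  In ``simulated`` history mode the generator signal is
re-evaluated sequentially so that already-generated spikes feed back through
the post-spike kernel (self-history), which is how a conditionally Poisson
process with refractory feedback must be sampled.

Synthetic neurons are built from the same generative structure the fitted
models use: a fixation receptive-field kernel plus skew-Gaussian RF/FF/ST
modulation sources with designed onset/offset epochs, latency bands and
amplitudes, pushed through the sigmoid nonlinearity and sampled as above.
They carry their full ground truth so recovery tests can compare against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .basis import InvalidInputError
from .experiment import (PROBE_DURATION_MS, Condition, ProbeGrid, Trial,
                         TrialSet, generate_conditions, rasterize,
                         rasterize_stream)
from .fmodel import DEFAULT_DELAY_BINS, skew_gaussian
from .smodel import sigmoid_rate


def generate_spikes(rate_fn, n_bins: int, seed: int,
                    history_mode: str = "none",
                    postspike_kernel: Optional[np.ndarray] = None,
                    delta_ms: float = 1.0) -> np.ndarray:
    """Sample a binary spike train from a conditional intensity.

    ``rate_fn`` maps a (possibly partial) spike history to the rate trace in
    spk/s: for ``history_mode='none'`` it is called once with no spikes; for
    ``'simulated'`` the rate is recomputed each bin with the spikes generated
    so far feeding the post-spike term.  When ``postspike_kernel`` (values of
    h(tau), tau = 1.. in ms, non-positive) is given in simulated mode, the
    feedback is applied additively on the generator returned by ``rate_fn``
    as a (generator, rmax) pair.
    """
    rng = np.random.default_rng(seed)
    delta_s = delta_ms / 1000.0
    spikes = np.zeros(n_bins, dtype=np.uint8)
    if history_mode == "none":
        lam = np.asarray(rate_fn(None), dtype=float)
        if np.any(lam < 0):
            raise FloatingPointError("negative rate in spike generation")
        p = np.minimum(lam * delta_s, 1.0)
        return (rng.random(n_bins) < p).astype(np.uint8)
    if history_mode != "simulated":
        raise InvalidInputError("history_mode must be 'none' or 'simulated'")
    gen, rmax = rate_fn(None)
    gen = np.asarray(gen, dtype=float).copy()
    h = np.zeros(0) if postspike_kernel is None \
        else np.asarray(postspike_kernel, dtype=float)
    nh = len(h)
    draws = rng.random(n_bins)
    p = np.minimum(sigmoid_rate(gen, rmax) * delta_s, 1.0)
    for t in range(n_bins):
        if draws[t] < p[t]:
            spikes[t] = 1
            if nh:
                end = min(n_bins, t + 1 + nh)
                gen[t + 1:end] += h[:end - t - 1]
                p[t + 1:end] = np.minimum(
                    sigmoid_rate(gen[t + 1:end], rmax) * delta_s, 1.0)
    return spikes


@dataclass
class SourceSchedule:
    """Perisaccadic modulation epoch of one skew-Gaussian source.

    ``onset``/``offset`` are ms relative to saccade onset during which the
    source is active; ``latency_band`` is the response-latency window (ms
    after stimulus onset) over which the source has weight; ``amplitude``
    scales the source's contribution to the generator signal.
    """

    center: Tuple[float, float]          # probe (row, col) units
    amplitude: float
    onset: float
    offset: float
    latency_band: Tuple[float, float]
    sigma: Tuple[float, float] = (0.8, 0.8)
    rho: float = 0.0
    skew: Tuple[float, float] = (0.0, 0.0)
    # 'stimulus': [onset, offset) gates the stimulus time t - tau, matching
    # how the effects are defined (stimuli flashed perisaccadically evoke
    # modulated responses later); 'response': it gates the response time t.
    gate: str = "stimulus"

    def phi(self) -> Dict[str, float]:
        return {"a": self.amplitude, "mu_x": self.center[1],
                "mu_y": self.center[0], "sigma_x": self.sigma[0],
                "sigma_y": self.sigma[1], "rho": self.rho,
                "gamma_x": self.skew[0], "gamma_y": self.skew[1]}


@dataclass
class SyntheticNeuronSpec:
    """Ground-truth recipe for a simulated probe-grid neuron.

    The fixation kernel gives the stationary receptive field (an early
    response at the RF probe); each scheduled source adds a gated
    skew-Gaussian contribution during its perisaccadic epoch and latency
    band.  Rates are in spk/s.
    """

    grid: ProbeGrid
    rf_loc: Tuple[int, int]
    baseline_rate: float = 10.0
    rmax: float = 120.0
    fixation_gain: float = 4.0
    fixation_latency: Tuple[float, float] = (50.0, 75.0)
    sources: Dict[str, SourceSchedule] = field(default_factory=dict)
    refractory_strength: float = 8.0
    refractory_span_ms: int = 3
    trial_length: int = 1200
    saccade_time: int = 600
    delay_support: int = 150
    smooth_latency: bool = True   # Gaussian latency tuning inside the band
    rf_sigma: float = 0.0         # spatial spread of the fixation RF
                                  # (probe spacings; 0 = single probe)

    def __post_init__(self):
        if self.baseline_rate <= 0 or self.rmax <= self.baseline_rate:
            raise InvalidInputError("need 0 < baseline_rate < rmax")
        for name, src in self.sources.items():
            lo, hi = src.latency_band
            if not (0 <= lo < hi <= self.delay_support):
                raise InvalidInputError(
                    f"latency band of source {name} outside the "
                    f"{self.delay_support} ms delay support")

    @property
    def b0(self) -> float:
        return float(np.log(self.baseline_rate /
                            (self.rmax - self.baseline_rate)))

    def _latency_weight(self, band: Tuple[float, float],
                        delay_grid: np.ndarray) -> np.ndarray:
        """Latency tuning inside a band: Gaussian bump (peak 1) or a box."""
        lo, hi = band
        if not self.smooth_latency:
            return ((delay_grid >= lo) & (delay_grid < hi)).astype(float)
        mid = 0.5 * (lo + hi)
        sd = max((hi - lo) / 4.0, 1.0)
        w = np.exp(-0.5 * ((delay_grid - mid) / sd) ** 2)
        w[(delay_grid < lo - 2 * sd) | (delay_grid > hi + 2 * sd)] = 0.0
        return w

    def kernel_field(self, time_grid: np.ndarray,
                     delay_grid: np.ndarray) -> np.ndarray:
        """(n_rows, n_cols, n_t, n_tau) ground-truth kernel values."""
        nr, nc = self.grid.n_rows, self.grid.n_cols
        time_grid = np.asarray(time_grid, dtype=float)
        delay_grid = np.asarray(delay_grid, dtype=float)
        out = np.zeros((nr, nc, len(time_grid), len(delay_grid)))
        w_fix = self._latency_weight(self.fixation_latency, delay_grid)
        cols, rows = np.meshgrid(np.arange(nc), np.arange(nr))
        if self.rf_sigma > 0:
            d2 = ((rows - self.rf_loc[0]) ** 2
                  + (cols - self.rf_loc[1]) ** 2)
            spatial = np.exp(-0.5 * d2 / self.rf_sigma ** 2)
        else:
            spatial = np.zeros((nr, nc))
            spatial[self.rf_loc] = 1.0
        out += (self.fixation_gain * spatial)[:, :, None, None] \
            * np.broadcast_to(w_fix, (len(time_grid), len(delay_grid)))
        for src in self.sources.values():
            g = skew_gaussian(cols.astype(float), rows.astype(float),
                              src.phi())
            w_tau = self._latency_weight(src.latency_band, delay_grid)
            if src.gate == "stimulus":
                stim_t = time_grid[:, None] - delay_grid[None, :]
                gate = ((stim_t >= src.onset)
                        & (stim_t < src.offset)).astype(float)
                mask2d = gate * w_tau[None, :]
            else:
                t_on = ((time_grid >= src.onset)
                        & (time_grid < src.offset)).astype(float)
                mask2d = np.outer(t_on, w_tau)
            out += g[:, :, None, None] * mask2d[None, None]
        return out

    def kernel_value(self, row: int, col: int, t: float, tau: float) -> float:
        """Ground-truth k_{x,y}(t, tau) at a single lattice point."""
        return float(self.kernel_field(np.array([t]),
                                       np.array([tau]))[row, col, 0, 0])


@dataclass
class SimulatedDataset:
    trials: TrialSet
    spec: SyntheticNeuronSpec
    seed: int


def _generator_signal(spec: SyntheticNeuronSpec, stimulus: np.ndarray,
                      t_start: int,
                      K: Optional[np.ndarray] = None) -> np.ndarray:
    """Stimulus drive + b0 (no history) on the trial lattice.

    ``K`` is the ground-truth kernel field on (probe, trial-time, delay);
    pass it in when simulating many trials on a shared time axis.
    """
    nr, nc, T = stimulus.shape
    gen = np.full(T, spec.b0)
    nd = spec.delay_support
    if K is None:
        K = spec.kernel_field(np.arange(t_start, t_start + T),
                              np.arange(nd))
    flat = stimulus.reshape(nr * nc, T)
    on_any = flat.any(axis=0)
    if not on_any.any():
        return gen
    on = np.flatnonzero(on_any)
    probes = np.argmax(flat[:, on], axis=0)
    dg = np.arange(nd)
    resp = on[:, None] + dg[None, :]
    p = np.broadcast_to(probes[:, None], resp.shape)
    k_idx = np.broadcast_to(dg[None, :], resp.shape)
    ok = resp < T
    Kf = K.reshape(nr * nc, T, nd)
    np.add.at(gen, resp[ok], Kf[p[ok], resp[ok], k_idx[ok]])
    return gen


def make_synthetic_neuron(spec: SyntheticNeuronSpec, n_trials: int,
                          seed: int) -> SimulatedDataset:
    """Simulate a full trial set from a ground-truth neuron.

    Balanced probe conditions are generated, rasterized, and spikes sampled
    with sequential self-history feedback (refractory post-spike kernel).
    Bit-exact reproducible from (spec, n_trials, seed).
    """
    rng = np.random.default_rng(seed)
    span = spec.grid.size * PROBE_DURATION_MS
    per_trial = -(-spec.trial_length // span)
    conds = generate_conditions(spec.grid, n_trials * per_trial,
                                seed=int(rng.integers(2 ** 31)))
    # refractory post-spike kernel: strong suppression over a few ms
    h = -spec.refractory_strength * np.exp(
        -np.arange(1, spec.delay_support + 1) / spec.refractory_span_ms)
    trials = []
    t_start = -spec.saccade_time
    K = spec.kernel_field(np.arange(t_start, t_start + spec.trial_length),
                          np.arange(spec.delay_support))
    for l in range(n_trials):
        stim, t0 = rasterize_stream(
            conds[l * per_trial:(l + 1) * per_trial], spec.grid,
            spec.trial_length, spec.saccade_time)
        gen = _generator_signal(spec, stim, t0, K=K)
        spikes = generate_spikes(lambda _: (gen, spec.rmax),
                                 spec.trial_length,
                                 seed=int(rng.integers(2 ** 31)),
                                 history_mode="simulated",
                                 postspike_kernel=h)
        trials.append(Trial(stimulus=stim, spikes=spikes, t_start=t0,
                            trial_id=l))
    ts = TrialSet(grid=spec.grid, trials=trials,
                  time_axis=(t_start, t_start + spec.trial_length))
    return SimulatedDataset(trials=ts, spec=spec, seed=seed)


def simulate_model_rates(model, stimulus: np.ndarray, t_start: int,
                         seed: int) -> Tuple[np.ndarray, np.ndarray]:
    """Model rate trace with *simulated* spike history for one trial.

    The generator signal is evaluated without history, then spikes are
    sampled sequentially with the model's own post-spike kernel feeding
    back, and the instantaneous rate actually used at each bin is recorded.
    Returns ``(rates, spikes)``.
    """
    from .smodel import generator_signal

    if hasattr(model, "generator"):
        gen = model.generator(stimulus, t_start)
    else:
        gen = generator_signal(model, stimulus, t_start)
    h = model.postspike_kernel()
    T = gen.shape[0]
    rng = np.random.default_rng(seed)
    draws = rng.random(T)
    g = gen.copy()
    spikes = np.zeros(T, dtype=np.uint8)
    nh = len(h)
    delta_s = model.delta_ms / 1000.0
    rates = sigmoid_rate(g, model.rmax)
    for t in range(T):
        if draws[t] < min(rates[t] * delta_s, 1.0):
            spikes[t] = 1
            if nh:
                end = min(T, t + 1 + nh)
                g[t + 1:end] += h[:end - t - 1]
                rates[t + 1:end] = sigmoid_rate(g[t + 1:end], model.rmax)
    return rates, spikes


def simulate_sequences(model, grid: ProbeGrid, n_sequences: int,
                       trial_length: int, saccade_time: int,
                       seed: int) -> Tuple[np.ndarray, np.ndarray, int]:
    """Balanced-condition stimulus sequences driven through a model.

    Generates ``n_sequences`` rasterized probe conditions, runs each through
    the model with simulated spike history, and returns ``(rates,
    probe_at, t_start)`` where ``probe_at[s, t]`` is the flat index of the
    probe on screen (-1 when none) -- the layout the detectability analysis
    consumes.
    """
    rng = np.random.default_rng(seed)
    span = grid.size * PROBE_DURATION_MS
    per_trial = -(-trial_length // span)
    conds = generate_conditions(grid, n_sequences * per_trial,
                                seed=int(rng.integers(2 ** 31)))
    rates = np.empty((n_sequences, trial_length))
    probe_at = np.full((n_sequences, trial_length), -1, dtype=int)
    t_start = -int(saccade_time)
    for s in range(n_sequences):
        stim, t0 = rasterize_stream(
            conds[s * per_trial:(s + 1) * per_trial], grid, trial_length,
            saccade_time)
        r, _ = simulate_model_rates(model, stim, t0,
                                    seed=int(rng.integers(2 ** 31)))
        rates[s] = r
        flat = stim.reshape(-1, trial_length)
        on = flat.any(axis=0)
        probe_at[s, on] = np.argmax(flat[:, on], axis=0)
    return rates, probe_at, t_start


def shuffle_pairing(n_sequences: int, seed: int) -> np.ndarray:
    """A seeded permutation that breaks stimulus-rate correspondence.

    Returns a derangement-checked permutation of ``range(n_sequences)``:
    for n >= 2 the identity is never returned, so at least one pairing is
    broken while every marginal distribution is untouched.
    """
    if n_sequences < 2:
        raise InvalidInputError("need at least 2 sequences to shuffle")
    rng = np.random.default_rng(seed)
    while True:
        perm = rng.permutation(n_sequences)
        if np.any(perm != np.arange(n_sequences)):
            return perm
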