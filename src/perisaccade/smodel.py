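"""Sparse-variable GLM for time-varying perisaccadic encoding.

The conditional intensity of a neuron on trial ``l`` is

    lambda(t) = f( sum_{x,y,tau} k_{x,y}(t,tau) s_{x,y}(t-tau)
                   + sum_tau h(tau) r(t-tau) + b(t) + b0 ),

with f(u) = rmax / (1 + exp(-u)) a saturating sigmoid, k the time-varying
stimulus kernels, h the (non-positive) post-spike kernel, b the offset
kernel tracking saccade-locked baseline changes, and b0 = f^-1(r0) pinning
the resting rate to the measured mean rate r0.  All kernels are linear
combinations of quadratic B-splines (see :mod:`perisaccade.basis`); the
stimulus-kernel coefficients kappa_{x,y,i,j} are first screened against a
shuffled-response control and the retained subset is fitted by block
coordinate ascent of the point-process log-likelihood

    LL = sum_{l,t} r(t) log(lambda(t) Delta) - lambda(t) Delta,

with a 35/30/35 train/validation/test split: blocks are updated on the
training data and an update is kept only while the pooled train+validation
likelihood improves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize

from . import basis as basis_mod
from .basis import (BasisSet1D, BasisSet2D, InvalidInputError, KernelField,
                    realize_offset_kernel, realize_postspike_kernel,
                    realize_stimulus_kernel)
from .experiment import TrialSet

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Bases:
    """Bundle of the four kernel bases used by one model."""

    stimulus: BasisSet2D
    postspike: BasisSet1D
    offset: BasisSet1D

    @classmethod
    def default(cls) -> "Bases":
        b2d, post, off = basis_mod.default_bases()
        return cls(b2d, post, off)

    @classmethod
    def from_knots(cls, delay_knots, time_knots, postspike_knots,
                   offset_knots, delay_support=None,
                   time_support=None) -> "Bases":
        if delay_support is None:
            delay_support = (0, int(max(delay_knots)))
        if time_support is None:
            time_support = (int(min(time_knots)), int(max(time_knots)) + 1)
        b2d = BasisSet2D(
            basis_mod.bspline_basis(delay_knots,
                                    grid=np.arange(*delay_support)),
            basis_mod.bspline_basis(time_knots, grid=np.arange(*time_support)))
        post = basis_mod.bspline_basis(
            postspike_knots, grid=np.arange(1, int(delay_support[1]) + 1))
        off = basis_mod.bspline_basis(offset_knots,
                                      grid=np.arange(*time_support))
        return cls(b2d, post, off)


@dataclass
class SModelConfig:
    """Tunables of the selection screen and block-ascent fit."""

    n_resamples: int = 100          # resampled MLE fits in the screen
    selection_threshold: float = 1.5  # |mu - mu_ctrl| >= thr * sd_ctrl
    init_value: float = 1e-6        # non-zero init so gradients are non-zero
    inner_rel_tol: float = 0.01     # per-block stop: rel RMS change < 1%
    outer_rel_tol: float = 1e-6     # full-cycle stop on the parameter vector
    max_cycles: int = 10
    max_inner_iters: int = 60       # ascent micro-steps per block visit
    lbfgs_maxiter: int = 3          # L-BFGS iterations per micro-step
    inner_patience: int = 5         # micro-steps without pooled-LL gain
    rate_floor: float = 1e-12       # floor on lambda*Delta inside logs
    rmax_fwhm_ms: float = 33.0      # smoothing for the empirical rmax
    screen_newton_iters: int = 25
    # overrides for the empirical rate constants (spk/s); None = estimate
    # from the data.  Fixing these to known generative values matters in
    # recovery studies: kernels are only comparable across models that
    # share the same sigmoid parameterization.
    r0: float = None
    rmax: float = None


@dataclass
class FitSplit:
    """Disjoint train/validation/test trial indices (default 35/30/35 %)."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int = 0

    @classmethod
    def make(cls, n_trials: int, seed: int,
             fractions: Tuple[float, float, float] = (0.35, 0.30, 0.35)
             ) -> "FitSplit":
        if sum(fractions) > 1.0 + 1e-9:
            raise InvalidInputError("split fractions must sum to <= 1")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n_trials)
        n_tr = int(round(fractions[0] * n_trials))
        n_va = int(round(fractions[1] * n_trials))
        return cls(train=np.sort(perm[:n_tr]),
                   validation=np.sort(perm[n_tr:n_tr + n_va]),
                   test=np.sort(perm[n_tr + n_va:]), seed=seed)


@dataclass
class SelectionStats:
    """Per-coefficient resampling statistics behind the selection screen."""

    mean: np.ndarray          # mu_{x,y,i,j} over real-response resamples
    control_mean: np.ndarray  # mu-bar over shuffled-response resamples
    control_sd: np.ndarray    # sigma-bar over shuffled-response resamples
    n_resamples: int = 0


@dataclass
class SModel:
    """Fitted sparse-variable GLM."""

    kappa: np.ndarray            # (n_rows, n_cols, n_i, n_j)
    eta: np.ndarray              # (n_H,)
    beta: np.ndarray             # (n_O,)
    r0: float                    # mean firing rate, spk/s
    rmax: float                  # sigmoid ceiling, spk/s
    bases: Bases
    selection_mask: Optional[np.ndarray] = None   # bool, same shape as kappa
    delta_ms: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.rmax <= 0:
            raise InvalidInputError("rmax must be positive")
        if not (0 < self.r0 < self.rmax):
            raise InvalidInputError("need 0 < r0 < rmax for b0 to exist")

    @property
    def b0(self) -> float:
        """f^-1(r0): the generator offset pinning the resting rate."""
        return float(np.log(self.r0 / (self.rmax - self.r0)))

    def stimulus_kernels(self) -> KernelField:
        return realize_stimulus_kernel(self.kappa, self.bases.stimulus)

    def postspike_kernel(self) -> np.ndarray:
        return realize_postspike_kernel(self.eta, self.bases.postspike)

    def offset_kernel(self) -> np.ndarray:
        return realize_offset_kernel(self.beta, self.bases.offset)


def sigmoid_rate(u: np.ndarray, rmax: float) -> np.ndarray:
    """f(u) = rmax / (1 + e^-u); bounded in (0, rmax)."""
    out = np.empty_like(u, dtype=float)
    pos = u >= 0
    out[pos] = rmax / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = rmax * eu / (1.0 + eu)
    return out


def estimate_rate_constants(trials: TrialSet,
                            fwhm_ms: float = 33.0) -> Tuple[float, float]:
    """Empirical (r0, rmax) in spk/s.

    r0 is total spikes over total valid time; rmax is the maximum of the
    spike trains smoothed with a Gaussian (FWHM ``fwhm_ms``), taken across
    trials, never below twice r0 so the sigmoid has headroom.
    """
    spikes = trials.spike_matrix().astype(float)
    valid = trials.valid_matrix()
    total_s = valid.sum() / 1000.0
    r0 = float(spikes[valid].sum() / total_s) if total_s > 0 else 0.0
    sigma = fwhm_ms * FWHM_TO_SIGMA
    sm = gaussian_filter1d(spikes * 1000.0, sigma=sigma, axis=1)
    rmax = float(max(sm.max(initial=0.0), 2.0 * r0, 1.0))
    return r0, rmax


# ---------------------------------------------------------------------------
# Design caches: basis functions and stimulus convolutions on the trial axis

def _eval_on_times(b: BasisSet1D, times: np.ndarray) -> np.ndarray:
    return b.evaluate(times.astype(float))


def delay_convolution(stimulus_probe: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Causal convolution C_i(t) = sum_tau U_i(tau) s(t - tau).

    ``stimulus_probe`` is a binary (T,) train of on-bins for one probe and
    ``U`` the (n_i, n_tau) delay basis with tau starting at the first grid
    value of the basis (0 for stimulus kernels).
    """
    T = stimulus_probe.shape[-1]
    ni, ntau = U.shape
    C = np.zeros((ni, T))
    on = np.flatnonzero(stimulus_probe)
    for t0 in on:
        end = min(T, t0 + ntau)
        C[:, t0:end] += U[:, :end - t0]
    return C


def history_convolution(spikes: np.ndarray, H: np.ndarray,
                        tau0: int = 1) -> np.ndarray:
    """P_i(t) = sum_tau H_i(tau) r(t - tau), tau from ``tau0`` (causal)."""
    T = spikes.shape[-1]
    ni, ntau = H.shape
    P = np.zeros((ni, T))
    on = np.flatnonzero(spikes)
    for t0 in on:
        lo = t0 + tau0
        end = min(T, lo + ntau)
        if lo < T:
            P[:, lo:end] += H[:, :end - lo]
    return P


class DesignCache:
    """Pre-computed regressors for one trial set under one basis bundle."""

    def __init__(self, trials: TrialSet, bases: Bases):
        self.trials = trials
        self.bases = bases
        self.grid = trials.grid
        t0, t1 = trials.time_axis
        self.times = np.arange(t0, t1)
        self.T = len(self.times)
        self.Vt = _eval_on_times(bases.stimulus.time_basis, self.times)
        self.Ot = _eval_on_times(bases.offset, self.times)
        self.spikes = trials.spike_matrix().astype(float)
        self.valid = trials.valid_matrix()
        U = bases.stimulus.delay_basis.values
        stim = trials.stimulus_tensor()
        n_l = len(trials)
        self._C: Dict[Tuple[int, int], np.ndarray] = {}
        self._stim = stim
        self._U = U
        H = bases.postspike.values
        self.P = np.stack([history_convolution(self.spikes[l], H)
                           for l in range(n_l)])   # (L, n_H, T)

    def C(self, row: int, col: int) -> np.ndarray:
        """(L, n_i, T) delay-convolved stimulus for one probe; lazy+cached."""
        key = (row, col)
        if key not in self._C:
            L = self._stim.shape[0]
            self._C[key] = np.stack([
                delay_convolution(self._stim[l, row, col], self._U)
                for l in range(L)])
        return self._C[key]


# ---------------------------------------------------------------------------
# CIF and likelihood

def generator_signal(model: SModel, stimulus: np.ndarray, t_start: int,
                     design: Optional[dict] = None) -> np.ndarray:
    """History-free generator signal u(t) = stimulus drive + b(t) + b0."""
    n_r, n_c, T = stimulus.shape
    times = np.arange(t_start, t_start + T)
    if design is not None and "Vt" in design:
        Vt, Ot = design["Vt"], design["Ot"]
    else:
        Vt = _eval_on_times(model.bases.stimulus.time_basis, times)
        Ot = _eval_on_times(model.bases.offset, times)
    U = model.bases.stimulus.delay_basis.values
    u = np.full(T, model.b0, dtype=float)
    u += model.beta @ Ot
    for r in range(n_r):
        for c in range(n_c):
            kap = model.kappa[r, c]
            if not np.any(kap):
                continue
            if not stimulus[r, c].any():
                continue
            Ci = delay_convolution(stimulus[r, c].astype(float), U)
            u += np.einsum("ij,it,jt->t", kap, Ci, Vt, optimize=True)
    return u


def kernel_drive(kernels: KernelField, stimulus: np.ndarray,
                 t_start: int) -> np.ndarray:
    """Stimulus drive sum_{x,y,tau} k_{x,y}(t,tau) s_{x,y}(t-tau).

    Works directly on a realized kernel field (e.g. a reconstructed,
    factorized one); kernel time points are matched to trial times by
    nearest neighbour so coarsely fitted (sub-sampled) fields act as step
    functions, and times outside the field's support contribute nothing.
    """
    nr, nc, T = stimulus.shape
    tg = kernels.time_grid.astype(int)
    dg = kernels.delay_grid.astype(int)
    times = np.arange(t_start, t_start + T)
    flat = stimulus.reshape(nr * nc, T)
    on_any = flat.any(axis=0)
    probe_at = np.full(T, -1, dtype=int)
    probe_at[on_any] = np.argmax(flat[:, on_any], axis=0)
    u = np.zeros(T)
    K = kernels.values.reshape(nr * nc, len(tg), len(dg))
    t_lo, t_hi = tg[0], tg[-1]
    on = np.flatnonzero(probe_at >= 0)
    if on.size == 0:
        return u
    # all (on-bin, delay) contribution pairs at once
    resp = on[:, None] + dg[None, :]                 # receiving bins
    p = np.broadcast_to(probe_at[on][:, None], resp.shape)
    k_idx = np.broadcast_to(np.arange(len(dg))[None, :], resp.shape)
    ok = resp < T
    resp, p, k_idx = resp[ok], p[ok], k_idx[ok]
    t_resp = times[resp]
    in_sup = (t_resp >= t_lo) & (t_resp <= t_hi)
    resp, p, k_idx, t_resp = (resp[in_sup], p[in_sup], k_idx[in_sup],
                              t_resp[in_sup])
    ti = np.clip(np.searchsorted(tg, t_resp), 0, len(tg) - 1)
    before = (ti > 0) & (np.abs(tg[np.maximum(ti - 1, 0)] - t_resp)
                         < np.abs(tg[ti] - t_resp))
    ti[before] -= 1
    np.add.at(u, resp, K[p, ti, k_idx])
    return u


def cif(model: SModel, stimulus: np.ndarray, t_start: int,
        spikes: Optional[np.ndarray] = None,
        design: Optional[dict] = None) -> np.ndarray:
    """Conditional intensity (spk/s) for one trial.

    ``stimulus`` is the (n_rows, n_cols, T) binary lattice; ``spikes`` feeds
    the post-spike term (pass None for a history-free rate).  The caller
    chooses whether the history is the true, a simulated, or no spike train.
    """
    u = generator_signal(model, stimulus, t_start, design=design)
    if spikes is not None and np.any(model.eta):
        H = model.bases.postspike.values
        P = history_convolution(np.asarray(spikes, dtype=float), H)
        u += -(model.eta ** 2) @ P
    return sigmoid_rate(u, model.rmax)


def log_likelihood(rate: np.ndarray, spikes: np.ndarray,
                   delta_ms: float = 1.0,
                   valid: Optional[np.ndarray] = None,
                   floor: float = 1e-12) -> float:
    """Point-process log-likelihood (nats) of binary spike trains.

    ``rate`` in spk/s and ``spikes`` share shape; invalid (padding) bins are
    skipped; lambda*Delta is floored at ``floor`` inside the log.
    """
    rate = np.asarray(rate, dtype=float)
    spikes = np.asarray(spikes, dtype=float)
    if rate.shape != spikes.shape:
        raise InvalidInputError("rate and spikes must share a shape")
    if np.any(rate < 0):
        raise InvalidInputError("negative rate passed to the likelihood")
    lam_dt = rate * (delta_ms / 1000.0)
    term = spikes * np.log(np.maximum(lam_dt, floor)) - lam_dt
    if valid is not None:
        term = term[valid]
    return float(term.sum())


# ---------------------------------------------------------------------------
# Parameter-selection screen

def _newton_1d(x: np.ndarray, r: np.ndarray, b0: float, rmax: float,
               delta_s: float, iters: int = 25) -> float:
    """MLE of kappa in lambda = f(kappa*x + b0) over active bins.

    Bins with x = 0 do not affect the argmax and must be excluded by the
    caller.  Damped Newton with a gradient-ascent fallback.
    """
    kap = 0.0
    for _ in range(iters):
        u = kap * x + b0
        lam = sigmoid_rate(u, rmax)
        w = 1.0 - lam / rmax
        g_bin = (r - lam * delta_s) * w
        grad = float(g_bin @ x)
        dlam = lam * w
        dg = dlam * (-delta_s * w) + (r - lam * delta_s) * (-dlam / rmax)
        hess = float((dg * x) @ x)
        if hess < 0:
            step = -grad / hess
        else:
            step = 0.1 * np.sign(grad)
        step = float(np.clip(step, -5.0, 5.0))
        kap += step
        if abs(step) < 1e-8:
            break
    return kap


def _rate_constants(trials: TrialSet, config: "SModelConfig"):
    r0, rmax = estimate_rate_constants(trials, config.rmax_fwhm_ms)
    if config.r0 is not None:
        r0 = float(config.r0)
    if config.rmax is not None:
        rmax = float(config.rmax)
    return r0, rmax


def select_parameters(trials: TrialSet, bases: Bases,
                      config: Optional[SModelConfig] = None,
                      seed: int = 0,
                      design: Optional[DesignCache] = None
                      ) -> Tuple[np.ndarray, SelectionStats]:
    """Screen stimulus-kernel coefficients against a shuffled control.

    For every kappa index, a one-parameter model (no history, no offset) is
    fitted by MLE on ``n_resamples`` random 65% subsets of the trials, once
    with the real spike trains and once with spike trains permuted across
    trials.  An index is retained when |mu - mu_ctrl| >= 1.5 * sd_ctrl.
    """
    config = config or SModelConfig()
    if config.n_resamples < 2:
        raise InvalidInputError("need at least 2 resamples")
    rng = np.random.default_rng(seed)
    if design is None:
        design = DesignCache(trials, bases)
    n_l = len(trials)
    spikes = design.spikes
    if spikes.sum() == 0:
        import warnings
        ni, nj = bases.stimulus.shape
        shape = (trials.grid.n_rows, trials.grid.n_cols, ni, nj)
        warnings.warn("all-zero spike trains: empty selection mask")
        z = np.zeros(shape)
        return np.zeros(shape, dtype=bool), SelectionStats(z, z, z, 0)

    r0, rmax = _rate_constants(trials, config)
    b0 = float(np.log(r0 / (rmax - r0)))
    delta_s = 1e-3
    ni, nj = bases.stimulus.shape
    n_keep = int(round(0.65 * n_l))
    subsets = [rng.choice(n_l, size=n_keep, replace=False)
               for _ in range(config.n_resamples)]
    perms = [rng.permutation(n_l) for _ in range(config.n_resamples)]
    Vt = design.Vt
    shape = (trials.grid.n_rows, trials.grid.n_cols, ni, nj)
    mu = np.zeros(shape)
    mu_c = np.zeros(shape)
    sd_c = np.zeros(shape)
    for row in range(trials.grid.n_rows):
        for col in range(trials.grid.n_cols):
            C = design.C(row, col)          # (L, ni, T)
            for i in range(ni):
                Ci = C[:, i, :]
                for j in range(nj):
                    X = Ci * Vt[j][None, :]   # (L, T)
                    act_l, act_t = np.nonzero(X)
                    if act_l.size == 0:
                        continue
                    xa = X[act_l, act_t]
                    vals = np.empty(config.n_resamples)
                    ctrl = np.empty(config.n_resamples)
                    for s_ix in range(config.n_resamples):
                        sub = subsets[s_ix]
                        in_sub = np.isin(act_l, sub)
                        xs = xa[in_sub]
                        ls, ts = act_l[in_sub], act_t[in_sub]
                        rr = spikes[ls, ts]
                        vals[s_ix] = _newton_1d(
                            xs, rr, b0, rmax, delta_s,
                            config.screen_newton_iters)
                        rr_sh = spikes[perms[s_ix][ls], ts]
                        ctrl[s_ix] = _newton_1d(
                            xs, rr_sh, b0, rmax, delta_s,
                            config.screen_newton_iters)
                    mu[row, col, i, j] = vals.mean()
                    mu_c[row, col, i, j] = ctrl.mean()
                    sd_c[row, col, i, j] = ctrl.std(ddof=1)
    mask = apply_selection_rule(mu, mu_c, sd_c, config.selection_threshold)
    return mask, SelectionStats(mu, mu_c, sd_c, config.n_resamples)


def apply_selection_rule(mu: np.ndarray, control_mean: np.ndarray,
                         control_sd: np.ndarray,
                         threshold: float = 1.5) -> np.ndarray:
    """Retention rule: |mu - mu_ctrl| >= threshold * sd_ctrl (sd > 0)."""
    return (np.abs(mu - control_mean) >= threshold * control_sd) \
        & (control_sd > 0)


# ---------------------------------------------------------------------------
# Block coordinate ascent

class _FitState:
    """Mutable generator-signal bookkeeping during block ascent."""

    def __init__(self, trials: TrialSet, bases: Bases, mask: np.ndarray,
                 config: SModelConfig, design: DesignCache,
                 split: FitSplit):
        self.design = design
        self.config = config
        self.split = split
        self.r0, self.rmax = _rate_constants(trials, config)
        self.b0 = float(np.log(self.r0 / (self.rmax - self.r0)))
        self.mask = mask
        shape = mask.shape
        self.kappa = np.where(mask, config.init_value, 0.0)
        self.eta = np.full(bases.postspike.n_basis, config.init_value)
        self.beta = np.full(bases.offset.n_basis, config.init_value)
        self.spikes = design.spikes
        self.valid = design.valid
        self.delta_s = 1e-3
        L, T = self.spikes.shape
        # Cached per-source drive components; u = b0 + stim + hist + off
        self.stim_drive = np.zeros((L, T))
        self.blocks = [(r, c) for r in range(shape[0]) for c in range(shape[1])
                       if mask[r, c].any()]
        for (r, c) in self.blocks:
            self.stim_drive += self._probe_drive(r, c)
        self.hist_drive = np.einsum(
            "i,lit->lt", -(self.eta ** 2), design.P)
        self.off_drive = self.beta @ design.Ot

    def _probe_drive(self, row, col, kap_block=None):
        kap = self.kappa[row, col] if kap_block is None else kap_block
        idx = np.nonzero(self.mask[row, col])
        if idx[0].size == 0:
            return 0.0
        C = self.design.C(row, col)
        out = 0.0
        for i, j in zip(*idx):
            if kap[i, j] != 0.0:
                out = out + kap[i, j] * C[:, i, :] * self.design.Vt[j][None, :]
        if np.isscalar(out):
            return np.zeros_like(self.stim_drive)
        return out

    def generator(self):
        return self.b0 + self.stim_drive + self.hist_drive + self.off_drive

    def ll(self, u, trial_idx):
        lam = sigmoid_rate(u[trial_idx], self.rmax)
        lam_dt = lam * self.delta_s
        r = self.spikes[trial_idx]
        v = self.valid[trial_idx]
        term = r * np.log(np.maximum(lam_dt, self.config.rate_floor)) - lam_dt
        return float(term[v].sum())

    def grad_common(self, u, trial_idx):
        """d LL / d u per bin for the given trials (zero on invalid bins)."""
        lam = sigmoid_rate(u[trial_idx], self.rmax)
        g = (self.spikes[trial_idx] - lam * self.delta_s) * \
            (1.0 - lam / self.rmax)
        g[~self.valid[trial_idx]] = 0.0
        return g


def _optimize_block(state: _FitState, theta0: np.ndarray, pack, unpack,
                    drive_of, grad_of) -> Tuple[np.ndarray, bool]:
    """Generic inner-block ascent with pooled train+validation guard.

    Maximizes the training likelihood in micro-steps (a few L-BFGS
    iterations each); a micro-step is accepted only while the pooled
    train+validation likelihood improves; iteration stops when the relative
    RMS change of the block parameters drops below the configured 1%.
    """
    cfg = state.config
    tr, va = state.split.train, state.split.validation
    pooled = np.concatenate([tr, va])
    base_u_tr = state.generator()[tr] - drive_of(theta0)[tr]
    base_u_po = state.generator()[pooled] - drive_of(theta0)[pooled]

    def neg_ll_grad(theta):
        d = drive_of(theta)
        u = base_u_tr + d[tr]
        lam = sigmoid_rate(u, state.rmax)
        lam_dt = lam * state.delta_s
        r = state.spikes[tr]
        v = state.valid[tr]
        term = r * np.log(np.maximum(lam_dt, cfg.rate_floor)) - lam_dt
        g_bin = (r - lam_dt) * (1.0 - lam / state.rmax)
        g_bin[~v] = 0.0
        return -float(term[v].sum()), -grad_of(theta, g_bin, tr)

    def pooled_ll(theta):
        d = drive_of(theta)
        u = base_u_po + d[pooled]
        lam_dt = sigmoid_rate(u, state.rmax) * state.delta_s
        r = state.spikes[pooled]
        v = state.valid[pooled]
        term = r * np.log(np.maximum(lam_dt, cfg.rate_floor)) - lam_dt
        return float(term[v].sum())

    theta = theta0.copy()
    best_theta = theta.copy()
    best_pooled = pooled_ll(theta)
    start_pooled = best_pooled
    stall = 0
    for it in range(cfg.max_inner_iters):
        res = minimize(neg_ll_grad, theta, jac=True, method="L-BFGS-B",
                       options={"maxiter": cfg.lbfgs_maxiter})
        cand = res.x
        if not np.all(np.isfinite(cand)):
            raise FloatingPointError("non-finite parameters in block ascent")
        cand_pooled = pooled_ll(cand)
        rms_prev = np.sqrt(np.mean(theta ** 2))
        rel = np.sqrt(np.mean((cand - theta) ** 2)) / max(rms_prev, 1e-300)
        theta = cand
        if cand_pooled > best_pooled + 1e-9:
            best_pooled = cand_pooled
            best_theta = cand.copy()
            stall = 0
        else:
            # training ascent no longer helps held-in validation: early stop
            stall += 1
            if stall >= cfg.inner_patience:
                break
        if rel < cfg.inner_rel_tol and it > 0:
            break
    changed = best_pooled > start_pooled + 1e-9
    return best_theta, changed


def fit(trials: TrialSet, split: Optional[FitSplit] = None,
        config: Optional[SModelConfig] = None,
        bases: Optional[Bases] = None,
        selection_mask: Optional[np.ndarray] = None,
        seed: int = 0) -> SModel:
    """Fit the sparse-variable GLM by cross-validated block coordinate ascent.

    Blocks are visited as: the selected kappa coefficients of each probe in
    turn, then the post-spike eta block, then the offset beta block; cycles
    repeat until the full parameter vector stops moving.  Test trials are
    never touched.  If no ``selection_mask`` is given the screen is run
    first with the given config.
    """
    config = config or SModelConfig()
    bases = bases or Bases.default()
    if split is None:
        split = FitSplit.make(len(trials), seed)
    design = DesignCache(trials, bases)
    if selection_mask is None:
        selection_mask, _ = select_parameters(trials, bases, config,
                                              seed=seed, design=design)
    state = _FitState(trials, bases, selection_mask, config, design, split)
    if not state.blocks:
        return SModel(kappa=np.zeros_like(state.kappa),
                      eta=np.zeros_like(state.eta) * 0.0,
                      beta=np.zeros_like(state.beta) * 0.0,
                      r0=state.r0, rmax=state.rmax, bases=bases,
                      selection_mask=selection_mask, seed=seed)

    Vt, Ot, P = design.Vt, design.Ot, design.P

    def full_vector():
        return np.concatenate([state.kappa[state.mask].ravel(),
                               state.eta, state.beta])

    for _cycle in range(config.max_cycles):
        prev = full_vector()
        any_change = False
        # -- step 1: per-probe stimulus-kernel blocks
        for (row, col) in state.blocks:
            idx = np.nonzero(state.mask[row, col])
            C = design.C(row, col)
            Xb = np.stack([C[:, i, :] * Vt[j][None, :]
                           for i, j in zip(*idx)])      # (P, L, T)
            theta0 = state.kappa[row, col][idx]

            def drive_of(th, Xb=Xb):
                return np.einsum("p,plt->lt", th, Xb)

            def grad_of(th, g_bin, trs, Xb=Xb):
                return np.einsum("plt,lt->p", Xb[:, trs, :], g_bin)

            old_drive = state._probe_drive(row, col)
            theta, ch = _optimize_block(state, theta0, None, None,
                                        drive_of, grad_of)
            if ch:
                state.kappa[row, col][idx] = theta
                state.stim_drive += state._probe_drive(row, col) - old_drive
                any_change = True
        # -- step 2: post-spike block (h = -eta^2 H, chain rule in eta)
        theta0 = state.eta.copy()

        def drive_of_eta(th):
            return np.einsum("i,lit->lt", -(th ** 2), P)

        def grad_of_eta(th, g_bin, trs):
            return -2.0 * th * np.einsum("lit,lt->i", P[trs], g_bin)

        theta, ch = _optimize_block(state, theta0, None, None,
                                    drive_of_eta, grad_of_eta)
        if ch:
            state.eta = theta
            state.hist_drive = drive_of_eta(theta)
            any_change = True
        # -- step 3: offset block
        theta0 = state.beta.copy()

        def drive_of_beta(th):
            return np.broadcast_to(th @ Ot, state.stim_drive.shape)

        def grad_of_beta(th, g_bin, trs):
            return np.einsum("jt,lt->j", Ot, g_bin)

        theta, ch = _optimize_block(state, theta0, None, None,
                                    drive_of_beta, grad_of_beta)
        if ch:
            state.beta = theta
            state.off_drive = theta @ Ot
            any_change = True
        # -- step 4: repeat until no update
        now = full_vector()
        rel = np.sqrt(np.mean((now - prev) ** 2)) / \
            max(np.sqrt(np.mean(prev ** 2)), 1e-300)
        if not any_change or rel < config.outer_rel_tol:
            break

    return SModel(kappa=state.kappa, eta=state.eta, beta=state.beta,
                  r0=state.r0, rmax=state.rmax, bases=bases,
                  selection_mask=selection_mask, seed=seed)


def predict_rates(model: SModel, trials: TrialSet,
                  history: str = "true") -> np.ndarray:
    """Model rate traces (spk/s) for every trial of a set.

    ``history``: 'true' feeds each trial's recorded spikes into the
    post-spike term; 'none' drops the history term.  (Simulated history
    lives in :mod:`perisaccade.simulate`.)
    """
    if history not in ("true", "none"):
        raise InvalidInputError("history must be 'true' or 'none'")
    t0, _ = trials.time_axis
    times = np.arange(*trials.time_axis)
    design = {"Vt": _eval_on_times(model.bases.stimulus.time_basis, times),
              "Ot": _eval_on_times(model.bases.offset, times)}
    out = np.empty((len(trials), len(times)))
    for l, tr in enumerate(trials.trials):
        sp = tr.spikes if history == "true" else None
        out[l] = cif(model, tr.stimulus, t0, spikes=sp, design=design)
    return out
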