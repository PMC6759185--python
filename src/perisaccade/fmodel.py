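"""Factorization of fitted stimulus kernels into modulatory sources.

A fitted time-varying stimulus-kernel field is decomposed, at each time
``t`` and delay bin, into

    khat_{x,y}(t,tau) = kfix_{x,y}(tau) + sum_sr G(x,y; phi_sr(t,tau)) + c(t,tau)

where ``kfix`` is the time-averaged kernel over the fixation period
([-400, -300] ms before saccade), each ``G`` is a spatial skew-Gaussian
tied to one of the RF / FF / ST modulation sources, and ``c`` is a spatially
uniform baseline.  Parameters are estimated per (time, delay-bin) cell by
bounded nonlinear least squares on the sum-squared kernel difference, with
the source centers confined to one probe spacing of their nominal probe,
spreads to two probe spacings, |rho| <= 1 and |skewness| <= 5.  The
reconstructed kernels are smoothed along delay with a 10 ms moving average
to remove bin-edge discontinuities.

Knockout variants replace a source's parameters with draws from its own
fixation-period values, which nulls its perisaccadic modulation while
preserving its fixation statistics; the aggregate model is the element-wise
mean of several factorizations fitted to resampled kernel fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.special import ndtr

from .basis import InvalidInputError, KernelField

SOURCES = ("RF", "FF", "ST")
PHI_FIELDS = ("a", "mu_x", "mu_y", "sigma_x", "sigma_y", "rho",
              "gamma_x", "gamma_y")
N_PHI = len(PHI_FIELDS)

# Delay-bin boundaries (ms): dense around the typical early/late response
# latencies, coarse elsewhere.  28 boundaries -> 27 bins over the 150 ms
# delay support.
DEFAULT_DELAY_BINS = (1, 20, 40, 50, 53, 56, 59, 62, 65, 68, 71, 74, 77, 80,
                      85, 90, 95, 100, 105, 110, 115, 120, 125, 130, 135,
                      140, 145, 151)

FIXATION_WINDOW = (-400, -300)


def _phi_array(phi) -> np.ndarray:
    if isinstance(phi, dict):
        return np.array([phi[f] for f in PHI_FIELDS], dtype=float)
    phi = np.asarray(phi, dtype=float)
    if phi.shape[-1] != N_PHI:
        raise InvalidInputError(f"phi must have {N_PHI} entries")
    return phi


def skew_gaussian(x, y, phi):
    """Spatial skew-Gaussian source profile at probe coordinates (x, y).

    ``phi`` is a dict or length-8 array ordered as ``PHI_FIELDS``:
    amplitude a, center (mu_x, mu_y), spreads (sigma_x, sigma_y),
    orientation rho, and skewnesses (gamma_x, gamma_y).  The profile is an
    orientation-correlated bivariate Gaussian multiplied by two standard
    normal CDF skew factors; with zero skews its value at the center is a/4.
    """
    a, mx, my, sx, sy, rho, gx, gy = _phi_array(phi)
    if sx <= 0 or sy <= 0:
        raise InvalidInputError("spreads must be positive")
    if abs(rho) >= 1:
        raise InvalidInputError("|rho| = 1 gives a singular covariance")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    zx = (x - mx) / sx
    zy = (y - my) / sy
    q = (zx ** 2 + zy ** 2 - 2.0 * rho * zx * zy) / (2.0 * (1.0 - rho ** 2))
    return a * np.exp(-q) * ndtr(gx * (x - mx)) * ndtr(gy * (y - my))


def fixation_kernel(s_kernels: KernelField, t1: int = FIXATION_WINDOW[0],
                    t2: int = FIXATION_WINDOW[1]) -> np.ndarray:
    """Time-average of the kernel field over the fixation window [t1, t2]."""
    sel = (s_kernels.time_grid >= t1) & (s_kernels.time_grid <= t2)
    if not np.any(sel):
        raise InvalidInputError(
            f"fixation window [{t1}, {t2}] outside the kernel time support")
    return s_kernels.values[:, :, sel, :].mean(axis=2)


def moving_average(x: np.ndarray, span: int, axis: int = -1) -> np.ndarray:
    """Moving average with shrinking windows at the edges (no zero padding)."""
    x = np.moveaxis(np.asarray(x, dtype=float), axis, -1)
    n = x.shape[-1]
    out = np.empty_like(x)
    half_lo = (span - 1) // 2
    half_hi = span - 1 - half_lo
    for i in range(n):
        lo = max(0, i - half_lo)
        hi = min(n, i + half_hi + 1)
        out[..., i] = x[..., lo:hi].mean(axis=-1)
    return np.moveaxis(out, -1, axis)


@dataclass
class FactorizationConfig:
    delay_bins: Tuple[int, ...] = DEFAULT_DELAY_BINS
    fixation_window: Tuple[int, int] = FIXATION_WINDOW
    smoothing_span_ms: int = 10
    time_step: int = 1            # fit every k-th time point of the kernel
    max_center_shift: float = 1.0  # probe spacings (max-norm)
    max_spread: float = 2.0        # probe spacings
    max_skew: float = 5.0
    min_spread: float = 0.05
    max_nfev: int = 200
    perturb_scale: float = 0.3

    def __post_init__(self):
        b = np.asarray(self.delay_bins)
        if not np.all(np.diff(b) > 0):
            raise InvalidInputError("delay-bin boundaries must increase")


@dataclass
class FModel:
    """Per-(time, delay-bin) source parameters plus fixation kernel."""

    sources: Dict[str, np.ndarray]      # sr -> (n_t, n_bins, 8)
    baseline: np.ndarray                # c(t, bin): (n_t, n_bins)
    fixation: np.ndarray                # (n_rows, n_cols, n_tau)
    bins: np.ndarray                    # boundaries, len n_bins + 1
    time_grid: np.ndarray               # (n_t,) ms from saccade
    delay_grid: np.ndarray              # (n_tau,) ms
    source_locs: Dict[str, Tuple[int, int]]
    smoothing_span_ms: int = 10
    sse: Optional[np.ndarray] = None    # per-(t, bin) fit residual

    def __post_init__(self):
        n_t, n_b = self.baseline.shape
        for sr, arr in self.sources.items():
            if arr.shape != (n_t, n_b, N_PHI):
                raise InvalidInputError(f"source {sr} has shape {arr.shape}")
        if len(self.bins) != n_b + 1:
            raise InvalidInputError("bin boundaries do not match baseline")

    def phi(self, sr: str, t_idx: int, b_idx: int) -> np.ndarray:
        return self.sources[sr][t_idx, b_idx]

    def reconstruct(self, grid_shape: Tuple[int, int],
                    smooth: bool = True) -> KernelField:
        """Rebuild khat_{x,y}(t, tau) on the stored lattices.

        Delays outside the binned range carry the fixation kernel only.
        The 10 ms delay moving average is applied to the rebuilt kernels
        (stored phi trajectories stay raw).
        """
        nr, nc = grid_shape
        n_t = len(self.time_grid)
        n_tau = len(self.delay_grid)
        cols, rows = np.meshgrid(np.arange(nc), np.arange(nr))
        out = np.broadcast_to(self.fixation[:, :, None, :],
                              (nr, nc, n_t, n_tau)).copy()
        bin_of = np.searchsorted(self.bins, self.delay_grid, side="right") - 1
        in_range = (bin_of >= 0) & (bin_of < len(self.bins) - 1) \
            & (self.delay_grid >= self.bins[0]) \
            & (self.delay_grid < self.bins[-1])
        for ti in range(n_t):
            g_cache = {}
            for tau_i in np.flatnonzero(in_range):
                b = int(bin_of[tau_i])
                if b not in g_cache:
                    add = np.full((nr, nc), self.baseline[ti, b])
                    for sr in self.sources:
                        add = add + skew_gaussian(
                            cols.astype(float), rows.astype(float),
                            self.sources[sr][ti, b])
                    g_cache[b] = add
                out[:, :, ti, tau_i] += g_cache[b]
        if smooth and self.smoothing_span_ms > 1:
            out = moving_average(out, self.smoothing_span_ms, axis=-1)
        return KernelField(out, self.time_grid, self.delay_grid)


class FModelPredictor:
    """Rate predictor pairing a factorized kernel field with its parent GLM.

    The factorization replaces only the stimulus kernels; the post-spike
    kernel, offset kernel and rate constants are inherited from the parent
    fitted GLM.
    """

    def __init__(self, fmodel: FModel, parent, grid_shape=None):
        self.fmodel = fmodel
        self.parent = parent
        if grid_shape is None:
            grid_shape = parent.kappa.shape[:2]
        self.kernels = fmodel.reconstruct(grid_shape)
        self.rmax = parent.rmax
        self.delta_ms = parent.delta_ms

    def generator(self, stimulus: np.ndarray, t_start: int) -> np.ndarray:
        from .smodel import _eval_on_times, kernel_drive
        T = stimulus.shape[-1]
        times = np.arange(t_start, t_start + T)
        Ot = _eval_on_times(self.parent.bases.offset, times)
        return kernel_drive(self.kernels, stimulus, t_start) \
            + self.parent.beta @ Ot + self.parent.b0

    def postspike_kernel(self) -> np.ndarray:
        return self.parent.postspike_kernel()

    def rates(self, stimulus: np.ndarray, t_start: int,
              spikes=None) -> np.ndarray:
        from .smodel import history_convolution, sigmoid_rate
        u = self.generator(stimulus, t_start)
        if spikes is not None:
            H = self.parent.bases.postspike.values
            P = history_convolution(np.asarray(spikes, dtype=float), H)
            u = u - (self.parent.eta ** 2) @ P
        return sigmoid_rate(u, self.rmax)


def _pack(phis: Dict[str, np.ndarray], c: float) -> np.ndarray:
    return np.concatenate([phis[sr] for sr in SOURCES] + [np.array([c])])


def _unpack(theta: np.ndarray):
    phis = {sr: theta[k * N_PHI:(k + 1) * N_PHI]
            for k, sr in enumerate(SOURCES)}
    return phis, float(theta[-1])


def _bounds(source_locs: Dict[str, Tuple[int, int]],
            cfg: FactorizationConfig):
    lo, hi = [], []
    for sr in SOURCES:
        row, col = source_locs[sr]
        lo += [-np.inf, col - cfg.max_center_shift, row - cfg.max_center_shift,
               cfg.min_spread, cfg.min_spread, -0.999,
               -cfg.max_skew, -cfg.max_skew]
        hi += [np.inf, col + cfg.max_center_shift, row + cfg.max_center_shift,
               cfg.max_spread, cfg.max_spread, 0.999,
               cfg.max_skew, cfg.max_skew]
    lo.append(-np.inf)
    hi.append(np.inf)
    return np.array(lo), np.array(hi)


def _nominal_theta(source_locs, cfg) -> np.ndarray:
    parts = []
    for sr in SOURCES:
        row, col = source_locs[sr]
        parts.append(np.array([0.0, col, row, 1.0, 1.0, 0.0, 0.0, 0.0]))
    return np.concatenate(parts + [np.zeros(1)])


def fit_factorization(s_kernels: KernelField,
                      source_locs: Dict[str, Tuple[int, int]],
                      config: Optional[FactorizationConfig] = None,
                      fixation: Optional[np.ndarray] = None,
                      seed: int = 0) -> FModel:
    """Fit skew-Gaussian sources + baseline per (time, delay-bin) cell.

    Within a delay bin the sources and baseline are constant, so the SSE of
    the kernel difference over (probes x in-bin delays) is minimized by
    fitting the spatial profile to the in-bin delay average of
    ``k - kfix`` (the in-bin variance is an additive constant).  Three
    seeded starts are tried per cell -- the previous bin's solution, the
    nominal source centers with unit spread, and a perturbed variant -- and
    the lowest-SSE solution wins.  Bins are visited in increasing delay so
    warm starts are well defined; if the optimizer fails at a cell the
    previous bin's solution is kept with a warning.
    """
    import warnings

    cfg = config or FactorizationConfig()
    for sr in SOURCES:
        if sr not in source_locs:
            raise InvalidInputError(f"missing source location for {sr}")
    if fixation is None:
        fixation = fixation_kernel(s_kernels, *cfg.fixation_window)
    rng = np.random.default_rng(seed)
    nr, nc = s_kernels.values.shape[:2]
    time_idx = np.arange(0, len(s_kernels.time_grid), cfg.time_step)
    time_grid = s_kernels.time_grid[time_idx]
    bins = np.asarray(cfg.delay_bins)
    n_b = len(bins) - 1
    n_t = len(time_idx)
    cols, rows = np.meshgrid(np.arange(nc).astype(float),
                             np.arange(nr).astype(float))
    lo, hi = _bounds(source_locs, cfg)
    nominal = np.clip(_nominal_theta(source_locs, cfg), lo, hi)
    sources = {sr: np.zeros((n_t, n_b, N_PHI)) for sr in SOURCES}
    baseline = np.zeros((n_t, n_b))
    sse = np.zeros((n_t, n_b))
    delay = s_kernels.delay_grid

    def profile(theta):
        phis, c = _unpack(theta)
        out = np.full((nr, nc), c)
        for sr in SOURCES:
            out = out + skew_gaussian(cols, rows, phis[sr])
        return out

    for t_pos, ti in enumerate(time_idx):
        prev = None
        for b in range(n_b):
            tau_sel = (delay >= bins[b]) & (delay < bins[b + 1])
            if not np.any(tau_sel):
                continue
            n_tau = int(tau_sel.sum())
            target = (s_kernels.values[:, :, ti, :][:, :, tau_sel]
                      - fixation[:, :, tau_sel]).mean(axis=2)

            def resid(theta):
                return (profile(theta) - target).ravel() * np.sqrt(n_tau)

            starts = [nominal]
            if prev is not None:
                starts.insert(0, prev)
            pert = nominal + rng.normal(scale=cfg.perturb_scale,
                                        size=nominal.shape)
            starts.append(np.clip(pert, lo, hi))
            best, best_cost = None, np.inf
            for th0 in starts:
                try:
                    res = least_squares(resid, np.clip(th0, lo, hi),
                                        bounds=(lo, hi),
                                        max_nfev=cfg.max_nfev)
                except Exception:
                    continue
                if res.cost < best_cost:
                    best, best_cost = res.x, res.cost
            if best is None:
                warnings.warn(f"factorization failed at t={ti}, bin={b}; "
                              "keeping previous bin")
                best = prev if prev is not None else nominal
                best_cost = float(np.sum(resid(best) ** 2) / 2)
            phis, c = _unpack(best)
            for sr in SOURCES:
                sources[sr][t_pos, b] = phis[sr]
            baseline[t_pos, b] = c
            sse[t_pos, b] = 2.0 * best_cost
            prev = best
    return FModel(sources=sources, baseline=baseline, fixation=fixation,
                  bins=bins, time_grid=time_grid, delay_grid=delay,
                  source_locs=dict(source_locs),
                  smoothing_span_ms=cfg.smoothing_span_ms, sse=sse)


def knockout(model: FModel, keep: Sequence[str], seed: int = 0,
             fixation_window: Tuple[int, int] = FIXATION_WINDOW) -> FModel:
    """Null every source not in ``keep`` using its own fixation statistics.

    For each knocked-out source, every (t, bin) parameter vector is replaced
    by one drawn uniformly (seeded, independently per cell) from that
    source's fitted values at fixation-period times.  ``keep=()`` gives the
    no-source model; ``keep=('FF',)`` the +FF variant; ``keep=('RF','ST')``
    the -FF variant.
    """
    keep = set(keep)
    unknown = keep - set(SOURCES)
    if unknown:
        raise InvalidInputError(f"unknown sources: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    t1, t2 = fixation_window
    pool_idx = np.flatnonzero((model.time_grid >= t1)
                              & (model.time_grid <= t2))
    if pool_idx.size == 0:
        raise InvalidInputError(
            f"no fitted time points inside the fixation window [{t1}, {t2}]")
    new_sources = {}
    n_t, n_b = model.baseline.shape
    for sr in SOURCES:
        arr = model.sources[sr]
        if sr in keep:
            new_sources[sr] = arr.copy()
            continue
        out = np.empty_like(arr)
        for ti in range(n_t):
            for b in range(n_b):
                out[ti, b] = arr[rng.choice(pool_idx), b]
        new_sources[sr] = out
    return replace(model, sources=new_sources,
                   baseline=model.baseline.copy())


def aggregate(fmodels: Sequence[FModel]) -> FModel:
    """Element-wise mean of the source parameters and baselines.

    All inputs must share bins, lattices and source locations; kernels of
    the aggregate are rebuilt from the averaged parameters on demand.
    """
    if not fmodels:
        raise InvalidInputError("need at least one model to aggregate")
    ref = fmodels[0]
    for m in fmodels[1:]:
        if not np.array_equal(m.bins, ref.bins) or \
                not np.array_equal(m.time_grid, ref.time_grid) or \
                m.baseline.shape != ref.baseline.shape:
            raise InvalidInputError("models have mismatched structures")
    sources = {sr: np.mean([m.sources[sr] for m in fmodels], axis=0)
               for sr in SOURCES}
    baseline = np.mean([m.baseline for m in fmodels], axis=0)
    fixation = np.mean([m.fixation for m in fmodels], axis=0)
    return replace(ref, sources=sources, baseline=baseline,
                   fixation=fixation)
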