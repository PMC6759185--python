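"""ROC-based spatiotemporal stimulus detectability.

For each probe location (x, y), time ``t`` relative to saccade and latency
``tau``, the rates a model predicts at ``t`` across many simulated stimulus
sequences are split into the set where a stimulus occupied (x, y) at
``t - tau`` and the set obtained after re-pairing the same rates with
shuffled stimulus sequences (no causal stimulus-response link).  The area
under the ROC between the two sets -- computed through the rank-sum
(Mann-Whitney) identity, so any monotone transform of the rates leaves it
unchanged -- is the detectability ``roc(x, y, t, tau)``; 0.5 is chance.
Significance is assessed against a null distribution of shuffle-vs-shuffle
ROCs (100 repeats) with a t-type comparison of the observed value to that
distribution at a very conservative threshold (1e-9; 1e-7 for population
neurons); the comparison of a single value to a null sample is an
interpretation of the published two-sample test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata, t as t_dist

from .basis import InvalidInputError
from .fmodel import FModel, N_PHI, SOURCES, moving_average
from .simulate import shuffle_pairing


def roc_auc(a: np.ndarray, b: np.ndarray) -> float:
    """Area under the ROC separating sample ``a`` (signal) from ``b``.

    Computed as the Mann-Whitney U statistic of ``a`` over the pooled
    ranking, i.e. (concordant pairs + half ties) / (n_a * n_b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both rate sets must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    u = ranks[:a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


@dataclass
class DetectabilityMap:
    roc: np.ndarray          # (n_probes, n_t, n_tau)
    significant: np.ndarray  # same shape, bool
    p_values: np.ndarray
    probes: List[Tuple[int, int]]
    t_values: np.ndarray
    tau_values: np.ndarray
    n_sequences: int
    n_null: int


def _null_p(obs: float, null: np.ndarray) -> float:
    """t-type comparison of one observed ROC to the shuffle-null sample."""
    m, s = null.mean(), null.std(ddof=1)
    if s == 0:
        return 0.0 if obs > m else 1.0
    tt = (obs - m) / (s * np.sqrt(1.0 + 1.0 / null.size))
    return float(t_dist.sf(tt, df=null.size - 1))


def roc_map(rates: np.ndarray, probe_at: np.ndarray, t_start: int,
            probes: Sequence[Tuple[int, int]], grid_cols: int,
            t_values: Sequence[int], tau_values: Sequence[int],
            n_null: int = 100, seed: int = 0,
            p_threshold: float = 1e-9) -> DetectabilityMap:
    """Detectability over (probe, time, latency) from simulated sequences.

    ``rates`` is (n_sequences, n_bins) model-predicted firing rates on the
    common time axis starting at ``t_start``; ``probe_at`` the matching
    (n_sequences, n_bins) flat probe index on screen per bin (-1 where
    none).  Cells whose stimulus set is empty are left NaN.
    """
    rates = np.asarray(rates, dtype=float)
    probe_at = np.asarray(probe_at)
    n_seq, n_bins = rates.shape
    t_values = np.asarray(t_values, dtype=int)
    tau_values = np.asarray(tau_values, dtype=int)
    rng = np.random.default_rng(seed)
    pair_perm = shuffle_pairing(n_seq, int(rng.integers(2 ** 31)))
    null_perms = [(shuffle_pairing(n_seq, int(rng.integers(2 ** 31))),
                   shuffle_pairing(n_seq, int(rng.integers(2 ** 31))))
                  for _ in range(n_null)]
    flat_probes = [r * grid_cols + c for (r, c) in probes]
    shape = (len(probes), len(t_values), len(tau_values))
    roc = np.full(shape, np.nan)
    pvals = np.ones(shape)
    for pi, pflat in enumerate(flat_probes):
        for ti, t in enumerate(t_values):
            it = int(t) - t_start
            if not (0 <= it < n_bins):
                continue
            for ki, tau in enumerate(tau_values):
                i_stim = it - int(tau)
                if not (0 <= i_stim < n_bins):
                    continue
                sel = np.flatnonzero(probe_at[:, i_stim] == pflat)
                if sel.size < 2:
                    continue
                obs = rates[sel, it]
                sh = rates[pair_perm[sel], it]
                roc[pi, ti, ki] = roc_auc(obs, sh)
                null = np.array([roc_auc(rates[pa[sel], it],
                                         rates[pb[sel], it])
                                 for pa, pb in null_perms])
                pvals[pi, ti, ki] = _null_p(roc[pi, ti, ki], null)
    sig = (pvals < p_threshold) & np.isfinite(roc)
    return DetectabilityMap(roc=roc, significant=sig, p_values=pvals,
                            probes=list(probes), t_values=t_values,
                            tau_values=tau_values, n_sequences=n_seq,
                            n_null=n_null)


@dataclass
class MaxDetectTrace:
    """Peak detectability I and its latency T per probe over time."""

    I: np.ndarray            # (n_probes, n_t); NaN where not reportable
    T: np.ndarray
    probes: List[Tuple[int, int]]
    t_values: np.ndarray


def max_trace(dmap: DetectabilityMap, latency_floor: float = 50.0,
              smooth_span_ms: int = 7) -> MaxDetectTrace:
    """Peak detectability and latency traces from a detectability map.

    Per probe and time, I is the maximum of roc over latency and T its
    argmax (ties to the smallest latency).  Both are smoothed over time
    with a 7 ms moving average; entries are reported only where the peak is
    significant and its (smoothed) latency exceeds ``latency_floor``.
    """
    roc = np.where(np.isfinite(dmap.roc), dmap.roc, -np.inf)
    any_ok = np.isfinite(dmap.roc).any(axis=2)
    arg = np.argmax(roc, axis=2)
    I = np.take_along_axis(dmap.roc, arg[:, :, None], axis=2)[:, :, 0]
    T = dmap.tau_values[arg].astype(float)
    sig = np.take_along_axis(dmap.significant, arg[:, :, None],
                             axis=2)[:, :, 0]
    I_s = moving_average(np.where(any_ok, I, np.nan), smooth_span_ms, axis=1)
    T_s = moving_average(np.where(any_ok, T, np.nan), smooth_span_ms, axis=1)
    ok = any_ok & sig & (T_s > latency_floor)
    I_out = np.where(ok, I_s, np.nan)
    T_out = np.where(ok, T_s, np.nan)
    return MaxDetectTrace(I=I_out, T=T_out, probes=dmap.probes,
                          t_values=dmap.t_values)


def population_neuron(fmodels: Sequence[FModel], effect: str,
                      spacings: Optional[Sequence[float]] = None,
                      include_suppression: bool = False) -> FModel:
    """Average source parameters across neurons into a synthetic neuron.

    Spatial parameters (centers, spreads) are normalized by each session's
    inter-probe distance before averaging, the parameters of the chosen
    effect's source are kept, and the other sources are zeroed.
    Suppression (the RF source) is excluded by default because few neurons
    show it; pass ``include_suppression=True`` to override.
    """
    from dataclasses import replace

    source = {"suppression": "RF", "FF": "FF", "ST": "ST"}.get(effect)
    if source is None:
        raise InvalidInputError(f"unknown effect {effect!r}")
    if source == "RF" and not include_suppression:
        raise InvalidInputError(
            "suppression is excluded from the population analysis by "
            "default (too few neurons); pass include_suppression=True")
    if not fmodels:
        raise InvalidInputError("need at least one qualifying model")
    if spacings is None:
        spacings = [1.0] * len(fmodels)
    if len(spacings) != len(fmodels):
        raise InvalidInputError("one spacing per model required")
    spatial = (1, 2, 3, 4)   # mu_x, mu_y, sigma_x, sigma_y in PHI_FIELDS
    stacked = []
    for m, d in zip(fmodels, spacings):
        arr = m.sources[source].copy()
        arr[..., list(spatial)] /= float(d)
        stacked.append(arr)
    mean_phi = np.mean(stacked, axis=0)
    ref = fmodels[0]
    sources = {sr: (mean_phi if sr == source
                    else np.zeros_like(ref.sources[sr]))
               for sr in SOURCES}
    baseline = np.mean([m.baseline for m in fmodels], axis=0)
    fixation = np.mean([m.fixation for m in fmodels], axis=0)
    return replace(ref, sources=sources, baseline=baseline,
                   fixation=fixation)
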