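"""Perisaccadic effect localization, classification and prevalence.

Three effects are analyzed, each defined by a stimulus window (probe onset
relative to saccade) and a response window (latency after probe onset):

* saccadic suppression -- a significant *decrease* of the early response
  (50-75 ms latency) to RF probes flashed -30..0 ms before the saccade,
  relative to fixation (-500..-100 ms);
* FF-remapping and ST-remapping -- significant *increases* of the late
  response (80-150 ms latency) to FF / ST probes flashed -50..0 ms before
  the saccade, relative to fixation.

Spike-count comparisons use the one-sided Wilcoxon signed-rank test when the
two arms can be paired by presentation order, falling back to the rank-sum
test for unequal arms; model-predicted rates always use the one-sided
rank-sum test.  Alpha is 0.05 with no multiplicity adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import mannwhitneyu, wilcoxon

from .basis import InvalidInputError
from .experiment import ProbeGrid, TrialSet

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

EFFECTS = ("suppression", "FF", "ST")


@dataclass(frozen=True)
class EffectWindows:
    """Stimulus and response windows (ms), half-open [lo, hi)."""

    suppression_stim: Tuple[float, float] = (-30.0, 0.0)
    early_response: Tuple[float, float] = (50.0, 75.0)
    remap_stim: Tuple[float, float] = (-50.0, 0.0)
    late_response: Tuple[float, float] = (80.0, 150.0)
    fixation_stim: Tuple[float, float] = (-500.0, -100.0)

    def stim_window(self, effect: str) -> Tuple[float, float]:
        return self.suppression_stim if effect == "suppression" \
            else self.remap_stim

    def response_window(self, effect: str) -> Tuple[float, float]:
        return self.early_response if effect == "suppression" \
            else self.late_response


@dataclass
class EffectCall:
    effect: str
    significant: bool
    p_value: float
    peri_mean: float
    fix_mean: float
    n_peri: int = 0
    n_fix: int = 0


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def _flash_onsets(stimulus: np.ndarray, row: int, col: int,
                  t_start: int) -> np.ndarray:
    """Onset times (ms from saccade) of every flash of one probe."""
    on = np.flatnonzero(stimulus[row, col])
    if on.size == 0:
        return on
    starts = on[np.r_[True, np.diff(on) > 1]]
    return starts + t_start


def aligned_counts(trials: TrialSet, probe: Tuple[int, int],
                   stim_window: Tuple[float, float],
                   response_window: Tuple[float, float]) -> np.ndarray:
    """Per-flash spike counts in the response window, stimulus-aligned.

    One count per flash of ``probe`` whose onset falls in ``stim_window``;
    flashes whose response window leaves the trial axis are dropped.
    Ordered by (trial, onset) so paired tests can match presentation order.
    """
    lo, hi = response_window
    t0_ax, t1_ax = trials.time_axis
    out = []
    for tr in trials.trials:
        for onset in _flash_onsets(tr.stimulus, probe[0], probe[1],
                                   tr.t_start):
            if not (stim_window[0] <= onset < stim_window[1]):
                continue
            a, b = onset + lo, onset + hi
            if a < t0_ax or b > t1_ax:
                continue
            i0, i1 = int(a) - tr.t_start, int(b) - tr.t_start
            out.append(tr.spikes[i0:i1].sum())
    return np.asarray(out, dtype=float)


def mean_rate_in_window(counts: np.ndarray,
                        window: Tuple[float, float]) -> float:
    """Mean rate (spk/s) implied by per-flash counts over a window."""
    dur_s = (window[1] - window[0]) / 1000.0
    return float(counts.mean() / dur_s) if counts.size else 0.0


def estimate_locations(trials: TrialSet,
                       saccade_vector_dva: Tuple[float, float],
                       windows: Optional[EffectWindows] = None
                       ) -> Dict[str, Tuple[int, int]]:
    """Locate the RF, FF and ST probes from raw spike counts.

    RF: the probe with maximum fixation-period early-window rate.  FF: the
    RF probe shifted by the saccade vector rounded to probe units.  ST: of
    the 4 x 4 probes centered on the saccade-target location, the one with
    the largest perisaccadic-minus-fixation late-window rate, with the FF
    probe and its 8-neighborhood excluded.  Argmax ties break to the lowest
    (row, col).
    """
    windows = windows or EffectWindows()
    grid = trials.grid
    fix_w = windows.fixation_stim
    early = windows.early_response
    late = windows.late_response
    peri = windows.remap_stim
    rates = np.zeros((grid.n_rows, grid.n_cols))
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            rates[r, c] = mean_rate_in_window(
                aligned_counts(trials, (r, c), fix_w, early), early)
    rf = tuple(int(v) for v in np.unravel_index(np.argmax(rates),
                                                rates.shape))
    d_cols = round_half_away(saccade_vector_dva[0] / grid.dx)
    d_rows = round_half_away(saccade_vector_dva[1] / grid.dy)
    ff = (rf[0] + d_rows, rf[1] + d_cols)
    if not (0 <= ff[0] < grid.n_rows and 0 <= ff[1] < grid.n_cols):
        raise InvalidInputError(
            f"FF probe {ff} is off the grid; enlarge the probe grid so the "
            "saccade vector keeps the future field on it")
    # nominal ST probe: grid point nearest the saccade-target dva position
    coords = np.array([[grid.coord(r, c)
                        for c in range(grid.n_cols)]
                       for r in range(grid.n_rows)])
    d2 = ((coords - np.asarray(grid.st)) ** 2).sum(axis=2)
    st_nom = np.unravel_index(np.argmin(d2), d2.shape)
    r_lo, c_lo = st_nom[0] - 1, st_nom[1] - 1
    cand = [(r, c)
            for r in range(max(0, r_lo), min(grid.n_rows, r_lo + 4))
            for c in range(max(0, c_lo), min(grid.n_cols, c_lo + 4))
            if max(abs(r - ff[0]), abs(c - ff[1])) > 1]
    if not cand:
        raise InvalidInputError("no ST candidates left after FF exclusion")
    best, best_val = cand[0], -np.inf
    for (r, c) in cand:
        peri_rate = mean_rate_in_window(
            aligned_counts(trials, (r, c), peri, late), late)
        fix_rate = mean_rate_in_window(
            aligned_counts(trials, (r, c), fix_w, late), late)
        val = peri_rate - fix_rate
        if val > best_val:
            best, best_val = (r, c), val
    return {"RF": rf, "FF": ff, "ST": best}


def classify_effect(peri: np.ndarray, fix: np.ndarray, effect: str,
                    mode: str = "counts", alpha: float = 0.05) -> EffectCall:
    """One-sided test of a perisaccadic change against fixation.

    ``effect='suppression'`` tests for a decrease (peri < fixation);
    ``'FF'``/``'ST'`` test for an increase.  ``mode='counts'`` uses the
    paired signed-rank test when the arms have equal length (presentation
    order pairing), otherwise the unpaired rank-sum test; ``mode='rates'``
    always uses the rank-sum test.
    """
    if effect not in EFFECTS:
        raise InvalidInputError(f"unknown effect {effect!r}")
    peri = np.asarray(peri, dtype=float)
    fix = np.asarray(fix, dtype=float)
    if peri.size < 2 or fix.size < 2:
        warnings.warn("empty or singleton arm: effect call undefined, "
                      "flagged not significant")
        return EffectCall(effect, False, 1.0,
                          float(peri.mean()) if peri.size else np.nan,
                          float(fix.mean()) if fix.size else np.nan,
                          peri.size, fix.size)
    alternative = "less" if effect == "suppression" else "greater"
    paired = (mode == "counts") and (peri.size == fix.size)
    if mode == "counts" and not paired:
        warnings.warn("unequal arms: falling back to the rank-sum test")
    try:
        if paired:
            if np.all(peri == fix):
                p = 1.0
            else:
                p = float(wilcoxon(peri, fix, alternative=alternative,
                                   zero_method="zsplit").pvalue)
        else:
            p = float(mannwhitneyu(peri, fix, alternative=alternative).pvalue)
    except ValueError:
        p = 1.0
    return EffectCall(effect, bool(p < alpha), p, float(peri.mean()),
                      float(fix.mean()), peri.size, fix.size)


def classify_from_trials(trials: TrialSet, effect: str,
                         locs: Dict[str, Tuple[int, int]],
                         windows: Optional[EffectWindows] = None,
                         alpha: float = 0.05) -> EffectCall:
    """Spike-count classification of one effect straight from a trial set."""
    windows = windows or EffectWindows()
    probe = locs["RF"] if effect == "suppression" else locs[effect]
    resp = windows.response_window(effect)
    peri = aligned_counts(trials, probe, windows.stim_window(effect), resp)
    fix = aligned_counts(trials, probe, windows.fixation_stim, resp)
    return classify_effect(peri, fix, effect, mode="counts", alpha=alpha)


def gaussian_smooth(traces: np.ndarray, fwhm_ms: float = 13.0,
                    axis: int = -1) -> np.ndarray:
    """Gaussian smoothing on the ms lattice; FWHM 13 ms for display traces,
    33 ms when estimating instantaneous rates from spike trains."""
    sigma = fwhm_ms * FWHM_TO_SIGMA
    return gaussian_filter1d(np.asarray(traces, dtype=float), sigma=sigma,
                             axis=axis)


def grand_mean(peri_mean: float, fix_mean: float) -> float:
    """The mean of the perisaccadic and fixation mean responses."""
    return 0.5 * (peri_mean + fix_mean)


def normalize_responses(peri: np.ndarray, fix: np.ndarray
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Divide both response traces by their shared grand mean."""
    gm = grand_mean(float(np.mean(peri)), float(np.mean(fix)))
    if gm == 0:
        raise ZeroDivisionError("grand mean of the responses is zero")
    return np.asarray(peri) / gm, np.asarray(fix) / gm


def prevalence_mask(samples, fix_samples, effect: str,
                    alpha: float = 0.05) -> np.ndarray:
    """Binary significance mask over the (time, latency) lattice.

    ``samples[t][tau]`` holds the rate observations for stimuli at the
    source probe at time ``t`` with response latency ``tau``;
    ``fix_samples[tau]`` the fixation observations at the same latency.
    Suppression masks cells where the rate is significantly *below*
    fixation; remapping masks significant increases.  Cells with fewer than
    two observations in either arm stay 0.
    """
    if effect not in EFFECTS:
        raise InvalidInputError(f"unknown effect {effect!r}")
    alternative = "less" if effect == "suppression" else "greater"
    n_t = len(samples)
    n_tau = len(fix_samples)
    mask = np.zeros((n_t, n_tau), dtype=np.uint8)
    for ti in range(n_t):
        row = samples[ti]
        for tau in range(min(len(row), n_tau)):
            a = np.asarray(row[tau], dtype=float)
            b = np.asarray(fix_samples[tau], dtype=float)
            if a.size < 2 or b.size < 2:
                continue
            try:
                p = mannwhitneyu(a, b, alternative=alternative).pvalue
            except ValueError:
                continue
            mask[ti, tau] = 1 if p < alpha else 0
    return mask


def population_prevalence(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Percentage of neurons significant at each (t, tau) cell."""
    if not len(masks):
        raise InvalidInputError("need at least one mask")
    return np.mean([np.asarray(m, dtype=float) for m in masks],
                   axis=0) * 100.0


def collect_rate_samples(rates: np.ndarray, trials: TrialSet,
                         probe: Tuple[int, int],
                         stim_times: Sequence[int],
                         latencies: Sequence[int],
                         fixation_window: Tuple[float, float] = (-500, -100)):
    """Gather per-(t, tau) and fixation rate observations for one probe.

    ``rates`` is the (n_trials, n_bins) rate array (smoothed spikes or model
    predictions) on the trial time axis.  Returns ``(samples, fix_samples)``
    in the layout :func:`prevalence_mask` expects.
    """
    t0_ax, t1_ax = trials.time_axis
    onsets = [(l, int(t))
              for l, tr in enumerate(trials.trials)
              for t in _flash_onsets(tr.stimulus, probe[0], probe[1],
                                     tr.t_start)]
    samples = [[[] for _ in latencies] for _ in stim_times]
    fix = [[] for _ in latencies]
    for (l, onset) in onsets:
        for k, tau in enumerate(latencies):
            t_resp = onset + int(tau)
            if not (t0_ax <= t_resp < t1_ax):
                continue
            v = rates[l, t_resp - t0_ax]
            if fixation_window[0] <= onset < fixation_window[1]:
                fix[k].append(v)
            for si, st in enumerate(stim_times):
                if onset == st:
                    samples[si][k].append(v)
    return samples, fix
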