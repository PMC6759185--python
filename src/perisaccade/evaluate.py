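"""Model goodness-of-fit and model-comparison statistics.

Performance is the held-out log-likelihood gain over a NULL model whose
instantaneous rate is the neuron's average firing rate, normalized per
spike and reported in bits (``delta LL / spk``).  Perisaccadic spikes are
those in [0, 150) ms after saccade onset; fixation spikes those in
[-450, 0).  Agreement between data-based and model-based effect calls is
summarized by a confusion matrix and the classification metrics
sensitivity, accuracy, precision, GSP (geometric mean of sensitivity and
precision) and the F-measure with alpha = 1/2; paired model comparisons use
the one-tailed mid-p McNemar test.  The perisaccadic-to-fixation
performance ratio of a model over a population is the slope of a
zero-intercept robust (IRLS, 'fair' weights) regression of perisaccadic on
fixation performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .basis import InvalidInputError
from .smodel import log_likelihood

LN2 = float(np.log(2.0))

PERI_SPIKE_WINDOW = (0.0, 150.0)
FIX_SPIKE_WINDOW = (-450.0, 0.0)


def delta_ll_per_spike(model_rates: np.ndarray, spikes: np.ndarray,
                       t_start: int,
                       window: Optional[Tuple[float, float]] = None,
                       null_rate: Optional[float] = None,
                       valid: Optional[np.ndarray] = None,
                       delta_ms: float = 1.0) -> float:
    """Log-likelihood gain over the constant-rate NULL model, bits/spike.

    ``model_rates`` and ``spikes`` are (n_trials, n_bins) on a common axis
    starting at ``t_start`` ms from saccade.  ``window`` restricts the
    evaluation (half-open, ms from saccade); ``null_rate`` defaults to the
    neuron's average rate over the evaluated bins.  Returns NaN when the
    window holds no spikes (the quantity is undefined there).
    """
    rates = np.atleast_2d(np.asarray(model_rates, dtype=float))
    spk = np.atleast_2d(np.asarray(spikes, dtype=float))
    if valid is None:
        valid = np.ones_like(spk, dtype=bool)
    valid = np.atleast_2d(valid)
    if window is not None:
        times = np.arange(t_start, t_start + spk.shape[1])
        in_w = (times >= window[0]) & (times < window[1])
        rates, spk, valid = rates[:, in_w], spk[:, in_w], valid[:, in_w]
    n_spk = spk[valid].sum()
    if n_spk == 0:
        return float("nan")
    if null_rate is None:
        total_s = valid.sum() * (delta_ms / 1000.0)
        null_rate = float(n_spk / total_s)
    ll_model = log_likelihood(rates, spk, delta_ms, valid)
    ll_null = log_likelihood(np.full_like(rates, null_rate), spk,
                             delta_ms, valid)
    return float((ll_model - ll_null) / n_spk / LN2)


@dataclass
class ConfusionMatrix:
    """Counts of neurons by (data significant) x (model significant)."""

    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FN, self.FP, self.TN) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @classmethod
    def from_calls(cls, data_calls: Sequence[bool],
                   model_calls: Sequence[bool]) -> "ConfusionMatrix":
        d = np.asarray(data_calls, dtype=bool)
        m = np.asarray(model_calls, dtype=bool)
        if d.shape != m.shape:
            raise InvalidInputError("call vectors must have equal length")
        return cls(TP=int(np.sum(d & m)), FN=int(np.sum(d & ~m)),
                   FP=int(np.sum(~d & m)), TN=int(np.sum(~d & ~m)))

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN


def dichotomous_metrics(cm: ConfusionMatrix,
                        alpha: float = 0.5) -> Dict[str, float]:
    """Sensitivity, accuracy, precision, GSP and F-measure from a matrix.

    Metrics with zero denominators are reported as NaN (undefined).
    """
    def safe(num, den):
        return num / den if den > 0 else float("nan")

    sens = safe(cm.TP, cm.TP + cm.FN)
    acc = safe(cm.TP + cm.TN, cm.total)
    prec = safe(cm.TP, cm.TP + cm.FP)
    gsp = float(np.sqrt(sens * prec)) if np.isfinite(sens) and \
        np.isfinite(prec) else float("nan")
    if np.isfinite(sens) and np.isfinite(prec) and \
            (alpha ** 2 * prec + sens) > 0:
        f = (1 + alpha ** 2) * sens * prec / (alpha ** 2 * prec + sens)
    else:
        f = float("nan")
    return {"sensitivity": sens, "accuracy": acc, "precision": prec,
            "GSP": gsp, "F": f}


def mcnemar_mid_p(model_a_correct: Sequence[bool],
                  model_b_correct: Sequence[bool]) -> float:
    """One-tailed mid-p McNemar test on paired correctness indicators.

    With ``b`` = #(A correct, B wrong) and ``c`` = #(A wrong, B correct) and
    X ~ Binomial(b + c, 1/2), returns P(X > b) + 0.5 P(X = b) -- small when
    A is right on more discordant pairs than B (alternative: the first
    model performs better; swap the arguments for the other direction).
    No discordant pairs gives p = 1 by convention.
    """
    a = np.asarray(model_a_correct, dtype=bool)
    bb = np.asarray(model_b_correct, dtype=bool)
    if a.shape != bb.shape:
        raise InvalidInputError("paired indicators must have equal length")
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    n = b + c
    if n == 0:
        return 1.0
    pmf = [comb(n, k) * 0.5 ** n for k in range(n + 1)]
    return float(sum(pmf[b + 1:]) + 0.5 * pmf[b])


def qualifying_trials(trials, locs: Dict[str, Tuple[int, int]],
                      window: Tuple[float, float] = (-50.0, 0.0)
                      ) -> np.ndarray:
    """Trial indices with an RF/FF/ST flash onset in the perisaccadic window.

    The perisaccadic-to-fixation ratio is only meaningful on trials where a
    stimulus could evoke a perisaccadic response at one of the source
    probes, so the performance records are restricted to these.
    """
    from .effects import _flash_onsets

    keep = []
    for l, tr in enumerate(trials.trials):
        hit = False
        for probe in locs.values():
            on = _flash_onsets(tr.stimulus, probe[0], probe[1], tr.t_start)
            if np.any((on >= window[0]) & (on < window[1])):
                hit = True
                break
        if hit:
            keep.append(l)
    return np.asarray(keep, dtype=int)


def _mad_scale(resid: np.ndarray) -> float:
    return float(np.median(np.abs(resid)) / 0.6745)


def peri_fix_ratio(fix: np.ndarray, peri: np.ndarray,
                   tuning: float = 1.4, max_iter: int = 50,
                   tol: float = 1e-10) -> Tuple[float, float]:
    """Zero-intercept IRLS slope of perisaccadic on fixation performance.

    Iteratively reweighted least squares with the 'fair' weight function
    ``w = 1 / (1 + |r| / (tuning * s))`` where ``s`` is the MAD-based
    residual scale re-estimated each iteration.  Returns (slope, SE) with
    the SE taken from the final weighted fit.  All-collinear data (zero
    residual scale) reduce to ordinary zero-intercept least squares.
    """
    x = np.asarray(fix, dtype=float)
    y = np.asarray(peri, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise InvalidInputError("need >= 3 paired performance records")
    if np.allclose(x, 0):
        raise InvalidInputError("degenerate fixation performance (all zero)")
    slope = float((x @ y) / (x @ x))
    for _ in range(max_iter):
        r = y - slope * x
        s = _mad_scale(r)
        if s <= tol:
            w = np.ones_like(x)
        else:
            w = 1.0 / (1.0 + np.abs(r) / (tuning * s))
        new = float((w * x) @ y / ((w * x) @ x))
        if abs(new - slope) < tol * max(1.0, abs(slope)):
            slope = new
            break
        slope = new
    r = y - slope * x
    dof = max(x.size - 1, 1)
    sigma2 = float((w * r ** 2).sum() / dof)
    se = float(np.sqrt(sigma2 / (w * x ** 2).sum()))
    return slope, se


def contribution_percentages(ratios: Dict[str, float]) -> Dict[str, float]:
    """Increase/decrease percentages of each source's contribution.

    ``ratios`` maps model variants to their peri/fixation performance
    ratios: 'F', 'no_source', and any of '+RF', '+FF', '+ST', '-RF', '-FF',
    '-ST'.  The increase percentage of '+src' is the fraction of the full
    F-minus-no-source gain recovered by adding that source alone; the
    decrease percentage of '-src' the fraction lost by removing it.
    """
    if "F" not in ratios or "no_source" not in ratios:
        raise InvalidInputError("need 'F' and 'no_source' ratios")
    r_f, r_0 = ratios["F"], ratios["no_source"]
    gain = r_f - r_0
    if gain == 0:
        raise ZeroDivisionError("F and no-source ratios coincide")
    out = {}
    for key, val in ratios.items():
        if key.startswith("+"):
            out[f"increase%{key[1:]}"] = 100.0 * (val - r_0) / gain
        elif key.startswith("-"):
            out[f"decrease%{key[1:]}"] = 100.0 * (val - r_f) / (r_0 - r_f)
    return out
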