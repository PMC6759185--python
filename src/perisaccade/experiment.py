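"""Probe-grid experiment data model.

A session flashes single white probes, one at a time, on a grid of possible
locations (9 x 9 in the reference paradigm).  Each probe flash lasts 7 ms and
flashes abut with no overlap, so within one *condition* -- a pseudorandom
ordering in which every grid location appears exactly once -- exactly one
probe is on at every time point.  Trials are aligned so that t = 0 is
saccade onset, with 1 ms bins throughout, half-open convention [t, t+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .basis import InvalidInputError

PROBE_DURATION_MS = 7


@dataclass(frozen=True)
class ProbeGrid:
    """Geometry of the probe lattice in degrees of visual angle (dva).

    Probe indices are 0-based (row, col); dva coordinates are derived from
    ``origin`` and the spacings ``dx``/``dy`` and only matter for reporting.
    """

    n_rows: int = 9
    n_cols: int = 9
    origin: Tuple[float, float] = (-16.0, -10.0)
    dx: float = 3.3
    dy: float = 2.3
    fp: Tuple[float, float] = (0.0, 0.0)
    st: Tuple[float, float] = (-10.0, 0.0)

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidInputError("grid must have at least one probe")
        if self.dx <= 0 or self.dy <= 0:
            raise InvalidInputError("probe spacings must be positive")

    @property
    def size(self) -> int:
        return self.n_rows * self.n_cols

    def coord(self, row: int, col: int) -> Tuple[float, float]:
        """Dva coordinate of probe (row, col)."""
        return (self.origin[0] + col * self.dx, self.origin[1] + row * self.dy)

    def flat(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def unflat(self, idx: int) -> Tuple[int, int]:
        return divmod(int(idx), self.n_cols)


@dataclass(frozen=True)
class Condition:
    """One pseudorandom probe ordering; every location appears exactly once."""

    order: Tuple[int, ...]
    probe_duration: int = PROBE_DURATION_MS

    def __post_init__(self):
        if self.probe_duration <= 0:
            raise InvalidInputError("probe_duration must be positive")
        if len(set(self.order)) != len(self.order):
            raise InvalidInputError("each probe must appear exactly once")

    @property
    def span_ms(self) -> int:
        return len(self.order) * self.probe_duration


@dataclass
class Trial:
    """Saccade-aligned binary stimulus lattice and spike train for one trial.

    ``stimulus`` has shape (n_rows, n_cols, n_bins); ``spikes`` and ``valid``
    have shape (n_bins,).  ``valid`` masks padding bins for variable-length
    trials so likelihood sums can skip them.
    """

    stimulus: np.ndarray
    spikes: np.ndarray
    t_start: int
    saccade_offset: float = 0.0
    trial_id: int = 0
    valid: Optional[np.ndarray] = None

    def __post_init__(self):
        self.stimulus = np.asarray(self.stimulus, dtype=np.uint8)
        self.spikes = np.asarray(self.spikes, dtype=np.uint8)
        n = self.stimulus.shape[-1]
        if self.spikes.shape != (n,):
            raise InvalidInputError("stimulus and spikes must share a time axis")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        per_bin = self.stimulus.sum(axis=(0, 1))
        if per_bin.max(initial=0) > 1:
            raise InvalidInputError("at most one probe may be on per time bin")
        if self.spikes.max(initial=0) > 1:
            raise InvalidInputError("spike trains are binary at 1 ms bins")

    @property
    def n_bins(self) -> int:
        return self.stimulus.shape[-1]

    @property
    def time(self) -> np.ndarray:
        """Bin start times in ms relative to saccade onset."""
        return np.arange(self.t_start, self.t_start + self.n_bins)


@dataclass
class TrialSet:
    grid: ProbeGrid
    trials: List[Trial]
    time_axis: Tuple[int, int]

    def __post_init__(self):
        for tr in self.trials:
            if tr.t_start != self.time_axis[0] or \
                    tr.t_start + tr.n_bins != self.time_axis[1]:
                raise InvalidInputError("all trials must share the time axis")

    def __len__(self) -> int:
        return len(self.trials)

    def stimulus_tensor(self) -> np.ndarray:
        """(n_trials, n_rows, n_cols, n_bins) stacked stimulus."""
        return np.stack([t.stimulus for t in self.trials])

    def spike_matrix(self) -> np.ndarray:
        return np.stack([t.spikes for t in self.trials])

    def valid_matrix(self) -> np.ndarray:
        return np.stack([t.valid for t in self.trials])


def generate_conditions(grid: ProbeGrid, n_conditions: int,
                        seed: int) -> List[Condition]:
    """Pseudorandom balanced probe orderings.

    Conditions are built in cycles of ``grid.size``: each cycle takes a
    fresh seeded random permutation and uses its cyclic shifts (a
    Latin-square construction), so within every complete cycle -- and hence
    whenever ``n_conditions`` is a multiple of the grid size -- the
    position-by-location occupancy is exactly uniform.  A trailing partial
    cycle leaves a residual imbalance of at most one occurrence per
    (position, location) cell.  Refreshing the base permutation every cycle
    keeps the sequence continuations diverse across trials, which the
    kernel estimators rely on.
    """
    if n_conditions < 1:
        raise InvalidInputError("n_conditions must be >= 1")
    n = grid.size
    rng = np.random.default_rng(seed)
    out: List[Condition] = []
    while len(out) < n_conditions:
        base = rng.permutation(n)
        shifts = rng.permutation(n)
        for s in shifts[:n_conditions - len(out)]:
            out.append(Condition(tuple(int(v)
                                       for v in np.roll(base, int(s)))))
    return out


def rasterize(condition: Condition, grid: ProbeGrid, trial_length: int,
              saccade_time: int) -> Tuple[np.ndarray, int]:
    """Rasterize consecutive non-overlapping probe flashes into 1 ms bins.

    Probe ``k`` of the condition occupies bins ``[k*d, (k+1)*d)`` with
    ``d = probe_duration``; the returned lattice is re-indexed so that t = 0
    is ``saccade_time``.  Returns ``(stimulus, t_start)``.
    """
    if trial_length < condition.span_ms:
        raise InvalidInputError(
            f"trial_length {trial_length} shorter than the condition span "
            f"{condition.span_ms}")
    stim = np.zeros((grid.n_rows, grid.n_cols, trial_length), dtype=np.uint8)
    d = condition.probe_duration
    for k, probe in enumerate(condition.order):
        r, c = grid.unflat(probe)
        stim[r, c, k * d:(k + 1) * d] = 1
    return stim, -int(saccade_time)


def rasterize_stream(conditions: Sequence[Condition], grid: ProbeGrid,
                     trial_length: int, saccade_time: int
                     ) -> Tuple[np.ndarray, int]:
    """Rasterize back-to-back conditions filling a whole trial.

    Probes flash consecutively with no gaps: condition ``m`` occupies bins
    ``[m * span, (m + 1) * span)``; the last condition is truncated at the
    trial end.  Supply ``ceil(trial_length / span)`` conditions.
    """
    if not conditions:
        raise InvalidInputError("need at least one condition")
    span = conditions[0].span_ms
    need = -(-trial_length // span)
    if len(conditions) < need:
        raise InvalidInputError(
            f"need {need} conditions to fill {trial_length} ms, "
            f"got {len(conditions)}")
    stim = np.zeros((grid.n_rows, grid.n_cols, trial_length), dtype=np.uint8)
    d = conditions[0].probe_duration
    for m in range(need):
        off = m * span
        for k, probe in enumerate(conditions[m].order):
            a = off + k * d
            if a >= trial_length:
                break
            r, c = grid.unflat(probe)
            stim[r, c, a:min(trial_length, a + d)] = 1
    return stim, -int(saccade_time)


def derasterize(stimulus: np.ndarray, grid: ProbeGrid,
                probe_duration: int = PROBE_DURATION_MS) -> Tuple[int, ...]:
    """Recover the probe order from a rasterized lattice (round-trip check)."""
    on = np.argwhere(stimulus.sum(axis=2) > 0)
    onsets = []
    for r, c in on:
        tt = np.flatnonzero(stimulus[r, c])
        for start in tt[np.r_[True, np.diff(tt) > 1]]:
            onsets.append((int(start), grid.flat(int(r), int(c))))
    return tuple(p for _, p in sorted(onsets))


def window_spikes(trial: Trial, window: Tuple[float, float]) -> int:
    """Spike count in ``[start, end)`` ms relative to saccade onset."""
    start, end = window
    if start < trial.t_start or end > trial.t_start + trial.n_bins:
        raise InvalidInputError(
            f"window {window} outside trial axis "
            f"[{trial.t_start}, {trial.t_start + trial.n_bins})")
    i0 = int(start) - trial.t_start
    i1 = int(end) - trial.t_start
    return int(trial.spikes[i0:i1].sum())
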