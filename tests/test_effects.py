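"""Effect localization, classification, normalization, prevalence."""

import numpy as np
import pytest

from perisaccade.basis import InvalidInputError
from perisaccade.effects import (EffectWindows, aligned_counts,
                                 classify_effect, collect_rate_samples,
                                 estimate_locations, gaussian_smooth,
                                 grand_mean, normalize_responses,
                                 population_prevalence, prevalence_mask,
                                 round_half_away)
from perisaccade.experiment import ProbeGrid, Trial, TrialSet


def test_round_half_away_from_zero():
    assert round_half_away(2.5) == 3
    assert round_half_away(-2.5) == -3
    assert round_half_away(2.4) == 2
    assert round_half_away(-0.4) == 0


def build_trialset(grid, spikes_for_probe, n_trials=30, seed=0,
                   t_span=(-550, 250)):
    """Trials flashing every probe once pre- and once peri-saccade.

    ``spikes_for_probe(probe, onset)`` returns spike times to plant for a
    flash of ``probe`` at ``onset``.
    """
    rng = np.random.default_rng(seed)
    t0, t1 = t_span
    n = t1 - t0
    trials = []
    for l in range(n_trials):
        stim = np.zeros((grid.n_rows, grid.n_cols, n), dtype=np.uint8)
        spk = np.zeros(n, dtype=np.uint8)
        onsets_fix = -500 + 7 * np.arange(grid.size)
        onsets_peri = -45 + rng.integers(0, 3)
        slots = list(zip(onsets_fix, range(grid.size)))
        peri_probe = l % grid.size
        slots.append((onsets_peri, peri_probe))
        for onset, p in slots:
            r, c = grid.unflat(p)
            stim[r, c, onset - t0:onset - t0 + 7] = 1
            for ts in spikes_for_probe((r, c), onset, rng):
                idx = int(ts) - t0
                if 0 <= idx < n:
                    spk[idx] = 1
        trials.append(Trial(stimulus=stim, spikes=spk, t_start=t0,
                            trial_id=l))
    return TrialSet(grid=grid, trials=trials, time_axis=(t0, t1))


@pytest.fixture(scope="module")
def located_set():
    """3x3 grid; probe (1,2) drives early fixation responses (the RF);
    probe (1,0) shows a late perisaccadic response (toward the ST)."""
    grid = ProbeGrid(n_rows=3, n_cols=3, origin=(-9.9, -3.3), dx=3.3,
                     dy=3.3, fp=(0.0, 0.0), st=(-6.6, 0.0))

    def spiker(probe, onset, rng):
        out = []
        if probe == (1, 2) and onset < -100:
            out += list(onset + rng.integers(50, 75, size=4))
        if probe == (1, 0) and onset >= -50:
            out += list(onset + rng.integers(80, 150, size=5))
        return out

    return grid, build_trialset(grid, spiker, n_trials=60)


class TestEstimateLocations:
    def test_rf_ff_st(self, located_set):
        grid, ts = located_set
        locs = estimate_locations(ts, (-6.6, 0.0))
        assert locs["RF"] == (1, 2)
        # saccade is two probe columns leftward
        assert locs["FF"] == (1, 0)
        # FF and its 8-neighborhood are excluded from ST candidates
        assert max(abs(locs["ST"][0] - locs["FF"][0]),
                   abs(locs["ST"][1] - locs["FF"][1])) > 1

    def test_ff_off_grid_raises(self, located_set):
        grid, ts = located_set
        with pytest.raises(InvalidInputError):
            estimate_locations(ts, (-66.0, 0.0))


class TestClassifyEffect:
    def test_identical_arms_not_significant(self):
        x = np.arange(20.0)
        call = classify_effect(x, x.copy(), "FF", mode="counts")
        assert not call.significant

    def test_planted_increase_detected(self):
        rng = np.random.default_rng(3)
        fix = rng.poisson(1.0, size=300).astype(float)
        peri = rng.poisson(3.0, size=300).astype(float)
        call = classify_effect(peri, fix, "FF", mode="rates")
        assert call.significant and call.p_value < 1e-6

    def test_suppression_direction(self):
        rng = np.random.default_rng(4)
        fix = rng.poisson(3.0, size=200).astype(float)
        peri = rng.poisson(1.0, size=200).astype(float)
        assert classify_effect(peri, fix, "suppression").significant
        # swapped arms flip a decrease into a non-decrease
        assert not classify_effect(fix, peri, "suppression").significant

    def test_symmetry_of_one_sided_tests(self):
        """Swapping arms and flipping the direction gives the same p."""
        rng = np.random.default_rng(5)
        a = rng.poisson(2.0, size=50).astype(float)
        b = rng.poisson(4.0, size=50).astype(float)
        p_inc = classify_effect(b, a, "FF", mode="rates").p_value
        p_dec = classify_effect(a, b, "suppression", mode="rates").p_value
        assert p_inc == pytest.approx(p_dec)

    def test_tiny_arms_flagged(self):
        with pytest.warns(UserWarning):
            call = classify_effect(np.array([1.0]), np.array([2.0, 3.0]),
                                   "ST")
        assert not call.significant and call.p_value == 1.0


class TestNormalizeSmooth:
    def test_constant_trace_unchanged_by_smoothing(self):
        x = np.full(300, 7.0)
        assert np.allclose(gaussian_smooth(x, 13.0), 7.0)
        assert np.allclose(gaussian_smooth(x, 33.0), 7.0)

    def test_grand_mean_definition(self):
        """Means 2 and 4 give grand mean 3; normalized means 2/3 and 4/3."""
        assert grand_mean(2.0, 4.0) == 3.0
        peri, fix = normalize_responses(np.full(5, 2.0), np.full(5, 4.0))
        assert np.allclose(peri, 2 / 3) and np.allclose(fix, 4 / 3)

    def test_zero_grand_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            normalize_responses(np.zeros(3), np.zeros(3))

    def test_fwhm_of_impulse_response(self):
        """The smoothed impulse has a measured FWHM near the nominal one."""
        for fwhm in (13.0, 33.0):
            x = np.zeros(601)
            x[300] = 1.0
            y = gaussian_smooth(x, fwhm)
            half = y.max() / 2.0
            width = np.sum(y >= half)
            assert abs(width - fwhm) <= 2


class TestPrevalence:
    def test_mask_is_binary_and_planted_cells_light_up(self):
        rng = np.random.default_rng(6)
        n_t, n_tau = 6, 8
        fix = [rng.normal(10, 1, size=40) for _ in range(n_tau)]
        samples = [[rng.normal(10, 1, size=40) for _ in range(n_tau)]
                   for _ in range(n_t)]
        for tau in (2, 3):
            samples[4][tau] = rng.normal(25, 1, size=40)
        mask = prevalence_mask(samples, fix, "FF")
        assert set(np.unique(mask)) <= {0, 1}
        assert mask[4, 2] == 1 and mask[4, 3] == 1
        assert mask.sum() <= 2 + 3   # a few alpha-level false positives

    def test_undersampled_cells_stay_zero(self):
        fix = [np.array([1.0, 2.0])] * 3
        samples = [[np.array([5.0])] * 3]
        assert prevalence_mask(samples, fix, "FF").sum() == 0

    def test_population_percentage_range(self):
        masks = [np.eye(4, dtype=int), np.ones((4, 4), dtype=int)]
        pop = population_prevalence(masks)
        assert pop.min() >= 0 and pop.max() <= 100
        assert pop[0, 0] == 100.0 and pop[0, 1] == 50.0


def test_aligned_counts_reads_only_window_bins(located_set):
    """Window containment: counts equal a brute-force loop restricted to
    the declared stimulus and response windows."""
    grid, ts = located_set
    w = EffectWindows()
    got = aligned_counts(ts, (1, 2), w.fixation_stim, w.early_response)
    brute = []
    for tr in ts.trials:
        on = np.flatnonzero(tr.stimulus[1, 2])
        starts = on[np.r_[True, np.diff(on) > 1]] + tr.t_start
        for s in starts:
            if -500 <= s < -100:
                lo = int(s + 50) - tr.t_start
                hi = int(s + 75) - tr.t_start
                brute.append(tr.spikes[lo:hi].sum())
    assert np.array_equal(got, np.array(brute, dtype=float))


def test_collect_rate_samples_layout(located_set):
    grid, ts = located_set
    rates = np.tile(ts.spike_matrix().astype(float) * 1000.0, (1, 1))
    samples, fix = collect_rate_samples(rates, ts, (1, 2),
                                        stim_times=[-45, -44],
                                        latencies=[60, 100])
    assert len(samples) == 2 and len(fix) == 2
    assert all(len(row) == 2 for row in samples)
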