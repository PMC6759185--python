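"""Conditional intensity, point-process likelihood, screen, ascent."""

import numpy as np
import pytest

from perisaccade import smodel as sm
from perisaccade.basis import InvalidInputError
from perisaccade.experiment import ProbeGrid, Trial, TrialSet
from perisaccade.simulate import SyntheticNeuronSpec, make_synthetic_neuron


def small_bases():
    return sm.Bases.from_knots(
        delay_knots=list(range(-13, 163, 25)),
        time_knots=list(range(-350, 351, 100)),
        postspike_knots=[1, 2, 3, 4, 6, 8, 15, 22],
        offset_knots=list(range(-350, 351, 100)),
        delay_support=(0, 150), time_support=(-150, 150))


def baseline_model(r0=10.0, rmax=100.0, bases=None):
    bases = bases or small_bases()
    ni, nj = bases.stimulus.shape
    return sm.SModel(kappa=np.zeros((2, 2, ni, nj)),
                     eta=np.zeros(bases.postspike.n_basis),
                     beta=np.zeros(bases.offset.n_basis),
                     r0=r0, rmax=rmax, bases=bases)


class TestCif:
    def test_no_input_gives_resting_rate(self):
        """With everything zero, f(b0) = r0 by construction of b0."""
        m = baseline_model()
        stim = np.zeros((2, 2, 300), dtype=np.uint8)
        lam = sm.cif(m, stim, -150)
        assert np.allclose(lam, 10.0)

    def test_rate_saturates_at_rmax_and_stays_in_range(self):
        m = baseline_model()
        m.kappa[0, 0, :, :] = 50.0   # enormous drive
        stim = np.zeros((2, 2, 300), dtype=np.uint8)
        stim[0, 0, 100:107] = 1
        lam = sm.cif(m, stim, -150)
        assert lam.max() <= m.rmax + 1e-9
        assert lam.max() > 0.99 * m.rmax
        assert lam.min() >= 0.0

    def test_single_flash_matches_scalar_convolution(self):
        """One nonzero kappa: lambda equals a hand-computed
        sigmoid(kappa * U_i(t - t0) * V_j(t) + b0) at sampled bins."""
        bases = small_bases()
        m = baseline_model(bases=bases)
        m.kappa[1, 0, 2, 3] = 1.7
        stim = np.zeros((2, 2, 300), dtype=np.uint8)
        t0_bin = 120
        stim[1, 0, t0_bin] = 1     # single 1 ms flash
        lam = sm.cif(m, stim, -150)
        U = bases.stimulus.delay_basis
        V = bases.stimulus.time_basis
        for t in range(100, 299, 10):
            tau = t - t0_bin
            drive = 0.0
            if 0 <= tau < 150:
                drive = 1.7 * U.evaluate([tau])[2, 0] \
                    * V.evaluate([t - 150])[3, 0]
            expect = m.rmax / (1.0 + np.exp(-(drive + m.b0)))
            assert lam[t] == pytest.approx(expect, rel=1e-9)

    def test_history_term_suppresses_post_spike_bins(self):
        bases = small_bases()
        m = baseline_model(bases=bases)
        m.eta[:] = 3.0
        stim = np.zeros((2, 2, 300), dtype=np.uint8)
        spikes = np.zeros(300, dtype=np.uint8)
        spikes[150] = 1
        lam = sm.cif(m, stim, -150, spikes=spikes)
        # quadratic splines vanish at their first simple knot, so the
        # suppression sets in from tau = 2 onward
        assert lam[152] < 10.0 * 0.5
        assert lam[149] == pytest.approx(10.0)


class TestLogLikelihood:
    def test_single_bin_closed_form(self):
        """r = 1, lambda*Delta = 0.5: LL = ln(0.5) - 0.5."""
        ll = sm.log_likelihood(np.array([500.0]), np.array([1.0]))
        assert ll == pytest.approx(np.log(0.5) - 0.5)

    def test_identical_models_have_equal_likelihood(self):
        rng = np.random.default_rng(0)
        spikes = (rng.random(1000) < 0.02).astype(float)
        mean_rate = spikes.mean() * 1000
        a = sm.log_likelihood(np.full(1000, mean_rate), spikes)
        b = sm.log_likelihood(np.full(1000, mean_rate), spikes)
        assert a == b

    def test_raising_rate_at_spike_bins_increases_ll(self):
        rng = np.random.default_rng(1)
        spikes = (rng.random(500) < 0.05).astype(float)
        rate = np.full(500, 20.0)
        base = sm.log_likelihood(rate, spikes)
        rate2 = rate.copy()
        rate2[spikes > 0] = 60.0
        assert sm.log_likelihood(rate2, spikes) > base

    def test_validity_mask_skips_bins(self):
        spikes = np.array([1.0, 1.0])
        rate = np.array([100.0, 100.0])
        full = sm.log_likelihood(rate, spikes)
        half = sm.log_likelihood(rate, spikes,
                                 valid=np.array([True, False]))
        assert half == pytest.approx(full / 2)

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidInputError):
            sm.log_likelihood(np.array([-1.0]), np.array([0.0]))


class TestSelectionRule:
    def test_threshold_is_one_and_a_half_control_sd(self):
        """1.6 sigma-bar retained; 1.4 sigma-bar excluded."""
        mu = np.array([1.6, 1.4, -1.6])
        ctrl = np.zeros(3)
        sd = np.ones(3)
        mask = sm.apply_selection_rule(mu, ctrl, sd, threshold=1.5)
        assert mask.tolist() == [True, False, True]

    def test_zero_spikes_gives_empty_mask(self, grid3):
        stim = np.zeros((3, 3, 100), dtype=np.uint8)
        trials = [Trial(stimulus=stim, spikes=np.zeros(100, dtype=np.uint8),
                        t_start=-50, trial_id=i) for i in range(4)]
        ts = TrialSet(grid=grid3, trials=trials, time_axis=(-50, 50))
        with pytest.warns(UserWarning):
            mask, stats = sm.select_parameters(ts, small_bases(),
                                               sm.SModelConfig(n_resamples=2),
                                               seed=0)
        assert not mask.any()

    def test_planted_probe_indices_retained(self, grid3):
        """A probe driving spikes with huge gain keeps its central kappa
        entries; the shuffled-null keeps far fewer elsewhere."""
        spec = SyntheticNeuronSpec(
            grid=grid3, rf_loc=(1, 2), trial_length=300, saccade_time=150,
            baseline_rate=8.0, rmax=100.0, fixation_gain=1.0,
            fixation_latency=(40, 100))
        ds = make_synthetic_neuron(spec, 120, seed=2)
        bases = small_bases()
        mask, stats = sm.select_parameters(
            ds.trials, bases, sm.SModelConfig(n_resamples=8), seed=1)
        assert mask[1, 2].sum() >= 2
        assert stats.n_resamples == 8
        on_frac = mask[1, 2].mean()
        off_frac = (mask.sum() - mask[1, 2].sum()) / (mask.size - mask[1, 2].size)
        assert on_frac > off_frac


class TestFitMachinery:
    def test_split_fractions_and_disjointness(self):
        split = sm.FitSplit.make(100, seed=3)
        assert len(split.train) == 35
        assert len(split.validation) == 30
        assert len(split.test) == 35
        all_idx = np.concatenate([split.train, split.validation, split.test])
        assert len(set(all_idx.tolist())) == 100

    def test_empty_mask_returns_baseline_model(self, grid3):
        rng = np.random.default_rng(0)
        stim = np.zeros((3, 3, 200), dtype=np.uint8)
        trials = [Trial(stimulus=stim,
                        spikes=(rng.random(200) < 0.01).astype(np.uint8),
                        t_start=-100, trial_id=i) for i in range(12)]
        ts = TrialSet(grid=grid3, trials=trials, time_axis=(-100, 100))
        bases = small_bases()
        ni, nj = bases.stimulus.shape
        model = sm.fit(ts, config=sm.SModelConfig(n_resamples=2),
                       bases=bases,
                       selection_mask=np.zeros((3, 3, ni, nj), dtype=bool),
                       seed=0)
        assert not model.kappa.any()
        assert np.allclose(sm.cif(model, stim, -100), model.r0)

    def test_rate_constants_from_data(self, grid3):
        rng = np.random.default_rng(5)
        stim = np.zeros((3, 3, 1000), dtype=np.uint8)
        trials = [Trial(stimulus=stim,
                        spikes=(rng.random(1000) < 0.02).astype(np.uint8),
                        t_start=-500, trial_id=i) for i in range(20)]
        ts = TrialSet(grid=grid3, trials=trials, time_axis=(-500, 500))
        r0, rmax = sm.estimate_rate_constants(ts)
        assert r0 == pytest.approx(20.0, rel=0.15)
        assert rmax > r0


def test_invalid_rate_constants_rejected():
    bases = small_bases()
    ni, nj = bases.stimulus.shape
    with pytest.raises(InvalidInputError):
        sm.SModel(kappa=np.zeros((1, 1, ni, nj)),
                  eta=np.zeros(bases.postspike.n_basis),
                  beta=np.zeros(bases.offset.n_basis),
                  r0=50.0, rmax=40.0, bases=bases)
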