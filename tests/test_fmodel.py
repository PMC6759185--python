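"""Skew-Gaussian source factorization, knockouts, aggregation."""

import numpy as np
import pytest
from scipy.stats import norm

from perisaccade.basis import InvalidInputError, KernelField
from perisaccade.fmodel import (DEFAULT_DELAY_BINS, FactorizationConfig,
                                FModel, N_PHI, PHI_FIELDS, SOURCES,
                                aggregate, fit_factorization,
                                fixation_kernel, knockout, moving_average,
                                skew_gaussian)


def phi(**kw):
    base = {"a": 1.0, "mu_x": 0.0, "mu_y": 0.0, "sigma_x": 1.0,
            "sigma_y": 1.0, "rho": 0.0, "gamma_x": 0.0, "gamma_y": 0.0}
    base.update(kw)
    return base


class TestSkewGaussian:
    def test_center_value_with_zero_skew_is_quarter_amplitude(self):
        """Phi(0)^2 = 1/4 makes the center value a/4."""
        assert skew_gaussian(0.0, 0.0, phi(a=2.0)) == pytest.approx(0.5)
        assert skew_gaussian(3.0, -1.0, phi(a=8.0, mu_x=3.0, mu_y=-1.0)) \
            == pytest.approx(2.0)

    def test_factorizes_when_uncorrelated(self):
        p = phi(a=1.0, sigma_x=1.3, sigma_y=0.7, gamma_x=2.0, gamma_y=-1.0)
        x, y = 0.8, -0.4
        fx = np.exp(-0.5 * (x / 1.3) ** 2) * norm.cdf(2.0 * x)
        fy = np.exp(-0.5 * (y / 0.7) ** 2) * norm.cdf(-1.0 * y)
        assert skew_gaussian(x, y, p) == pytest.approx(fx * fy)

    def test_matches_independent_scalar_evaluator_on_grid(self):
        """Second hand-written implementation agrees at all 81 points."""
        rng = np.random.default_rng(42)
        p = phi(a=rng.normal(), mu_x=rng.uniform(2, 6),
                mu_y=rng.uniform(2, 6), sigma_x=rng.uniform(0.5, 2),
                sigma_y=rng.uniform(0.5, 2), rho=rng.uniform(-0.8, 0.8),
                gamma_x=rng.uniform(-4, 4), gamma_y=rng.uniform(-4, 4))

        def oracle(x, y):
            zx = (x - p["mu_x"]) / p["sigma_x"]
            zy = (y - p["mu_y"]) / p["sigma_y"]
            rho = p["rho"]
            e = np.exp(-(zx * zx + zy * zy - 2 * rho * zx * zy)
                       / (2 * (1 - rho * rho)))
            return (p["a"] * e * norm.cdf(p["gamma_x"] * (x - p["mu_x"]))
                    * norm.cdf(p["gamma_y"] * (y - p["mu_y"])))

        for x in range(9):
            for y in range(9):
                assert skew_gaussian(float(x), float(y), p) == \
                    pytest.approx(oracle(x, y), rel=1e-12)

    def test_singular_orientation_rejected(self):
        with pytest.raises(InvalidInputError):
            skew_gaussian(0, 0, phi(rho=1.0))
        with pytest.raises(InvalidInputError):
            skew_gaussian(0, 0, phi(sigma_x=0.0))


def make_field(values, t_lo=-450, tau_n=150):
    n_t = values.shape[2]
    return KernelField(values, np.arange(t_lo, t_lo + n_t),
                       np.arange(tau_n))


class TestFixationKernel:
    def test_time_invariant_kernel_is_unchanged(self):
        vals = np.tile(np.linspace(0, 1, 150), (2, 2, 200, 1))
        f = fixation_kernel(make_field(vals), -400, -300)
        assert np.allclose(f, vals[:, :, 0, :])

    def test_linear_ramp_averages_to_midpoint(self):
        t = np.arange(-450, -250)
        vals = np.broadcast_to(t[None, None, :, None],
                               (1, 1, 200, 150)).astype(float)
        f = fixation_kernel(make_field(vals), -400, -300)
        assert np.allclose(f, -350.0)

    def test_window_outside_support_rejected(self):
        vals = np.zeros((1, 1, 50, 150))
        with pytest.raises(InvalidInputError):
            fixation_kernel(make_field(vals, t_lo=0), -400, -300)


def test_moving_average_shrinking_edges_preserve_constants():
    x = np.full(40, 3.14)
    assert np.allclose(moving_average(x, 10), 3.14)
    y = np.arange(10.0)
    sm = moving_average(y, 3)
    assert sm[0] == pytest.approx((0 + 1) / 2)       # shrunk left edge
    assert sm[5] == pytest.approx(5.0)


def test_default_delay_bins_are_28_increasing_boundaries():
    assert len(DEFAULT_DELAY_BINS) == 28
    assert DEFAULT_DELAY_BINS[0] == 1 and DEFAULT_DELAY_BINS[-1] == 151
    assert all(b < a for b, a in zip(DEFAULT_DELAY_BINS,
                                     DEFAULT_DELAY_BINS[1:]))


def synth_fmodel(n_t=5, n_b=4, seed=0, amp=1.0):
    rng = np.random.default_rng(seed)
    sources = {}
    for sr in SOURCES:
        arr = np.zeros((n_t, n_b, N_PHI))
        arr[..., 0] = amp * rng.random((n_t, n_b))
        arr[..., 1] = 4.0
        arr[..., 2] = 4.0
        arr[..., 3] = 1.0
        arr[..., 4] = 1.0
        sources[sr] = arr
    return FModel(sources=sources, baseline=rng.random((n_t, n_b)),
                  fixation=np.zeros((9, 9, 150)),
                  bins=np.array([1, 40, 80, 120, 151]),
                  time_grid=np.array([-400, -350, -300, 0, 50]),
                  delay_grid=np.arange(150),
                  source_locs={"RF": (4, 4), "FF": (4, 1), "ST": (4, 2)})


class TestKnockout:
    def test_keep_all_is_identity(self):
        m = synth_fmodel()
        k = knockout(m, SOURCES, seed=3)
        for sr in SOURCES:
            assert np.array_equal(k.sources[sr], m.sources[sr])

    def test_keep_none_replaces_every_source_from_fixation_pool(self):
        m = synth_fmodel(seed=1)
        k = knockout(m, (), seed=3)
        fix_rows = [0, 1, 2]   # time_grid entries within [-400, -300]
        for sr in SOURCES:
            arr = k.sources[sr]
            for ti in range(arr.shape[0]):
                for b in range(arr.shape[1]):
                    assert any(np.array_equal(arr[ti, b],
                                              m.sources[sr][r, b])
                               for r in fix_rows)

    def test_seeded_determinism(self):
        m = synth_fmodel(seed=2)
        a = knockout(m, ("FF",), seed=9)
        b = knockout(m, ("FF",), seed=9)
        for sr in SOURCES:
            assert np.array_equal(a.sources[sr], b.sources[sr])

    def test_unknown_source_rejected(self):
        with pytest.raises(InvalidInputError):
            knockout(synth_fmodel(), ("XX",))


class TestAggregate:
    def test_identical_models_average_to_themselves(self):
        m = synth_fmodel(seed=4)
        a = aggregate([m] * 10)
        for sr in SOURCES:
            assert np.allclose(a.sources[sr], m.sources[sr])
        assert np.allclose(a.baseline, m.baseline)

    def test_elementwise_mean(self):
        m0 = synth_fmodel(seed=5, amp=0.0)
        m2 = synth_fmodel(seed=5, amp=0.0)
        m2.sources["FF"][..., 0] = 2.0
        a = aggregate([m0, m2])
        assert np.allclose(a.sources["FF"][..., 0], 1.0)

    def test_random_ensemble_matches_brute_force(self):
        models = [synth_fmodel(seed=s) for s in range(4)]
        a = aggregate(models)
        for sr in SOURCES:
            brute = sum(m.sources[sr] for m in models) / 4.0
            assert np.allclose(a.sources[sr], brute)

    def test_mismatched_structures_rejected(self):
        with pytest.raises(InvalidInputError):
            aggregate([synth_fmodel(), synth_fmodel(n_t=3)])
        with pytest.raises(InvalidInputError):
            aggregate([])


class TestFitFactorization:
    def locs(self):
        return {"RF": (4, 6), "FF": (4, 3), "ST": (4, 2)}

    def test_planted_source_recovery(self):
        """Fixation + one in-bounds skew Gaussian + constant: SSE ~ 0 and
        the planted center/baseline are recovered."""
        rng = np.random.default_rng(0)
        cols, rows = np.meshgrid(np.arange(9.0), np.arange(9.0))
        fix = rng.normal(scale=0.05, size=(9, 9, 150))
        planted = phi(a=2.0, mu_x=3.4, mu_y=4.3, sigma_x=1.2, sigma_y=0.9,
                      gamma_x=1.5, gamma_y=0.0)
        g = skew_gaussian(cols, rows, planted)
        c_true = 0.3
        vals = fix[:, :, None, :] + (g + c_true)[:, :, None, None]
        vals = np.broadcast_to(vals, (9, 9, 3, 150)).copy()
        field = KernelField(vals, np.array([-400, -350, 0]),
                            np.arange(150))
        cfg = FactorizationConfig(delay_bins=(1, 50, 100, 151))
        fm = fit_factorization(field, self.locs(), cfg, fixation=fix,
                               seed=1)
        # the FF source sits nearest the planted center
        ff = fm.sources["FF"]
        ti, b = 2, 1
        assert abs(ff[ti, b, 1] - 3.4) < 0.1
        assert abs(ff[ti, b, 2] - 4.3) < 0.1
        total_amp = sum(abs(fm.sources[sr][ti, b, 0]) for sr in SOURCES)
        assert total_amp > 1.0   # the planted bump is captured
        recon = fm.reconstruct((9, 9), smooth=False)
        sse = ((recon.values[:, :, ti, :] - vals[:, :, ti, :]) ** 2).mean()
        assert sse < 5e-3
        assert abs(fm.baseline[ti, b] - c_true) < 0.05

    def test_fixation_only_kernel_gives_zero_sources(self):
        rng = np.random.default_rng(3)
        fix = rng.normal(scale=0.3, size=(9, 9, 150))
        vals = np.broadcast_to(fix[:, :, None, :], (9, 9, 2, 150)).copy()
        field = KernelField(vals, np.array([-350, 0]), np.arange(150))
        cfg = FactorizationConfig(delay_bins=(1, 75, 151))
        fm = fit_factorization(field, self.locs(), cfg, fixation=fix,
                               seed=2)
        for sr in SOURCES:
            assert np.all(np.abs(fm.sources[sr][..., 0]) < 1e-3)
        assert np.all(np.abs(fm.baseline) < 1e-3)
        assert np.all(fm.sse < 1e-8)

    def test_constraints_enforced_post_fit(self):
        """Every fitted phi respects the four bound constraints."""
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(9, 9, 2, 150))
        field = KernelField(vals, np.array([-350, 0]), np.arange(150))
        cfg = FactorizationConfig(delay_bins=(1, 75, 151))
        fm = fit_factorization(field, self.locs(), cfg,
                               fixation=np.zeros((9, 9, 150)), seed=3)
        for sr in SOURCES:
            row, col = self.locs()[sr]
            arr = fm.sources[sr]
            assert np.all(np.abs(arr[..., 1] - col) <= 1.0 + 1e-9)
            assert np.all(np.abs(arr[..., 2] - row) <= 1.0 + 1e-9)
            assert np.all(arr[..., 3] <= 2.0 + 1e-9)
            assert np.all(arr[..., 4] <= 2.0 + 1e-9)
            assert np.all(np.abs(arr[..., 5]) <= 1.0)
            assert np.all(np.abs(arr[..., 6:]) <= 5.0 + 1e-9)

    def test_reconstruction_beats_fixation_only(self):
        """Fitted reconstruction SSE <= fixation-only SSE per (t, bin)."""
        rng = np.random.default_rng(7)
        fix = np.zeros((9, 9, 150))
        cols, rows = np.meshgrid(np.arange(9.0), np.arange(9.0))
        g = skew_gaussian(cols, rows, phi(a=1.0, mu_x=6.0, mu_y=4.0))
        vals = np.broadcast_to(g[:, :, None, None],
                               (9, 9, 1, 150)).copy()
        vals += rng.normal(scale=0.02, size=vals.shape)
        field = KernelField(vals, np.array([0]), np.arange(150))
        cfg = FactorizationConfig(delay_bins=(1, 75, 151))
        fm = fit_factorization(field, self.locs(), cfg, fixation=fix,
                               seed=4)
        bins = cfg.delay_bins
        for b in range(len(bins) - 1):
            sel = (field.delay_grid >= bins[b]) \
                & (field.delay_grid < bins[b + 1])
            target = (vals[:, :, 0, :][:, :, sel] - fix[:, :, sel])
            fix_only_sse = (target.mean(axis=2) ** 2).sum() * sel.sum()
            assert fm.sse[0, b] <= fix_only_sse + 1e-9

    def test_smoothing_attenuates_peak(self):
        m = synth_fmodel(seed=8)
        rough = m.reconstruct((9, 9), smooth=False)
        smooth = m.reconstruct((9, 9), smooth=True)
        assert np.abs(smooth.values).max() <= np.abs(rough.values).max() + 1e-12
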