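"""Multi-exponential curve fitting, window selection and model comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tddc import (
    CompartmentSet,
    FitConfig,
    FitTask,
    akaike_weights,
    b_value,
    fit_attenuation,
    fit_series,
    forward_attenuation,
    information_criteria,
    interval_strategy_series,
    select_b_window,
    stejskal_tanner,
    yeast_truth,
)
from tddc.fitting import BWindow
from tddc.synthetic import generate


def _curve(protocol, comps, tm, noise=0.0, rng=None):
    E = forward_attenuation(protocol, comps, protocol.tau_grid, tm,
                            reference_normalized=True)
    if noise:
        E = np.clip(E + rng.normal(0, noise, E.shape), 1e-6, None)
    return protocol.tau_grid, E


class TestFitAttenuation:
    def test_single_exponential_recovered(self, protocol):
        comps = CompartmentSet((1e-9,), (1.0,))
        curve = _curve(protocol, comps, 5e-3)
        res = fit_attenuation(curve, protocol, FitConfig(model_id="model0"),
                              tm=5e-3)
        dominant = int(np.argmax(res.estimates.p))
        assert res.estimates.D[dominant] == pytest.approx(1e-9, rel=1e-3)

    def test_two_pool_simplex_recovery(self, protocol):
        comps = CompartmentSet((1.6e-9, 0.1e-9), (0.3, 0.7))
        curve = _curve(protocol, comps, 5e-3)
        res = fit_attenuation(
            curve, protocol, FitConfig(model_id="model0", unit_sum=True),
            tm=5e-3,
        )
        assert res.estimates.D[0] == pytest.approx(1.6e-9, rel=1e-2)
        assert res.estimates.D[1] == pytest.approx(0.1e-9, rel=1e-2)
        assert res.estimates.p[0] == pytest.approx(0.3, rel=1e-2)
        # simplex constraint: fractions sum to one essentially exactly
        assert sum(res.estimates.p) == pytest.approx(1.0, abs=1e-8)

    def test_three_pool_noisy_median_recovery(self, protocol):
        """Intermediate mixing time, 0.5% noise: the cytoplasmic coefficient
        is recovered within 10% (median).  The slow pool attenuates by at
        most ~1/3 over the b-range at 7% amplitude, so its single-curve
        coefficient is information-limited (Fisher bound ~30% relative SE);
        assert it stays within that statistical envelope."""
        tm = float(protocol.tm_grid[8])  # ~4.1 ms: all pools contribute
        errs2, errs3 = [], []
        for seed in range(30):
            truth = yeast_truth(noise_sigma=0.005, seed=seed)
            comps = truth.compartments_at(tm)
            rng = np.random.default_rng(seed)
            curve = _curve(protocol, comps, tm, noise=0.005, rng=rng)
            res = fit_attenuation(curve, protocol, FitConfig(model_id="model2"),
                                  tm=tm)
            errs2.append(abs(res.estimates.D[1] / comps.D[1] - 1))
            errs3.append(abs(res.estimates.D[2] / comps.D[2] - 1))
        assert np.median(errs2) <= 0.10
        assert np.median(errs3) <= 0.35

    def test_fixed_parameter_honoured_exactly(self, protocol):
        comps = CompartmentSet((1.6e-9, 0.1e-9), (0.3, 0.7))
        curve = _curve(protocol, comps, 5e-3)
        res = fit_attenuation(
            curve, protocol,
            FitConfig(model_id="model0", fixed_params={"D1": 1.5e-9}),
            tm=5e-3,
        )
        assert res.estimates.D[0] == 1.5e-9
        assert res.std_errors["D1"] == 0.0

    def test_window_shorter_than_parameters_rejected(self, protocol):
        comps = CompartmentSet((1e-9,), (1.0,))
        curve = _curve(protocol, comps, 5e-3)
        with pytest.raises(ValueError):
            fit_attenuation(curve, protocol,
                            FitConfig(model_id="model2", b_window=(0, 4)),
                            tm=5e-3)

    def test_intercept_never_increases_rss(self, protocol):
        """model 1 nests model 0: warm-started, its RSS cannot be larger."""
        rng = np.random.default_rng(3)
        comps = CompartmentSet((1.6e-9, 0.1e-9), (0.3, 0.7))
        curve = _curve(protocol, comps, 5e-3, noise=0.005, rng=rng)
        r0 = fit_attenuation(curve, protocol, FitConfig(model_id="model0"),
                             tm=5e-3)
        r1 = fit_attenuation(
            curve, protocol,
            FitConfig(model_id="model1",
                      init=(r0.estimates.D, r0.estimates.p, 0.0)),
            tm=5e-3,
        )
        assert r1.RSS <= r0.RSS * (1 + 1e-12)


class TestWindowSelection:
    def test_already_attenuated_gives_full_range(self):
        att = np.full(20, 0.001)
        win = select_b_window(att, 0.02)
        assert (win.start, win.stop, win.warning) == (0, 19, False)

    def test_fast_pool_exclusion_on_default_grid(self, protocol):
        b = b_value(protocol.tau_grid, 10e-3, protocol.G, protocol.gamma)
        win = select_b_window(stejskal_tanner(1.6e-9, b), 0.02)
        assert 2 <= win.start <= 4

    def test_epsilon_one_excludes_nothing(self):
        att = np.exp(-np.linspace(0, 5, 20))
        win = select_b_window(att, 1.0)
        assert win.start == 0 and not win.warning

    def test_never_attenuated_warns(self):
        att = np.exp(-np.linspace(0, 0.5, 20))
        win = select_b_window(att, 0.02)
        assert win.warning and win.start == 0


class TestInformationCriteria:
    def test_aic_difference_is_two_delta_k(self):
        a4 = information_criteria(1.0, 20, 4)
        a6 = information_criteria(1.0, 20, 6)
        assert a6.AIC - a4.AIC == pytest.approx(4.0)
        assert a6.BIC - a4.BIC == pytest.approx(2 * math.log(20))

    def test_zero_rss_sentinel(self):
        ic = information_criteria(0.0, 20, 4)
        assert ic.degenerate and ic.AIC == -math.inf

    def test_aicc_correction(self):
        plain = information_criteria(1.0, 20, 4)
        corr = information_criteria(1.0, 20, 4, aicc=True)
        assert corr.AIC - plain.AIC == pytest.approx(2 * 4 * 5 / 15)

    def test_akaike_weights(self):
        assert akaike_weights([10.0, 10.0]) == pytest.approx([0.5, 0.5])
        w = akaike_weights([100.0, 102.0])
        assert w == pytest.approx([0.7311, 0.2689], abs=1e-4)
        with pytest.raises(ValueError):
            akaike_weights([1.0])

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_weights_normalized(self, aics):
        assert akaike_weights(aics).sum() == pytest.approx(1.0, abs=1e-12)


class TestSeries:
    def test_single_mixing_time_series(self, dataset_noiseless):
        tasks = [FitTask(0, FitConfig(model_id="model2"), {0: 1, 1: 2, 2: 3})]
        series = fit_series(dataset_noiseless, tasks)
        assert series.n_mixing_times() == 1
        assert series.comps() == [1, 2, 3]

    def test_interval_strategy_keeps_compartment_identity(
        self, dataset_noiseless, truth_noiseless
    ):
        """On noiseless truth the per-compartment traces stay on their own
        branch: no fast/slow identity swaps across the strategy switch."""
        series = interval_strategy_series(dataset_noiseless)
        truth = truth_noiseless.series(dataset_noiseless.protocol.tm_grid)
        for comp in (2, 3):
            est = series.trace(comp)
            tru = truth[truth.comp == comp].sort_values("tm")
            merged = est.merge(tru, on="tm", suffixes=("_est", "_tru"))
            assert len(merged) >= 13
            assert np.allclose(merged.D_est, merged.D_tru, rtol=0.05)

    def test_matched_class_noiseless_is_exact(self, dataset_noiseless,
                                              truth_noiseless):
        tasks = [FitTask(i, FitConfig(model_id="model2"), {0: 1, 1: 2, 2: 3})
                 for i in range(15)]
        series = fit_series(dataset_noiseless, tasks)
        truth = truth_noiseless.series(dataset_noiseless.protocol.tm_grid)
        for comp in (1, 2, 3):
            est = series.trace(comp)["D"].to_numpy()
            tru = truth[truth.comp == comp].sort_values("tm")["D"].to_numpy()
            assert np.allclose(est, tru, rtol=1e-3)
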