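"""Selectivity statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flexdec import selectivity, task
from flexdec.selectivity import (RateTable, label_ct_it, modulation_index,
                                 partial_corr, rf_center, roc_auc,
                                 screen_units, sliding_roc)


def brute_force_auc(a, b):
    wins = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    return wins / (len(a) * len(b))


def regress_out(y, x):
    """Residual of y after OLS on x (with intercept)."""
    X = np.column_stack([np.ones(len(x)), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


class TestRocAuc:
    @pytest.mark.parametrize("a,b,expected", [
        ([1, 2, 3], [1, 2, 3], 0.5),
        ([5, 6], [1, 2], 1.0),
        ([3, 5], [2, 4], 0.75),
    ])
    def test_known_values(self, a, b, expected):
        assert roc_auc(a, b) == pytest.approx(expected)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            na, nb = rng.integers(2, 8, size=2)
            a = rng.integers(0, 5, size=na)     # ties likely
            b = rng.integers(0, 5, size=nb)
            assert roc_auc(a, b) == pytest.approx(brute_force_auc(a, b))

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=6),
           st.lists(st.floats(-10, 10), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_complement_identity(self, a, b):
        assert roc_auc(a, b) + roc_auc(b, a) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(1, 1, 10), rng.normal(0, 1, 12)
        base = roc_auc(a, b)
        for f in (np.exp, lambda v: v ** 3, lambda v: 5 * v - 2):
            assert roc_auc(f(a), f(b)) == pytest.approx(base)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])


def synth_table(n_units=6, n_trials=200, d_prime=0.0, seed=0,
                coherences=(0.0, 0.13, 0.25, 0.5), hemisphere=0):
    """Gaussian-rate table with optional injected direction selectivity."""
    rng = np.random.default_rng(seed)
    times = np.arange(-200.0, 400.0, 10.0)
    direction = rng.choice([135.0, 315.0], size=n_trials)
    coherence = rng.choice(coherences, size=n_trials)
    conf = rng.integers(0, 2, size=n_trials)
    choice = rng.integers(0, 2, size=n_trials)
    sig = np.where(direction == 315, 0.5, -0.5) * d_prime
    post = times >= 0
    rates = rng.normal(5.0, 1.0, size=(n_units, n_trials, len(times)))
    rates[:, :, post] += sig[None, :, None]
    labels = pd.DataFrame({
        "direction": direction, "coherence": coherence, "choice": choice,
        "correct": np.ones(n_trials, dtype=int),
        "rt_ms": rng.uniform(200, 500, n_trials),
        "target_config": conf})
    return RateTable(rates, times, labels,
                     np.full(n_units, hemisphere))


class TestSlidingRoc:
    def test_label_independent_rates_near_half(self):
        table = synth_table(n_units=4, n_trials=1000, d_prime=0.0)
        centers, roc = sliding_roc(table, step=50.0)
        se = np.sqrt(1 / (12 * 250))     # rough AUC SE at n~500 per class
        assert np.nanmax(np.abs(roc - 0.5)) < 6 * se

    def test_injected_dprime_matches_gaussian_closed_form(self):
        # AUC for two unit-variance Gaussians d' apart is Phi(d'/sqrt 2)
        from scipy.stats import norm
        d = 1.0
        table = synth_table(n_units=4, n_trials=1500, d_prime=d, seed=2)
        # window-mean over 100 ms of 10 ms bins shrinks the noise; compute
        # the oracle for the window-averaged variables
        n_bins = 10
        sd_eff = 1.0 / np.sqrt(n_bins)
        expected = norm.cdf(d / np.sqrt(2) / sd_eff)
        centers, roc = sliding_roc(table, step=100.0)
        post = centers > 100
        got = np.nanmean(roc[:, post])
        assert got == pytest.approx(expected, abs=0.03)


class TestScreening:
    def test_constant_unit_excluded(self):
        table = synth_table(n_units=2, n_trials=50)
        table.rates[0] = 3.0
        flags = screen_units(table, mode="ephys")
        assert not flags.loc[0, "keep"]
        assert flags.loc[0, "reason"] == "degenerate_variance"

    def test_low_rate_unit_excluded(self):
        table = synth_table(n_units=2, n_trials=400, d_prime=1.0, seed=3)
        table.rates[1] = table.rates[1] * 0.2   # max mean rate ~1 sp/s
        flags = screen_units(table, mode="ephys")
        assert not flags.loc[1, "keep"]
        assert flags.loc[1, "reason"] == "low_rate"

    def test_fraction_kept_matches_mixture(self):
        # half the units strongly selective: expect ~half kept (+ alpha
        # false positives among the nulls)
        rng = np.random.default_rng(4)
        tables = []
        n_sel = 0
        table = synth_table(n_units=40, n_trials=300, d_prime=0.0, seed=4)
        sig = np.where(table.labels["direction"].to_numpy() == 315, 2.0, -2.0)
        table.rates[:20, :, table.times >= 0] += sig[None, :, None]
        flags = screen_units(table, mode="ephys")
        kept = flags["keep"].to_numpy()
        assert kept[:20].mean() > 0.9
        assert kept[20:].mean() < 0.2


class TestCtIt:
    def test_definition_and_mirror(self):
        table = synth_table(n_units=2, n_trials=20, seed=5)
        table.hemisphere = np.array([0, 1])     # left, right
        ct = label_ct_it(table, use="choice")
        side = table.labels["choice"].to_numpy()
        # left-hemisphere unit: CT iff the target is on the right
        assert np.array_equal(ct[0], side == task.RIGHT)
        assert np.array_equal(ct[1], side == task.LEFT)
        assert np.array_equal(ct[0], ~ct[1])    # swap hemisphere = swap CT/IT

    def test_correct_target_definition(self):
        table = synth_table(n_units=1, n_trials=8, seed=6)
        table.labels["coherence"] = 0.5         # no zero-coh override
        ct = label_ct_it(table, use="correct")
        side = selectivity.target_side(table.labels, "correct")
        assert np.array_equal(ct[0], side == task.RIGHT)


class TestPartialCorr:
    def test_construction_extremes(self):
        rng = np.random.default_rng(0)
        stim = rng.normal(size=500)
        choice = rng.normal(size=500)
        assert partial_corr(stim, stim, choice) == pytest.approx(1.0)
        r = partial_corr(rng.normal(size=500), stim, choice)
        assert abs(r) < 3 / np.sqrt(500)

    def test_matches_regress_out_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x, y, z = rng.normal(size=(3, 6))
            expected = np.corrcoef(regress_out(x, z), regress_out(y, z))[0, 1]
            assert partial_corr(x, y, z) == pytest.approx(expected,
                                                          abs=1e-10)

    def test_zero_variance_flagged(self):
        assert np.isnan(partial_corr([1, 1, 1], [1, 2, 3], [2, 1, 3]))

    def test_series_on_constructed_data(self):
        table = synth_table(n_units=2, n_trials=600, seed=8)
        prefs = np.array([315.0, 315.0])
        stim, dec = selectivity.stimulus_choice_codes(table, prefs)
        # unit 0's activity IS the stimulus code
        table.rates[0] = stim[0][:, None] + 0.0
        centers, r_stim, r_dec = selectivity.partial_corr_series(
            table, step=100.0, prefs=prefs)
        assert np.nanmin(r_stim[0]) > 0.99
        assert np.nanmax(np.abs(r_dec[0])) < 0.15


class TestModulationIndex:
    def _table_with_deltas(self, dc, di):
        """Rates built so delta_contra=dc and delta_ipsi=di exactly."""
        n_trials = 80
        rng = np.random.default_rng(9)
        direction = np.tile([315.0, 135.0], n_trials // 2)
        choice = np.repeat([1, 0], n_trials // 2)   # contra=1 for hemi 0
        rates = np.full((1, n_trials, 60), 10.0)
        pref = direction == 315
        contra = choice == 1
        rates[0, pref & contra] += dc
        rates[0, pref & ~contra] += di
        labels = pd.DataFrame({
            "direction": direction, "coherence": 0.5, "choice": choice,
            "correct": 1, "rt_ms": 300.0, "target_config": 0})
        times = np.arange(-200.0, 400.0, 10.0)
        return RateTable(rates, times, labels, np.array([0]))

    @pytest.mark.parametrize("dc,di,expected", [
        (2.0, 2.0, 0.0),
        (3.0, 0.0, 1.0),
        (3.0, 1.0, 0.5),
    ])
    def test_formula_cases(self, dc, di, expected):
        table = self._table_with_deltas(dc, di)
        mi = modulation_index(table, prefs=np.array([315.0]))
        assert mi.loc[0, "mi"] == pytest.approx(expected)

    def test_undefined_flagged(self):
        table = self._table_with_deltas(0.0, 0.0)
        mi = modulation_index(table, prefs=np.array([315.0]))
        assert not mi.loc[0, "defined"]

    def test_antisymmetric_under_contra_ipsi_swap(self):
        table = self._table_with_deltas(3.0, 1.0)
        mi1 = modulation_index(table, prefs=np.array([315.0]))
        table.hemisphere = np.array([1])        # swap hemisphere
        mi2 = modulation_index(table, prefs=np.array([315.0]))
        assert mi1.loc[0, "mi"] == pytest.approx(-mi2.loc[0, "mi"])


class TestCorrectErrorRoc:
    def _decision_table(self, lam, n_trials=400, seed=10):
        from flexdec.ephys import EphysSimConfig, simulate_session
        cfg = EphysSimConfig(n_neurons=6, trials_per_condition=n_trials // 8,
                             lam=lam, ds_amp=12.0)
        return simulate_session(cfg, np.random.default_rng(seed))

    def test_choice_locked_unit(self):
        table = self._decision_table(lam=1.0)
        low = sorted(set(table.labels["coherence"]) - {0.0})[0]
        centers, r_stim, r_choice, inc = selectivity.correct_error_roc(
            table, low, step=50.0)
        assert inc.size > 0
        post = centers > 100
        assert np.nanmean(np.abs(r_choice[:, post] - 0.5)) > \
            np.nanmean(np.abs(r_stim[:, post] - 0.5)) + 0.05

    def test_stimulus_locked_unit(self):
        # note: at low coherence the choice still tracks the stimulus on
        # ~3/4 of trials, so choice-locked ROC sits well above 0.5 even
        # for a purely stimulus-driven unit; only the ordering is tested
        table = self._decision_table(lam=0.0, n_trials=800)
        low = sorted(set(table.labels["coherence"]) - {0.0})[0]
        centers, r_stim, r_choice, inc = selectivity.correct_error_roc(
            table, low, step=50.0)
        assert inc.size > 0
        post = centers > 100
        assert np.nanmean(np.abs(r_stim[:, post] - 0.5)) > \
            np.nanmean(np.abs(r_choice[:, post] - 0.5)) + 0.02

    def test_insufficient_errors_excluded(self):
        table = self._decision_table(lam=0.5)
        table.labels.loc[table.labels["direction"] == 315, "correct"] = 1
        low = sorted(set(table.labels["coherence"]) - {0.0})[0]
        _, _, _, inc = selectivity.correct_error_roc(table, low)
        assert inc.size == 0


class TestRfCenter:
    def test_flat_responses_none(self):
        rng = np.random.default_rng(0)
        responses = [rng.poisson(10, 20) for _ in range(8)]
        center, reason = rf_center(responses, rng.poisson(10, 60))
        assert center is None

    def test_recovery_within_10_degrees(self):
        from flexdec.ephys import MGSSimConfig, simulate_mgs
        cfg = MGSSimConfig(center_deg=90.0, width_deg=40.0, amp=30.0,
                           trials_per_location=40)
        responses, base, angles = simulate_mgs(cfg, np.random.default_rng(1))
        center, reason = rf_center(responses, base, angles)
        assert reason == "ok"
        err = abs((center - 90.0 + 180) % 360 - 180)
        assert err < 10.0

    def test_below_baseline_none(self):
        rng = np.random.default_rng(2)
        # tuned but suppressed below the baseline level
        responses = [rng.poisson(4 + 10 * np.exp(-0.5 * ((th - 90) / 50) ** 2),
                                 40)
                     for th in np.arange(0, 360, 45)]
        center, reason = rf_center(responses, rng.poisson(20, 60))
        assert center is None
        assert reason == "not_above_baseline"
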