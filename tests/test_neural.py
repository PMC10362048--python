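"""Tests of bursting classification, censored PSTHs and epoch responses."""

import numpy as np
import pandas as pd
import pytest

from stepwise_bf.config import NeuronConfig
from stepwise_bf.neural import (
    ExclusionError, PopulationActivity, classify_bursting, compute_psth,
    evaluation_response, outcome_response, pool_population,
    resolve_evaluation_epoch, stimulus_response_difference, trial_trend,
)
from stepwise_bf.synthetic import simulate_spikes


def trials_frame(n_sleft=10, n_catch=20, spacing=5.0):
    rows = []
    t = 10.0
    for _ in range(n_sleft):
        rows.append({"type": "s_left", "t_stim": t, "t_light_on": t - 2.0})
        t += spacing
    for _ in range(n_catch):
        rows.append({"type": "catch", "t_stim": t, "t_light_on": t - 2.0})
        t += spacing
    return pd.DataFrame(rows)


def spikes_with_window_counts(trials, sleft_per_trial, catch_per_trial,
                              baseline_per_trial=0):
    """Deterministic spike train realizing exact per-window rates."""
    times = []
    for _, row in trials.iterrows():
        k = sleft_per_trial if row["type"] == "s_left" else catch_per_trial
        times.extend(row.t_stim + 0.05 + 0.01 * np.arange(k))
        times.extend(row.t_light_on - 1.0 + 0.01 * np.arange(baseline_per_trial))
    return {"u0": np.sort(np.asarray(times))}


class TestClassifyBursting:
    def test_strong_sleft_contrast_is_bursting(self):
        # 10 vs 3 spikes/s in the [0.05, 0.2] s window, baseline 5
        tr = trials_frame()
        # 10 s_left trials x 1.5 spikes -> use 15 spikes over 10 windows
        units = {"u0": np.sort(np.concatenate([
            np.concatenate([row.t_stim + 0.06 + 0.01 * np.arange(
                3 if i < 5 else 0) for i, (_, row) in
                enumerate(tr[tr.type == "s_left"].iterrows())]),
            np.concatenate([row.t_stim + 0.06 + 0.01 * np.arange(
                3 if i < 3 else 0) for i, (_, row) in
                enumerate(tr[tr.type == "catch"].iterrows())]),
            np.concatenate([row.t_light_on - 0.9 + 0.1 * np.arange(5)
                            for _, row in tr.iterrows()]),
        ]))}
        out = classify_bursting(units, tr)
        assert out.sleft_window_rate[0] == pytest.approx(15 / (0.15 * 10))
        assert out.catch_window_rate[0] == pytest.approx(9 / (0.15 * 20))
        assert out.baseline_rate[0] == pytest.approx(5.0)
        assert bool(out.is_bursting[0])

    def test_contrast_below_threshold_is_not_bursting(self):
        tr = trials_frame()
        units = spikes_with_window_counts(tr, sleft_per_trial=1,
                                          catch_per_trial=0)  # 6.67 vs 0...
        # 1 spike/window over 0.15 s = 6.67 spikes/s; catch 0 -> bursting;
        # instead craft 4 vs 3 spikes/s: 6 spikes over 10 s_left windows
        times = []
        for i, (_, row) in enumerate(tr[tr.type == "s_left"].iterrows()):
            if i < 6:
                times.append(row.t_stim + 0.1)
        for i, (_, row) in enumerate(tr[tr.type == "catch"].iterrows()):
            if i < 9:
                times.append(row.t_stim + 0.1)
        out = classify_bursting({"u0": np.sort(np.asarray(times))}, tr)
        assert out.sleft_window_rate[0] == pytest.approx(4.0)
        assert out.catch_window_rate[0] == pytest.approx(3.0)
        assert not bool(out.is_bursting[0])

    def test_contrast_of_exactly_two_rejected(self):
        # the criterion is strictly greater than 2 spikes/s
        tr = trials_frame()
        units = spikes_with_window_counts(tr, sleft_per_trial=3,
                                          catch_per_trial=0)
        out = classify_bursting(units, tr)
        assert out.sleft_window_rate[0] == pytest.approx(20.0)
        assert bool(out.is_bursting[0])
        # shift catch windows to 18 spikes/s: difference exactly 2.0
        units2 = spikes_with_window_counts(tr, 3, 0)
        extra = []
        for _, row in tr[tr.type == "catch"].iterrows():
            extra.extend(row.t_stim + 0.05 + 0.005 * np.arange(2.7 * 10 // 10))
        # 27 spikes over 20 catch windows -> 9/s; instead place 2.7/trial
        times = list(units2["u0"])
        catch_rows = tr[tr.type == "catch"].reset_index(drop=True)
        total = 54  # 54 spikes / (0.15 * 20 trials) = 18.0 spikes/s
        per = np.full(20, total // 20)
        per[: total % 20] += 1
        for k, row in catch_rows.iterrows():
            times.extend(row.t_stim + 0.05 + 0.004 * np.arange(per[k]))
        out2 = classify_bursting({"u0": np.sort(np.asarray(times))}, tr)
        assert out2.sleft_window_rate[0] - out2.catch_window_rate[0] == \
            pytest.approx(2.0)
        assert not bool(out2.is_bursting[0])

    def test_high_baseline_excluded(self):
        tr = trials_frame()
        units = spikes_with_window_counts(tr, sleft_per_trial=3,
                                          catch_per_trial=0,
                                          baseline_per_trial=12)
        out = classify_bursting(units, tr)
        assert out.baseline_rate[0] >= 10.0
        assert not bool(out.is_bursting[0])

    def test_no_catch_trials_raises(self):
        tr = trials_frame(n_catch=0)
        with pytest.raises(ExclusionError, match="no catch trials"):
            classify_bursting({"u0": np.array([1.0])}, tr)

    def test_planted_classes_recovered(self):
        # gains 8 vs 0 spikes/s, 600 trials: exact recovery across seeds
        neurons = NeuronConfig(n_units=10, p_bursting=0.5)
        rows = []
        t = 5.0
        for i in range(1200):
            rows.append({
                "kind": "trial", "trial_type": "s_left" if i % 2 else "catch",
                "label": None, "post_transition": False, "session_frac": 0.0,
                "t_stim": t, "t_fix_out": t + 0.5, "t_port_in": np.nan,
                "t_outcome": np.nan, "t_end": t + 1.0,
                "expectation": np.nan, "rpe": np.nan,
                "t_light_on": t - 1.5,
            })
            t += 2.2
        truth = pd.DataFrame(rows)
        events = pd.DataFrame({"time_s": [t], "event": ["lick"],
                               "port": ["right"], "trial_hint": [0]})
        trials = truth.rename(columns={"trial_type": "type"})[
            ["type", "t_stim", "t_light_on"]]
        for seed in range(10):
            sp, units = simulate_spikes(events, truth, neurons,
                                        np.random.default_rng(seed))
            det = classify_bursting(sp, trials)
            merged = det.merge(units, on="unit_id")
            assert (merged.is_bursting_x == merged.is_bursting_y).all()

    def test_invariant_to_unit_relabeling_and_outside_spikes(self):
        tr = trials_frame()
        units = spikes_with_window_counts(tr, 3, 0, baseline_per_trial=2)
        out1 = classify_bursting(units, tr)
        shifted = {"zz": np.sort(np.concatenate(
            [units["u0"], np.array([500.0, 600.0, 700.0])]))}
        out2 = classify_bursting(shifted, tr)
        assert bool(out1.is_bursting[0]) == bool(out2.is_bursting[0])


class TestPoolPopulation:
    def cls(self, ids, bursting):
        return pd.DataFrame({"unit_id": ids, "is_bursting": bursting})

    def test_pooled_counts_and_normalizer(self):
        units = {"a": np.arange(10.0), "b": np.arange(10.0) + 0.5}
        pop = pool_population(units, self.cls(["a", "b"], [True, True]))
        assert len(pop.times) == 20 and pop.n_units == 2
        assert np.all(np.diff(pop.times) >= 0)

    def test_single_bursting_unit_excluded(self):
        units = {"a": np.arange(10.0), "b": np.arange(10.0)}
        with pytest.raises(ExclusionError, match="population analysis"):
            pool_population(units, self.cls(["a", "b"], [True, False]))

    def test_normalization_identity_for_identical_units(self):
        train = np.arange(0.0, 100.0, 0.2)
        units = {f"u{i}": train for i in range(4)}
        pop = pool_population(units, self.cls(list(units), [True] * 4))
        single = PopulationActivity(times=train, n_units=1)
        assert pop.rate(10, 20) == pytest.approx(single.rate(10, 20))


class TestComputePsth:
    def test_single_trial_bin_rate(self):
        # 2 spikes in one 10 ms bin, 1 unit, 1 trial -> 200 spikes/s
        pop = PopulationActivity(np.array([10.105, 10.108]), n_units=1)
        p = compute_psth(pop, np.array([10.0]), window=(0.0, 0.2),
                         truncate=None)
        i = int(np.flatnonzero(np.isclose(p.bin_edges[:-1], 0.10))[0])
        assert p.rate[i] == pytest.approx(200.0)
        assert p.trials_per_bin[i] == 1

    def test_censoring_removes_post_fixout_spikes(self):
        # fix-out at 0.25 s: spikes at t >= 0.25 contribute to no bin
        pop = PopulationActivity(np.array([10.1, 10.25, 10.3, 10.9]), 1)
        p = compute_psth(pop, np.array([10.0]), window=(0.0, 1.0),
                         obs_hi=np.array([0.25]), truncate=None)
        assert np.nansum(p.counts) == 1
        assert np.all(p.trials_per_bin[25:] == 0)
        assert np.all(np.isnan(p.rate[25:]))

    def test_truncated_at_median_censor_latency(self):
        pop = PopulationActivity(np.arange(0.0, 300.0, 0.11), 1)
        aligns = np.arange(10.0, 210.0, 10.0)
        obs = np.full(20, 0.4)
        obs[:10] = 0.8
        p = compute_psth(pop, aligns, window=(0.0, 1.0), obs_hi=obs,
                         truncate="median")
        assert p.truncation[1] == pytest.approx(0.6)
        assert p.bin_edges[-1] <= 0.6 + 1e-9

    def test_spike_conservation_and_poisson_bounds(self):
        rng = np.random.default_rng(5)
        r, n_units, n_trials = 20.0, 4, 80
        duration = 1000.0
        pop = PopulationActivity(
            np.sort(rng.uniform(0, duration, rng.poisson(r * n_units * duration))),
            n_units)
        aligns = np.arange(5.0, 5.0 + 10.0 * n_trials, 10.0)
        p = compute_psth(pop, aligns, window=(-0.5, 0.5), truncate=None)
        # conservation: sum(rate * width * tpb * n_units) == pooled count
        lhs = np.nansum(p.rate * 0.01 * p.trials_per_bin * p.n_units)
        assert lhs == pytest.approx(p.counts.sum())
        lam = r * 0.01 * n_trials * n_units
        bound = 4 * np.sqrt(lam) / (0.01 * n_trials * n_units)
        assert np.all(np.abs(p.rate - r) <= bound)

    def test_censoring_monotonicity(self):
        rng = np.random.default_rng(6)
        pop = PopulationActivity(np.sort(rng.uniform(0, 500, 2000)), 2)
        aligns = np.arange(5.0, 405.0, 10.0)
        obs = rng.uniform(0.1, 1.0, len(aligns))
        p = compute_psth(pop, aligns, window=(0.0, 1.0), obs_hi=obs,
                         truncate=None)
        assert np.all(np.diff(p.trials_per_bin) <= 0)


class TestEvaluationResponse:
    def brute_force(self, times, t0, t1, n_units, w=0.5):
        spikes = times[(times >= t0) & (times <= t1)]
        cands = [t0, t1 - w] + [s for s in spikes if s <= t1 - w]
        best = 0
        for a in cands:
            best = max(best, int(np.sum((spikes >= a) & (spikes <= a + w))))
        return best / (w * n_units)

    def test_regular_train_returns_its_rate(self):
        # deterministic 5 spikes/s per neuron, 20 units pooled
        n_units, r = 20, 5.0
        times = np.arange(0.0, 10.0, 1.0 / (r * n_units))
        pop = PopulationActivity(times, n_units)
        res = evaluation_response(pop, 2.0, 8.0)
        assert res.rate == pytest.approx(r, abs=1.0 / (0.5 * n_units) + 1e-9)

    def test_isolated_burst(self):
        # 10 spikes in 0.2 s inside a quiet epoch, 1 unit -> 20 spikes/s
        times = 5.0 + np.linspace(0, 0.2, 10)
        pop = PopulationActivity(times, 1)
        res = evaluation_response(pop, 4.0, 7.0)
        assert res.rate == pytest.approx(20.0)

    def test_short_epoch_used_whole_and_flagged(self):
        pop = PopulationActivity(np.array([1.0, 1.1, 1.2]), 1)
        res = evaluation_response(pop, 0.9, 1.2)
        assert res.used_whole_epoch
        assert res.rate == pytest.approx(3 / 0.3)

    def test_matches_spike_anchored_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            n = rng.integers(0, 40)
            t0 = rng.uniform(0, 5)
            t1 = t0 + rng.uniform(0.6, 4.0)
            times = np.sort(rng.uniform(t0 - 1, t1 + 1, n))
            pop = PopulationActivity(times, 2)
            res = evaluation_response(pop, t0, t1)
            assert res.rate == pytest.approx(
                self.brute_force(times, t0, t1, 2))

    def test_dominates_epoch_mean(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            times = np.sort(rng.uniform(0, 4, rng.integers(5, 80)))
            pop = PopulationActivity(times, 1)
            res = evaluation_response(pop, 0.0, 4.0)
            assert res.rate >= pop.rate(0.0, 4.0) - 1e-9


class TestEvaluationEpochRules:
    durs = np.array([0.8, 1.0, 1.2, 1.4, 2.0])

    def test_lick_trial_epoch(self):
        row = {"label": "light_lick", "t_fix_out": 10.0, "t_outcome": 11.1,
               "t_port_in": 10.6}
        assert resolve_evaluation_epoch(row, self.durs) == (10.0, 11.1)

    def test_no_fixation_bout_anchored_before_port_entry(self):
        row = {"label": "no_fixation_lick", "t_fix_out": np.nan,
               "t_outcome": 20.4, "t_port_in": 20.0}
        start, end = resolve_evaluation_epoch(row, self.durs)
        assert end == 20.4
        assert start <= 20.0 - 0.5
        assert end - start >= np.percentile(self.durs, 95) - 1e-9

    def test_no_lick_trial_uses_median_duration(self):
        row = {"label": "catch_no_lick", "t_fix_out": 30.0,
               "t_outcome": np.nan, "t_port_in": np.nan}
        start, end = resolve_evaluation_epoch(row, self.durs)
        assert (start, end) == (30.0, 30.0 + np.median(self.durs))


class TestOutcomeAndTrends:
    def test_outcome_window_rate(self):
        # 3 pooled spikes in [0.05, 0.35] s, 2 units -> 5 spikes/s
        pop = PopulationActivity(np.array([10.1, 10.2, 10.3]), 2)
        assert outcome_response(pop, 10.0) == pytest.approx(5.0)

    def test_outcome_empty_window(self):
        pop = PopulationActivity(np.array([1.0]), 2)
        assert outcome_response(pop, 10.0) == 0.0

    def test_outcome_requires_event(self):
        pop = PopulationActivity(np.array([1.0]), 2)
        with pytest.raises(ValueError, match="no outcome"):
            outcome_response(pop, np.nan)

    def test_trend_constant_series(self):
        x = np.full(30, 3.5)
        assert np.allclose(trial_trend(x), 3.5)

    def test_trend_removes_single_outlier(self):
        x = np.full(30, 1.0)
        x[15] = 50.0
        assert np.allclose(trial_trend(x), 1.0)

    def test_trend_matches_sort_based_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=57)
        out = trial_trend(x, window=10)
        for i in range(len(x)):
            seg = x[max(0, i - 4): min(len(x), i + 6)]
            assert out[i] == pytest.approx(np.median(np.sort(seg)))

    def test_stimulus_response_difference(self):
        rng = np.random.default_rng(10)
        pop_a = PopulationActivity(np.sort(rng.uniform(0, 100, 4000)), 2)
        aligns = np.arange(2.0, 92.0, 10.0)
        pa = compute_psth(pop_a, aligns, window=(0.0, 0.5), truncate=None)
        assert stimulus_response_difference(pa, pa, (0.1, 0.3)) == 0.0
        with pytest.raises(ValueError, match="overlap"):
            pb = compute_psth(pop_a, aligns, window=(2.0, 2.5), truncate=None)
            stimulus_response_difference(pa, pb, (0.1, 0.3))
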