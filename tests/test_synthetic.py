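"""Tests of the ground-truthed task/agent/spike simulator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stepwise_bf.config import AgentConfig, NeuronConfig
from stepwise_bf.synthetic import (
    AgentPlan, AgentState, simulate_session, simulate_spikes, simulate_trial,
    simulate_study,
)
from .conftest import small_agent

PLAN = AgentPlan(d0=0, d1=1, d2=3, transition_trial=20, step2_offset=60)


def make_state(task, agent, session=1, combined=100, plan=PLAN):
    return AgentState(task=task, cfg=agent, plan=plan, session=session,
                      combined=combined)


class TestSimulateTrial:
    def test_sleft_trial_ends_with_three_drop_reward_at_third_lick(self, task):
        agent = small_agent(left_p_correct=1.0, early_exit_hazard=0.0)
        rng = np.random.default_rng(0)
        ev, info = simulate_trial(task, make_state(task, agent), "s_left", rng)
        df = pd.DataFrame(ev, columns=["t", "event", "port"])
        drops = df[df.event == "reward_drop"]
        assert len(drops) == 3
        assert (drops.port == "left").all()
        left_licks = df[(df.event == "lick") & (df.port == "left")].t.to_numpy()
        assert len(left_licks) >= 3
        # delivery starts at the 3rd lick
        assert drops.t.iloc[0] == pytest.approx(left_licks[2], abs=0.02)
        assert info["rewarded"] and info["label"] == "left_lick"
        assert info["t_outcome"] == pytest.approx(left_licks[2])

    def test_catch_trial_with_zero_lick_probability_has_no_licks(self, task):
        agent = small_agent(early_exit_hazard=0.0)
        state = make_state(task, agent, session=0, combined=0)  # pre-transition
        ev, info = simulate_trial(task, state, "catch", np.random.default_rng(1))
        kinds = [e for _, e, _ in ev]
        assert kinds == ["fixlight_on", "fix_in", "catch_mark", "fix_out"]
        assert info["label"] == "catch_no_lick"
        assert info["t_stim"] is not None  # would-be-stimulus timestamp exists

    def test_unknown_trial_type_raises(self, task):
        agent = small_agent()
        with pytest.raises(ValueError, match="unknown trial_type"):
            simulate_trial(task, make_state(task, agent), "s_up",
                           np.random.default_rng(0))

    def test_lick_rate_matches_configuration(self, task):
        # post-transition light trials; empirical inter-lick rate within 3 SE
        agent = small_agent(early_exit_hazard=0.0, p_lick_light_post=1.0)
        rng = np.random.default_rng(2)
        ilis = []
        for _ in range(1000):
            ev, info = simulate_trial(task, make_state(task, agent), "light", rng)
            licks = np.array([t for t, e, p in ev if e == "lick"])
            ilis.extend(np.diff(licks))
        ilis = np.asarray(ilis)
        se = ilis.std() / np.sqrt(len(ilis))
        assert abs(ilis.mean() - 1.0 / task.lick_rate_hz) < 3 * se

    def test_event_times_are_ordered(self, task):
        agent = small_agent()
        rng = np.random.default_rng(3)
        for ttype in ("s_left", "light", "catch"):
            ev, _ = simulate_trial(task, make_state(task, agent), ttype, rng)
            t = [r[0] for r in ev]
            assert t == sorted(t)


class TestSimulateSession:
    def test_no_rightward_licks_before_d1(self, task, agent_small):
        rng = np.random.default_rng(4)
        plan = AgentPlan(d0=0, d1=2, d2=4, transition_trial=20, step2_offset=60)
        _, truth = simulate_session(task, agent_small, 0, rng, plan=plan)
        bad = truth.label.isin(["light_lick", "catch_lick", "no_fixation_lick"])
        assert not bad.any()

    def test_catch_lick_frequency_peaks_at_d2(self, task):
        agent = AgentConfig(n_trials_mean=250, n_trials_sd=10)
        rng = np.random.default_rng(5)
        plan = AgentPlan.sample(agent, rng)
        rates = []
        for s in range(agent.n_sessions):
            _, truth = simulate_session(task, agent, s, rng, plan=plan)
            n_catch = truth.trial_type.eq("catch").sum()
            rates.append(truth.label.eq("catch_lick").sum() / max(1, n_catch))
        assert int(np.argmax(rates)) == plan.d2

    def test_trial_type_counts_within_binomial_bounds(self, task, agent_small):
        rng = np.random.default_rng(6)
        _, truth = simulate_session(task, agent_small, 0, rng, plan=PLAN,
                                    n_trials=300)
        counts = truth[truth.kind == "trial"].trial_type.value_counts()
        lo, hi = sps.binom.ppf([0.005, 0.995], 300, 1 / 3)
        for ttype in ("s_left", "light", "catch"):
            assert lo <= counts[ttype] <= hi

    def test_streams_ordered_and_licks_follow_port_entry(self, task, d1_session):
        events, truth, _ = d1_session
        t = events.time_s.to_numpy()
        assert (np.diff(t) >= 0).all()
        for _, grp in events.groupby("trial_hint"):
            licks = grp[grp.event == "lick"]
            pins = grp[grp.event == "port_in"]
            if len(licks):
                assert len(pins) > 0
                assert licks.time_s.min() >= pins.time_s.min()

    def test_repertoire_refinement_ordering(self, task):
        # peak no-fixation session <= peak catch session; light rate does
        # not degrade after D1 (within binomial noise)
        agent = small_agent(n_trials_mean=150.0)
        for seed in (0, 1):
            rng = np.random.default_rng(seed)
            plan = AgentPlan.sample(agent, rng)
            nofix, catch, light = [], [], []
            for s in range(agent.n_sessions):
                _, truth = simulate_session(task, agent, s, rng, plan=plan)
                n_tr = (truth.kind == "trial").sum()
                nofix.append(truth.label.eq("no_fixation_lick").sum() / n_tr)
                n_catch = truth.trial_type.eq("catch").sum()
                catch.append(truth.label.eq("catch_lick").sum() / max(1, n_catch))
                n_light = truth.trial_type.eq("light").sum()
                light.append(truth.label.eq("light_lick").sum() / max(1, n_light))
            assert int(np.argmax(nofix)) <= int(np.argmax(catch))
            after_d1 = np.asarray(light[plan.d1 + 1:])
            assert np.all(np.diff(after_d1) > -0.1)


class TestSimulateSpikes:
    def _flat_truth(self, t_end=99.0):
        return pd.DataFrame(columns=["trial_type", "t_stim", "t_end"]), \
            pd.DataFrame({"time_s": [t_end], "event": ["lick"],
                          "port": ["right"], "trial_hint": [0]})

    def test_baseline_poisson_count_bounds(self):
        # 5 Hz, no gains, 100 s: count within +-4 sigma of 500
        neurons = NeuronConfig(n_units=1, p_bursting=1.0, baseline_hz=5.0,
                               baseline_jitter_hz=0.0, refractory_s=0.0)
        truth, events = self._flat_truth()
        sp, units = simulate_spikes(events, truth, neurons,
                                    np.random.default_rng(0))
        assert 400 <= len(sp) <= 600
        assert units.is_bursting.all()

    def test_sleft_window_contrast_matches_planted_gain(self, task, agent_small,
                                                        neurons_small):
        rng = np.random.default_rng(7)
        ev, truth = simulate_session(task, agent_small, 1, rng, plan=PLAN,
                                     n_trials=150)
        sp, units = simulate_spikes(ev, truth, neurons_small, rng,
                                    session_index=1, d2=PLAN.d2)
        bursting = units[units.is_bursting].unit_id
        times = np.sort(sp[sp.unit_id.isin(bursting)].time_s.to_numpy())

        def window_rate(stims, w0, w1):
            c = (np.searchsorted(times, stims + w1)
                 - np.searchsorted(times, stims + w0))
            return c.mean() / (w1 - w0) / len(bursting)

        sl = truth[truth.trial_type == "s_left"].t_stim.dropna().to_numpy()
        ca = truth[truth.trial_type == "catch"].t_stim.dropna().to_numpy()
        diff = window_rate(sl, 0.05, 0.2) - window_rate(ca, 0.05, 0.2)
        assert diff == pytest.approx(neurons_small.sleft_gain_hz, abs=2.0)

    def test_outcome_gain_scales_with_rpe(self):
        # expectation 1 (rpe 0) leaves the outcome window at baseline
        neurons = NeuronConfig(n_units=1, p_bursting=1.0, baseline_hz=5.0,
                               baseline_jitter_hz=0.0, eval_gain_hz=0.0)
        rows = []
        for i, rpe in enumerate([0.0, 1.0]):
            for k in range(150):
                t0 = 5000.0 * i + 10.0 * k
                rows.append({
                    "kind": "trial", "trial_type": "catch",
                    "label": "catch_lick", "post_transition": True,
                    "session_frac": 0.5, "t_stim": t0, "t_fix_out": t0 + 0.5,
                    "t_port_in": t0 + 1.0, "t_outcome": t0 + 1.3,
                    "t_end": t0 + 3.0, "expectation": 1.0 - rpe, "rpe": rpe,
                })
        truth = pd.DataFrame(rows)
        events = pd.DataFrame({"time_s": [11000.0], "event": ["lick"],
                               "port": ["right"], "trial_hint": [0]})
        sp, _ = simulate_spikes(events, truth, neurons,
                                np.random.default_rng(1), session_index=0, d2=0)
        times = np.sort(sp.time_s.to_numpy())

        def outcome_rate(sub):
            o = sub.t_outcome.to_numpy()
            c = (np.searchsorted(times, o + 0.35)
                 - np.searchsorted(times, o + 0.05))
            return c.mean() / 0.3

        zero = outcome_rate(truth[truth.rpe == 0.0])
        full = outcome_rate(truth[truth.rpe == 1.0])
        assert zero == pytest.approx(neurons.baseline_hz, abs=1.5)
        assert full - zero == pytest.approx(neurons.outcome_gain_hz, abs=2.5)


class TestSimulateStudy:
    def test_same_seed_reproduces_identical_bundles(self, task):
        agent = small_agent(n_sessions=2, d1_index=1, d2_gap_choices=(0,),
                            n_trials_mean=40.0, n_trials_min=30)
        neurons = NeuronConfig(n_units=3)
        a = simulate_study(task, agent, neurons, n_animals=2, seed=9)
        b = simulate_study(task, agent, neurons, n_animals=2, seed=9)
        for an_a, an_b in zip(a.animals, b.animals):
            for s_a, s_b in zip(an_a.sessions, an_b.sessions):
                pd.testing.assert_frame_equal(s_a.events, s_b.events)
                pd.testing.assert_frame_equal(s_a.spikes, s_b.spikes)

    def test_planted_landmarks_ordered_in_every_animal(self, task):
        agent = AgentConfig()
        rng = np.random.default_rng(10)
        for _ in range(50):
            plan = AgentPlan.sample(agent, rng)
            assert plan.d0 <= plan.d1 <= plan.d2 < agent.n_sessions

    def test_empty_study(self, task, agent_small, neurons_small):
        study = simulate_study(task, agent_small, neurons_small,
                               n_animals=0, seed=1)
        assert study.animals == []
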