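"""Configuration objects for the task, the learning agent and the model neurons.

The defaults encode the study conditions of the behavioral paradigm this
package analyzes: a three-alternative fixation task (S-left sound, S-right
light, catch) with equiprobable trial types, four foreperiods, an unsignaled
4-6 s inter-trial interval, a 3 s response window, and three reward drops
delivered starting at the 3rd lick.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

__all__ = ["TaskConfig", "AgentConfig", "NeuronConfig"]


@dataclass
class TaskConfig:
    """Static task parameters.

    Parameters
    ----------
    trial_type_probs : tuple of float
        Probabilities of (s_left, light, catch) trials. Must sum to 1.
    foreperiods_s : tuple of float
        Allowed fixation foreperiods; drawn iid per trial by default.
    iti_range_s : tuple of float
        (min, max) of the uniform, unsignaled inter-trial interval.
    response_window_s : float
        Post-stimulus window within which the lick response must complete.
    reward_drops : int
        Number of reward drops, delivered starting at the 3rd lick.
    lick_rate_hz : float
        Mean within-bout licking rate of the agent.
    trial_end_after_last_lick_s : float
        A trial with licks ends this long after the last lick.
    foreperiod_counterbalanced : bool
        If True, foreperiods are drawn from shuffled blocks of the four
        values instead of iid (the task description does not state which
        scheme was used; iid is the default).
    """

    trial_type_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    foreperiods_s: tuple[float, ...] = (0.35, 0.5, 0.65, 0.8)
    iti_range_s: tuple[float, float] = (4.0, 6.0)
    response_window_s: float = 3.0
    reward_drops: int = 3
    lick_rate_hz: float = 7.0
    trial_end_after_last_lick_s: float = 1.0
    foreperiod_counterbalanced: bool = False

    def __post_init__(self) -> None:
        if abs(sum(self.trial_type_probs) - 1.0) > 1e-9:
            raise ValueError("trial_type_probs must sum to 1")
        if any(p < 0 for p in self.trial_type_probs):
            raise ValueError("trial_type_probs must be non-negative")
        if any(f <= 0 for f in self.foreperiods_s):
            raise ValueError("foreperiods must be positive")
        if not (0 < self.iti_range_s[0] <= self.iti_range_s[1]):
            raise ValueError("invalid ITI range")
        for name in ("response_window_s", "lick_rate_hz", "trial_end_after_last_lick_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.reward_drops < 1:
            raise ValueError("reward_drops must be >= 1")


@dataclass
class AgentConfig:
    """Stepwise-learning agent: a 3-state predictor set with per-state
    lick-probability tables.

    The agent acquires the reward-predicting sequence backwards in three
    steps.  Step 1 (lick-right) switches on abruptly at ``transition_trial``
    (a combined-trial index within the D1 session); all three rightward
    licking behaviors (light licks, catch licks, no-fixation licks) emerge
    together.  Step 2 (fixation-exit) consolidates ``step2_offset_trials``
    combined trials later, after which no-fixation licks decline.  Step 3
    (the light stimulus) is learned in the D2 session, after which catch
    licks decline.

    Landmark sessions are planted per animal: D0 is the first session with
    the new stimulus, D1 carries the abrupt transition, and D2 is the session
    whose catch-lick probability is the study maximum.  ``d1_jitter`` and the
    D2 gap distribution produce the between-animal variability in learning
    speed; a zero gap reproduces the occasional accelerated learner whose D1
    and D2 coincide.
    """

    n_sessions: int = 9
    d0_index: int = 0
    d1_index: int = 2
    d1_jitter: int = 1
    d2_gap_choices: tuple[int, ...] = (0, 1, 2, 3)
    d2_gap_probs: tuple[float, ...] = (0.14, 0.36, 0.36, 0.14)
    transition_trial: int = 40
    transition_jitter: int = 10
    step2_offset_trials: int = 60

    # lick-probability tables (per learning state x sequence type)
    pre_transition_p_lick: float = 0.0
    p_lick_light_post: float = 0.97
    p_lick_catch_d1: float = 0.75
    p_lick_catch_mid: float = 0.65
    p_lick_catch_d2: float = 0.92
    catch_decay: float = 0.35
    catch_floor: float = 0.05

    # no-fixation lick hazard per inter-trial interval
    nofix_rate_step1: float = 0.5
    nofix_rate_d1_late: float = 0.15
    nofix_rate_post_d1: float = 0.05
    nofix_decay: float = 0.5
    nofix_floor: float = 0.005

    early_exit_hazard: float = 0.05
    left_p_correct: float = 0.94
    laterality: str = "right"

    # latency models (seconds)
    rt_light_mean_s: float = 0.55
    rt_light_sd_s: float = 0.08
    rt_light_d2_slope_s: float = 0.04
    rt_light_min_s: float = 0.30
    rt_left_mean_s: float = 0.40
    rt_left_sd_s: float = 0.08
    catch_exit_mean_s: float = 0.50
    catch_exit_sd_s: float = 0.12

    # session size (total initiated trials)
    n_trials_mean: float = 330.0
    n_trials_sd: float = 35.0
    n_trials_min: int = 150

    # reward expectation carried by right-lick trials (drives the neurons'
    # RPE rule); grows across sessions after D2 as the light is learned
    expect_base_pre_d2: float = 0.10
    expect_sess_step: float = 0.15
    expect_sess_max: float = 0.55
    expect_trial_range: float = 0.50
    expect_left: float = 0.80

    def __post_init__(self) -> None:
        if not (0 <= self.d0_index <= self.d1_index - self.d1_jitter):
            raise ValueError("need d0 <= d1 - jitter")
        max_d2 = self.d1_index + self.d1_jitter + max(self.d2_gap_choices)
        if max_d2 >= self.n_sessions:
            raise ValueError("d2 can exceed n_sessions under the configured jitter")
        if abs(sum(self.d2_gap_probs) - 1.0) > 1e-9:
            raise ValueError("d2_gap_probs must sum to 1")
        if self.step2_offset_trials < 1:
            raise ValueError("step2_offset_trials must be >= 1")
        if self.transition_trial - self.transition_jitter < 0:
            raise ValueError("transition_trial - jitter must be >= 0")
        for name in (
            "pre_transition_p_lick", "p_lick_light_post", "p_lick_catch_d1",
            "p_lick_catch_mid", "p_lick_catch_d2", "left_p_correct",
            "early_exit_hazard",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.laterality not in ("right", "left"):
            raise ValueError("laterality must be 'right' or 'left'")


@dataclass
class NeuronConfig:
    """Rate model for the simulated BF population.

    Each unit is an inhomogeneous Poisson process: a constant baseline plus
    event-locked gain terms. Bursting-class units carry a phasic S-left
    boxcar ([0.05, 0.2] s after sound onset), a light-onset response that is
    zero before the D2 session and grows afterwards, an evaluation-epoch
    ramp on right-lick (and left-lick) trials scaled by the trial's planted
    reward expectation, and an outcome boxcar ([0.05, 0.35] s after the 3rd
    lick) scaled by the RPE rule ``outcome_gain_hz * max(0, 1 - expectation)``
    for every completed lick episode.  Non-bursting units fire at a higher
    flat baseline with no event gains.
    """

    n_units: int = 32   # ~22 bursting units/session at p_bursting = 0.7
    p_bursting: float = 0.7
    baseline_hz: float = 5.0
    baseline_jitter_hz: float = 1.0
    nonbursting_baseline_hz: float = 8.0
    sleft_gain_hz: float = 8.0
    eval_gain_hz: float = 10.0
    light_gain_d2_start_hz: float = 2.0
    light_gain_d2_end_hz: float = 6.0
    light_gain_slope_hz: float = 1.5
    light_gain_max_hz: float = 9.0
    outcome_gain_hz: float = 12.0
    refractory_s: float = 0.002

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_bursting <= 1.0:
            raise ValueError("p_bursting must be a probability")
        for name in (
            "baseline_hz", "nonbursting_baseline_hz", "sleft_gain_hz",
            "eval_gain_hz", "outcome_gain_hz",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_units < 0:
            raise ValueError("n_units must be >= 0")
        if self.sleft_gain_hz <= 2.0 and self.n_units:
            # the bursting-class definition uses a > 2 spikes/s contrast;
            # a planted gain at or below threshold makes classes unrecoverable
            raise ValueError("sleft_gain_hz must exceed the 2 spikes/s criterion")
        if self.baseline_hz >= 10.0:
            raise ValueError("bursting-class baseline must stay below 10 spikes/s")

    def light_gain(self, session: int, d2: int, frac: float) -> float:
        """Light-onset added rate for a trial at fractional position ``frac``
        of session ``session``, given the animal's D2 session."""
        if session < d2:
            return 0.0
        if session == d2:
            lo, hi = self.light_gain_d2_start_hz, self.light_gain_d2_end_hz
            return lo + (hi - lo) * float(frac)
        g = self.light_gain_d2_end_hz + self.light_gain_slope_hz * (session - d2)
        return min(g, self.light_gain_max_hz)


def config_dict(*cfgs) -> dict:
    """Serialize a set of config dataclasses to one plain dict."""
    out = {}
    for c in cfgs:
        out[type(c).__name__] = asdict(c)
    return out
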