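"""Stepwise-learning agent and per-session behavioral event generator.

The agent formalizes backward-chaining sequence learning as three predictor
states with per-state lick-probability tables.  Before the planted
transition trial the rightward-lick repertoire is absent; at the transition
it switches on as a step (no sigmoid ramp, which keeps change-point recovery
well-posed); no-fixation licks decline a fixed number of combined trials
later; catch licks peak in the planted D2 session and decline afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..config import AgentConfig, TaskConfig
from ..vocab import EVENT_COLUMNS

__all__ = ["AgentPlan", "AgentState", "simulate_trial", "simulate_session"]

_TRUTH_COLUMNS = [
    "record", "kind", "trial_type", "label", "combined_index", "post_transition",
    "t_start", "t_fix_in", "t_stim", "t_fix_out", "t_port_in", "t_first_lick",
    "t_outcome", "t_last_lick", "t_end", "n_licks", "rewarded",
    "expectation", "rpe", "session_frac",
]


@dataclass(frozen=True)
class AgentPlan:
    """Per-animal resolved learning schedule (the planted ground truth)."""

    d0: int
    d1: int
    d2: int
    transition_trial: int
    step2_offset: int

    @classmethod
    def sample(cls, cfg: AgentConfig, rng: np.random.Generator) -> "AgentPlan":
        d1 = cfg.d1_index + int(rng.integers(-cfg.d1_jitter, cfg.d1_jitter + 1))
        d1 = max(cfg.d0_index, d1)
        gap = int(rng.choice(cfg.d2_gap_choices, p=cfg.d2_gap_probs))
        d2 = min(d1 + gap, cfg.n_sessions - 1)
        tt = cfg.transition_trial + int(
            rng.integers(-cfg.transition_jitter, cfg.transition_jitter + 1)
        )
        return cls(
            d0=cfg.d0_index,
            d1=d1,
            d2=d2,
            transition_trial=max(0, tt),
            step2_offset=cfg.step2_offset_trials,
        )


@dataclass
class AgentState:
    """Mutable per-session agent state fed to :func:`simulate_trial`."""

    task: TaskConfig
    cfg: AgentConfig
    plan: AgentPlan
    session: int
    combined: int = 0          # combined-trial counter within this session
    session_frac: float = 0.0  # fractional position of the current trial
    _fp_block: list = field(default_factory=list)

    @property
    def post_transition(self) -> bool:
        s, plan = self.session, self.plan
        if s < plan.d1:
            return False
        if s > plan.d1:
            return True
        return self.combined >= plan.transition_trial

    def next_foreperiod(self, rng: np.random.Generator) -> float:
        fps = self.task.foreperiods_s
        if not self.task.foreperiod_counterbalanced:
            return float(fps[rng.integers(len(fps))])
        if not self._fp_block:
            block = list(fps)
            rng.shuffle(block)
            self._fp_block = block
        return float(self._fp_block.pop())


def _p_lick(state: AgentState, trial_type: str) -> float:
    cfg, plan, s = state.cfg, state.plan, state.session
    if trial_type == "s_left":
        return cfg.left_p_correct
    if not state.post_transition:
        return cfg.pre_transition_p_lick
    if trial_type == "light":
        return cfg.p_lick_light_post
    # catch-lick probability profile across sessions; peaks at D2
    if s == plan.d2:
        return cfg.p_lick_catch_d2
    if s == plan.d1:
        return cfg.p_lick_catch_d1
    if s < plan.d2:
        return cfg.p_lick_catch_mid
    return max(cfg.p_lick_catch_d2 * cfg.catch_decay ** (s - plan.d2), cfg.catch_floor)


def _nofix_hazard(state: AgentState) -> float:
    cfg, plan, s = state.cfg, state.plan, state.session
    if s < plan.d1 or not state.post_transition:
        return 0.0
    if s == plan.d1:
        since = state.combined - plan.transition_trial
        if since < plan.step2_offset:
            return cfg.nofix_rate_step1
        return cfg.nofix_rate_d1_late
    return max(cfg.nofix_rate_post_d1 * cfg.nofix_decay ** (s - plan.d1 - 1), cfg.nofix_floor)


def _light_rt(state: AgentState, rng: np.random.Generator) -> float:
    cfg, plan, s = state.cfg, state.plan, state.session
    mean = cfg.rt_light_mean_s
    if s >= plan.d2:
        mean = max(cfg.rt_light_min_s, mean - cfg.rt_light_d2_slope_s * (s - plan.d2 + 1))
    return max(0.12, rng.normal(mean, cfg.rt_light_sd_s))


def _expectation(state: AgentState, rng: np.random.Generator, side: str) -> float:
    cfg, plan, s = state.cfg, state.plan, state.session
    if side == "left":
        return cfg.expect_left
    if s < plan.d2:
        base = cfg.expect_base_pre_d2
    else:
        base = min(
            cfg.expect_base_pre_d2 + cfg.expect_sess_step * (s - plan.d2 + 1),
            cfg.expect_sess_max,
        )
    return float(np.clip(base + cfg.expect_trial_range * rng.random(), 0.0, 0.95))


def _lick_train(
    task: TaskConfig, rng: np.random.Generator, t_first: float, n_licks: int
) -> np.ndarray:
    ili = np.maximum(0.06, rng.normal(1.0 / task.lick_rate_hz, 0.015, size=n_licks - 1))
    return t_first + np.concatenate([[0.0], np.cumsum(ili)])


def simulate_trial(
    task: TaskConfig,
    agent_state: AgentState,
    trial_type: str,
    rng: np.random.Generator,
):
    """Simulate one initiated trial.

    Returns ``(events, info)`` where ``events`` is a chronologically ordered
    list of ``(time_s, event, port)`` tuples with time 0 at fixation-light
    onset, and ``info`` records the latent trial facts (label, epoch times,
    reward expectation).

    Raises ``ValueError`` for an unknown ``trial_type``.
    """
    if trial_type not in ("s_left", "light", "catch"):
        raise ValueError(f"unknown trial_type {trial_type!r}")
    cfg = agent_state.cfg
    side = cfg.laterality
    ev: list[tuple[float, str, str]] = [(0.0, "fixlight_on", "center")]
    t_fix_in = float(rng.uniform(0.3, 1.2))
    ev.append((t_fix_in, "fix_in", "center"))
    fp = agent_state.next_foreperiod(rng)

    info = dict.fromkeys(_TRUTH_COLUMNS)
    info.update(
        kind="trial", trial_type=trial_type, t_fix_in=t_fix_in, rewarded=False,
        n_licks=0, post_transition=agent_state.post_transition,
        session_frac=agent_state.session_frac,
    )

    if rng.random() < cfg.early_exit_hazard:
        t_exit = t_fix_in + float(rng.uniform(0.05, 0.92)) * fp
        ev.append((t_exit, "fix_out", "center"))
        info.update(label="early_exit", t_fix_out=t_exit, t_end=t_exit)
        return ev, info

    t_stim = t_fix_in + fp
    stim_event = {"s_left": "stim_on_left", "light": "stim_on_light", "catch": "catch_mark"}
    ev.append((t_stim, stim_event[trial_type], "none"))
    info["t_stim"] = t_stim

    licks = rng.random() < _p_lick(agent_state, trial_type)
    port = "left" if trial_type == "s_left" else side

    if trial_type == "light":
        rt = _light_rt(agent_state, rng)
    elif trial_type == "s_left":
        rt = max(0.12, rng.normal(cfg.rt_left_mean_s, cfg.rt_left_sd_s))
    else:
        rt = max(0.10, rng.normal(cfg.catch_exit_mean_s, cfg.catch_exit_sd_s))
    t_fix_out = t_stim + rt
    ev.append((t_fix_out, "fix_out", "center"))
    info["t_fix_out"] = t_fix_out

    if not licks:
        info.update(
            label=f"{'left' if trial_type == 's_left' else trial_type}_no_lick",
            t_end=t_stim + task.response_window_s,
        )
        return ev, info

    t_port_in = t_fix_out + max(0.2, rng.normal(0.5, 0.1))
    ev.append((t_port_in, "port_in", port))
    t_first = t_port_in + max(0.03, rng.normal(0.1, 0.03))
    n_licks = 3 + int(rng.poisson(9.0 if trial_type != "catch" else 2.0))
    lick_times = _lick_train(task, rng, t_first, n_licks)
    ev.extend((float(t), "lick", port) for t in lick_times)
    t_outcome = float(lick_times[2])

    correct = (trial_type == "s_left" and port == "left") or (
        trial_type == "light" and port == side
    )
    rewarded = correct and (t_outcome <= t_stim + task.response_window_s)
    if rewarded:
        for k in range(task.reward_drops):
            ev.append((t_outcome + 0.01 + 0.15 * k, "reward_drop", port))

    t_last = float(lick_times[-1])
    ev.append((t_last + max(0.1, rng.normal(0.4, 0.1)), "port_out", port))
    ev.sort(key=lambda r: r[0])

    label = {"s_left": "left_lick", "light": "light_lick", "catch": "catch_lick"}[trial_type]
    expectation = _expectation(agent_state, rng, "left" if port == "left" else "new")
    info.update(
        label=label, t_port_in=t_port_in, t_first_lick=t_first, t_outcome=t_outcome,
        t_last_lick=t_last, n_licks=n_licks, rewarded=rewarded,
        t_end=t_last + task.trial_end_after_last_lick_s,
        expectation=expectation, rpe=max(0.0, 1.0 - expectation),
    )
    return ev, info


def _simulate_nofix_bout(
    task: TaskConfig,
    agent_state: AgentState,
    rng: np.random.Generator,
):
    """A self-initiated lick bout at the new-learning reward port during the
    inter-trial interval (no preceding fixation)."""
    cfg = agent_state.cfg
    port = cfg.laterality
    ev: list[tuple[float, str, str]] = []
    t_port_in = 0.0
    ev.append((t_port_in, "port_in", port))
    t_first = t_port_in + max(0.03, rng.normal(0.1, 0.03))
    n_licks = 3 + int(rng.poisson(2.0))
    lick_times = _lick_train(task, rng, t_first, n_licks)
    ev.extend((float(t), "lick", port) for t in lick_times)
    t_last = float(lick_times[-1])
    t_port_out = t_last + max(0.1, rng.normal(0.4, 0.1))
    ev.append((t_port_out, "port_out", port))

    expectation = _expectation(agent_state, rng, "new")
    info = dict.fromkeys(_TRUTH_COLUMNS)
    info.update(
        kind="bout", label="no_fixation_lick", t_port_in=t_port_in,
        t_first_lick=t_first, t_outcome=float(lick_times[2]), t_last_lick=t_last,
        t_end=t_port_out, n_licks=n_licks, rewarded=False,
        post_transition=agent_state.post_transition,
        session_frac=agent_state.session_frac,
        expectation=expectation, rpe=max(0.0, 1.0 - expectation),
    )
    return ev, info


def simulate_session(
    task: TaskConfig,
    agent: AgentConfig,
    session_index: int,
    rng: np.random.Generator,
    plan: AgentPlan | None = None,
    n_trials: int | None = None,
):
    """Simulate one full session of the task.

    Trials are concatenated with uniform unsignaled ITIs.  A no-fixation
    lick bout during the ITI resets the ITI timer (a fresh full ITI is drawn
    after the bout, so no trial-initiating fixation occurs within the reset
    window).  Returns ``(events_df, truth_df)`` where ``events_df`` has the
    session event-stream columns and ``truth_df`` one row per trial/bout with
    all latent quantities, both with absolute session times.
    """
    if plan is None:
        plan = AgentPlan.sample(agent, rng)
    if not 0 <= session_index < agent.n_sessions:
        raise ValueError("session_index out of range")
    if n_trials is None:
        n_trials = max(agent.n_trials_min, int(round(rng.normal(agent.n_trials_mean, agent.n_trials_sd))))

    state = AgentState(task=task, cfg=agent, plan=plan, session=session_index)
    has_light = session_index >= plan.d0
    probs = np.asarray(task.trial_type_probs, dtype=float)
    if not has_light:
        # before the new stimulus is introduced there are no light trials
        probs = np.array([probs[0] + probs[1], 0.0, probs[2]])
    types = np.asarray(TRIAL_TYPE_ORDER)

    rows: list[list] = []
    all_events: list[tuple[float, str, str, int]] = []
    t = 0.0
    last_fix_out = -np.inf
    record = 0
    for i in range(n_trials):
        state.session_frac = i / max(1, n_trials - 1)
        # --- inter-trial interval, possibly interrupted by no-fixation bouts
        iti = float(rng.uniform(*task.iti_range_s))
        for _ in range(3):  # at most a few bouts per ITI
            if rng.random() >= _nofix_hazard(state):
                break
            # a planted bout satisfies the detection criteria by construction:
            # its first lick falls > 2 s after the last fixation exit and
            # > 1 s after the last reward-port exit
            bout_start = max(t + float(rng.uniform(1.0, 2.5)), last_fix_out + 2.05)
            ev, info = _simulate_nofix_bout(task, state, rng)
            all_events.extend((bt + bout_start, e, p, record) for bt, e, p in ev)
            info["record"] = record
            info["combined_index"] = state.combined
            _shift_times(info, bout_start)
            rows.append([info[c] for c in _TRUTH_COLUMNS])
            record += 1
            state.combined += 1
            t = info["t_end"]
            iti = float(rng.uniform(*task.iti_range_s))  # ITI timer reset
        t_trial = t + iti

        trial_type = str(rng.choice(types, p=probs))
        ev, info = simulate_trial(task, state, trial_type, rng)
        all_events.extend((et + t_trial, e, p, record) for et, e, p in ev)
        info["record"] = record
        if info["label"] != "early_exit" and trial_type in ("light", "catch"):
            info["combined_index"] = state.combined
            state.combined += 1
        else:
            info["combined_index"] = -1
        _shift_times(info, t_trial)
        rows.append([info[c] for c in _TRUTH_COLUMNS])
        record += 1
        t = info["t_end"]
        if info["t_fix_out"] is not None:
            last_fix_out = info["t_fix_out"]

    events_df = pd.DataFrame(all_events, columns=list(EVENT_COLUMNS))
    events_df["time_s"] = events_df["time_s"].round(3)
    events_df = events_df.sort_values("time_s", kind="stable").reset_index(drop=True)
    truth_df = pd.DataFrame(rows, columns=_TRUTH_COLUMNS)
    return events_df, truth_df


TRIAL_TYPE_ORDER = ("s_left", "light", "catch")

_TIME_KEYS = (
    "t_start", "t_fix_in", "t_stim", "t_fix_out", "t_port_in", "t_first_lick",
    "t_outcome", "t_last_lick", "t_end",
)


def _shift_times(info: dict, offset: float) -> None:
    info["t_start"] = offset
    for k in _TIME_KEYS[1:]:
        if info.get(k) is not None:
            info[k] = info[k] + offset
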