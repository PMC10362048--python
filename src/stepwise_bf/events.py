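"""Parsing raw event streams into trials, lick bouts and sequence labels.

A trial is delimited by a fixation-light / fixation-entry pair and ends
either one second after its last lick or at the end of the response window.
Licks that belong to no trial are grouped into bouts using a 1 s inter-lick
gap, the same threshold the no-fixation-lick criteria use for reward-port
re-entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vocab import EVENT_TYPES, STIM_EVENTS

__all__ = [
    "Trial", "LickBout", "parse_events", "classify_response",
    "detect_no_fixation_licks", "session_summary", "trials_to_frame",
]

REWARD_PORTS = ("left", "right")


@dataclass
class Trial:
    """One parsed trial (an initiated fixation attempt)."""

    index: int
    t_light_on: float
    t_fix_in: float
    t_fix_out: float = np.nan
    t_stim: float = np.nan
    type: str | None = None
    foreperiod_s: float = np.nan
    early: bool = False
    t_end: float = np.nan
    licks: dict = field(default_factory=dict)   # port -> ndarray of times
    t_port_in: float = np.nan
    rewarded: bool = False
    label: str | None = None
    responded_port: str | None = None
    t_outcome: float = np.nan

    def n_licks(self, port: str) -> int:
        return len(self.licks.get(port, ()))


@dataclass
class LickBout:
    """An out-of-trial lick episode at one reward port."""

    port: str
    lick_times: np.ndarray
    t_port_in: float = np.nan
    status: str = "candidate"   # candidate | no_fixation_lick | merged | rejected
    reason: str | None = None

    @property
    def t_first(self) -> float:
        return float(self.lick_times[0])

    @property
    def t_last(self) -> float:
        return float(self.lick_times[-1])

    @property
    def n_licks(self) -> int:
        return len(self.lick_times)


def parse_events(
    events: pd.DataFrame,
    response_window_s: float = 3.0,
    trial_end_after_last_lick_s: float = 1.0,
    bout_gap_s: float = 1.0,
) -> tuple[list[Trial], list[LickBout]]:
    """Parse a session event stream into trials and out-of-trial lick bouts.

    Every lick event is assigned to exactly one trial or one bout.  Raises
    ``ValueError`` on unordered timestamps, unknown event names, or a
    fixation exit without a preceding fixation entry.
    """
    if len(events) == 0:
        return [], []
    t = events["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("event timestamps are not sorted")
    ev = events["event"].to_numpy()
    port = events["port"].to_numpy()
    unknown = set(ev) - set(EVENT_TYPES)
    if unknown:
        raise ValueError(f"unknown event names: {sorted(unknown)}")

    # ---- structural pass: delimit trials
    trials: list[Trial] = []
    cur: Trial | None = None
    pending_light = np.nan
    for i in range(len(t)):
        e = ev[i]
        if e == "fixlight_on":
            pending_light = t[i]
        elif e == "fix_in" and port[i] == "center":
            if cur is not None and np.isnan(cur.t_fix_out):
                # repeated fixation entry within one attempt; keep the first
                continue
            cur = Trial(index=len(trials), t_light_on=pending_light, t_fix_in=t[i])
            pending_light = np.nan
        elif e in STIM_EVENTS:
            if cur is None or not np.isnan(cur.t_fix_out):
                raise ValueError(f"stimulus at t={t[i]:.3f} outside a fixation epoch")
            cur.t_stim = t[i]
            cur.type = STIM_EVENTS[e]
            cur.foreperiod_s = t[i] - cur.t_fix_in
        elif e == "fix_out" and port[i] == "center":
            if cur is None:
                raise ValueError(f"fix_out at t={t[i]:.3f} without fix_in")
            cur.t_fix_out = t[i]
            cur.early = np.isnan(cur.t_stim)
            if cur.early:
                cur.t_end = cur.t_fix_out
            trials.append(cur)
            cur = None
    if cur is not None:  # session truncated mid-fixation
        cur.early = np.isnan(cur.t_stim)
        cur.t_end = cur.t_fix_out if not np.isnan(cur.t_fix_out) else t[-1]
        trials.append(cur)

    # ---- lick assignment: chain rule within each trial's response period
    lick_idx = np.flatnonzero((ev == "lick") & np.isin(port, REWARD_PORTS))
    lick_t = t[lick_idx]
    lick_p = port[lick_idx]
    used = np.zeros(len(lick_idx), dtype=bool)

    light_on_times = t[ev == "fixlight_on"]
    for k, tr in enumerate(trials):
        if tr.early or np.isnan(tr.t_stim):
            continue
        hard_stop = np.inf
        nxt = np.searchsorted(light_on_times, tr.t_stim, side="right")
        if nxt < len(light_on_times):
            hard_stop = light_on_times[nxt]
        sel = []
        last = None
        j0 = np.searchsorted(lick_t, tr.t_stim, side="left")
        for j in range(j0, len(lick_t)):
            if used[j] or lick_t[j] >= hard_stop:
                if lick_t[j] >= hard_stop:
                    break
                continue
            in_window = lick_t[j] <= tr.t_stim + response_window_s
            chained = last is not None and lick_t[j] - last <= trial_end_after_last_lick_s
            if in_window or chained:
                sel.append(j)
                last = lick_t[j]
            elif last is not None or not in_window:
                break
        if sel:
            sel = np.asarray(sel)
            used[sel] = True
            for p in REWARD_PORTS:
                times = lick_t[sel][lick_p[sel] == p]
                if times.size:
                    tr.licks[p] = times
            tr.t_end = last + trial_end_after_last_lick_s
        else:
            tr.t_end = tr.t_stim + response_window_s

    # reward drops and reward-port entries within the trial span
    drop_t = t[ev == "reward_drop"]
    pin_idx = np.flatnonzero((ev == "port_in") & np.isin(port, REWARD_PORTS))
    for tr in trials:
        if tr.early or np.isnan(tr.t_stim):
            continue
        tr.rewarded = bool(
            np.any((drop_t >= tr.t_stim) & (drop_t <= tr.t_end))
        )
        m = (t[pin_idx] >= tr.t_stim) & (t[pin_idx] <= tr.t_end)
        if m.any():
            tr.t_port_in = float(t[pin_idx][m][0])

    # ---- remaining licks: per-port bouts split at the 1 s gap
    bouts: list[LickBout] = []
    for p in REWARD_PORTS:
        m = ~used & (lick_p == p)
        times = lick_t[m]
        if times.size == 0:
            continue
        splits = np.flatnonzero(np.diff(times) > bout_gap_s) + 1
        pin_p = t[pin_idx][port[pin_idx] == p]
        for grp in np.split(times, splits):
            b = LickBout(port=p, lick_times=grp)
            before = pin_p[pin_p <= grp[0]]
            if before.size:
                b.t_port_in = float(before[-1])
            bouts.append(b)
    bouts.sort(key=lambda b: b.t_first)
    return trials, bouts


def classify_response(
    trial: Trial,
    response_window_s: float = 3.0,
    min_licks: int = 3,
    rule: str = "third_lick_in_window",
    new_side: str = "right",
) -> str:
    """Assign the sequence label of one trial.

    A lick response requires at least ``min_licks`` licks in one reward
    port; under the default rule the ``min_licks``-th lick (the trial
    outcome event, at which reward delivery starts) must fall within the
    response window after stimulus onset.  Under ``all_three_in_window``
    the count is restricted to licks inside the window.
    """
    if trial.early or trial.type is None:
        trial.label = "early_exit"
        return trial.label
    responded = None
    for p in REWARD_PORTS:
        lt = np.asarray(trial.licks.get(p, ()))
        if rule == "all_three_in_window":
            lt = lt[(lt >= trial.t_stim) & (lt <= trial.t_stim + response_window_s)]
        if len(lt) >= min_licks and lt[min_licks - 1] <= trial.t_stim + response_window_s:
            if responded is None or trial.n_licks(p) > trial.n_licks(responded):
                responded = p
    trial.responded_port = responded
    if responded is not None:
        trial.t_outcome = float(np.asarray(trial.licks[responded])[min_licks - 1])

    ttype = trial.type
    if responded is None:
        trial.label = {"s_left": "left_no_lick", "light": "light_no_lick",
                       "catch": "catch_no_lick"}[ttype]
    elif ttype == "s_left":
        trial.label = "left_lick" if responded == "left" else "wrong_port"
    elif ttype == "light":
        trial.label = "light_lick" if responded == new_side else "wrong_port"
    else:  # catch: rightward licks define the catch-lick sequence
        trial.label = "catch_lick" if responded == new_side else "wrong_port"
    return trial.label


def detect_no_fixation_licks(
    bouts: list[LickBout],
    trials: list[Trial],
    events: pd.DataFrame,
    new_side: str = "right",
    min_licks: int = 3,
    fixout_gap_s: float = 2.0,
    port_reentry_gap_s: float = 1.0,
) -> list[LickBout]:
    """Label out-of-trial bouts at the new-learning reward port.

    A bout is a no-fixation lick when (1) it has at least three licks,
    (2) its first lick comes more than ``fixout_gap_s`` after the last
    fixation-port exit, and (3) more than ``port_reentry_gap_s`` after the
    last exit from the same reward port — otherwise it is merged into the
    preceding same-port episode.  Returns the same-side bouts with their
    status set.
    """
    t = events["time_s"].to_numpy(dtype=float)
    ev = events["event"].to_numpy()
    port = events["port"].to_numpy()
    fixout_t = t[(ev == "fix_out") & (port == "center")]
    portout_t = t[(ev == "port_out") & (port == new_side)]

    out = []
    for b in bouts:
        if b.port != new_side:
            continue
        if b.n_licks < min_licks:
            b.status, b.reason = "rejected", "fewer than 3 licks"
            out.append(b)
            continue
        i = np.searchsorted(fixout_t, b.t_first)
        if i > 0 and b.t_first - fixout_t[i - 1] <= fixout_gap_s:
            b.status, b.reason = "rejected", "within 2 s of fixation exit"
            out.append(b)
            continue
        j = np.searchsorted(portout_t, b.t_first)
        if j > 0 and b.t_first - portout_t[j - 1] <= port_reentry_gap_s:
            b.status, b.reason = "merged", "within 1 s of reward-port exit"
            out.append(b)
            continue
        b.status = "no_fixation_lick"
        out.append(b)
    return out


def trials_to_frame(trials: list[Trial]) -> pd.DataFrame:
    """Flatten parsed trials to a DataFrame (one row per trial)."""
    rows = []
    for tr in trials:
        rows.append({
            "index": tr.index,
            "type": tr.type,
            "label": tr.label,
            "early": tr.early,
            "t_light_on": tr.t_light_on,
            "t_fix_in": tr.t_fix_in,
            "t_stim": tr.t_stim,
            "t_fix_out": tr.t_fix_out,
            "foreperiod_s": tr.foreperiod_s,
            "t_port_in": tr.t_port_in,
            "t_outcome": tr.t_outcome,
            "t_end": tr.t_end,
            "n_licks_left": tr.n_licks("left"),
            "n_licks_right": tr.n_licks("right"),
            "rewarded": tr.rewarded,
            "responded_port": tr.responded_port,
        })
    return pd.DataFrame(rows)


def session_summary(
    trials: list[Trial],
    nofix_bouts: list[LickBout] | None = None,
    new_side: str = "right",
) -> dict:
    """Per-session behavioral summary.

    Hit rates are per trial type; the no-fixation-lick frequency is reported
    per 100 initiated trials (the source analysis does not state this
    normalization; see the methods note).  Reaction time is the median
    stimulus-onset-to-fixation-exit latency in light lick trials, and catch
    lick duration the median first-to-last lick interval in catch lick
    trials; both are missing (NaN) when the defining trials are absent.
    """
    labels = [tr.label for tr in trials]
    counts = {lab: labels.count(lab) for lab in set(labels) if lab}
    n_initiated = len(trials)
    n_light = counts.get("light_lick", 0) + counts.get("light_no_lick", 0)
    n_catch = counts.get("catch_lick", 0) + counts.get("catch_no_lick", 0)
    n_left = counts.get("left_lick", 0) + counts.get("left_no_lick", 0)
    nofix = [b for b in (nofix_bouts or []) if b.status == "no_fixation_lick"]

    def rate(num, den):
        return num / den if den else np.nan

    rt_vals = [
        tr.t_fix_out - tr.t_stim
        for tr in trials
        if tr.label == "light_lick" and not np.isnan(tr.t_fix_out)
    ]
    dur_vals = []
    for tr in trials:
        if tr.label == "catch_lick" and tr.responded_port:
            lt = tr.licks[tr.responded_port]
            dur_vals.append(float(lt[-1] - lt[0]))

    n_rewarded_light = sum(
        1 for tr in trials if tr.type == "light" and tr.rewarded
    )
    return {
        "n_initiated": n_initiated,
        "n_light": n_light,
        "n_catch": n_catch,
        "n_left": n_left,
        "n_early": counts.get("early_exit", 0),
        "n_nofix": len(nofix),
        "n_rewarded_light": n_rewarded_light,
        "light_lick_rate": rate(counts.get("light_lick", 0), n_light),
        "catch_lick_rate": rate(counts.get("catch_lick", 0), n_catch),
        "left_lick_rate": rate(counts.get("left_lick", 0), n_left),
        "nofix_per_100": rate(100.0 * len(nofix), n_initiated),
        "rt_light_s": float(np.median(rt_vals)) if rt_vals else np.nan,
        "catch_lick_duration_s": float(np.median(dur_vals)) if dur_vals else np.nan,
        "has_light_trials": n_light > 0,
        **{f"n_{lab}": counts.get(lab, 0) for lab in (
            "light_lick", "catch_lick", "left_lick", "light_no_lick",
            "catch_no_lick", "left_no_lick", "wrong_port")},
    }
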