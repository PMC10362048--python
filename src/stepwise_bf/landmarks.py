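"""Learning landmarks (D0/D1/D2) and the within-session behavioral
transition point.

The transition statistic is the difference in rightward-lick probability
between the 20 trials after and the 20 trials before each candidate point
of the combined series (light trials, catch trials and no-fixation licks in
chronological order, coded 1 when the animal licked the new-side reward
port).  The detected maximizer is adjusted to the closest light-lick trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import LickBout, Trial

__all__ = [
    "LearningLandmarks", "TransitionResult", "build_combined_series",
    "find_transition", "identify_landmarks", "light_learning_index",
]


@dataclass
class LearningLandmarks:
    """Per-animal landmark session ordinals.

    d0: first session with the new stimulus; d1: first session with at
    least three rewarded new-stimulus trials; d2: session of peak catch-lick
    frequency.  Animals whose d1 and d2 coincide (accelerated learners) are
    flagged and excluded from D1-dynamics analyses downstream.
    """

    d0: int | None
    d1: int | None
    d2: int | None
    merged_flag: bool = False

    @property
    def complete(self) -> bool:
        return None not in (self.d0, self.d1, self.d2)


@dataclass
class TransitionResult:
    raw_index: int | None
    adjusted_index: int | None
    statistic: float
    profile: np.ndarray            # D(t) at each candidate t
    candidates: np.ndarray         # the candidate indices
    found: bool = True
    low_confidence: bool = False
    shift: int = 0
    shift_exceeded: bool = False


def build_combined_series(
    trials: list[Trial],
    nofix_bouts: list[LickBout],
    new_side: str = "right",
) -> pd.DataFrame:
    """Chronological combined series of light trials, catch trials and
    accepted no-fixation bouts, coded 1 for a new-side lick."""
    rows = []
    for tr in trials:
        if tr.type not in ("light", "catch") or tr.early:
            continue
        code = int(tr.label in ("light_lick", "catch_lick"))
        rows.append((tr.t_stim, tr.label or "", code, tr.label == "light_lick"))
    for b in nofix_bouts:
        if b.status == "no_fixation_lick":
            rows.append((b.t_first, "no_fixation_lick", 1, False))
    rows.sort(key=lambda r: r[0])
    return pd.DataFrame(rows, columns=["time_s", "label", "code", "is_light_lick"])


def find_transition(
    series: np.ndarray,
    w: int = 20,
    light_lick_mask: np.ndarray | None = None,
    max_shift: int = 5,
    low_confidence_height: float = 0.3,
) -> TransitionResult:
    """Locate the abrupt onset of rightward licking in a binary series.

    For every candidate ``t`` in ``[w, n - w]`` the statistic is
    ``D(t) = mean(series[t:t+w]) - mean(series[t-w:t])``; the raw index is
    the earliest maximizer.  When a light-lick mask is supplied the index is
    adjusted to the closest light-lick trial (ties toward earlier); a shift
    beyond ``max_shift`` trials raises a warning and is flagged.

    Raises ``ValueError`` when the series is shorter than ``2 * w``.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2 * w:
        raise ValueError(f"series length {n} < 2*w = {2 * w}")
    t = np.arange(w, n - w + 1)
    if np.all(x == np.round(x)):
        # binary/integer codes: exact integer arithmetic keeps ties exact,
        # so the earliest-maximizer tie-break is deterministic
        c = np.concatenate([[0], np.cumsum(x.astype(np.int64))])
        d = ((c[t + w] - c[t]) - (c[t] - c[t - w])) / w
    else:
        c = np.concatenate([[0.0], np.cumsum(x)])
        d = ((c[t + w] - c[t]) - (c[t] - c[t - w])) / w
    k = int(np.argmax(d))  # argmax returns the earliest maximizer
    raw = int(t[k])
    stat = float(d[k])
    res = TransitionResult(
        raw_index=raw, adjusted_index=raw, statistic=stat,
        profile=d, candidates=t,
        found=stat > 0.0, low_confidence=stat < low_confidence_height,
    )
    if not res.found:
        res.raw_index = None
        res.adjusted_index = None
        return res
    if light_lick_mask is not None:
        ll = np.flatnonzero(np.asarray(light_lick_mask, dtype=bool))
        if ll.size:
            dist = np.abs(ll - raw)
            j = int(np.argmin(dist))  # ties resolve to the earlier trial
            res.adjusted_index = int(ll[j])
            res.shift = int(res.adjusted_index - raw)
            if dist[j] > max_shift:
                res.shift_exceeded = True
                warnings.warn(
                    f"transition adjusted by {dist[j]} trials "
                    f"(> max_shift={max_shift})", stacklevel=2,
                )
        else:
            res.shift_exceeded = True
    return res


def identify_landmarks(
    session_summaries: pd.DataFrame,
    min_rewarded: int = 3,
) -> LearningLandmarks:
    """Locate D0/D1/D2 from ordered per-session summaries.

    Expects the columns ``has_light_trials``, ``n_rewarded_light`` and
    ``catch_lick_rate`` (one row per session in chronological order).  Ties
    in peak catch-lick frequency resolve to the earliest session.  An animal
    with no session reaching ``min_rewarded`` rewarded new-stimulus trials
    has an undefined d1.
    """
    df = session_summaries.reset_index(drop=True)
    light = np.flatnonzero(df["has_light_trials"].to_numpy(dtype=bool))
    d0 = int(light[0]) if light.size else None
    ok = np.flatnonzero(df["n_rewarded_light"].to_numpy() >= min_rewarded)
    d1 = int(ok[0]) if ok.size else None
    rates = df["catch_lick_rate"].to_numpy(dtype=float)
    d2 = None
    if np.any(~np.isnan(rates)):
        d2 = int(np.nanargmax(rates))
    return LearningLandmarks(
        d0=d0, d1=d1, d2=d2,
        merged_flag=(d1 is not None and d1 == d2),
    )


def light_learning_index(summary: dict | pd.Series) -> float:
    """Behavioral index of light learning for one session:
    P(new-side lick | light trial) - P(new-side lick | catch trial)."""
    p_light = summary["light_lick_rate"]
    p_catch = summary["catch_lick_rate"]
    if p_light is None or p_catch is None or np.isnan(p_light) or np.isnan(p_catch):
        return np.nan
    return float(p_light - p_catch)
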