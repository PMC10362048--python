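"""BF bursting-neuron classification and population activity measures.

The analysis unit is the pooled spike train of all bursting neurons in a
session, normalized per neuron.  PSTHs use 10 ms bins and support per-trial
censoring (e.g. stimulus-aligned histograms built only from spikes before
fixation-port exit) with per-bin effective-trial normalization, truncated at
the session's median censoring interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExclusionError", "PopulationActivity", "PSTH", "EvalResponse",
    "classify_bursting", "pool_population", "compute_psth", "average_psths",
    "evaluation_response", "resolve_evaluation_epoch", "outcome_response",
    "epoch_responses", "trial_window_rates", "trial_trend",
    "aligned_trend_mean", "stimulus_response_difference",
]

BIN_S = 0.01

SLEFT_WINDOW = (0.05, 0.2)
LIGHT_WINDOW = (0.1, 0.3)
OUTCOME_WINDOW = (0.05, 0.35)
BASELINE_WINDOW = (-1.0, 0.0)
PRE_FIXOUT_WINDOW = (-0.3, 0.0)
POST_FIXOUT_WINDOW = (0.0, 0.3)
EVAL_WINDOW_S = 0.5


class ExclusionError(RuntimeError):
    """A session (or analysis cell) fails an inclusion rule."""


@dataclass
class PopulationActivity:
    """Pooled spike times of the session's bursting units."""

    times: np.ndarray
    n_units: int

    def count(self, t0: float, t1: float) -> int:
        return int(
            np.searchsorted(self.times, t1, side="left")
            - np.searchsorted(self.times, t0, side="left")
        )

    def rate(self, t0: float, t1: float) -> float:
        """Spikes/s per neuron in the half-open window [t0, t1)."""
        if np.isnan(t0) or np.isnan(t1) or t1 <= t0:
            return np.nan
        return self.count(t0, t1) / ((t1 - t0) * self.n_units)


@dataclass
class PSTH:
    """Binned, censored, per-neuron-normalized population histogram."""

    align: str
    bin_edges: np.ndarray
    rate: np.ndarray
    counts: np.ndarray
    trials_per_bin: np.ndarray
    n_units: int
    truncation: tuple[float, float]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def window_mean(self, t0: float, t1: float) -> float:
        """Mean rate over the bins fully inside [t0, t1)."""
        lo, hi = self.bin_edges[:-1], self.bin_edges[1:]
        m = (lo >= t0 - 1e-9) & (hi <= t1 + 1e-9) & ~np.isnan(self.rate)
        return float(np.mean(self.rate[m])) if m.any() else np.nan


@dataclass
class EvalResponse:
    rate: float
    window: tuple[float, float]
    used_whole_epoch: bool = False


def _unit_dict(units) -> dict[str, np.ndarray]:
    if isinstance(units, pd.DataFrame):
        return {
            uid: np.sort(g["time_s"].to_numpy(dtype=float))
            for uid, g in units.groupby("unit_id", sort=True)
        }
    return {k: np.asarray(v, dtype=float) for k, v in units.items()}


def _mean_window_rate(times: np.ndarray, starts: np.ndarray, w0: float, w1: float) -> float:
    starts = starts[~np.isnan(starts)]
    if starts.size == 0:
        return np.nan
    lo = np.searchsorted(times, starts + w0, side="left")
    hi = np.searchsorted(times, starts + w1, side="left")
    return float(np.mean(hi - lo) / (w1 - w0))


def classify_bursting(
    units,
    trials: pd.DataFrame,
    sleft_window: tuple[float, float] = SLEFT_WINDOW,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    contrast_hz: float = 2.0,
    baseline_max_hz: float = 10.0,
    baseline_event: str = "t_light_on",
) -> pd.DataFrame:
    """Classify units as bursting by their S-left sound response.

    A unit is bursting when its mean rate in the post-stimulus window of
    S-left trials exceeds the corresponding would-be-stimulus window of
    catch trials by strictly more than ``contrast_hz`` spikes/s, with a
    baseline (pre-trial-start) rate strictly below ``baseline_max_hz``.
    The catch-trial contrast removes the nonstationary pre-stimulus
    baseline.  Raises :class:`ExclusionError` when the session has no catch
    (or no S-left) trials.
    """
    sleft_t = trials.loc[trials["type"] == "s_left", "t_stim"].to_numpy(dtype=float)
    catch_t = trials.loc[trials["type"] == "catch", "t_stim"].to_numpy(dtype=float)
    base_t = trials[baseline_event].to_numpy(dtype=float)
    if np.count_nonzero(~np.isnan(catch_t)) == 0:
        raise ExclusionError("no catch trials: bursting classification impossible")
    if np.count_nonzero(~np.isnan(sleft_t)) == 0:
        raise ExclusionError("no S-left trials: bursting classification impossible")

    rows = []
    for uid, times in _unit_dict(units).items():
        s = _mean_window_rate(times, sleft_t, *sleft_window)
        c = _mean_window_rate(times, catch_t, *sleft_window)
        b = _mean_window_rate(times, base_t, *baseline_window)
        rows.append({
            "unit_id": uid,
            "sleft_window_rate": s,
            "catch_window_rate": c,
            "baseline_rate": b,
            "is_bursting": bool((s - c > contrast_hz) and (b < baseline_max_hz)),
        })
    return pd.DataFrame(rows)


def pool_population(units, classification: pd.DataFrame) -> PopulationActivity:
    """Pool spike timestamps of the session's bursting units.

    Raises :class:`ExclusionError` when fewer than two bursting units are
    present (a single-unit session is excluded from population analyses).
    """
    udict = _unit_dict(units)
    ids = classification.loc[classification["is_bursting"], "unit_id"].tolist()
    if len(ids) < 2:
        raise ExclusionError(
            f"{len(ids)} bursting unit(s); population analysis needs >= 2"
        )
    pooled = np.sort(np.concatenate([udict[i] for i in ids]))
    return PopulationActivity(times=pooled, n_units=len(ids))


def compute_psth(
    pop: PopulationActivity,
    align_times: np.ndarray,
    window: tuple[float, float],
    obs_lo: np.ndarray | float = -np.inf,
    obs_hi: np.ndarray | float = np.inf,
    bin_s: float = BIN_S,
    truncate: str | tuple[float, float] | None = "median",
    align: str = "event",
) -> PSTH:
    """Censored population PSTH aligned at ``align_times``.

    ``obs_lo``/``obs_hi`` give each trial's observed interval relative to
    its alignment event (e.g. fixation-port exit latency for
    stimulus-aligned histograms).  A trial contributes to a bin only when
    the bin lies entirely inside its observed interval, so the per-bin rate
    is count / (trials_per_bin * n_units * bin width).  ``truncate='median'``
    cuts the histogram at the median censoring latency on each censored
    side; a ``(lo, hi)`` tuple cuts explicitly; ``None`` keeps all bins.

    Raises ``ValueError`` when no trial contributes to any bin.
    """
    align_times = np.asarray(align_times, dtype=float)
    keep = ~np.isnan(align_times)
    obs_lo = np.broadcast_to(np.asarray(obs_lo, dtype=float), align_times.shape)[keep]
    obs_hi = np.broadcast_to(np.asarray(obs_hi, dtype=float), align_times.shape)[keep]
    align_times = align_times[keep]

    edges = np.round(np.arange(window[0], window[1] + bin_s / 2, bin_s), 9)
    nbins = len(edges) - 1
    counts = np.zeros(nbins)
    tpb = np.zeros(nbins, dtype=int)
    for a, lo, hi in zip(align_times, obs_lo, obs_hi):
        inc = (edges[:-1] >= lo - 1e-9) & (edges[1:] <= hi + 1e-9)
        if not inc.any():
            continue
        idx = np.searchsorted(pop.times, a + edges, side="left")
        counts[inc] += np.diff(idx)[inc]
        tpb[inc] += 1
    if tpb.sum() == 0:
        raise ValueError("no trials contribute to any PSTH bin")

    if truncate == "median":
        cut_hi = np.inf
        fin = np.isfinite(obs_hi)
        if fin.any():
            cut_hi = float(np.median(obs_hi[fin]))
        cut_lo = -np.inf
        fin = np.isfinite(obs_lo)
        if fin.any():
            cut_lo = float(np.median(obs_lo[fin]))
        truncation = (cut_lo, cut_hi)
    elif truncate is None:
        truncation = (-np.inf, np.inf)
    else:
        truncation = (float(truncate[0]), float(truncate[1]))

    keep_bins = (edges[:-1] >= truncation[0] - 1e-9) & (edges[1:] <= truncation[1] + 1e-9)
    edges_out = np.append(edges[:-1][keep_bins], edges[1:][keep_bins][-1]) \
        if keep_bins.any() else edges[:1]
    counts = counts[keep_bins]
    tpb = tpb[keep_bins]
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(tpb > 0, counts / (tpb * pop.n_units * bin_s), np.nan)
    return PSTH(
        align=align, bin_edges=edges_out, rate=rate, counts=counts,
        trials_per_bin=tpb, n_units=pop.n_units, truncation=truncation,
    )


def average_psths(psths: list[PSTH], min_contributing: int = 1) -> PSTH:
    """Average PSTHs across animals on their shared 10 ms grid, truncated at
    the mean of the per-animal truncation latencies."""
    if not psths:
        raise ValueError("no PSTHs to average")
    start = min(p.bin_edges[0] for p in psths)
    stop = max(p.bin_edges[-1] for p in psths)
    edges = np.round(np.arange(start, stop + BIN_S / 2, BIN_S), 9)
    nb = len(edges) - 1
    acc = np.zeros(nb)
    n = np.zeros(nb, dtype=int)
    for p in psths:
        i0 = int(round((p.bin_edges[0] - start) / BIN_S))
        for k in range(len(p.rate)):
            if not np.isnan(p.rate[k]):
                acc[i0 + k] += p.rate[k]
                n[i0 + k] += 1
    his = [p.truncation[1] for p in psths if np.isfinite(p.truncation[1])]
    los = [p.truncation[0] for p in psths if np.isfinite(p.truncation[0])]
    cut_hi = float(np.mean(his)) if his else np.inf
    cut_lo = float(np.mean(los)) if los else -np.inf
    keep = (
        (edges[:-1] >= cut_lo - 1e-9) & (edges[1:] <= cut_hi + 1e-9)
        & (n >= min_contributing)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n > 0, acc / np.maximum(n, 1), np.nan)
    if keep.any():
        lo_i, hi_i = np.flatnonzero(keep)[[0, -1]]
    else:
        lo_i, hi_i = 0, nb - 1
    sl = slice(lo_i, hi_i + 1)
    return PSTH(
        align=psths[0].align, bin_edges=edges[lo_i:hi_i + 2], rate=rate[sl],
        counts=np.full(hi_i + 1 - lo_i, np.nan), trials_per_bin=n[sl],
        n_units=0, truncation=(cut_lo, cut_hi),
    )


def evaluation_response(
    pop: PopulationActivity,
    t0: float,
    t1: float,
    window_s: float = EVAL_WINDOW_S,
) -> EvalResponse:
    """Maximum per-neuron firing rate of any ``window_s`` window in
    ``[t0, t1]``.

    The scan is continuous: a maximizing window can always be anchored with
    its left edge at a spike time (or flush against the epoch end), so those
    are the candidates examined.  An epoch shorter than the window is used
    whole and flagged.
    """
    if np.isnan(t0) or np.isnan(t1) or t1 <= t0:
        return EvalResponse(np.nan, (np.nan, np.nan))
    if t1 - t0 < window_s:
        c = pop.count(t0, t1 + 1e-12)
        return EvalResponse(c / ((t1 - t0) * pop.n_units), (t0, t1), True)
    times = pop.times
    i0 = np.searchsorted(times, t0, side="left")
    i1 = np.searchsorted(times, t1, side="right")
    spikes = times[i0:i1]
    starts = spikes[spikes <= t1 - window_s]
    starts = np.append(starts, [t0, t1 - window_s])
    lo = np.searchsorted(spikes, starts, side="left")
    hi = np.searchsorted(spikes, starts + window_s, side="right")
    counts = hi - lo
    k = int(np.argmax(counts))
    return EvalResponse(
        float(counts[k]) / (window_s * pop.n_units),
        (float(starts[k]), float(starts[k]) + window_s),
    )


def resolve_evaluation_epoch(
    row,
    lick_epoch_durations: np.ndarray,
    min_pre_entry_s: float = 0.5,
) -> tuple[float, float] | None:
    """Evaluation epoch [start, end] for one trial/bout, per its label.

    Lick trials use [fix-out, outcome].  No-fixation licks (no fix-out) use
    the 95th percentile of the session's lick-trial epoch durations, ending
    at the outcome and beginning at least ``min_pre_entry_s`` before
    reward-port entry.  No-lick trials use the median duration, starting at
    fix-out.  ``lick_epoch_durations`` are the session's light-lick and
    catch-lick epoch lengths.
    """
    label = row["label"]
    durs = np.asarray(lick_epoch_durations, dtype=float)
    durs = durs[~np.isnan(durs)]
    if label in ("light_lick", "catch_lick", "left_lick", "wrong_port"):
        if np.isnan(row["t_fix_out"]) or np.isnan(row["t_outcome"]):
            return None
        return float(row["t_fix_out"]), float(row["t_outcome"])
    if label == "no_fixation_lick":
        if durs.size == 0 or np.isnan(row["t_outcome"]):
            return None
        dur = float(np.percentile(durs, 95))
        end = float(row["t_outcome"])
        start = end - dur
        if not np.isnan(row["t_port_in"]):
            start = min(start, float(row["t_port_in"]) - min_pre_entry_s)
        return start, end
    if label in ("light_no_lick", "catch_no_lick", "left_no_lick"):
        if durs.size == 0 or np.isnan(row["t_fix_out"]):
            return None
        dur = float(np.median(durs))
        return float(row["t_fix_out"]), float(row["t_fix_out"]) + dur
    return None


def outcome_response(pop: PopulationActivity, t_outcome: float) -> float:
    """Rate in the [0.05, 0.35] s window after the 3rd lick, per neuron.
    Computed for rewarded and non-rewarded lick episodes alike."""
    if np.isnan(t_outcome):
        raise ValueError("trial has no outcome event")
    return pop.rate(t_outcome + OUTCOME_WINDOW[0], t_outcome + OUTCOME_WINDOW[1])


def epoch_responses(
    pop: PopulationActivity,
    episodes: pd.DataFrame,
    eval_reference_durations: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-trial epoch response set (spikes/s per neuron).

    ``episodes`` holds one row per trial or no-fixation bout with the
    columns label, t_light_on, t_stim, t_fix_out, t_port_in, t_outcome.
    The evaluation-epoch duration references default to the session's own
    light-lick and catch-lick trials.
    """
    if eval_reference_durations is None:
        m = episodes["label"].isin(["light_lick", "catch_lick"])
        eval_reference_durations = (
            episodes.loc[m, "t_outcome"] - episodes.loc[m, "t_fix_out"]
        ).to_numpy(dtype=float)

    def wrate(t, w):
        return pop.rate(t + w[0], t + w[1]) if not np.isnan(t) else np.nan

    rows = []
    for _, row in episodes.iterrows():
        t_stim = row.get("t_stim", np.nan)
        rec = {
            "label": row["label"],
            "sleft_onset": wrate(t_stim, SLEFT_WINDOW) if row.get("type") == "s_left" else np.nan,
            "light_onset": wrate(t_stim, LIGHT_WINDOW) if row.get("type") == "light" else np.nan,
            "catch_would_be": wrate(t_stim, LIGHT_WINDOW) if row.get("type") == "catch" else np.nan,
            "pre_fixout": wrate(row.get("t_fix_out", np.nan), PRE_FIXOUT_WINDOW),
            "post_fixout": wrate(row.get("t_fix_out", np.nan), POST_FIXOUT_WINDOW),
            "baseline": wrate(row.get("t_light_on", np.nan), BASELINE_WINDOW),
            "outcome": np.nan,
            "evaluation": np.nan,
            "evaluation_flagged": False,
        }
        t_out = row.get("t_outcome", np.nan)
        if not np.isnan(t_out):
            rec["outcome"] = outcome_response(pop, t_out)
        epoch = resolve_evaluation_epoch(row, eval_reference_durations)
        if epoch is not None:
            er = evaluation_response(pop, *epoch)
            rec["evaluation"] = er.rate
            rec["evaluation_flagged"] = er.used_whole_epoch
        rows.append(rec)
    return pd.DataFrame(rows, index=episodes.index)


def trial_window_rates(
    pop: PopulationActivity,
    align_times: np.ndarray,
    window_starts: np.ndarray,
    width_s: float = 0.1,
    obs_lo: np.ndarray | float = -np.inf,
    obs_hi: np.ndarray | float = np.inf,
) -> np.ndarray:
    """Per-trial rates in sliding windows (trials x windows), NaN where the
    window is not fully observed for that trial."""
    align_times = np.asarray(align_times, dtype=float)
    window_starts = np.asarray(window_starts, dtype=float)
    obs_lo = np.broadcast_to(np.asarray(obs_lo, dtype=float), align_times.shape)
    obs_hi = np.broadcast_to(np.asarray(obs_hi, dtype=float), align_times.shape)
    out = np.full((len(align_times), len(window_starts)), np.nan)
    for i, (a, lo, hi) in enumerate(zip(align_times, obs_lo, obs_hi)):
        if np.isnan(a):
            continue
        valid = (window_starts >= lo - 1e-9) & (window_starts + width_s <= hi + 1e-9)
        if not valid.any():
            continue
        s = window_starts[valid]
        c = (
            np.searchsorted(pop.times, a + s + width_s, side="left")
            - np.searchsorted(pop.times, a + s, side="left")
        )
        out[i, valid] = c / (width_s * pop.n_units)
    return out


def trial_trend(series: np.ndarray, window: int = 10) -> np.ndarray:
    """Centered moving median over ``window`` trials, windows shrinking at
    the edges; NaN entries are ignored within each window."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    out = np.full(n, np.nan)
    half_lo = (window - 1) // 2
    half_hi = window // 2 + 1
    for i in range(n):
        seg = x[max(0, i - half_lo): min(n, i + half_hi)]
        seg = seg[~np.isnan(seg)]
        if seg.size:
            out[i] = np.median(seg)
    return out


def aligned_trend_mean(
    trends: list[tuple[np.ndarray, np.ndarray]],
    min_animals: int = 4,
) -> pd.DataFrame:
    """Average transition-aligned smoothed series across animals, keeping
    only offsets with data from at least ``min_animals`` animals.

    Each element of ``trends`` is ``(offsets, values)``.
    """
    if not trends:
        return pd.DataFrame(columns=["offset", "mean", "n"])
    lo = min(int(o.min()) for o, _ in trends)
    hi = max(int(o.max()) for o, _ in trends)
    offsets = np.arange(lo, hi + 1)
    acc = np.zeros(len(offsets))
    n = np.zeros(len(offsets), dtype=int)
    for o, v in trends:
        idx = (np.asarray(o, dtype=int) - lo)
        ok = ~np.isnan(v)
        np.add.at(acc, idx[ok], v[ok])
        np.add.at(n, idx[ok], 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(n >= min_animals, acc / np.maximum(n, 1), np.nan)
    df = pd.DataFrame({"offset": offsets, "mean": mean, "n": n})
    return df[df["n"] >= min_animals].reset_index(drop=True)


def stimulus_response_difference(
    psth_a: PSTH,
    psth_b: PSTH,
    window: tuple[float, float] = LIGHT_WINDOW,
) -> float:
    """Mean over ``window`` of (psth_a - psth_b) on their shared bin grid.

    Raises ``ValueError`` when the grids are disjoint over the window.
    """
    lo = max(psth_a.bin_edges[0], psth_b.bin_edges[0], window[0])
    hi = min(psth_a.bin_edges[-1], psth_b.bin_edges[-1], window[1])
    if hi <= lo:
        raise ValueError("PSTH grids do not overlap on the requested window")

    def wmean(p: PSTH) -> float:
        return p.window_mean(lo, hi)

    return wmean(psth_a) - wmean(psth_b)
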