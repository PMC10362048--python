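"""Inhomogeneous-Poisson spike generator for the simulated BF population.

Each unit's rate is a constant baseline plus event-locked piecewise-constant
gain segments derived from the session's latent trial table.  Sampling is
exact for a piecewise-constant rate: each constant segment contributes a
Poisson count with uniformly placed spike times (superposition property).
A short absolute refractory period is then enforced and times are rounded
to 1 ms, mirroring the resolution of the acquisition systems this format
emulates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import NeuronConfig

__all__ = ["simulate_spikes"]

_RAMP_SEGMENTS = 8


def _segments_for_unit(
    truth: pd.DataFrame,
    neurons: NeuronConfig,
    session: int,
    d2: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-locked gain segments (start, duration, added rate) for one
    bursting-class unit; all bursting units share the same rate profile."""
    starts: list[float] = []
    durs: list[float] = []
    rates: list[float] = []

    def add(a: float, b: float, r: float) -> None:
        if b > a and r > 0:
            starts.append(a)
            durs.append(b - a)
            rates.append(r)

    for row in truth.itertuples(index=False):
        t_stim = row.t_stim
        if row.trial_type == "s_left" and t_stim is not None and not _isnan(t_stim):
            add(t_stim + 0.05, t_stim + 0.2, neurons.sleft_gain_hz)
        if row.trial_type == "light" and t_stim is not None and not _isnan(t_stim):
            g = neurons.light_gain(session, d2, row.session_frac)
            add(t_stim + 0.05, t_stim + 0.3, g)

        has_outcome = row.t_outcome is not None and not _isnan(row.t_outcome)
        if not has_outcome:
            continue
        e = row.expectation
        if e is None or _isnan(e):
            continue
        # evaluation-epoch ramp: approach-to-port activity scaled by the
        # trial's reward expectation (left trials and post-transition
        # right-lick episodes carry the learned approach predictor)
        if row.label == "left_lick" or bool(row.post_transition):
            if row.kind == "bout":
                w0 = row.t_port_in - 0.5
            else:
                w0 = row.t_fix_out
            w1 = row.t_outcome
            if w1 > w0:
                peak = neurons.eval_gain_hz * e
                edges = np.linspace(w0, w1, _RAMP_SEGMENTS + 1)
                mids = (np.arange(_RAMP_SEGMENTS) + 0.5) / _RAMP_SEGMENTS
                for k in range(_RAMP_SEGMENTS):
                    add(edges[k], edges[k + 1], peak * mids[k])
            # outcome response scaled by the RPE rule
            add(row.t_outcome + 0.05, row.t_outcome + 0.35,
                neurons.outcome_gain_hz * row.rpe)

    return (np.asarray(starts), np.asarray(durs), np.asarray(rates))


def _isnan(x) -> bool:
    try:
        return bool(np.isnan(x))
    except TypeError:
        return False


def _sample_piecewise(
    rng: np.random.Generator,
    baseline: float,
    duration: float,
    seg_start: np.ndarray,
    seg_dur: np.ndarray,
    seg_rate: np.ndarray,
) -> np.ndarray:
    n_base = rng.poisson(baseline * duration)
    times = [rng.random(n_base) * duration]
    if seg_start.size:
        counts = rng.poisson(seg_rate * seg_dur)
        total = int(counts.sum())
        if total:
            u = rng.random(total)
            times.append(np.repeat(seg_start, counts) + u * np.repeat(seg_dur, counts))
    t = np.sort(np.concatenate(times))
    return t


def _apply_refractory(t: np.ndarray, refractory_s: float) -> np.ndarray:
    # iteratively drop the later spike of every sub-refractory pair; at the
    # firing rates used here violations are ~1-2% and chains are rare, so a
    # couple of vectorized passes converge
    while t.size and refractory_s > 0:
        close = np.diff(t) < refractory_s
        if not close.any():
            break
        t = np.delete(t, np.flatnonzero(close) + 1)
    return t


def simulate_spikes(
    events: pd.DataFrame,
    truth: pd.DataFrame,
    neurons: NeuronConfig,
    rng: np.random.Generator,
    session_index: int = 0,
    d2: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-unit spike tables for one session.

    Parameters
    ----------
    events, truth
        Output of :func:`~stepwise_bf.synthetic.agent.simulate_session`.
    session_index, d2
        The session ordinal and the animal's planted D2 session (the
        light-onset gain is zero before D2 and grows afterwards).

    Returns ``(spikes_df, units_df)``: spike rows ``(unit_id, time_s)`` and
    the planted unit classes (the per-unit ground truth).
    """
    duration = 1.0
    if len(events):
        duration = float(events["time_s"].max()) + 1.0
    if len(truth):
        duration = max(duration, float(truth["t_end"].max()) + 1.0)

    n_burst = int(round(neurons.n_units * neurons.p_bursting))
    seg = _segments_for_unit(truth, neurons, session_index, d2)

    unit_rows = []
    spike_frames = []
    for u in range(neurons.n_units):
        bursting = u < n_burst
        if bursting:
            base = max(0.5, rng.normal(neurons.baseline_hz, neurons.baseline_jitter_hz))
            base = min(base, 9.0)
            t = _sample_piecewise(rng, base, duration, *seg)
        else:
            base = max(0.5, rng.normal(neurons.nonbursting_baseline_hz,
                                       neurons.baseline_jitter_hz))
            t = _sample_piecewise(rng, base, duration,
                                  np.empty(0), np.empty(0), np.empty(0))
        t = _apply_refractory(t, neurons.refractory_s)
        t = np.round(t, 3)
        t = t[np.concatenate([[True], np.diff(t) > 0])] if t.size else t
        uid = f"u{u:03d}"
        unit_rows.append((uid, bursting, float(base)))
        spike_frames.append(pd.DataFrame({"unit_id": uid, "time_s": t}))

    spikes_df = (
        pd.concat(spike_frames, ignore_index=True)
        if spike_frames
        else pd.DataFrame(columns=["unit_id", "time_s"])
    )
    units_df = pd.DataFrame(unit_rows, columns=["unit_id", "is_bursting", "baseline_hz"])
    return spikes_df, units_df
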