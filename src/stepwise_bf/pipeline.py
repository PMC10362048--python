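"""End-to-end analysis of a study directory (or in-memory study).

Stages: event parsing and sequence classification -> learning landmarks and
the within-D1 transition -> bursting-unit classification and population
epoch responses -> sliding-window, ROC and RPE statistics -> plot-ready
tables.  Exclusion rules mirror the analysis conventions: animals whose D1
and D2 coincide are excluded from D1-dynamics analyses, sessions with fewer
than two bursting units from population analyses, single-trial non-rewarded
RPE correlations require 50 pooled non-rewarded licks, and lick/no-lick ROC
cells require 10% class balance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .events import (
    LickBout, Trial, classify_response, detect_no_fixation_licks,
    parse_events, session_summary, trials_to_frame,
)
from .landmarks import (
    build_combined_series, find_transition, identify_landmarks,
    light_learning_index,
)
from .neural import (
    ExclusionError, PopulationActivity, classify_bursting, compute_psth,
    epoch_responses, pool_population, trial_trend, trial_window_rates,
    aligned_trend_mean,
)
from .stats import (
    lick_discrimination_auc, pearson_corr, single_trial_rpe_correlations,
    sliding_auc, sliding_paired_comparison,
)
from .synthetic.study import StudyData

__all__ = ["PipelineConfig", "StudyReport", "run_study", "verify_against_truth"]


@dataclass
class PipelineConfig:
    """All tunable analysis parameters, with the analysis-convention values
    as defaults."""

    study_dir: str | None = None
    out_dir: str | None = None
    seed: int = 0
    new_side: str = "right"
    response_window_s: float = 3.0
    lick_rule: str = "third_lick_in_window"
    transition_window: int = 20
    max_shift: int = 5
    alphas: tuple[float, float] = (0.01, 0.05)
    run_len: int = 3
    sliding_window_s: float = 0.1
    sliding_step_s: float = 0.01
    auc_n_perm: int = 10000
    auc_alpha: float = 0.001
    lick_auc_n_perm: int = 1000
    lick_auc_alpha: float = 0.05
    min_class_frac: float = 0.1
    min_nonrewarded: int = 50
    min_animals_trend: int = 4
    trend_window: int = 10
    psth_window: tuple[float, float] = (-0.5, 1.0)
    early_late_n: int = 20
    compute_sliding_roc: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - fields
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for k in ("alphas", "psth_window"):
            if k in raw and isinstance(raw[k], list):
                raw[k] = tuple(raw[k])
        return cls(**raw)


@dataclass
class StudyReport:
    landmark_table: pd.DataFrame
    session_table: pd.DataFrame
    transition_table: pd.DataFrame
    behavior_trends: pd.DataFrame
    response_trends: pd.DataFrame
    group_behavior_trend: pd.DataFrame
    group_response_trend: pd.DataFrame
    d1_psth_table: pd.DataFrame
    d1_roc_table: pd.DataFrame
    d2_sliding_table: pd.DataFrame
    d2_sliding_runs: pd.DataFrame
    d2_light_table: pd.DataFrame
    correlation_table: pd.DataFrame
    rpe_table: pd.DataFrame
    auc_table: pd.DataFrame
    exclusions: pd.DataFrame
    manifest: dict

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self._tables().items():
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.6g")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1))
        return out

    def _tables(self) -> dict[str, pd.DataFrame]:
        return {
            "landmarks": self.landmark_table,
            "sessions": self.session_table,
            "transitions": self.transition_table,
            "behavior_trends": self.behavior_trends,
            "response_trends": self.response_trends,
            "group_behavior_trend": self.group_behavior_trend,
            "group_response_trend": self.group_response_trend,
            "d1_psth": self.d1_psth_table,
            "d1_roc": self.d1_roc_table,
            "d2_sliding": self.d2_sliding_table,
            "d2_sliding_runs": self.d2_sliding_runs,
            "d2_light": self.d2_light_table,
            "correlations": self.correlation_table,
            "rpe": self.rpe_table,
            "auc": self.auc_table,
            "exclusions": self.exclusions,
        }


# --------------------------------------------------------------------------
# per-session working state

@dataclass
class _Session:
    index: int
    trials: list[Trial]
    bouts: list[LickBout]
    nofix: list[LickBout]
    episodes: pd.DataFrame
    summary: dict
    pop: PopulationActivity | None = None
    units: pd.DataFrame | None = None
    n_bursting: int = 0


def _episodes_frame(trials: list[Trial], nofix: list[LickBout]) -> pd.DataFrame:
    df = trials_to_frame(trials)
    df["kind"] = "trial"
    df["order_time"] = df["t_stim"].fillna(df["t_fix_in"])
    rows = []
    for b in nofix:
        if b.status != "no_fixation_lick":
            continue
        rows.append({
            "type": None, "label": "no_fixation_lick", "kind": "bout",
            "early": False, "t_light_on": np.nan, "t_fix_in": np.nan,
            "t_stim": np.nan, "t_fix_out": np.nan, "foreperiod_s": np.nan,
            "t_port_in": b.t_port_in, "t_outcome": float(b.lick_times[2]),
            "t_end": b.t_last, "rewarded": False, "responded_port": b.port,
            "n_licks_left": 0, "n_licks_right": b.n_licks,
            "order_time": b.t_first,
        })
    if rows:
        df = pd.concat([df, pd.DataFrame(rows)], ignore_index=True)
    return df.sort_values("order_time").reset_index(drop=True)


def _analyze_session(
    sess_events: pd.DataFrame,
    spikes: pd.DataFrame | None,
    index: int,
    cfg: PipelineConfig,
    exclusions: list,
    animal: str,
) -> _Session:
    trials, bouts = parse_events(
        sess_events, response_window_s=cfg.response_window_s
    )
    for tr in trials:
        classify_response(
            tr, response_window_s=cfg.response_window_s,
            rule=cfg.lick_rule, new_side=cfg.new_side,
        )
    nofix = detect_no_fixation_licks(bouts, trials, sess_events, new_side=cfg.new_side)
    summary = session_summary(trials, nofix, new_side=cfg.new_side)
    episodes = _episodes_frame(trials, nofix)
    episodes["session"] = index
    s = _Session(index=index, trials=trials, bouts=bouts, nofix=nofix,
                 episodes=episodes, summary=summary)
    if spikes is not None and len(spikes):
        try:
            cls = classify_bursting(spikes, episodes[episodes["kind"] == "trial"])
            s.units = cls
            s.n_bursting = int(cls["is_bursting"].sum())
            s.pop = pool_population(spikes, cls)
        except ExclusionError as e:
            exclusions.append({"animal": animal, "session": index,
                               "analysis": "population", "reason": str(e)})
    if s.pop is not None:
        ep = epoch_responses(s.pop, episodes)
        s.episodes = pd.concat([episodes, ep.drop(columns=["label"])], axis=1)
    return s


def _stim_psth(pop, episodes, mask, cfg, censor=True):
    sub = episodes[mask]
    obs_hi = (sub["t_fix_out"] - sub["t_stim"]).to_numpy() if censor else np.inf
    return compute_psth(
        pop, sub["t_stim"].to_numpy(), window=cfg.psth_window,
        obs_hi=obs_hi, truncate="median", align="stim_on",
    )


def _psth_matrix(psths):
    """Stack per-animal PSTH rate vectors onto a common bin grid."""
    start = min(p.bin_edges[0] for p in psths)
    stop = max(p.bin_edges[-1] for p in psths)
    edges = np.round(np.arange(start, stop + 0.005, 0.01), 9)
    mat = np.full((len(psths), len(edges) - 1), np.nan)
    for i, p in enumerate(psths):
        i0 = int(round((p.bin_edges[0] - start) / 0.01))
        mat[i, i0:i0 + len(p.rate)] = p.rate
    return mat, edges


def run_study(config: PipelineConfig, study: StudyData | None = None) -> StudyReport:
    """Run the full analysis.

    ``study`` may be an in-memory :class:`StudyData`; otherwise
    ``config.study_dir`` is read.  Landmark failures and inclusion-rule
    exclusions are reported per animal and the run continues.
    """
    if study is None:
        if config.study_dir is None:
            raise ValueError("either a study or config.study_dir is required")
        study = io.read_study(config.study_dir)
    rng = np.random.default_rng(config.seed)
    exclusions: list[dict] = []

    landmark_rows, session_rows, transition_rows = [], [], []
    beh_trend_rows, resp_trend_rows = [], []
    d1_psth_rows, d2_light_rows = [], []
    d1_roc_frames: list[pd.DataFrame] = []
    rpe_frames, auc_rows = [], []
    beh_trends, eval_trends, outcome_trends = [], [], []
    d2_pairs = []  # (psth_light, psth_catch) per animal

    for animal in study.animals:
        aid = animal.animal_id
        sessions: list[_Session] = []
        for sd in animal.sessions:
            sessions.append(_analyze_session(
                sd.events, sd.spikes, sd.session_index, config, exclusions, aid,
            ))
        summaries = pd.DataFrame([s.summary for s in sessions])
        lm = identify_landmarks(summaries)

        # per-session behavioral + neural series (Fig 2c / 7 analogues)
        for s in sessions:
            row = {"animal": aid, "session": s.index, **s.summary}
            row["learning_index"] = light_learning_index(s.summary)
            row["n_bursting"] = s.n_bursting
            row["rel_d2"] = s.index - lm.d2 if lm.d2 is not None else np.nan
            ep = s.episodes
            if s.pop is not None and "light_onset" in ep.columns:
                base = np.nanmean(ep["baseline"])
                ll = ep[ep["label"] == "light_lick"]
                row["baseline_hz"] = base
                row["light_onset_resp"] = np.nanmean(ll["light_onset"]) - base if len(ll) else np.nan
                row["outcome_resp_light"] = np.nanmean(ll["outcome"]) - base if len(ll) else np.nan
                row["eval_resp_mean"] = np.nanmean(ep["evaluation"]) - base
            session_rows.append(row)

        landmark_rows.append({
            "animal": aid, "d0": lm.d0, "d1": lm.d1, "d2": lm.d2,
            "merged": lm.merged_flag, "complete": lm.complete,
        })
        if not lm.complete:
            exclusions.append({"animal": aid, "session": -1,
                               "analysis": "landmarks",
                               "reason": "landmarks unresolved"})
            continue

        # ---- D1 dynamics (transition point and aligned trends)
        if lm.merged_flag:
            exclusions.append({"animal": aid, "session": lm.d1,
                               "analysis": "d1_dynamics",
                               "reason": "D1 and D2 in the same session"})
        else:
            d1s = sessions[lm.d1]
            combined = build_combined_series(d1s.trials, d1s.nofix, config.new_side)
            if len(combined) >= 2 * config.transition_window:
                tres = find_transition(
                    combined["code"].to_numpy(),
                    w=config.transition_window,
                    light_lick_mask=combined["is_light_lick"].to_numpy(),
                    max_shift=config.max_shift,
                )
                transition_rows.append({
                    "animal": aid, "session": lm.d1,
                    "raw_index": tres.raw_index,
                    "adjusted_index": tres.adjusted_index,
                    "statistic": tres.statistic,
                    "found": tres.found,
                    "low_confidence": tres.low_confidence,
                    "n_combined": len(combined),
                })
                if tres.found:
                    t0 = tres.adjusted_index
                    offs = np.arange(len(combined)) - t0
                    sm = trial_trend(combined["code"].to_numpy(), config.trend_window)
                    beh_trends.append((offs, sm))
                    for o, v, raw in zip(offs, sm, combined["code"]):
                        beh_trend_rows.append({"animal": aid, "offset": int(o),
                                               "code": int(raw), "smoothed": v})
                    # combined-episode evaluation/outcome response trends
                    ep = d1s.episodes
                    if d1s.pop is not None and "evaluation" in ep.columns:
                        mask = ep["label"].isin(
                            ["light_lick", "catch_lick", "no_fixation_lick",
                             "light_no_lick", "catch_no_lick"])
                        sub = ep[mask].reset_index(drop=True)
                        ev_sm = trial_trend(sub["evaluation"].to_numpy(), config.trend_window)
                        out_sm = trial_trend(sub["outcome"].to_numpy(), config.trend_window)
                        offs2 = np.arange(len(sub)) - t0
                        eval_trends.append((offs2, ev_sm))
                        outcome_trends.append((offs2, out_sm))
                        for o, a, b in zip(offs2, ev_sm, out_sm):
                            resp_trend_rows.append({
                                "animal": aid, "offset": int(o),
                                "evaluation": a, "outcome": b,
                            })

            # D1 four-way PSTH panel (light/catch x lick/no-lick)
            if d1s.pop is not None:
                for ttype in ("light", "catch"):
                    for lick in (True, False):
                        lab = (f"{ttype}_lick" if lick
                               else f"{ttype}_no_lick")
                        m = d1s.episodes["label"] == lab
                        if m.sum() < 2:
                            continue
                        try:
                            p = _stim_psth(d1s.pop, d1s.episodes, m, config)
                        except ValueError:
                            continue
                        for e0, r, npb in zip(p.bin_edges[:-1], p.rate,
                                              p.trials_per_bin):
                            d1_psth_rows.append({
                                "animal": aid, "label": lab, "bin_start": e0,
                                "rate": r, "trials_per_bin": npb,
                                "n_units": p.n_units,
                            })

                # sliding ROC: light vs catch trials in the D1 session
                if config.compute_sliding_roc:
                    epi = d1s.episodes
                    sub = epi[epi["type"].isin(["light", "catch"]) & ~epi["early"]]
                    if len(sub) >= 8:
                        starts = np.round(np.arange(
                            config.psth_window[0],
                            config.psth_window[1] - config.sliding_window_s + 1e-9,
                            config.sliding_step_s), 9)
                        rates = trial_window_rates(
                            d1s.pop, sub["t_stim"].to_numpy(), starts,
                            width_s=config.sliding_window_s,
                            obs_hi=(sub["t_fix_out"] - sub["t_stim"]).to_numpy(),
                        )
                        roc = sliding_auc(
                            rates, (sub["type"] == "light").to_numpy(), starts,
                            n_perm=config.auc_n_perm, alpha=config.auc_alpha,
                            rng=rng,
                        )
                        roc["animal"] = aid
                        d1_roc_frames.append(roc)

        # ---- D2 light-response analyses
        d2s = sessions[lm.d2]
        if d2s.pop is not None:
            epi = d2s.episodes
            try:
                p_light = _stim_psth(d2s.pop, epi, epi["label"] == "light_lick", config)
                p_catch = _stim_psth(d2s.pop, epi, epi["label"] == "catch_lick", config)
                d2_pairs.append((p_light, p_catch))
            except ValueError:
                pass

            def _subset_diff(ep_frame, phase, head):
                ll = ep_frame[ep_frame["label"] == "light_lick"]
                cc = ep_frame[ep_frame["label"] == "catch_lick"]
                n = config.early_late_n
                ll = ll.head(n) if head else ll.tail(n)
                cc = cc.head(n) if head else cc.tail(n)
                if len(ll) < 3 or len(cc) < 3:
                    return None
                diff = (np.nanmean(ll["light_onset"].to_numpy())
                        - np.nanmean(cc["catch_would_be"].to_numpy()))
                return {"animal": aid, "phase": phase, "light_response": diff}

            for phase, head in (("d2_early", True), ("d2_late", False)):
                row = _subset_diff(epi, phase, head)
                if row:
                    d2_light_rows.append(row)
            if lm.d2 - 1 >= 0 and sessions[lm.d2 - 1].pop is not None:
                prev = sessions[lm.d2 - 1]
                row = _subset_diff(prev.episodes, "pre_d2_late", False)
                if row:
                    d2_light_rows.append(row)

        # ---- RPE single-trial correlations
        neural_eps = [s.episodes for s in sessions
                      if s.pop is not None and "evaluation" in s.episodes.columns]
        if neural_eps:
            all_eps = pd.concat(neural_eps, ignore_index=True)
            rpe = single_trial_rpe_correlations(
                all_eps, d2=lm.d2, min_nonrewarded=config.min_nonrewarded,
            )
            rpe["animal"] = aid
            rpe_frames.append(rpe)

        # ---- lick vs no-lick discrimination from post-fix-out activity
        for s in sessions:
            if s.pop is None:
                continue
            for ttype in ("light", "catch"):
                if ttype == "light" and s.index >= lm.d2:
                    continue  # light trials only before D2
                sub = s.episodes[(s.episodes["type"] == ttype)
                                 & ~s.episodes["early"]]
                if len(sub) < 4:
                    continue
                rates = trial_window_rates(
                    s.pop, sub["t_fix_out"].to_numpy(), np.array([0.0]),
                    width_s=0.5,
                )[:, 0]
                labels = sub["label"].isin(
                    ["light_lick", "catch_lick"]).to_numpy()
                res = lick_discrimination_auc(
                    rates, labels, n_perm=config.lick_auc_n_perm,
                    alpha=config.lick_auc_alpha, rng=rng,
                    min_class_frac=config.min_class_frac,
                )
                auc_rows.append({
                    "animal": aid, "session": s.index, "trial_type": ttype,
                    "auc": res.auc, "p": res.p, "n_pos": res.n_pos,
                    "n_neg": res.n_neg, "significant": res.significant,
                    "skipped": res.skipped, "reason": res.reason,
                })
                if res.skipped:
                    exclusions.append({
                        "animal": aid, "session": s.index,
                        "analysis": f"lick_auc_{ttype}", "reason": res.reason,
                    })

    # ---- group-level tables
    session_table = pd.DataFrame(session_rows)
    group_beh = aligned_trend_mean(beh_trends, config.min_animals_trend)
    group_resp = pd.DataFrame(columns=["offset", "evaluation", "outcome", "n"])
    if eval_trends:
        ge = aligned_trend_mean(eval_trends, config.min_animals_trend)
        go = aligned_trend_mean(outcome_trends, config.min_animals_trend)
        group_resp = ge.rename(columns={"mean": "evaluation"}).merge(
            go.rename(columns={"mean": "outcome"}), on="offset",
            suffixes=("", "_out"),
        )

    d2_sliding_table = pd.DataFrame()
    d2_run_rows = []
    if len(d2_pairs) >= 3:
        mat_l, edges = _psth_matrix([p for p, _ in d2_pairs])
        mat_c, _ = _psth_matrix([c for _, c in d2_pairs])
        nb = min(mat_l.shape[1], mat_c.shape[1])
        comp = sliding_paired_comparison(
            mat_l[:, :nb], mat_c[:, :nb], edges[:nb + 1],
            alphas=config.alphas, window_s=config.sliding_window_s,
            step_s=config.sliding_step_s, run_len=config.run_len,
        )
        d2_sliding_table = comp.table
        for alpha, runs in comp.runs.items():
            for a, b in runs:
                d2_run_rows.append({"alpha": alpha, "start_s": a, "end_s": b})

    corr_rows = []
    if len(session_table):
        pairs = [
            ("light_onset_vs_outcome", "light_onset_resp", "outcome_resp_light"),
            ("light_onset_vs_learning_index", "light_onset_resp", "learning_index"),
            ("light_onset_vs_rt", "light_onset_resp", "rt_light_s"),
        ]
        for name, xcol, ycol in pairs:
            if xcol not in session_table.columns or ycol not in session_table.columns:
                continue
            sub = session_table.dropna(subset=[xcol, ycol])
            if len(sub) < 3:
                continue
            c = pearson_corr(sub[xcol], sub[ycol])
            corr_rows.append({"name": name, "r": c.r, "p": c.p, "n": c.n})

    report = StudyReport(
        landmark_table=pd.DataFrame(landmark_rows),
        session_table=session_table,
        transition_table=pd.DataFrame(transition_rows),
        behavior_trends=pd.DataFrame(beh_trend_rows),
        response_trends=pd.DataFrame(resp_trend_rows),
        group_behavior_trend=group_beh,
        group_response_trend=group_resp,
        d1_psth_table=pd.DataFrame(d1_psth_rows),
        d1_roc_table=(pd.concat(d1_roc_frames, ignore_index=True)
                      if d1_roc_frames else pd.DataFrame()),
        d2_sliding_table=d2_sliding_table,
        d2_sliding_runs=pd.DataFrame(d2_run_rows),
        d2_light_table=pd.DataFrame(d2_light_rows),
        correlation_table=pd.DataFrame(corr_rows),
        rpe_table=(pd.concat(rpe_frames, ignore_index=True)
                   if rpe_frames else pd.DataFrame()),
        auc_table=pd.DataFrame(auc_rows),
        exclusions=pd.DataFrame(exclusions),
        manifest={
            "version": __version__,
            "seed": config.seed,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(config).items()},
            "n_animals": len(study.animals),
        },
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report


def verify_against_truth(
    report: StudyReport,
    study: StudyData,
    transition_tol: int = 2,
) -> pd.DataFrame:
    """Compare detected landmarks, transition points and unit classes with
    the simulator's planted ground truth.

    Raises ``ValueError`` when the study carries no ground truth.
    """
    rows = []
    truth_found = False
    lm = report.landmark_table.set_index("animal") if len(report.landmark_table) else None
    tt = (report.transition_table.set_index("animal")
          if len(report.transition_table) else None)
    for animal in study.animals:
        aid = animal.animal_id
        truths = [s.truth for s in animal.sessions if s.truth is not None]
        if not truths:
            continue
        truth_found = True
        t0 = truths[0]
        for name in ("d0", "d1", "d2"):
            det = (int(lm.loc[aid, name])
                   if lm is not None and aid in lm.index
                   and lm.loc[aid, name] is not None
                   and not pd.isna(lm.loc[aid, name]) else None)
            planted = getattr(t0, name)
            rows.append({
                "animal": aid, "quantity": name, "detected": det,
                "planted": planted,
                "error": (det - planted) if det is not None else np.nan,
                "passed": det == planted,
            })
        if t0.d1 != t0.d2:
            det = None
            if tt is not None and aid in tt.index:
                det = tt.loc[aid, "raw_index"]
                det = int(det) if det is not None and not pd.isna(det) else None
            err = (det - t0.transition_trial) if det is not None else np.nan
            rows.append({
                "animal": aid, "quantity": "transition", "detected": det,
                "planted": t0.transition_trial, "error": err,
                "passed": det is not None and abs(err) <= transition_tol,
            })
        # unit classes: compare planted against the per-session detection
        for s in animal.sessions:
            if s.truth is None or s.truth.units is None or s.spikes is None:
                continue
            try:
                det_units = classify_bursting(
                    s.spikes,
                    _episodes_frame(*_parse_classified(s.events)),
                )
            except ExclusionError:
                continue
            merged = det_units.merge(s.truth.units, on="unit_id")
            agree = float((merged["is_bursting_x"] == merged["is_bursting_y"]).mean())
            rows.append({
                "animal": aid, "quantity": f"unit_classes_s{s.session_index}",
                "detected": agree, "planted": 1.0, "error": agree - 1.0,
                "passed": agree == 1.0,
            })
    if not truth_found:
        raise ValueError("study carries no ground truth")
    return pd.DataFrame(rows)


def _parse_classified(events: pd.DataFrame):
    trials, bouts = parse_events(events)
    for tr in trials:
        classify_response(tr)
    nofix = detect_no_fixation_licks(bouts, trials, events)
    return trials, nofix
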