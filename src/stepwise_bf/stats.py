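"""Sliding-window paired comparisons, permutation ROC/AUC, and the
reward-prediction-error correlation analyses.

Conventions: tied observations use the midrank (Mann-Whitney) AUC; the
two-sided permutation p-value is (1 + #{|stat_perm| >= |stat_obs|}) /
(1 + n_perm), which can never be exactly zero; significance of a sliding
comparison requires the stated alpha for at least three consecutive
windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SlidingComparison", "AUCResult", "CorrelationResult",
    "find_runs", "sliding_paired_comparison",
    "mann_whitney_auc", "permutation_auc_pvalue", "sliding_auc",
    "lick_discrimination_auc", "pearson_corr",
    "single_trial_rpe_correlations", "quartile_summary",
]


# --------------------------------------------------------------------------
# sliding-window paired comparison with the consecutive-bin rule

@dataclass
class SlidingComparison:
    table: pd.DataFrame                     # window_start, window_end, mean_diff, t, p, n
    runs: dict = field(default_factory=dict)  # alpha -> list of (start_s, end_s)
    window_s: float = 0.1
    step_s: float = 0.01
    run_len: int = 3


def find_runs(mask: np.ndarray, min_len: int = 3) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_len, as (start, end) index
    pairs with an exclusive end."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    padded = np.concatenate([[False], m, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(a), int(b)) for a, b in zip(starts, ends) if b - a >= min_len]


def sliding_paired_comparison(
    rates_a: np.ndarray,
    rates_b: np.ndarray,
    bin_edges: np.ndarray,
    alphas: tuple[float, ...] = (0.01, 0.05),
    window_s: float = 0.1,
    step_s: float = 0.01,
    run_len: int = 3,
    min_pairs: int = 3,
) -> SlidingComparison:
    """Paired two-sided t-test per 100 ms sliding window (10 ms step).

    ``rates_a`` and ``rates_b`` are (animals x bins) mean-rate matrices on a
    shared bin grid (NaN where an animal's histogram is truncated).  Each
    window uses the animals with complete data in it; windows with fewer
    than ``min_pairs`` pairs are skipped.  Significant intervals are the
    maximal runs of at least ``run_len`` consecutive windows with p below
    each alpha.
    """
    a = np.atleast_2d(np.asarray(rates_a, dtype=float))
    b = np.atleast_2d(np.asarray(rates_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("paired rate matrices must share a shape")
    if a.shape[0] < min_pairs:
        raise ValueError(f"need at least {min_pairs} pairs")
    edges = np.asarray(bin_edges, dtype=float)
    nb = len(edges) - 1
    bins_per_win = int(round(window_s / (edges[1] - edges[0])))
    step_bins = max(1, int(round(step_s / (edges[1] - edges[0]))))

    rows = []
    for i0 in range(0, nb - bins_per_win + 1, step_bins):
        sl = slice(i0, i0 + bins_per_win)
        wa = a[:, sl].mean(axis=1)
        wb = b[:, sl].mean(axis=1)
        ok = ~np.isnan(wa) & ~np.isnan(wb)
        if ok.sum() < min_pairs:
            continue
        d = wa[ok] - wb[ok]
        if np.allclose(d, d[0]):
            t_stat, p = (0.0, 1.0) if np.allclose(d, 0) else (np.inf, 0.0)
        else:
            t_stat, p = sps.ttest_rel(wa[ok], wb[ok])
        rows.append({
            "window_start": edges[i0],
            "window_end": edges[i0 + bins_per_win],
            "mean_diff": float(np.mean(d)),
            "t": float(t_stat),
            "p": float(p),
            "n": int(ok.sum()),
        })
    table = pd.DataFrame(rows)
    runs: dict[float, list[tuple[float, float]]] = {}
    for alpha in alphas:
        runs[alpha] = []
        if len(table):
            mask = table["p"].to_numpy() < alpha
            for i, j in find_runs(mask, run_len):
                runs[alpha].append(
                    (float(table["window_start"].iloc[i]),
                     float(table["window_end"].iloc[j - 1]))
                )
    return SlidingComparison(table=table, runs=runs, window_s=window_s,
                             step_s=step_s, run_len=run_len)


# --------------------------------------------------------------------------
# permutation ROC / AUC

@dataclass
class AUCResult:
    auc: float
    p: float
    n_perm: int
    n_pos: int
    n_neg: int
    alpha: float
    significant: bool
    skipped: bool = False
    reason: str | None = None


def mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC = P(pos > neg) + 0.5 P(pos = neg), via midranks."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def _perm_aucs(
    values: np.ndarray, n_pos: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """AUCs under random reassignment of the positive label.  Only ranks
    matter, so each permutation is a rank-sum over a random subset."""
    ranks = sps.rankdata(values)
    n = len(values)
    # argsort of uniforms = a uniformly random permutation per row
    order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_pos]
    sums = ranks[order].sum(axis=1)
    n_neg = n - n_pos
    return (sums - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def permutation_auc_pvalue(
    values: np.ndarray,
    labels: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Observed AUC and its two-sided label-shuffle permutation p-value."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    auc = mann_whitney_auc(values[labels], values[~labels])
    perm = _perm_aucs(values, n_pos, n_perm, rng)
    obs_dev = abs(auc - 0.5)
    p = (1.0 + np.sum(np.abs(perm - 0.5) >= obs_dev - 1e-12)) / (1.0 + n_perm)
    return auc, float(p)


def sliding_auc(
    window_rates: np.ndarray,
    labels: np.ndarray,
    window_starts: np.ndarray,
    n_perm: int = 10000,
    alpha: float = 0.001,
    rng: np.random.Generator | None = None,
    min_per_class: int = 3,
) -> pd.DataFrame:
    """ROC discrimination per sliding window.

    ``window_rates`` is (trials x windows), NaN marking censored cells; the
    same trial-label shuffles are applied to every window.  Returns one row
    per window with the AUC and its two-sided permutation p-value.
    """
    rng = np.random.default_rng() if rng is None else rng
    rates = np.asarray(window_rates, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    rows = []
    for j, w0 in enumerate(np.asarray(window_starts, dtype=float)):
        col = rates[:, j]
        ok = ~np.isnan(col)
        lab = labels[ok]
        n_pos, n_neg = int(lab.sum()), int((~lab).sum())
        if n_pos < min_per_class or n_neg < min_per_class:
            rows.append({"window_start": w0, "auc": np.nan, "p": np.nan,
                         "n_pos": n_pos, "n_neg": n_neg, "significant": False})
            continue
        auc, p = permutation_auc_pvalue(col[ok], lab, n_perm, rng)
        rows.append({"window_start": w0, "auc": auc, "p": p,
                     "n_pos": n_pos, "n_neg": n_neg, "significant": p < alpha})
    return pd.DataFrame(rows)


def lick_discrimination_auc(
    rates: np.ndarray,
    lick_labels: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    min_class_frac: float = 0.1,
) -> AUCResult:
    """Lick vs no-lick discrimination from post-fixation-exit activity
    ([0, 500] ms window rates), one session x trial type at a time.

    The session cell is skipped unless lick and no-lick trials each make up
    at least ``min_class_frac`` of the trials.
    """
    rng = np.random.default_rng() if rng is None else rng
    rates = np.asarray(rates, dtype=float)
    labels = np.asarray(lick_labels, dtype=bool)
    ok = ~np.isnan(rates)
    rates, labels = rates[ok], labels[ok]
    n = len(rates)
    n_pos = int(labels.sum())
    n_neg = n - n_pos
    if n == 0 or min(n_pos, n_neg) < min_class_frac * n or min(n_pos, n_neg) == 0:
        return AUCResult(
            auc=np.nan, p=np.nan, n_perm=n_perm, n_pos=n_pos, n_neg=n_neg,
            alpha=alpha, significant=False, skipped=True,
            reason=f"class balance below {min_class_frac:.0%}",
        )
    auc, p = permutation_auc_pvalue(rates, labels, n_perm, rng)
    return AUCResult(auc=auc, p=p, n_perm=n_perm, n_pos=n_pos, n_neg=n_neg,
                     alpha=alpha, significant=p < alpha)


# --------------------------------------------------------------------------
# Pearson correlations (RPE analyses)

@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    scope: str = "per_session"


def pearson_corr(x, y, scope: str = "per_session") -> CorrelationResult:
    """Pearson correlation; requires at least three complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    r, p = sps.pearsonr(x[ok], y[ok])
    return CorrelationResult(r=float(r), p=float(p), n=int(ok.sum()), scope=scope)


def single_trial_rpe_correlations(
    episode_table: pd.DataFrame,
    d2: int,
    min_nonrewarded: int = 50,
) -> pd.DataFrame:
    """Per-session correlation between single-trial evaluation and outcome
    responses, the single-trial signature of reward-prediction-error coding.

    ``episode_table`` needs the columns session, label, evaluation, outcome.
    Rewarded licks (light licks) are analyzed in pre-D2 sessions, where the
    light-onset response has not yet developed; non-rewarded licks (catch
    licks and no-fixation licks pooled) in sessions with at least
    ``min_nonrewarded`` such trials.
    """
    rows = []
    for session, g in episode_table.groupby("session"):
        rew = g[g["label"] == "light_lick"]
        if session < d2 and len(rew.dropna(subset=["evaluation", "outcome"])) >= 3:
            c = pearson_corr(rew["evaluation"], rew["outcome"], scope="single_trial")
            rows.append({"session": session, "group": "rewarded",
                         "r": c.r, "p": c.p, "n": c.n, "included": True})
        else:
            rows.append({"session": session, "group": "rewarded",
                         "r": np.nan, "p": np.nan, "n": len(rew),
                         "included": False})
        non = g[g["label"].isin(["catch_lick", "no_fixation_lick"])].dropna(
            subset=["evaluation", "outcome"]
        )
        if len(non) >= min_nonrewarded:
            c = pearson_corr(non["evaluation"], non["outcome"], scope="single_trial")
            rows.append({"session": session, "group": "non_rewarded",
                         "r": c.r, "p": c.p, "n": c.n, "included": True})
        else:
            rows.append({"session": session, "group": "non_rewarded",
                         "r": np.nan, "p": np.nan, "n": len(non),
                         "included": False})
    return pd.DataFrame(rows)


def quartile_summary(
    evaluation: np.ndarray, outcome: np.ndarray
) -> pd.DataFrame:
    """Sort trials by evaluation-response amplitude and summarize the four
    quartiles (plot-ready analogue of the quartile-trace panel)."""
    ev = np.asarray(evaluation, dtype=float)
    out = np.asarray(outcome, dtype=float)
    ok = ~np.isnan(ev) & ~np.isnan(out)
    ev, out = ev[ok], out[ok]
    if len(ev) < 4:
        raise ValueError("need at least 4 trials for quartiles")
    order = np.argsort(ev)
    quartiles = np.array_split(order, 4)
    rows = []
    for q, idx in enumerate(quartiles, start=1):
        rows.append({
            "quartile": q,
            "n": len(idx),
            "mean_evaluation": float(np.mean(ev[idx])),
            "mean_outcome": float(np.mean(out[idx])),
        })
    return pd.DataFrame(rows)
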