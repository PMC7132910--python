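"""Conditioned sniff-response analysis.

The behavioral readout of tone-odor learning is the nasal inhalation
evoked by a tone: its volume (time integral of inspiratory airflow over
the first post-tone inhalation), normalized by baseline breathing into
nvu (normalized sniff volume units, sniff volume divided by baseline
inhalation volume).  This module extracts sniff volumes from airflow
traces, normalizes them, applies the 3-SD participant outlier rule,
builds the night learning curve with its block-bin contrast, and runs
the morning retention comparison (paired t-test CSu vs CSp, with the
novel tone reported descriptively).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SNIFF_COLUMNS = ["participant_id", "session", "condition", "block",
                 "repetition", "volume_raw", "volume_nvu"]


# ---------------------------------------------------------------------------
# Volume extraction from airflow
# ---------------------------------------------------------------------------

def detect_inhalations(airflow: np.ndarray, fs: float,
                       min_duration_s: float = 0.2) -> list[tuple[int, int, float]]:
    """All inspiratory lobes in a trace: (start, stop) samples and volume (L).

    A lobe is a maximal run of positive flow lasting at least
    ``min_duration_s``; volume integrates flow (L/min) over time, hence
    the /60.
    """
    mask = np.asarray(airflow) > 0
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(np.int8), [0]))))
    out = []
    for s, e in zip(idx[::2], idx[1::2]):
        if (e - s) / fs >= min_duration_s:
            out.append((int(s), int(e), float(airflow[s:e].sum() / fs / 60.0)))
    return out


def sniff_volume(airflow: np.ndarray, fs: float, onset_s: float = 0.0,
                 max_latency_s: float = 10.0,
                 min_duration_s: float = 0.2) -> float:
    """Volume of the first inhalation beginning after ``onset_s``.

    Returns NaN (missing value) if no inspiratory lobe of at least
    ``min_duration_s`` starts within ``max_latency_s`` of the onset.
    """
    start = int(round(onset_s * fs))
    for s, e, vol in detect_inhalations(airflow, fs, min_duration_s):
        if s >= start and (s - start) / fs <= max_latency_s:
            return vol
    return float("nan")


def normalize_retention(volumes: np.ndarray, baseline_volumes: np.ndarray,
                        n_baseline: int = 15) -> np.ndarray:
    """nvu = sniff volume / mean of the last ``n_baseline`` baseline inhalations."""
    base = np.asarray(baseline_volumes, float)
    if base.size < n_baseline:
        raise ValueError(
            f"need >= {n_baseline} baseline inhalations, got {base.size}")
    denom = float(base[-n_baseline:].mean())
    if denom <= 0:
        raise ValueError("baseline inhalation volume is zero")
    return np.asarray(volumes, float) / denom


def night_nvu(airflow: np.ndarray, fs: float, onsets_s: np.ndarray,
              n_baseline: int = 15) -> np.ndarray:
    """Per-trial night nvu against the 15 inhalations preceding each tone.

    The original protocol defines normalization explicitly only for the
    retention session; for night trials each sniff is divided by the
    mean of the 15 inhalations completed before its own tone onset
    (local baseline), keeping the measure robust to slow drifts in
    breathing depth.
    """
    lobes = detect_inhalations(airflow, fs)
    starts = np.array([s for s, _, _ in lobes])
    vols = np.array([v for _, _, v in lobes])
    out = np.full(len(onsets_s), np.nan)
    for i, onset in enumerate(np.asarray(onsets_s, float)):
        onset_idx = int(round(onset * fs))
        v = sniff_volume(airflow, fs, onset)
        prior = vols[starts < onset_idx]
        if np.isnan(v) or prior.size < n_baseline:
            continue
        out[i] = v / prior[-n_baseline:].mean()
    return out


# ---------------------------------------------------------------------------
# Participant-level outlier rule
# ---------------------------------------------------------------------------

def exclude_outlier_participants(mean_nvu: pd.Series, k: float = 3.0
                                 ) -> tuple[pd.Series, pd.Series]:
    """Single-pass 3-SD rule on per-participant mean nvu.

    Participants whose mean deviates from the group mean by more than
    ``k`` group SDs (leave-one-in: statistics computed over everyone,
    one pass, no re-iteration) are dropped.  Returns (kept, dropped).
    """
    if len(mean_nvu) < 3:
        raise ValueError("outlier rule needs at least 3 participants")
    mu = mean_nvu.mean()
    sd = mean_nvu.std(ddof=1)
    if not np.isfinite(k) or sd == 0:
        return mean_nvu, mean_nvu.iloc[0:0]
    bad = (mean_nvu - mu).abs() > k * sd
    return mean_nvu[~bad], mean_nvu[bad]


# ---------------------------------------------------------------------------
# Night learning curve
# ---------------------------------------------------------------------------

@dataclass
class LearningCurveResult:
    curve: pd.DataFrame            # repetition x condition mean nvu
    contrast: pd.DataFrame         # per-participant late-bin minus early-bin diff
    statistic: float | None
    p_value: float | None
    n: int
    status: str = "ok"

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "p_value": self.p_value,
                "n": self.n, "status": self.status}


def learning_curve(table: pd.DataFrame, early_bin=(1, 2), late_bin=(4, 5),
                   max_repetition: int = 5, test: str = "wilcoxon"
                   ) -> LearningCurveResult:
    """Night learning curve and the late-vs-early block-bin contrast.

    ``table`` holds one row per non-reinforced night trial with columns
    participant_id, condition, repetition (per-condition presentation
    index 1..5, truncated upstream at the first arousal) and volume_nvu.
    The curve is the mean nvu per repetition per condition; the contrast
    compares per-participant mean (CSp - CSu) over repetitions 4-5
    against repetitions 1-2 with a Wilcoxon signed-rank test (``test`` =
    "ttest" switches to a paired t).
    """
    night = table[(table["session"] == "night")
                  & (table["repetition"] <= max_repetition)].copy()
    night = night.dropna(subset=["volume_nvu"])
    curve = (night.groupby(["repetition", "condition"])["volume_nvu"]
             .mean().unstack("condition"))

    diffs = (night.pivot_table(index=["participant_id", "repetition"],
                               columns="condition", values="volume_nvu")
             .reindex(columns=["CSp", "CSu"]))
    diffs["d"] = diffs["CSp"] - diffs["CSu"]
    per = diffs.reset_index()

    def bin_mean(lo, hi):
        sel = per[(per["repetition"] >= lo) & (per["repetition"] <= hi)]
        return sel.groupby("participant_id")["d"].mean()

    early = bin_mean(*early_bin)
    late = bin_mean(*late_bin)
    both = pd.DataFrame({"early": early, "late": late}).dropna()
    contrast = (both["late"] - both["early"]).rename("late_minus_early")
    if len(both) < 2:
        return LearningCurveResult(curve=curve, contrast=contrast.to_frame(),
                                   statistic=None, p_value=None, n=len(both),
                                   status="skipped: <2 participants with both bins")
    if test == "wilcoxon":
        if np.allclose(contrast, 0):
            stat, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(contrast, zero_method="wilcox",
                                 alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
    elif test == "ttest":
        res = stats.ttest_rel(both["late"], both["early"])
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return LearningCurveResult(curve=curve, contrast=contrast.to_frame(),
                               statistic=stat, p_value=p, n=len(both))


# ---------------------------------------------------------------------------
# Retention session
# ---------------------------------------------------------------------------

@dataclass
class RetentionResult:
    means: dict[str, float]
    t: float
    df: int
    p: float
    n: int
    outliers: list[str]

    def to_dict(self) -> dict:
        return {"means": self.means, "t": self.t, "df": self.df, "p": self.p,
                "n": self.n, "outliers": self.outliers}


def retention_test(table: pd.DataFrame, outlier_k: float = 3.0) -> RetentionResult:
    """Morning retention comparison: paired t-test of CSu vs CSp mean nvu.

    Participants failing the 3-SD outlier rule (on their grand-mean nvu)
    are excluded first.  The novel-tone mean is reported descriptively.
    Two-sided p; df = n - 1.
    """
    ret = table[table["session"] == "retention"].dropna(subset=["volume_nvu"])
    per = ret.pivot_table(index="participant_id", columns="condition",
                          values="volume_nvu", aggfunc="mean")
    if len(per) < 3:
        raise ValueError("retention test needs at least 3 participants")
    kept, dropped = exclude_outlier_participants(per.mean(axis=1), k=outlier_k)
    per = per.loc[kept.index]
    pair = per.dropna(subset=["CSu", "CSp"])
    n = len(pair)
    if np.allclose(pair["CSu"], pair["CSp"]):
        t, p = 0.0, 1.0
    else:
        res = stats.ttest_rel(pair["CSu"], pair["CSp"])
        t, p = float(res.statistic), float(res.pvalue)
    means = {c: float(per[c].mean()) for c in per.columns}
    return RetentionResult(means=means, t=t, df=n - 1, p=p, n=n,
                           outliers=list(dropped.index))


def plot_learning_curve(result: LearningCurveResult, path=None):
    """Night learning curve: mean nvu per non-reinforced repetition."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    for cond, color in (("CSp", "#d66"), ("CSu", "#888")):
        if cond in result.curve.columns:
            ax.plot(result.curve.index, result.curve[cond], "o-",
                    color=color, label=cond)
    ax.set_xlabel("non-reinforced repetition")
    ax.set_ylabel("sniff volume (nvu)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_retention(result: RetentionResult, path=None):
    """Retention-session bars: mean nvu for CSp, novel tone, and CSu."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [c for c in ("CSp", "novel", "CSu") if c in result.means]
    fig, ax = plt.subplots(figsize=(3.2, 3))
    ax.bar(order, [result.means[c] for c in order],
           color=["#d66", "#6a6", "#888"][: len(order)])
    ax.set_ylabel("sniff volume (nvu)")
    ax.set_title(f"t({result.df}) = {result.t:.2f}, p = {result.p:.3f}",
                 fontsize=9)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def nonreinforced_repetitions(events: pd.DataFrame) -> pd.Series:
    """Per-condition presentation index (1-based) of non-reinforced night trials.

    Index aligned with ``events``; reinforced and non-night rows get 0.
    """
    rep = pd.Series(0, index=events.index)
    mask = (~events["reinforced"].astype(bool)) & (events["session"] == "night")
    for cond in events.loc[mask, "condition"].unique():
        sel = mask & (events["condition"] == cond)
        rep.loc[sel] = np.arange(1, sel.sum() + 1)
    return rep
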