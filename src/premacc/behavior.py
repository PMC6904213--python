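"""Behavioural analysis: outcome classes, points, summaries, staircase.

Outcome classes partition trials: a response at or before 150 ms after the
sensory change is premature; no response within the 2000 ms deadline is a
miss; otherwise the choice is scored correct/error against the target.
Correct responses earn 40 points plus a speed bonus that falls linearly
from 40 (at 150 ms) to 0 (at the deadline); everything else earns 0.

Summary conventions: accuracy is
correct/(correct+error) (misses and premature responses excluded from the
denominator), mean RT pools corrects and errors, conditional accuracy
functions use equal-count RT bins (8 for the gratings task, 6 for the dot
task) and premature responses with a recorded choice enter the earliest
bins.  Sequential grids cross the current foreperiod with the previous
trial's foreperiod.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import TaskConfig
from .stimgen import TrialRecord, schedule_to_frame

__all__ = [
    "classify_outcome",
    "score_points",
    "summarize",
    "BehaviouralSummary",
    "run_staircase",
]


def classify_outcome(trial: TrialRecord, config: TaskConfig | None = None) -> str:
    """Classify one trial as correct / error / premature / miss.

    ``rt`` is relative to the sensory change; negative RTs (responses
    during the foreperiod) are premature by construction.
    """
    config = config or TaskConfig()
    if trial.choice is None:
        return "miss"
    if trial.rt is None:
        raise ValueError(f"trial {trial.index}: choice without an RT")
    if trial.rt > config.deadline:
        raise ValueError(
            f"trial {trial.index}: rt {trial.rt} ms exceeds the {config.deadline} ms "
            "deadline but a choice was recorded"
        )
    if trial.rt <= config.premature_cutoff:
        return "premature"
    return "correct" if trial.choice == trial.target else "error"


def score_points(outcome: str, rt: float | None, config: TaskConfig | None = None) -> int:
    """Points for one trial: 40 + linear speed bonus if correct, else 0."""
    config = config or TaskConfig()
    if outcome != "correct":
        return 0
    lo, hi = config.premature_cutoff, config.deadline
    frac = (hi - min(max(rt, lo), hi)) / (hi - lo)
    return int(round(40 + 40 * frac))


def classify_and_score(trials: list[TrialRecord], config: TaskConfig | None = None) -> list[TrialRecord]:
    """Fill ``outcome`` and ``points`` in place for every trial."""
    config = config or TaskConfig()
    for t in trials:
        t.outcome = classify_outcome(t, config)
        t.points = score_points(t.outcome, t.rt, config)
    return trials


@dataclass
class BehaviouralSummary:
    """Per-foreperiod summaries plus CAF and sequential (FPn × FPn−1) grids."""

    by_foreperiod: pd.DataFrame          # mean_rt, accuracy, miss/premature rates, points
    caf: pd.DataFrame                    # foreperiod × rt-bin: bin-centre RT and accuracy
    rt_grid: pd.DataFrame                # FPn × FPn−1 mean RT
    accuracy_grid: pd.DataFrame          # FPn × FPn−1 accuracy
    miss_by_prev: pd.Series              # miss rate by FPn−1 on short-FPn trials
    premature_by_prev: pd.Series         # premature rate by FPn−1 on long-FPn trials


def _accuracy(df: pd.DataFrame) -> float:
    resolved = df[df["outcome"].isin(["correct", "error"])]
    if len(resolved) == 0:
        return np.nan
    return 100.0 * (resolved["outcome"] == "correct").mean()


def _correct_rate(df: pd.DataFrame) -> float:
    """Percentage of all trials correctly reported (misses/prematures count against)."""
    if len(df) == 0:
        return np.nan
    return 100.0 * (df["outcome"] == "correct").mean()


def _summary_row(df: pd.DataFrame) -> dict:
    responded = df[df["outcome"].isin(["correct", "error"])]
    return {
        "n": len(df),
        "mean_rt": responded["rt"].mean() if len(responded) else np.nan,
        "accuracy": _accuracy(df),
        "correct_rate": _correct_rate(df),
        "miss_rate": 100.0 * (df["outcome"] == "miss").mean(),
        "premature_rate": 100.0 * (df["outcome"] == "premature").mean(),
        "points_per_trial": df["points"].mean(),
    }


def _equal_count_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count bin index per value; ties broken by original order."""
    n = len(values)
    if n < n_bins:
        raise ValueError(f"{n} trials cannot fill {n_bins} bins")
    order = np.lexsort((np.arange(n), values))   # stable: value then index
    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    bins = np.empty(n, dtype=int)
    bins[order] = np.repeat(np.arange(n_bins), sizes)
    return bins


def conditional_accuracy(df: pd.DataFrame, n_bins: int) -> pd.DataFrame:
    """CAF per foreperiod: equal-count RT bins with bin-centre RT and accuracy.

    Uses every trial with a recorded choice (premature responses with a
    choice included; misses excluded).
    """
    rows = []
    for fp, sub in df[df["choice"].notna()].groupby("foreperiod"):
        sub = sub.reset_index(drop=True)
        bins = _equal_count_bins(sub["rt"].to_numpy(float), n_bins)
        for b in range(n_bins):
            sel = sub[bins == b]
            rows.append(
                {
                    "foreperiod": fp,
                    "rt_bin": b,
                    "rt_center": sel["rt"].mean(),
                    "accuracy": 100.0 * (sel["choice"] == sel["target"]).mean(),
                    "n": len(sel),
                }
            )
    return pd.DataFrame(rows)


def summarize(
    trials: list[TrialRecord] | pd.DataFrame,
    config: TaskConfig | None = None,
    caf_bins: int = 8,
) -> BehaviouralSummary:
    """Full behavioural summary (per-FP, CAF, sequential grids).

    ``caf_bins`` defaults to the gratings-task convention (8); pass 6 for
    the dot task.  Empty sequential cells are reported as NaN, not zero.
    """
    config = config or TaskConfig()
    df = trials if isinstance(trials, pd.DataFrame) else schedule_to_frame(trials)
    if df["outcome"].isna().any():
        raise ValueError("trials must be classified before summarising")

    by_fp = pd.DataFrame(
        {fp: _summary_row(sub) for fp, sub in df.groupby("foreperiod")}
    ).T.rename_axis("foreperiod")

    caf = conditional_accuracy(df, caf_bins)

    # sequential grids: the RT grid pools every recorded response (including
    # anticipations, whose RTs are near or before the sensory change) because
    # the sequential analysis is about response timing; the accuracy grid uses
    # the percentage of all trials correctly reported, so that anticipations
    # and misses register as failures of foreperiod calibration
    seq = df[df["prev_foreperiod"].notna()]
    fps = sorted(df["foreperiod"].unique())
    responded = seq[seq["choice"].notna()]
    rt_grid = responded.pivot_table(
        index="foreperiod", columns="prev_foreperiod", values="rt", aggfunc="mean"
    ).reindex(index=fps, columns=fps)
    acc_grid = seq.groupby(["foreperiod", "prev_foreperiod"]).apply(
        _correct_rate, include_groups=False
    ).unstack().reindex(index=fps, columns=fps)

    short_fp, long_fp = fps[0], fps[-1]
    short = seq[seq["foreperiod"] == short_fp]
    miss_by_prev = short.groupby("prev_foreperiod").apply(
        lambda g: 100.0 * (g["outcome"] == "miss").mean(), include_groups=False
    ).reindex(fps)
    long_ = seq[seq["foreperiod"] == long_fp]
    prem_by_prev = long_.groupby("prev_foreperiod").apply(
        lambda g: 100.0 * (g["outcome"] == "premature").mean(), include_groups=False
    ).reindex(fps)

    return BehaviouralSummary(
        by_foreperiod=by_fp,
        caf=caf,
        rt_grid=rt_grid,
        accuracy_grid=acc_grid,
        miss_by_prev=miss_by_prev,
        premature_by_prev=prem_by_prev,
    )


def run_staircase(
    observer,
    n_trials: int = 80,
    seed: int | np.random.Generator = 0,
    start_level: float = 0.5,
    step_down: float = 0.02,
    step_up: float = 0.02,
    bounds: tuple[float, float] = (0.0, 1.0),
) -> tuple[np.ndarray, float]:
    """2-down 1-up staircase over an 80-trial block.

    ``observer(level)`` maps difficulty level (higher = easier) to
    p(correct).  The level steps down after two consecutive correct
    responses and up after every error; the long-run accuracy converges to
    the 2-down-1-up asymptote (~70.7%).  Returns the level trajectory
    (length ``n_trials``) and the final level.
    """
    rng = np.random.default_rng(seed)
    level = float(start_level)
    streak = 0
    traj = np.empty(n_trials)
    for i in range(n_trials):
        traj[i] = level
        correct = rng.uniform() < observer(level)
        if correct:
            streak += 1
            if streak == 2:
                level = max(level - step_down, bounds[0])
                streak = 0
        else:
            level = min(level + step_up, bounds[1])
            streak = 0
    return traj, level
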