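"""Electrode-cluster selection and windowed amplitude/slope measurements.

The decision signals are measured on small electrode clusters chosen per
subject from broad candidate sets: the 4 channels with the most positive
grand-average pre-response amplitude for the centro-parietal positivity
(CPP) and the occipital SSVEP cluster, the 4 with the largest
lateralisation for Mu/Beta, and the 3 most negative per hemisphere for
the bilateral N2.  Per-trial measures are window means (amplitude) or
ordinary-least-squares line slopes:

==================  ======================= =========================
measure             window                  alignment
==================  ======================= =========================
pre-evidence amp    [−50, +50] ms           sensory change
pre-response amp    [−150, −50] ms          response
pre-evidence slope  [−250, +50] ms          sensory change
pre-response slope  [−500, −200] ms         response
N2 amplitude        [200, 300] ms           sensory change
==================  ======================= =========================

Trials beyond ±3 SD of the within-subject mean of the pre-response
measure are flagged (single pass); RT binning uses equal-count bins
within each foreperiod level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ElectrodeCluster",
    "CLUSTER_SIZES",
    "MEASUREMENT_WINDOWS",
    "select_electrode_cluster",
    "measure_window",
    "reject_outlier_trials",
    "bin_trials",
    "estimate_accumulation_onset",
    "build_measurement_table",
]

CLUSTER_SIZES = {"CPP/Pz": 4, "SSVEP/Oz": 4, "MB/C3": 4, "MB/C4": 4, "N2/P7": 3, "N2/P8": 3}

MEASUREMENT_WINDOWS = {
    "pre_evidence_amp": (-50.0, 50.0),      # re sensory change
    "pre_response_amp": (-150.0, -50.0),    # re response
    "pre_evidence_slope": (-250.0, 50.0),   # re sensory change
    "pre_response_slope": (-500.0, -200.0), # re response
    "n2_amp": (200.0, 300.0),               # re sensory change
}


@dataclass
class ElectrodeCluster:
    name: str
    candidates: list[str]
    selected: list[str]


def select_electrode_cluster(
    topography: pd.Series | dict,
    candidates: list[str],
    k: int,
    sign: str = "positive",
    name: str = "",
) -> ElectrodeCluster:
    """Pick the k candidate channels where the grand average is maximal.

    ``sign``: "positive" (CPP/SSVEP), "negative" (N2) or "absolute"
    (Mu/Beta lateralisation).  Ties break by channel label order.
    """
    topo = pd.Series(topography)
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} candidate channels")
    missing = [c for c in candidates if c not in topo.index]
    if missing:
        raise ValueError(f"topography does not cover candidates: {missing}")
    vals = topo[candidates]
    if sign == "negative":
        vals = -vals
    elif sign == "absolute":
        vals = vals.abs()
    elif sign != "positive":
        raise ValueError(f"unknown sign {sign!r}")
    order = sorted(candidates, key=lambda c: (-vals[c], c))
    return ElectrodeCluster(name=name, candidates=list(candidates), selected=order[:k])


def measure_window(
    waveforms: np.ndarray,
    times_ms: np.ndarray,
    window: tuple[float, float],
    mode: str = "amplitude",
) -> np.ndarray:
    """Window mean (amplitude) or OLS line slope (μV/ms) per trial.

    ``waveforms`` is (trials, samples) — or (samples,) for a single
    trace.  A window outside the epoch raises, naming the offending
    span; trials whose window lands in their NaN padding yield NaN.
    """
    w = np.atleast_2d(np.asarray(waveforms, dtype=float))
    lo, hi = window
    if lo < times_ms[0] - 1e-9 or hi > times_ms[-1] + 1e-9:
        raise ValueError(
            f"window [{lo}, {hi}] ms outside the epoch span "
            f"[{times_ms[0]:.0f}, {times_ms[-1]:.0f}] ms"
        )
    sel = (times_ms >= lo) & (times_ms <= hi)
    t = times_ms[sel]
    seg = w[:, sel]
    if mode == "amplitude":
        out = seg.mean(axis=1)
    elif mode == "slope":
        tc = t - t.mean()
        out = seg @ tc / (tc @ tc)          # normal equations for a line fit
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out if np.asarray(waveforms).ndim == 2 else float(out[0])


def reject_outlier_trials(values: np.ndarray, n_sd: float = 3.0) -> np.ndarray:
    """Flag values beyond ``n_sd`` SD of the mean (single pass, no cascade).

    NaN values are never flagged; zero variance flags nothing.
    """
    v = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(v)) < 3:
        raise ValueError("need at least 3 finite values")
    mu = np.nanmean(v)
    sd = np.nanstd(v, ddof=1)
    if sd == 0:
        return np.zeros(v.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        return np.abs(v - mu) > n_sd * sd


def bin_trials(
    trials: pd.DataFrame,
    by: str = "rt",
    n_bins: int = 6,
) -> pd.Series:
    """Assign bin indices per trial.

    ``by='rt'``: equal-count RT bins within each foreperiod level
    (6 bins for the gratings analyses, 3 for the dot task, 8/6 for
    conditional accuracy functions); ties break by trial order.
    ``by='prev_foreperiod'``: the three previous-foreperiod levels.
    """
    out = pd.Series(-1, index=trials.index, dtype=int)
    if by == "rt":
        if n_bins < 2:
            raise ValueError("rt mode needs n_bins >= 2")
        for _, sub in trials.groupby("foreperiod"):
            sub = sub[sub["rt"].notna()]
            if len(sub) < n_bins:
                raise ValueError(
                    f"foreperiod level with {len(sub)} trials cannot fill {n_bins} RT bins"
                )
            rts = sub["rt"].to_numpy(float)
            order = np.lexsort((np.arange(len(rts)), rts))
            sizes = np.full(n_bins, len(rts) // n_bins)
            sizes[: len(rts) % n_bins] += 1
            bins = np.empty(len(rts), dtype=int)
            bins[order] = np.repeat(np.arange(n_bins), sizes)
            out.loc[sub.index] = bins
    elif by == "prev_foreperiod":
        levels = sorted(trials["prev_foreperiod"].dropna().unique())
        for i, lv in enumerate(levels):
            out.loc[trials["prev_foreperiod"] == lv] = i
    else:
        raise ValueError(f"unknown binning mode {by!r}")
    return out


def estimate_accumulation_onset(
    mean_waveform: np.ndarray,
    times_ms: np.ndarray,
    baseline_window: tuple[float, float] = (100.0, 550.0),
    n_sd: float = 2.0,
    min_run_ms: float = 100.0,
) -> float:
    """Threshold-crossing onset of the trial-averaged signal.

    The first time (after the baseline window) at which the waveform
    exceeds ``n_sd`` × the baseline SD and stays above it for
    ``min_run_ms``.  Returns NaN if it never does.
    """
    sel = (times_ms >= baseline_window[0]) & (times_ms <= baseline_window[1])
    base = mean_waveform[sel]
    thresh = np.nanmean(base) + n_sd * np.nanstd(base, ddof=1)
    dt = float(np.median(np.diff(times_ms)))
    run = max(int(round(min_run_ms / dt)), 1)
    after = times_ms > baseline_window[1]
    above = (mean_waveform > thresh) & after & np.isfinite(mean_waveform)
    count = 0
    for i, a in enumerate(above):
        count = count + 1 if a else 0
        if count >= run:
            return float(times_ms[i - run + 1])
    return float("nan")


def build_measurement_table(
    stim_waveforms: np.ndarray,
    stim_times_re_change: np.ndarray,
    resp_waveforms: np.ndarray | None,
    resp_times: np.ndarray | None,
    trials: pd.DataFrame,
    rt_bins: int = 6,
    pre_response_slope_window: tuple[float, float] = MEASUREMENT_WINDOWS["pre_response_slope"],
) -> pd.DataFrame:
    """Per-trial measurement table for one signal (e.g. the CPP cluster).

    ``stim_waveforms`` are change-aligned (trials × samples with
    ``stim_times_re_change`` in ms re the sensory change);
    ``resp_waveforms`` response-aligned.  Outlier flags use the
    pre-response amplitude (±3 SD, single pass).
    """
    tab = pd.DataFrame(index=trials.index)
    tab["pre_evidence_amp"] = measure_window(
        stim_waveforms, stim_times_re_change, MEASUREMENT_WINDOWS["pre_evidence_amp"], "amplitude"
    )
    tab["pre_evidence_slope"] = measure_window(
        stim_waveforms, stim_times_re_change, MEASUREMENT_WINDOWS["pre_evidence_slope"], "slope"
    )
    tab["n2_amp"] = measure_window(
        stim_waveforms, stim_times_re_change, MEASUREMENT_WINDOWS["n2_amp"], "amplitude"
    )
    if resp_waveforms is not None:
        tab["pre_response_amp"] = measure_window(
            resp_waveforms, resp_times, MEASUREMENT_WINDOWS["pre_response_amp"], "amplitude"
        )
        tab["pre_response_slope"] = measure_window(
            resp_waveforms, resp_times, pre_response_slope_window, "slope"
        )
        tab["outlier"] = reject_outlier_trials(tab["pre_response_amp"].to_numpy())
    else:
        tab["outlier"] = False
    tab["rt_bin"] = bin_trials(trials, by="rt", n_bins=rt_bins)
    tab["prev_fp_level"] = bin_trials(trials, by="prev_foreperiod")
    return tab
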