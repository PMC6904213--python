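"""End-to-end glue: dataset → cleaned epochs → cluster waveforms → measures.

These helpers chain the preprocessing, cluster-selection and measurement
steps the way the analyses use them, so tests, scripts and the CLI can run
the whole pipeline in a couple of calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import channels as chan
from .decision_metrics import (
    CLUSTER_SIZES,
    build_measurement_table,
    estimate_accumulation_onset,
    select_electrode_cluster,
)
from .preprocess import (
    ArtifactReport,
    EpochSet,
    epoch_and_baseline,
    filter_and_reference,
    reject_and_interpolate,
)
from .synthetic import SyntheticDataset

__all__ = [
    "preprocess_dataset",
    "align_to_change",
    "pre_response_topography",
    "select_cpp_cluster",
    "cpp_measurements",
    "onset_by_foreperiod",
]


def preprocess_dataset(
    ds: SyntheticDataset, reject: bool = True
) -> tuple[EpochSet, EpochSet, ArtifactReport | None]:
    """Filter/re-reference, epoch both alignments, and run artifact rules.

    Returns (stimulus-aligned epochs, response-aligned epochs, report).
    The response-aligned set keeps only trials retained in the
    stimulus-aligned pass (rejection is defined on the stimulus epoch).
    """
    info = ds.trial_table
    info.attrs["ch_names"] = ds.ch_names
    filtered = filter_and_reference(ds.eeg, ds.fs, n_valid=ds.n_samples)
    stim = epoch_and_baseline(
        filtered, ds.times_ms, ds.events, info, "stimulus", ds.fs, ds.n_samples, eog=ds.eog
    )
    resp = epoch_and_baseline(
        filtered, ds.times_ms, ds.events, info, "response", ds.fs, ds.n_samples, eog=ds.eog
    )
    report = None
    if reject:
        stim, report = reject_and_interpolate(stim)
        # propagate: a response epoch survives iff its stimulus epoch did
        stim_kept = set(stim.trial_info.index[stim.retained])
        resp.retained = np.array([i in stim_kept for i in resp.trial_info.index])
        resp.data[~resp.retained] = np.nan
    return stim, resp, report


def align_to_change(
    epochs: EpochSet, waveforms: np.ndarray, window_ms: tuple[float, float] = (-700.0, 500.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Re-align stimulus-aligned per-trial waveforms to the sensory change.

    Returns (trials × samples, times in ms re change).  The window must
    fit inside every trial's epoch (its left edge cannot reach before
    stimulus onset for the shortest foreperiod).
    """
    dt = 1000.0 / epochs.fs
    fps = epochs.trial_info["foreperiod"].to_numpy(float)
    if window_ms[0] < -fps.min():
        raise ValueError(
            f"window start {window_ms[0]} ms reaches before stimulus onset "
            f"for the {fps.min():.0f} ms foreperiod"
        )
    n_out = int(round((window_ms[1] - window_ms[0]) / dt))
    times = window_ms[0] + np.arange(n_out) * dt
    out = np.full((waveforms.shape[0], n_out), np.nan, dtype=float)
    for i, fp in enumerate(fps):
        start = int(round((fp + window_ms[0]) / dt))
        out[i] = waveforms[i, start:start + n_out]
    return out, times


def pre_response_topography(
    resp: EpochSet, window_ms: tuple[float, float] = (-150.0, -50.0)
) -> pd.Series:
    """Grand-average pre-response amplitude per channel (μV)."""
    sel = (resp.times_ms >= window_ms[0]) & (resp.times_ms <= window_ms[1])
    keep = resp.retained if resp.retained is not None else np.ones(resp.n_trials, bool)
    topo = np.nanmean(resp.data[keep][:, :, sel], axis=(0, 2))
    return pd.Series(topo, index=resp.ch_names)


def select_cpp_cluster(resp: EpochSet, n_candidates: int = 12):
    """Per-subject CPP cluster: 4 most positive candidates around Pz."""
    topo = pre_response_topography(resp)
    cands = chan.candidate_cluster("Pz", n_candidates)
    return select_electrode_cluster(topo, cands, CLUSTER_SIZES["CPP/Pz"], "positive", "CPP/Pz")


def cpp_measurements(
    stim: EpochSet, resp: EpochSet, rt_bins: int = 6
) -> tuple[pd.DataFrame, list[str]]:
    """Per-trial CPP measurement table on the selected cluster.

    Response-aligned measures are NaN for trials without a usable
    response epoch; rejected trials are dropped.
    """
    cluster = select_cpp_cluster(resp)
    keep = stim.retained if stim.retained is not None else np.ones(stim.n_trials, bool)
    wf_stim = stim.channel_data(cluster.selected)
    aligned, t_change = align_to_change(stim, wf_stim)

    wf_resp_full = np.full((stim.n_trials, len(resp.times_ms)), np.nan)
    stim_index = list(stim.trial_info.index)
    for j, idx in enumerate(resp.trial_info.index):
        if idx in stim_index:
            wf_resp_full[stim_index.index(idx)] = resp.channel_data(cluster.selected)[j]

    trials = stim.trial_info
    tab = build_measurement_table(
        aligned[keep], t_change, wf_resp_full[keep], resp.times_ms,
        trials[keep].reset_index(drop=True), rt_bins=rt_bins,
    )
    tab = pd.concat([trials[keep].reset_index(drop=True), tab], axis=1)
    return tab, cluster.selected


def pooled_onset_estimate(stim: EpochSet, cluster: list[str]) -> float:
    """Threshold-crossing onset of the all-trial average (ms re stimulus).

    Pools every retained trial (appropriate when the generative onset does
    not depend on the current foreperiod); the average is restricted to
    the span common to all epochs so each time point mixes the same trials.
    """
    import warnings

    keep = stim.retained if stim.retained is not None else np.ones(stim.n_trials, bool)
    wf = stim.channel_data(cluster)
    n_min = int(stim.n_valid.min())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_wf = np.nanmean(wf[keep, :n_min], axis=0)
    return estimate_accumulation_onset(mean_wf, stim.times_ms[:n_min])


def onset_by_foreperiod(
    stim: EpochSet, cluster: list[str]
) -> dict[float, float]:
    """Threshold-crossing accumulation-onset estimate per foreperiod (ms)."""
    import warnings

    keep = stim.retained if stim.retained is not None else np.ones(stim.n_trials, bool)
    wf = stim.channel_data(cluster)
    out = {}
    for fp, sub in stim.trial_info[keep].groupby("foreperiod"):
        sel = np.zeros(stim.n_trials, dtype=bool)
        sel[[list(stim.trial_info.index).index(i) for i in sub.index]] = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # NaN beyond short epochs
            mean_wf = np.nanmean(wf[sel & keep], axis=0)
        out[float(fp)] = estimate_accumulation_onset(mean_wf, stim.times_ms)
    return out
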