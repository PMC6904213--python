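"""EEG preprocessing: band-limiting, re-referencing, epoching, artifact rules.

The cleaning rules are threshold-based: a trial is rejected if the bipolar
vertical EOG exceeds 200 μV or any scalp channel exceeds 100 μV anywhere in
its stimulus-aligned epoch; a channel whose own artifact count exceeds 10%
of trials is interpolated from its nearest neighbours (at most 10% of
channels); a recording that still loses more than 40% of trials is flagged
for exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .channels import neighbor_weights

logger = logging.getLogger(__name__)

__all__ = [
    "EpochSet",
    "ArtifactReport",
    "filter_and_reference",
    "epoch_and_baseline",
    "reject_and_interpolate",
    "BASELINE_WINDOW_MS",
]

BASELINE_WINDOW_MS = (500.0, 550.0)   # post stimulus onset
RESPONSE_SPAN_MS = (-1000.0, 600.0)   # re response
EOG_THRESHOLD_UV = 200.0
CHANNEL_THRESHOLD_UV = 100.0
CHANNEL_BAD_TRIAL_FRAC = 0.10
MAX_INTERP_FRAC = 0.10
EXCLUSION_TRIAL_LOSS = 0.40


@dataclass
class EpochSet:
    """Trial-wise epochs with alignment metadata.

    ``data`` is (trials, channels, samples) in μV.  Stimulus-aligned
    epochs span [0, foreperiod + 2000] ms — trials with shorter
    foreperiods are NaN-padded beyond ``n_valid[i]`` samples.
    Response-aligned epochs span [−1000, +600] ms re response.
    """

    data: np.ndarray
    times_ms: np.ndarray
    alignment: str                       # {"stimulus", "response"}
    ch_names: list[str]
    fs: float
    trial_info: pd.DataFrame             # foreperiod, rt, ... (one row per epoch)
    n_valid: np.ndarray                  # valid samples per trial
    retained: np.ndarray | None = None   # bool mask after artifact rejection
    interpolated: list[str] = field(default_factory=list)
    eog: np.ndarray | None = None        # (trials, samples) bipolar VEOG

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times_ms=self.times_ms.copy(),
            alignment=self.alignment,
            ch_names=list(self.ch_names),
            fs=self.fs,
            trial_info=self.trial_info.copy(),
            n_valid=self.n_valid.copy(),
            retained=None if self.retained is None else self.retained.copy(),
            interpolated=list(self.interpolated),
            eog=None if self.eog is None else self.eog.copy(),
        )

    def channel_data(self, channels: list[str]) -> np.ndarray:
        """(trials, samples) average over a channel cluster."""
        import warnings

        idx = [self.ch_names.index(c) for c in channels]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # rejected trials are all-NaN
            return np.nanmean(self.data[:, idx, :], axis=1)


@dataclass
class ArtifactReport:
    """Outcome of the threshold-based artifact pass."""

    trial_flags: pd.DataFrame            # trial, rejected, cause in {"", "EOG", "channel"}
    channel_counts: pd.Series            # artifact count per channel (pre-interpolation)
    interpolated: list[str]
    n_input: int
    n_retained: int
    excluded: bool                       # trial loss > 40%

    @property
    def n_rejected(self) -> int:
        return self.n_input - self.n_retained


def _lowpass_kernel(fs: float, cutoff: float = 35.0, transition: float = 5.0) -> np.ndarray:
    numtaps = int(np.ceil(3.3 * fs / transition)) | 1   # odd symmetric -> zero phase
    return signal.firwin(numtaps, cutoff, fs=fs)


def filter_and_reference(
    eeg: np.ndarray,
    fs: float = 512.0,
    n_valid: np.ndarray | None = None,
    lowpass: float = 35.0,
    highpass: float = 0.05,
    detrend_mode: str | None = None,
) -> np.ndarray:
    """Band-limit (0.05–35 Hz), detrend and average-reference EEG.

    Accepts a continuous (channels, samples) array or trial-wise records
    (trials, channels, samples) with ``n_valid`` samples per trial.  The
    low-pass is a zero-phase windowed-sinc FIR (5 Hz transition); the
    high-pass a zero-phase 2nd-order Butterworth (a windowed-sinc at
    0.05 Hz would outlast any trial-wise record).  Detrending is linear on
    continuous input but constant (mean removal) on trial-wise records: a
    line fitted within a few seconds of data tips over slow event-related
    ramps and distorts them, which cannot happen when the fit spans a
    whole recording.
    """
    eeg = np.asarray(eeg)
    if eeg.ndim == 3:
        mode = detrend_mode or "constant"
        out = np.full_like(eeg, np.nan, dtype=np.float32)
        for i in range(eeg.shape[0]):
            n = int(n_valid[i]) if n_valid is not None else eeg.shape[2]
            out[i, :, :n] = filter_and_reference(
                eeg[i, :, :n], fs, lowpass=lowpass, highpass=highpass,
                detrend_mode=mode,
            )
        return out
    if not np.isfinite(eeg).all():
        raise ValueError("non-finite samples in EEG input")
    x = signal.detrend(eeg.astype(np.float64), axis=-1, type=detrend_mode or "linear")
    # the IIR high-pass only acts on records substantially longer than its
    # time constant; on trial-length records the linear detrend is the
    # whole drift correction (a 0.05 Hz filter is unobservable there)
    if eeg.shape[-1] > 2.0 * fs / highpass:
        sos = signal.butter(2, highpass, btype="highpass", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, x, axis=-1)
    kern = _lowpass_kernel(fs, lowpass)
    pad = len(kern) // 2
    xp = np.pad(x, [(0, 0), (pad, pad)], mode="reflect")
    x = signal.fftconvolve(xp, kern[None, :], mode="valid", axes=-1)
    x -= x.mean(axis=0, keepdims=True)   # average reference
    return x


def epoch_and_baseline(
    eeg: np.ndarray,
    times_ms: np.ndarray,
    events: pd.DataFrame,
    trial_info: pd.DataFrame,
    alignment: str = "stimulus",
    fs: float = 512.0,
    n_valid: np.ndarray | None = None,
    eog: np.ndarray | None = None,
) -> EpochSet:
    """Cut stimulus- or response-aligned epochs and baseline-correct them.

    ``eeg`` is (trials, channels, samples) raw trial records on a common
    time grid ``times_ms`` (re stimulus onset); ``events`` carries
    ``stimulus_sample``/``change_sample``/``response_sample`` per trial.
    Stimulus-aligned epochs span [0, foreperiod+2000] ms, response-aligned
    ones [−1000, +600] ms.  Every epoch has the mean over 500–550 ms post
    stimulus onset (computed in the stimulus frame) subtracted.  Trials
    whose epoch would leave the record are dropped with a logged cause.
    """
    dt = 1000.0 / fs
    n_trials, n_ch, n_samp = eeg.shape
    stim_idx = int(np.searchsorted(times_ms, -dt / 2))
    b0 = stim_idx + int(round(BASELINE_WINDOW_MS[0] / dt))
    b1 = stim_idx + int(round(BASELINE_WINDOW_MS[1] / dt))

    fps = trial_info["foreperiod"].to_numpy(float)
    if alignment == "stimulus":
        span_samp = int(round((fps.max() + 2000.0) / dt))
        out_times = np.arange(span_samp) * dt
    elif alignment == "response":
        pre = int(round(-RESPONSE_SPAN_MS[0] / dt))
        post = int(round(RESPONSE_SPAN_MS[1] / dt))
        span_samp = pre + post
        out_times = (np.arange(span_samp) - pre) * dt
    else:
        raise ValueError(f"unknown alignment {alignment!r}")

    kept, rows, data, eog_rows, valid = [], [], [], [], []
    for i in range(n_trials):
        limit = int(n_valid[i]) if n_valid is not None else n_samp
        baseline = np.nanmean(eeg[i, :, b0:b1], axis=1, keepdims=True)
        if alignment == "stimulus":
            n_epoch = int(round((fps[i] + 2000.0) / dt))
            start = stim_idx
        else:
            resp = int(events["response_sample"].iloc[i])
            if resp < 0:
                logger.info("trial %d dropped: no response for response alignment", i)
                continue
            n_epoch = span_samp
            start = resp - pre
        if start < 0 or start + n_epoch > limit:
            logger.info("trial %d dropped: epoch leaves the recorded span", i)
            continue
        seg = np.full((n_ch, span_samp), np.nan, dtype=np.float32)
        seg[:, :n_epoch] = eeg[i, :, start:start + n_epoch] - baseline
        data.append(seg)
        if eog is not None:
            e = np.full(span_samp, np.nan, dtype=np.float32)
            e[:n_epoch] = eog[i, start:start + n_epoch]
            eog_rows.append(e)
        valid.append(n_epoch)
        kept.append(i)
        rows.append(trial_info.iloc[i])

    ch_names = list(trial_info.attrs.get("ch_names", [])) or _default_names(n_ch)
    return EpochSet(
        data=np.stack(data),
        times_ms=out_times,
        alignment=alignment,
        ch_names=ch_names,
        fs=fs,
        trial_info=pd.DataFrame(rows).reset_index(drop=True),
        n_valid=np.asarray(valid),
        eog=np.stack(eog_rows) if eog is not None else None,
    )


def _default_names(n_ch: int) -> list[str]:
    from .channels import biosemi128_positions

    labels = sorted(biosemi128_positions())
    return labels if n_ch == len(labels) else [f"ch{i}" for i in range(n_ch)]


def reject_and_interpolate(
    epochs: EpochSet,
    eog: np.ndarray | None = None,
) -> tuple[EpochSet, ArtifactReport]:
    """Apply the threshold artifact rules to stimulus-aligned epochs.

    Channels whose own artifact count exceeds 10% of trials are
    interpolated first (distance-weighted nearest-neighbour average,
    capped at 10% of channels); trials are then rejected on the bipolar
    EOG (|EOG| > 200 μV) or any remaining channel exceeding 100 μV.
    Re-running on the cleaned output changes nothing.
    """
    import warnings

    out = epochs.copy()
    eog = eog if eog is not None else epochs.eog
    n_trials, n_ch, _ = out.data.shape

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN (already-rejected) rows
        over = np.nanmax(np.abs(out.data), axis=2) > CHANNEL_THRESHOLD_UV  # trials × channels
    counts = pd.Series(over.sum(axis=0), index=out.ch_names)

    bad = counts[counts > CHANNEL_BAD_TRIAL_FRAC * n_trials]
    cap = int(MAX_INTERP_FRAC * n_ch)
    to_interp = list(bad.sort_values(ascending=False, kind="stable").index)
    if len(to_interp) > cap:
        logger.warning(
            "%d channels qualify for interpolation; capping at %d", len(to_interp), cap
        )
        to_interp = to_interp[:cap]
    to_interp = [c for c in to_interp if c not in out.interpolated]
    for ch in to_interp:
        weights = neighbor_weights(
            ch, exclude=set(to_interp) | set(out.interpolated), available=out.ch_names
        )
        ci = out.ch_names.index(ch)
        acc = np.zeros_like(out.data[:, ci, :])
        for nb, w in weights.items():
            acc += w * out.data[:, out.ch_names.index(nb), :]
        out.data[:, ci, :] = acc
    out.interpolated = out.interpolated + to_interp

    interp_idx = [out.ch_names.index(c) for c in out.interpolated]
    scalp = np.ones(n_ch, dtype=bool)
    scalp[interp_idx] = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        chan_reject = (
            np.nanmax(np.abs(out.data[:, scalp, :]), axis=(1, 2)) > CHANNEL_THRESHOLD_UV
        )
        if eog is not None:
            eog_reject = np.nanmax(np.abs(eog), axis=1) > EOG_THRESHOLD_UV
        else:
            eog_reject = np.zeros(n_trials, dtype=bool)

    cause = np.where(eog_reject, "EOG", np.where(chan_reject, "channel", ""))
    rejected = eog_reject | chan_reject
    prev_retained = epochs.retained if epochs.retained is not None else np.ones(n_trials, dtype=bool)
    out.retained = prev_retained & ~rejected
    out.data[~out.retained] = np.nan

    n_retained = int(out.retained.sum())
    report = ArtifactReport(
        trial_flags=pd.DataFrame(
            {"trial": np.arange(n_trials), "rejected": rejected, "cause": cause}
        ),
        channel_counts=counts,
        interpolated=list(out.interpolated),
        n_input=n_trials,
        n_retained=n_retained,
        excluded=(1.0 - n_retained / n_trials) > EXCLUSION_TRIAL_LOSS,
    )
    return out, report
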