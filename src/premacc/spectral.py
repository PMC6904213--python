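"""STFT amplitude, SSVEP signal-to-noise ratio and Mu/Beta lateralisation.

Epochs are decomposed with overlapping 400 ms rectangular segments taken
at 50 ms intervals.  At 512 Hz a 400 ms window is 204.8 samples; segments
use 205 samples and the DFT is evaluated at the nominal 2.5 Hz bin grid
(0, 2.5, …, 35 Hz), which preserves the stated frequency resolution and
the integer-cycle property: one segment spans exactly 8 cycles at 20 Hz
and 10 at 25 Hz, so the two tag frequencies do not leak into each other.
DFT magnitude is divided by half the window length in samples, returning
a sinusoid's amplitude in signal units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EpochSet

__all__ = [
    "TimeFrequencyRep",
    "SSVEPTrace",
    "MuBetaTrace",
    "stft_amplitude",
    "ssvep_snr",
    "mu_beta_lateralisation",
    "SEGMENT_MS",
    "STEP_MS",
]

SEGMENT_MS = 400.0
STEP_MS = 50.0
FREQ_STEP_HZ = 1000.0 / SEGMENT_MS     # 2.5 Hz
MUBETA_BAND = (10.0, 30.0)
MUBETA_BASELINE_LABEL_MS = 550.0       # segment label used as Mu/Beta baseline
TAG_FREQS = (20.0, 25.0)


@dataclass
class TimeFrequencyRep:
    """Amplitude as (trials, channels, frequencies, segments), μV."""

    amplitude: np.ndarray
    freqs: np.ndarray                    # Hz, step 2.5
    seg_times_ms: np.ndarray             # segment median times, spaced 50 ms
    ch_names: list[str]
    trial_info: pd.DataFrame
    alignment: str


@dataclass
class SSVEPTrace:
    """Per-trial SSVEP SNR timecourses for target and non-target frequencies."""

    snr_target: np.ndarray               # (trials, segments)
    snr_nontarget: np.ndarray
    seg_times_ms: np.ndarray
    target_freq: np.ndarray              # per trial, Hz

    @property
    def d_ssvep(self) -> np.ndarray:
        return self.snr_target - self.snr_nontarget


@dataclass
class MuBetaTrace:
    """Baseline-corrected Mu/Beta per hemisphere and its lateralisation."""

    contra: np.ndarray                   # (trials, segments), μV
    ipsi: np.ndarray
    seg_times_ms: np.ndarray
    skipped: np.ndarray                  # trials without a recorded hand

    @property
    def lateralisation(self) -> np.ndarray:
        return self.contra - self.ipsi


def stft_amplitude(
    epochs: EpochSet,
    fmax: float = 35.0,
    channels: list[str] | None = None,
) -> TimeFrequencyRep:
    """Short-time Fourier amplitude with 400 ms segments every 50 ms.

    Rectangular (untapered) segments, matching the integer-cycle design;
    magnitude scaled by 2/N so a pure sinusoid of amplitude *a* measures
    *a* at its bin.  Segments are labelled by their median time; segments
    that would overrun a trial's valid span are NaN.
    """
    dt = 1000.0 / epochs.fs
    n_seg_samples = int(np.ceil(SEGMENT_MS / dt))   # 205 samples at 512 Hz
    if epochs.data.shape[2] < n_seg_samples:
        raise ValueError(
            f"epoch span ({epochs.data.shape[2]} samples) shorter than one "
            f"{SEGMENT_MS:.0f} ms segment ({n_seg_samples} samples)"
        )
    freqs = np.arange(0.0, fmax + FREQ_STEP_HZ / 2, FREQ_STEP_HZ)
    if channels is None:
        ch_idx = np.arange(len(epochs.ch_names))
        ch_names = list(epochs.ch_names)
    else:
        ch_idx = np.array([epochs.ch_names.index(c) for c in channels])
        ch_names = list(channels)

    t0 = epochs.times_ms[0]
    total_ms = epochs.times_ms[-1] - t0 + dt
    starts_ms = np.arange(0.0, total_ms - SEGMENT_MS + 1e-9, STEP_MS) + t0
    start_idx = np.round((starts_ms - t0) / dt).astype(int)
    seg_times = starts_ms + SEGMENT_MS / 2

    # DFT at the nominal bin grid: basis (freqs, n_seg_samples)
    n = np.arange(n_seg_samples)
    basis = np.exp(-2j * np.pi * freqs[:, None] * n[None, :] * dt / 1000.0)
    scale = 2.0 / n_seg_samples

    n_trials = epochs.data.shape[0]
    amp = np.full(
        (n_trials, len(ch_idx), len(freqs), len(starts_ms)), np.nan, dtype=np.float32
    )
    data = epochs.data[:, ch_idx, :]
    for s, i0 in enumerate(start_idx):
        seg = data[:, :, i0:i0 + n_seg_samples]
        ok = ~np.isnan(seg).any(axis=2)
        if not ok.any():
            continue
        spec = np.abs(np.einsum("tcn,fn->tcf", np.nan_to_num(seg), basis)) * scale
        amp[:, :, :, s] = np.where(ok[:, :, None], spec, np.nan)
    return TimeFrequencyRep(
        amplitude=amp,
        freqs=freqs,
        seg_times_ms=seg_times,
        ch_names=ch_names,
        trial_info=epochs.trial_info,
        alignment=epochs.alignment,
    )


def _adjacent_bins(freqs: np.ndarray, tag: float, n_side: int = 2) -> np.ndarray:
    """Indices of the immediately adjacent bins, excluding other tag
    frequencies and their harmonics."""
    i = int(np.argmin(np.abs(freqs - tag)))
    if abs(freqs[i] - tag) > 1e-9:
        raise ValueError(f"tag frequency {tag} Hz is not on the bin grid")
    excluded = set()
    for other in TAG_FREQS:
        if abs(other - tag) > 1e-9:
            for h in (other, 2 * other):
                j = np.nonzero(np.abs(freqs - h) < 1e-9)[0]
                excluded.update(j.tolist())
    cand = [j for j in range(max(i - n_side, 0), min(i + n_side + 1, len(freqs)))
            if j != i and j not in excluded]
    if not cand:
        raise ValueError(f"no adjacent bins left for {tag} Hz after exclusions")
    return np.asarray(cand)


def ssvep_snr(
    tfr: TimeFrequencyRep,
    cluster: list[str],
    target_freq_per_trial: np.ndarray,
) -> SSVEPTrace:
    """SSVEP SNR per trial and segment for the target and non-target tags.

    SNR = amplitude at the tag bin / mean amplitude of the immediately
    adjacent bins (2 per side, the other tag frequency excluded), after
    averaging over the occipital ``cluster`` channels.  The target is the
    contrast-increased grating's tag frequency.
    """
    target = np.asarray(target_freq_per_trial, dtype=float)
    bad = set(np.unique(target)) - set(TAG_FREQS)
    if bad:
        raise ValueError(
            f"target frequencies {sorted(bad)} are not tag frequencies on the "
            f"2.5 Hz bin grid ({TAG_FREQS})"
        )
    ch_idx = [tfr.ch_names.index(c) for c in cluster]
    amp = np.nanmean(tfr.amplitude[:, ch_idx], axis=1)  # trials × freqs × segments

    def snr_at(tag: float) -> np.ndarray:
        i = int(np.argmin(np.abs(tfr.freqs - tag)))
        adj = _adjacent_bins(tfr.freqs, tag)
        return amp[:, i, :] / amp[:, adj, :].mean(axis=1)

    snr = {f: snr_at(f) for f in TAG_FREQS}
    other = {TAG_FREQS[0]: TAG_FREQS[1], TAG_FREQS[1]: TAG_FREQS[0]}
    snr_t = np.empty_like(snr[TAG_FREQS[0]])
    snr_n = np.empty_like(snr_t)
    for f in TAG_FREQS:
        sel = target == f
        snr_t[sel] = snr[f][sel]
        snr_n[sel] = snr[other[f]][sel]
    return SSVEPTrace(
        snr_target=snr_t,
        snr_nontarget=snr_n,
        seg_times_ms=tfr.seg_times_ms,
        target_freq=target,
    )


def mu_beta_lateralisation(
    tfr: TimeFrequencyRep,
    hand_per_trial: np.ndarray,
    left_cluster: list[str],
    right_cluster: list[str],
    baseline_label_ms: float | None = MUBETA_BASELINE_LABEL_MS,
) -> MuBetaTrace:
    """Contralateral / ipsilateral Mu/Beta (10–30 Hz) and their difference.

    The band average spans 10–30 Hz excluding the 20 and 25 Hz tag bins
    (so motor and sensory activity do not mix).  Each hemisphere's trace
    is baseline-corrected against the stimulus-aligned segment labelled
    550 ms; lateralisation = contralateral − ipsilateral relative to the
    response hand.  Trials without a recorded hand are skipped (NaN).
    """
    band = (
        (tfr.freqs >= MUBETA_BAND[0])
        & (tfr.freqs <= MUBETA_BAND[1])
        & ~np.isin(tfr.freqs, TAG_FREQS)
    )

    def cluster_band(cluster: list[str]) -> np.ndarray:
        idx = [tfr.ch_names.index(c) for c in cluster]
        return np.nanmean(tfr.amplitude[:, idx][:, :, band, :], axis=(1, 2))

    left = cluster_band(left_cluster)    # left hemisphere, trials × segments
    right = cluster_band(right_cluster)
    if baseline_label_ms is not None:
        b = np.nonzero(np.abs(tfr.seg_times_ms - baseline_label_ms) < 1e-6)[0]
        if b.size == 0:
            raise ValueError(
                f"no segment labelled {baseline_label_ms} ms for Mu/Beta baseline"
            )
        left = left - left[:, b]
        right = right - right[:, b]

    hand = np.asarray(hand_per_trial, dtype=object)
    skipped = np.array([h not in ("left", "right") for h in hand])
    contra = np.full_like(left, np.nan)
    ipsi = np.full_like(left, np.nan)
    lh = hand == "left"
    rh = hand == "right"
    contra[lh], ipsi[lh] = right[lh], left[lh]
    contra[rh], ipsi[rh] = left[rh], right[rh]
    return MuBetaTrace(
        contra=contra, ipsi=ipsi, seg_times_ms=tfr.seg_times_ms, skipped=skipped
    )
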