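"""Ground-truth behaviour and forward-modelled EEG from a variable-onset accumulator.

The generative model is this package's own construct: the study it
emulates argues for, but does not formalise, premature evidence
accumulation whose onset is calibrated to recently experienced foreperiods.
Here that idea is made explicit:

* a single signed decision variable (DV) with absorbing bounds at ±bound
  starts integrating at ``t_on = onset_base + onset_prev_fp_gain *
  (prev_FP − mean FP) + jitter`` ms post stimulus onset — i.e. before the
  informative sensory change whenever ``t_on`` < foreperiod;
* from ``t_on`` the DV integrates drift (∝ momentary evidence) plus
  Gaussian diffusion noise, so pre-evidence excursions are noise- or
  stimulus-fluctuation-driven and produce premature responses, chance-level
  fast choices on long foreperiods, and sequential-foreperiod effects;
* EEG (128 BioSemi channels, 512 Hz, reference-free μV) is the sum of a
  centro-parietal component proportional to the chosen-bound-signed DV, tag
  -frequency oscillations over occipital scalp tracking grating contrast,
  effector-selective 10–30 Hz desynchronisation over motor scalp, a
  bilateral occipito-temporal transient after the sensory change, 1/f-like
  sensor noise, and injected blink / channel-pop artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .config import GenerativeParams, TaskConfig
from .stimgen import (
    GratingTimecourse,
    RDKFrameSet,
    TrialRecord,
    generate_rdk_frames,
    make_trial_schedule,
    render_grating_timecourse,
    schedule_from_frame,
    schedule_to_frame,
)
from .behavior import classify_and_score
from . import channels as chan

__all__ = [
    "AccumulatorPath",
    "SyntheticDataset",
    "simulate_trial_accumulator",
    "synthesize_eeg_trial",
    "generate_dataset",
]

FS = 512.0                      # EEG sampling rate, Hz
DT_MS = 1000.0 / FS
PRE_PAD_MS = 1200.0             # raw record span before stimulus onset
POST_PAD_MS = 600.0             # raw record span beyond stimulus offset


@dataclass
class AccumulatorPath:
    """Hidden truth of one simulated trial."""

    times_ms: np.ndarray         # re stimulus onset, EEG rate
    dv: np.ndarray               # signed decision variable (+ = rightward)
    t_on: float                  # accumulation onset, ms re stimulus onset
    crossing_ms: float | None    # bound crossing, ms re stimulus onset
    choice_sign: float           # +1 right / −1 left (sign of final DV if no crossing)
    degenerate: bool = False     # onset beyond the end of the trial


def evidence_trace_for_trial(
    trial: TrialRecord, config: TaskConfig, task: str = "gratings"
) -> np.ndarray:
    """Normalised momentary evidence (+ = rightward) at the EEG rate.

    Gratings task: zero during the foreperiod, ±1 after the contrast
    change.  (The dot task couples evidence to the rendered stimulus; see
    :func:`generate_dataset`.)
    """
    n = int(round((trial.foreperiod + config.evidence_duration) / DT_MS))
    t = np.arange(n) * DT_MS
    e = np.zeros(n)
    sign = 1.0 if trial.target == "right" else -1.0
    e[t >= trial.foreperiod] = sign
    return e


def simulate_trial_accumulator(
    trial: TrialRecord,
    evidence: np.ndarray,
    params: GenerativeParams,
    seed: int | np.random.Generator = 0,
    config: TaskConfig | None = None,
) -> tuple[TrialRecord, AccumulatorPath]:
    """Run the variable-onset accumulator for one trial.

    ``evidence`` is the signed momentary-evidence trace at the EEG rate
    covering [0, foreperiod + evidence duration] ms.  The trial record is
    updated in place with choice / rt / outcome / points; hidden truth
    (onset, crossing) lands in ``trial.extras``.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)
    n = len(evidence)
    t = np.arange(n) * DT_MS
    mean_fp = float(np.mean(config.foreperiods))
    prev = trial.prev_foreperiod if trial.prev_foreperiod is not None else mean_fp
    t_on = (
        params.onset_base
        + params.onset_prev_fp_gain * (prev - mean_fp)
        + params.onset_jitter_sd * rng.standard_normal()
    )
    t_end = trial.foreperiod + config.evidence_duration

    dv = np.zeros(n)
    degenerate = t_on >= t_end
    crossing_ms = None
    choice_sign = 0.0
    if not degenerate:
        i_on = max(int(np.ceil(t_on / DT_MS)), 0)
        m = n - i_on
        if m > 0:
            # the first step integrates only the partial interval [t_on, t_{i_on}]
            step_ms = np.full(m, DT_MS)
            step_ms[0] = max(i_on * DT_MS - t_on, 0.0) if t_on > 0 else DT_MS
            inc = params.drift_gain * evidence[i_on:] * step_ms
            if params.noise_sd > 0:
                inc = inc + params.noise_sd * np.sqrt(step_ms) * rng.standard_normal(m)
            path = params.start_bias + np.cumsum(inc)
            dv[i_on:] = path
            hits = np.nonzero(np.abs(path) >= params.bound)[0]
            if hits.size:
                j = int(hits[0])
                choice_sign = float(np.sign(path[j]))
                # linear interpolation to the exact bound crossing
                prev_v = path[j - 1] if j > 0 else params.start_bias
                num = choice_sign * params.bound - prev_v
                den = path[j] - prev_v
                fr = float(np.clip(num / den, 0.0, 1.0)) if den != 0 else 1.0
                t_prev = max(t_on, 0.0) if j == 0 else (i_on + j - 1) * DT_MS
                t_next = (i_on + j) * DT_MS
                crossing_ms = t_prev + fr * (t_next - t_prev)
                dv[i_on + j:] = choice_sign * params.bound
    if choice_sign == 0.0 and not degenerate:
        choice_sign = float(np.sign(dv[-1])) or 1.0

    rt_stim = None if crossing_ms is None else crossing_ms + params.motor_delay
    if rt_stim is not None and rt_stim - trial.foreperiod <= config.deadline:
        trial.choice = "right" if choice_sign > 0 else "left"
        trial.rt = rt_stim - trial.foreperiod
    else:
        trial.choice = None
        trial.rt = None
    classify_and_score([trial], config)
    trial.extras.update(
        {"t_on": t_on, "crossing_ms": crossing_ms, "degenerate_onset": degenerate}
    )
    path_obj = AccumulatorPath(
        times_ms=t, dv=dv, t_on=t_on, crossing_ms=crossing_ms,
        choice_sign=choice_sign, degenerate=degenerate,
    )
    return trial, path_obj


# ---------------------------------------------------------------------------
# forward EEG model


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], fs: float) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, unit variance, last axis = time."""
    n = shape[-1]
    spec = np.fft.rfft(rng.standard_normal(shape), axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(f, 1.0))
    out = np.fft.irfft(spec * shaping, n=n, axis=-1)
    out /= out.std(axis=-1, keepdims=True)
    return out


def _narrowband(rng: np.random.Generator, n: int, fs: float, band=(10.0, 30.0)) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise carrier."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n + 1024))[512:512 + n]
    return x / x.std()


def _trial_grid(foreperiod: float, config: TaskConfig) -> np.ndarray:
    total = PRE_PAD_MS + foreperiod + config.evidence_duration + POST_PAD_MS
    n = int(round(total / DT_MS))
    return np.arange(n) * DT_MS - PRE_PAD_MS


@dataclass
class _Maps:
    labels: list[str]
    cpp: np.ndarray
    oz: np.ndarray
    c3: np.ndarray
    c4: np.ndarray
    p7: np.ndarray
    p8: np.ndarray
    frontal: np.ndarray

    @classmethod
    def build(cls) -> "_Maps":
        labels, cpp = chan.gaussian_map("Pz")
        _, oz = chan.gaussian_map("Oz")
        _, c3 = chan.gaussian_map("C3", sigma=0.03)
        _, c4 = chan.gaussian_map("C4", sigma=0.03)
        _, p7 = chan.gaussian_map("P7", sigma=0.03)
        _, p8 = chan.gaussian_map("P8", sigma=0.03)
        # blink topography: strongest at the frontal pole, decaying backwards
        pos = chan.biosemi128_positions()
        y = np.array([pos[c][1] for c in labels])
        frontal = np.clip((y - y.min()) / (y.max() - y.min()), 0.0, 1.0) ** 3
        return cls(labels, cpp, oz, c3, c4, p7, p8, frontal)


def synthesize_eeg_trial(
    trial: TrialRecord,
    path: AccumulatorPath,
    stimulus: GratingTimecourse | RDKFrameSet | None,
    params: GenerativeParams,
    seed: int | np.random.Generator = 0,
    config: TaskConfig | None = None,
    maps: _Maps | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward-model one trial of EEG.

    Returns ``(eeg, eog, times_ms)``: eeg is (128, n_samples) μV on the
    grid [−1200, foreperiod + 2600] ms re stimulus onset, eog is the
    bipolar vertical EOG trace.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)
    maps = maps or _Maps.build()
    t = _trial_grid(trial.foreperiod, config)
    n = len(t)
    n_ch = len(maps.labels)

    # chosen-bound-signed DV, held through the motor delay then decaying
    dv_chosen = np.zeros(n)
    in_trial = (t >= 0) & (t < trial.foreperiod + config.evidence_duration)
    src = np.interp(t[in_trial], path.times_ms, path.dv * path.choice_sign)
    dv_chosen[in_trial] = src
    last = np.nonzero(in_trial)[0][-1]
    tail = np.arange(n - last - 1) * DT_MS
    dv_chosen[last + 1:] = dv_chosen[last] * np.exp(-tail / 200.0)

    # the centro-parietal build-up is positive-going irrespective of which
    # alternative wins (domain-general), so it follows |DV|
    dv_abs = np.zeros(n)
    dv_abs[in_trial] = np.interp(t[in_trial], path.times_ms, np.abs(path.dv))
    dv_abs[last + 1:] = dv_abs[last] * np.exp(-tail / 200.0)

    eeg = np.zeros((n_ch, n))
    eeg += params.cpp_gain * np.outer(maps.cpp, dv_abs)

    # SSVEP: tag-frequency oscillation scaled by momentary grating contrast;
    # the per-trial counterbalanced phase-reversal flag flips its polarity,
    # so phase-locked flicker components cancel in trial averages
    if isinstance(stimulus, GratingTimecourse):
        polarity = -1.0 if stimulus.phase_flag else 1.0
        for side, contrast in (("left", stimulus.contrast_left), ("right", stimulus.contrast_right)):
            freq = config.flicker_freqs[side]
            c = np.zeros(n)
            c[in_trial] = np.interp(t[in_trial], stimulus.times_ms, contrast)
            osc = polarity * c * np.sin(2 * np.pi * freq * t / 1000.0)
            eeg += params.ssvep_gain * np.outer(maps.oz, osc)

    # Mu/Beta: band-limited carrier with a DV-dependent envelope;
    # desynchronisation is strongest contralateral to the response hand
    dv_pos = np.clip(dv_chosen, 0.0, None)
    contra_map, ipsi_map = (maps.c4, maps.c3) if path.choice_sign < 0 else (maps.c3, maps.c4)
    env_contra = np.clip(params.mubeta_base - params.mubeta_dv_gain * dv_pos, 0.1, None)
    env_ipsi = np.clip(
        params.mubeta_base - params.mubeta_ipsi_frac * params.mubeta_dv_gain * dv_pos, 0.1, None
    )
    eeg += np.outer(contra_map, env_contra * _narrowband(rng, n, FS))
    eeg += np.outer(ipsi_map, env_ipsi * _narrowband(rng, n, FS))

    # bilateral occipito-temporal transient 200-300 ms after the sensory change
    pulse = -params.n2_gain * np.exp(-((t - trial.foreperiod - 250.0) ** 2) / (2 * 40.0 ** 2))
    eeg += np.outer(maps.p7 + maps.p8, pulse)

    eeg += params.sensor_noise_sd * _pink_noise(rng, (n_ch, n), FS)

    # artifacts
    eog = 40.0 * _pink_noise(rng, (n,), FS)
    n_blinks = rng.poisson(params.blink_rate)
    blink_times = rng.uniform(t[0] + 200.0, t[-1] - 200.0, size=n_blinks)
    for bt in blink_times:
        wave = np.clip(np.cos(np.pi * (t - bt) / 300.0), 0.0, None) ** 2
        wave[np.abs(t - bt) > 150.0] = 0.0
        eog += params.blink_amplitude * wave
        eeg += 0.5 * params.blink_amplitude * np.outer(maps.frontal, wave)
    pop_channels = []
    for _ in range(rng.poisson(params.channel_pop_rate)):
        ch = int(rng.integers(n_ch))
        start = int(rng.integers(n // 4, 3 * n // 4))
        eeg[ch, start:] += params.channel_pop_amplitude * rng.choice([-1.0, 1.0])
        pop_channels.append(maps.labels[ch])
    trial.extras.update(
        {
            "n_blinks": int(n_blinks),
            "blink_times_ms": ";".join(f"{bt:.0f}" for bt in blink_times),
            "pop_channels": ",".join(pop_channels),
        }
    )
    return eeg.astype(np.float32), eog.astype(np.float32), t


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class SyntheticDataset:
    """Trial table + raw trial-wise EEG records + event indices.

    ``eeg`` is (trials, 128, samples) on the grid of the longest
    foreperiod; trials with shorter foreperiods are valid up to
    ``n_samples[i]`` and NaN beyond.  Events are sample indices into that
    grid.
    """

    trials: list[TrialRecord]
    eeg: np.ndarray
    eog: np.ndarray
    times_ms: np.ndarray
    n_samples: np.ndarray
    ch_names: list[str]
    events: pd.DataFrame          # stimulus_sample, change_sample, response_sample
    fs: float
    config: TaskConfig
    params: GenerativeParams
    task: str
    paths: list[AccumulatorPath] = field(default_factory=list)
    frames: list[RDKFrameSet] | None = None

    @property
    def trial_table(self) -> pd.DataFrame:
        return schedule_to_frame(self.trials)

    def save(self, out_dir: str | Path) -> None:
        import h5py

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trial_table.to_csv(out / "trials.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        with h5py.File(out / "eeg.h5", "w") as f:
            f.create_dataset("eeg", data=self.eeg, compression="gzip")
            f.create_dataset("eog", data=self.eog, compression="gzip")
            f.create_dataset("times_ms", data=self.times_ms)
            f.create_dataset("n_samples", data=self.n_samples)
            f.attrs["fs"] = self.fs
            f.attrs["ch_names"] = json.dumps(self.ch_names)
            f.attrs["task"] = self.task
        (out / "config.json").write_text(
            json.dumps({"task": self.config.to_dict(), "generative": self.params.to_dict()}, indent=2)
        )

    @classmethod
    def load(cls, in_dir: str | Path) -> "SyntheticDataset":
        import h5py

        src = Path(in_dir)
        cfgs = json.loads((src / "config.json").read_text())
        cfg = TaskConfig(**{**cfgs["task"], "foreperiods": tuple(cfgs["task"]["foreperiods"])})
        params = GenerativeParams(**cfgs["generative"])
        trials = schedule_from_frame(pd.read_csv(src / "trials.csv"))
        events = pd.read_csv(src / "events.csv")
        with h5py.File(src / "eeg.h5", "r") as f:
            return cls(
                trials=trials,
                eeg=f["eeg"][()],
                eog=f["eog"][()],
                times_ms=f["times_ms"][()],
                n_samples=f["n_samples"][()],
                ch_names=json.loads(f.attrs["ch_names"]),
                events=events,
                fs=float(f.attrs["fs"]),
                config=cfg,
                params=params,
                task=str(f.attrs["task"]),
            )


def generate_dataset(
    config: TaskConfig | None = None,
    params: GenerativeParams | None = None,
    n_trials: int = 300,
    seed: int = 0,
    task: str = "gratings",
    with_eeg: bool = True,
    energy_coupled: bool = True,
) -> SyntheticDataset:
    """Generate a full synthetic dataset: schedule, behaviour, EEG.

    ``task='gratings'`` drives the accumulator with the contrast-difference
    step; ``task='rdk'`` renders dot frames and, when ``energy_coupled``,
    drives it with the opponent motion-energy trace of those frames
    (normalised so the mean post-onset energy has magnitude 1), so choices
    couple to pre-evidence stimulus fluctuations.  Fully reproducible from
    ``seed``; hidden-truth columns are retained in the trial table.
    """
    config = config or TaskConfig()
    params = params or GenerativeParams()
    rng = np.random.default_rng(seed)
    trials = make_trial_schedule(n_trials, config, seed=rng)
    maps = _Maps.build() if with_eeg else None

    stimuli: list = []
    evidences: list[np.ndarray] = []
    frames_list: list[RDKFrameSet] | None = [] if task == "rdk" else None
    if task == "gratings":
        for tr in trials:
            stim = render_grating_timecourse(tr, config, phase_flag=int(rng.integers(2)))
            stimuli.append(stim)
            evidences.append(evidence_trace_for_trial(tr, config, task))
    elif task == "rdk":
        from .motion_energy import MotionFilterParams, compute_motion_energy

        me_params = MotionFilterParams(resolution=0.1)
        raw_traces = []
        for tr in trials:
            frames = generate_rdk_frames(tr, config, seed=rng)
            frames_list.append(frames)
            stimuli.append(frames)
            if energy_coupled:
                raw_traces.append(compute_motion_energy(frames, me_params))
            else:
                # cheap frame-linked proxy: net coherent displacement per frame
                step_sign = 1.0 if tr.target == "right" else -1.0
                sig = frames.signal_mask.sum(axis=1).astype(float) * step_sign
                raw_traces.append(sig)
        # common normalisation: mean |post-onset evidence| across trials -> 1
        post_means = []
        for tr, frames, raw in zip(trials, frames_list, raw_traces):
            e = raw.energy if energy_coupled else raw
            post = e[frames.onset_frame + 30:]   # skip the filter rise after onset
            post_means.append(np.mean(post) * (1.0 if tr.target == "right" else -1.0))
        scale = float(np.mean(post_means))
        for tr, frames, raw in zip(trials, frames_list, raw_traces):
            e = (raw.energy if energy_coupled else raw) / scale
            frame_t = np.arange(frames.n_frames) * frames.frame_period_ms
            n = int(round((tr.foreperiod + config.evidence_duration) / DT_MS))
            t = np.arange(n) * DT_MS
            ev = np.interp(t, frame_t, e)
            if energy_coupled:
                # blank the filter warm-up transient
                ev[t < raw.valid_from * frames.frame_period_ms] = 0.0
            evidences.append(ev)
    else:
        raise ValueError(f"unknown task {task!r}")

    paths: list[AccumulatorPath] = []
    for tr, ev in zip(trials, evidences):
        _, path = simulate_trial_accumulator(tr, ev, params, seed=rng, config=config)
        paths.append(path)

    fp_max = max(config.foreperiods)
    times = _trial_grid(fp_max, config)
    n_max = len(times)
    n_ch = 128
    eeg = np.full((n_trials, n_ch, n_max), np.nan, dtype=np.float32) if with_eeg else np.zeros((n_trials, 0, 0), dtype=np.float32)
    eog = np.full((n_trials, n_max), np.nan, dtype=np.float32) if with_eeg else np.zeros((n_trials, 0), dtype=np.float32)
    n_samples = np.empty(n_trials, dtype=int)
    ev_rows = []
    stim_sample = int(round(PRE_PAD_MS / DT_MS))
    for i, (tr, path, stim) in enumerate(zip(trials, paths, stimuli)):
        if with_eeg:
            e, g, t = synthesize_eeg_trial(tr, path, stim, params, seed=rng, config=config, maps=maps)
            n_samples[i] = len(t)
            eeg[i, :, : len(t)] = e
            eog[i, : len(t)] = g
        else:
            n_samples[i] = len(_trial_grid(tr.foreperiod, config))
        resp = (
            int(round((PRE_PAD_MS + tr.foreperiod + tr.rt) / DT_MS))
            if tr.rt is not None
            else -1
        )
        ev_rows.append(
            {
                "trial": i,
                "stimulus_sample": stim_sample,
                "change_sample": int(round((PRE_PAD_MS + tr.foreperiod) / DT_MS)),
                "response_sample": resp,
            }
        )
    ch_names = maps.labels if with_eeg else [f"ch{i}" for i in range(n_ch)]
    return SyntheticDataset(
        trials=trials,
        eeg=eeg,
        eog=eog,
        times_ms=times,
        n_samples=n_samples,
        ch_names=list(ch_names),
        events=pd.DataFrame(ev_rows),
        fs=FS,
        config=config,
        params=params,
        task=task,
        paths=paths,
        frames=frames_list,
    )
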