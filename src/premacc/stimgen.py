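"""Trial schedules and stimulus streams for the two discrimination tasks.

Foreperiods (800/1200/1600 ms) are pseudorandomised balanced within blocks
of ``3*k`` trials.  The gratings task renders a per-frame contrast
timecourse for the two overlaid gratings flickering at 20 Hz (left-tilted)
and 25 Hz (right-tilted); the dot task renders per-frame dot coordinates of
a 100-dot random-dot kinematogram whose coherent signal switches on when
the foreperiod elapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TaskConfig

__all__ = [
    "TrialRecord",
    "GratingTimecourse",
    "RDKFrameSet",
    "make_trial_schedule",
    "render_grating_timecourse",
    "generate_rdk_frames",
    "schedule_to_frame",
    "schedule_from_frame",
]


@dataclass
class TrialRecord:
    """Design and behaviour of a single trial.

    ``rt`` is in ms relative to the sensory change (negative for responses
    during the foreperiod).  ``outcome`` is one of
    {"correct", "error", "premature", "miss"} once behaviour exists.
    """

    index: int
    foreperiod: float
    target: str                      # {"left", "right"}
    prev_foreperiod: float | None = None
    choice: str | None = None        # {"left", "right"} or None (no response)
    rt: float | None = None
    outcome: str | None = None
    points: int = 0
    extras: dict = field(default_factory=dict)


@dataclass
class GratingTimecourse:
    """Per-frame contrast and flicker state of the two overlaid gratings."""

    times_ms: np.ndarray             # frame onset times re stimulus onset
    contrast_left: np.ndarray
    contrast_right: np.ndarray
    flicker_left: np.ndarray         # on/off luminance modulation state (0/1)
    flicker_right: np.ndarray
    change_frame: int
    phase_flag: int = 0              # per-trial counterbalanced phase-reversal flag


@dataclass
class RDKFrameSet:
    """Per-frame dot coordinates (deg) of a random-dot kinematogram."""

    xy: np.ndarray                   # (n_frames, n_dots, 2)
    onset_frame: int                 # first frame with coherent signal
    direction: str                   # {"left", "right"}
    signal_mask: np.ndarray          # (n_frames, n_dots) bool, True = coherently displaced
    aperture_radius: float
    frame_period_ms: float

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    def mirrored(self) -> "RDKFrameSet":
        """Horizontal mirror image (x -> -x, direction flipped)."""
        xy = self.xy.copy()
        xy[..., 0] *= -1.0
        direction = "left" if self.direction == "right" else "right"
        return RDKFrameSet(
            xy=xy,
            onset_frame=self.onset_frame,
            direction=direction,
            signal_mask=self.signal_mask.copy(),
            aperture_radius=self.aperture_radius,
            frame_period_ms=self.frame_period_ms,
        )


def make_trial_schedule(
    n_trials: int,
    config: TaskConfig | None = None,
    seed: int | np.random.Generator = 0,
    balanced: bool = True,
) -> list[TrialRecord]:
    """Build a pseudorandom trial schedule (design fields only).

    In balanced mode each foreperiod occurs equally often, balanced within
    consecutive blocks of ``len(foreperiods)`` trials; targets are drawn
    left/right with equal probability.  ``prev_foreperiod`` is filled for
    trials 2..n.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)
    fps = np.asarray(config.foreperiods, dtype=float)
    k = len(fps)
    if balanced:
        if n_trials % k != 0:
            raise ValueError(
                f"n_trials={n_trials} not divisible by the {k} foreperiod levels "
                "in balanced mode"
            )
        blocks = [rng.permutation(fps) for _ in range(n_trials // k)]
        fp_seq = np.concatenate(blocks)
    else:
        fp_seq = rng.choice(fps, size=n_trials)
    targets = rng.choice(["left", "right"], size=n_trials)
    trials = []
    for i in range(n_trials):
        trials.append(
            TrialRecord(
                index=i,
                foreperiod=float(fp_seq[i]),
                target=str(targets[i]),
                prev_foreperiod=float(fp_seq[i - 1]) if i > 0 else None,
            )
        )
    return trials


def render_grating_timecourse(
    trial: TrialRecord, config: TaskConfig | None = None, phase_flag: int = 0
) -> GratingTimecourse:
    """Render the per-frame contrast/flicker timecourse of one gratings trial.

    Both gratings sit at ``baseline_contrast`` throughout the foreperiod;
    at the change the target steps up by ``contrast_delta`` while the
    non-target steps down by the same amount, for ``evidence_duration`` ms.
    Flicker is on-off luminance modulation at the tag frequency (left 20 Hz,
    right 25 Hz).
    """
    config = config or TaskConfig()
    delta = config.contrast_delta
    lo = config.baseline_contrast - delta
    hi = config.baseline_contrast + delta
    if not (0 < lo and hi < 1):
        raise ValueError("contrast_delta drives contrast outside (0, 1)")
    n = config.n_frames(trial.foreperiod)
    frame_ms = config.frame_period_ms
    times = np.arange(n) * frame_ms
    change_frame = int(round(trial.foreperiod * config.refresh_rate / 1000.0))

    c_left = np.full(n, config.baseline_contrast)
    c_right = np.full(n, config.baseline_contrast)
    if trial.target == "left":
        c_left[change_frame:] = hi
        c_right[change_frame:] = lo
    else:
        c_left[change_frame:] = lo
        c_right[change_frame:] = hi

    def onoff(freq: float) -> np.ndarray:
        frames_per_cycle = config.refresh_rate / freq
        phase = (np.arange(n) % frames_per_cycle) / frames_per_cycle
        return (phase < 0.5).astype(int)

    return GratingTimecourse(
        times_ms=times,
        contrast_left=c_left,
        contrast_right=c_right,
        flicker_left=onoff(config.flicker_freqs["left"]),
        flicker_right=onoff(config.flicker_freqs["right"]),
        change_frame=change_frame,
        phase_flag=phase_flag,
    )


def _uniform_in_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def generate_rdk_frames(
    trial: TrialRecord,
    config: TaskConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> RDKFrameSet:
    """Generate per-frame dot coordinates for one dot-motion trial.

    During the foreperiod every dot is repositioned uniformly at random
    within the aperture on each frame (0% coherence).  After the coherent
    onset, each dot is independently a signal dot with probability
    ``coherence``: signal dots are displaced by ``dot_speed / refresh_rate``
    in the signal direction (wrapping across the aperture), the rest are
    repositioned at random.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)
    n_frames = config.n_frames(trial.foreperiod)
    onset_frame = int(round(trial.foreperiod * config.refresh_rate / 1000.0))
    n_dots = config.n_dots
    radius = config.aperture_radius
    step = config.dot_speed / config.refresh_rate
    dx = step if trial.target == "right" else -step

    xy = np.empty((n_frames, n_dots, 2))
    signal_mask = np.zeros((n_frames, n_dots), dtype=bool)
    xy[0] = _uniform_in_disc(rng, n_dots, radius)
    for f in range(1, n_frames):
        if f < onset_frame:
            xy[f] = _uniform_in_disc(rng, n_dots, radius)
            continue
        sig = rng.uniform(size=n_dots) < config.coherence
        signal_mask[f] = sig
        new = _uniform_in_disc(rng, n_dots, radius)
        moved = xy[f - 1].copy()
        moved[:, 0] += dx
        # signal dots leaving the aperture wrap to the opposite edge of
        # their chord (re-entering at the same height)
        chord = np.sqrt(np.maximum(radius**2 - moved[:, 1] ** 2, 0.0))
        out = np.abs(moved[:, 0]) > chord
        moved[out, 0] -= np.sign(dx) * 2.0 * chord[out]
        xy[f] = np.where(sig[:, None], moved, new)
    return RDKFrameSet(
        xy=xy,
        onset_frame=onset_frame,
        direction=trial.target,
        signal_mask=signal_mask,
        aperture_radius=radius,
        frame_period_ms=config.frame_period_ms,
    )


# ---------------------------------------------------------------------------
# tabular I/O

_COLUMNS = [
    "index", "foreperiod", "prev_foreperiod", "target",
    "choice", "rt", "outcome", "points",
]


def schedule_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    """Trial records -> tidy DataFrame (one row per trial)."""
    rows = []
    for t in trials:
        row = {c: getattr(t, c) for c in _COLUMNS}
        row.update(t.extras)
        rows.append(row)
    return pd.DataFrame(rows)


def schedule_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    """Tidy DataFrame -> trial records; extra columns land in ``extras``."""
    trials = []
    for _, row in df.iterrows():
        extras = {c: row[c] for c in df.columns if c not in _COLUMNS}
        prev = row.get("prev_foreperiod")
        trials.append(
            TrialRecord(
                index=int(row["index"]),
                foreperiod=float(row["foreperiod"]),
                target=str(row["target"]),
                prev_foreperiod=None if pd.isna(prev) else float(prev),
                choice=None if pd.isna(row.get("choice")) else str(row["choice"]),
                rt=None if pd.isna(row.get("rt")) else float(row["rt"]),
                outcome=None if pd.isna(row.get("outcome")) else str(row["outcome"]),
                points=0 if pd.isna(row.get("points")) else int(row["points"]),
                extras=extras,
            )
        )
    return trials
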