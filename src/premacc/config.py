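"""Task and generative-model configuration objects.

``TaskConfig`` collects every stimulus/task constant of the two
discrimination tasks (overlaid flickering gratings; random-dot motion):
foreperiod set, flicker tag frequencies, contrast step, dot-field
parameters, response deadline and the premature-response cutoff.

``GenerativeParams`` parameterises the variable-onset accumulator and the
forward EEG model used by :mod:`premacc.synthetic`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

__all__ = ["TaskConfig", "GenerativeParams"]


@dataclass
class TaskConfig:
    """Stimulus and task constants shared by both experiments.

    Parameters
    ----------
    refresh_rate : float
        Monitor refresh rate in frames/s (100).
    foreperiods : tuple of float
        Foreperiod durations in ms ({800, 1200, 1600}); the delay between
        stimulus onset and the informative sensory change.
    evidence_duration : float
        Duration of the post-change evidence period in ms (2000).
    flicker_freqs : dict
        Flicker tag frequency per grating, Hz (left 20, right 25).
    baseline_contrast : float
        Contrast of both gratings during the foreperiod (0.50).
    contrast_delta : float
        Per-subject contrast step (titrated to 65-70% accuracy; group
        mean 0.055, range 0.02-0.07).
    n_dots, dot_diameter_px : int
        Random-dot field size (100 dots of 4 px).
    aperture_radius : float
        Aperture radius in degrees of visual angle (4 for the dot task,
        6 for the gratings task).
    coherence : float
        Fraction of dots displaced coherently per frame (titrated per
        subject; group mean 0.0742, range 0.03-0.12).
    dot_speed : float
        Coherent dot speed in deg/s. Not a task constant reported for the
        dot stimulus; default 5 deg/s, a conventional value.
    deadline : float
        Response deadline in ms relative to the sensory change (2000).
    premature_cutoff : float
        Responses at or before this time (ms re change) count as
        premature (150).
    """

    refresh_rate: float = 100.0
    foreperiods: tuple[float, ...] = (800.0, 1200.0, 1600.0)
    evidence_duration: float = 2000.0
    flicker_freqs: dict = field(default_factory=lambda: {"left": 20.0, "right": 25.0})
    baseline_contrast: float = 0.50
    contrast_delta: float = 0.055
    n_dots: int = 100
    dot_diameter_px: int = 4
    aperture_radius: float = 4.0
    coherence: float = 0.0742
    dot_speed: float = 5.0
    deadline: float = 2000.0
    premature_cutoff: float = 150.0

    def __post_init__(self) -> None:
        frame_ms = 1000.0 / self.refresh_rate
        for fp in self.foreperiods:
            if fp <= 0:
                raise ValueError(f"foreperiod {fp} must be positive")
            if abs(fp / frame_ms - round(fp / frame_ms)) > 1e-9:
                raise ValueError(
                    f"foreperiod {fp} ms is not a multiple of the frame period {frame_ms} ms"
                )
        if not 0 < self.coherence <= 1:
            raise ValueError("coherence must lie in (0, 1]")
        lo = self.baseline_contrast - self.contrast_delta
        hi = self.baseline_contrast + self.contrast_delta
        if not (0 < lo and hi < 1):
            raise ValueError(
                f"contrast step leaves (0, 1): baseline {self.baseline_contrast} "
                f"± delta {self.contrast_delta}"
            )

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.refresh_rate

    def n_frames(self, foreperiod: float) -> int:
        """Total stimulus frames for a trial with the given foreperiod."""
        total_ms = foreperiod + self.evidence_duration
        return int(round(total_ms * self.refresh_rate / 1000.0))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GenerativeParams:
    """Parameters of the variable-onset accumulator and EEG forward model.

    The behavioural core is a single signed decision variable (DV) with two
    absorbing bounds at ``±bound``.  Accumulation starts at an endogenous
    onset time

        t_on = onset_base + onset_prev_fp_gain * (prev_FP − mean FP) + jitter

    measured from stimulus onset, so the onset is recalibrated trial by
    trial toward the foreperiod the subject last experienced.  From t_on the
    DV integrates ``drift_gain * evidence(t) dt`` plus Gaussian increments
    of standard deviation ``noise_sd * sqrt(dt)``; evidence is zero during
    the foreperiod (gratings task) or the residual dot-motion fluctuation
    (dot task), so any pre-evidence excursion of the DV is noise- or
    stimulus-fluctuation-driven.  First crossing of a bound fixes the choice
    and RT = crossing time + ``motor_delay``.

    Units: evidence traces are normalised so that full post-change evidence
    has magnitude 1 a.u.; ``drift_gain`` is 1/(a.u.·ms), ``noise_sd`` is
    a.u./√ms, ``bound`` and ``start_bias`` are a.u.  EEG gains convert the
    DV / stimulus contrast into μV on fixed scalp maps.
    """

    onset_base: float = 800.0
    onset_prev_fp_gain: float = 1.0
    onset_jitter_sd: float = 50.0
    drift_gain: float = 0.0011
    noise_sd: float = 0.025
    bound: float = 1.0
    motor_delay: float = 100.0
    start_bias: float = 0.0

    # forward EEG model
    ssvep_gain: float = 4.0          # μV per unit contrast at the tag frequency
    cpp_gain: float = 8.0            # μV per unit DV on the centro-parietal map
    mubeta_base: float = 3.0         # μV baseline 10-30 Hz envelope
    mubeta_dv_gain: float = 1.5      # μV envelope reduction per unit chosen-DV
    mubeta_ipsi_frac: float = 0.5    # ipsilateral fraction of the DV-driven gain
    n2_gain: float = 5.0             # μV transient at the bilateral occipito-temporal sites
    sensor_noise_sd: float = 8.0     # μV broadband 1/f-like sensor noise
    blink_rate: float = 0.10         # expected blinks per trial
    blink_amplitude: float = 350.0   # μV at the EOG; frontal scalp scaled copy
    channel_pop_rate: float = 0.01   # expected single-channel step artifacts per trial
    channel_pop_amplitude: float = 150.0  # μV

    def __post_init__(self) -> None:
        if self.bound <= 0:
            raise ValueError("bound must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.motor_delay < 0:
            raise ValueError("motor_delay must be non-negative")
        for name in ("drift_gain", "ssvep_gain", "cpp_gain", "mubeta_dv_gain"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def to_dict(self) -> dict:
        return asdict(self)


TaskKind = Literal["gratings", "rdk"]
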