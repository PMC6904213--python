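import numpy as np
import pytest

from premacc.config import TaskConfig
from premacc.motion_energy import (
    MotionEnergyTrace,
    MotionFilterParams,
    compute_motion_energy,
    cumulative_motion_integral,
    rasterize_frames,
    split_by_integral_slope,
    _spatial_kernels,
    _temporal_kernels,
)
from premacc.stimgen import TrialRecord, generate_rdk_frames

COARSE = MotionFilterParams(resolution=0.1)


def _frames(coherence: float, seed: int, foreperiod: float = 800.0, target: str = "right"):
    cfg = TaskConfig(coherence=max(coherence, 1e-12))
    trial = TrialRecord(index=0, foreperiod=foreperiod, target=target)
    return generate_rdk_frames(trial, cfg, seed=seed)


class TestOpponentEnergy:
    def test_mirror_negates_trace(self):
        frames = _frames(0.25, seed=3)
        me = compute_motion_energy(frames, COARSE)
        me_m = compute_motion_energy(frames.mirrored(), COARSE)
        scale = np.abs(me.energy).max()
        np.testing.assert_allclose(me.energy, -me_m.energy, atol=1e-6 * scale)

    def test_zero_coherence_time_average_near_zero(self):
        # the trace is autocorrelated over the filter support, so the trial
        # is the unit of replication: average per-trial means over seeds
        trial_means = []
        for seed in range(6):
            frames = _frames(0.0, seed=seed, foreperiod=1600.0)
            me = compute_motion_energy(frames, COARSE)
            trial_means.append(me.energy[me.valid_from:].mean())
        trial_means = np.asarray(trial_means)
        sem = trial_means.std(ddof=1) / np.sqrt(len(trial_means))
        assert abs(trial_means.mean()) < 3 * sem + 1e-12

    def test_full_rightward_coherence_positive(self):
        frames = _frames(1.0, seed=5)
        me = compute_motion_energy(frames, COARSE)
        post = me.energy[frames.onset_frame + 30:]
        assert post.mean() > 0
        assert (post > 0).mean() > 0.95

    def test_monotone_in_coherence(self):
        means = []
        for coh in (0.0, 0.05, 0.25, 1.0):
            frames = _frames(coh, seed=11, foreperiod=1600.0)
            me = compute_motion_energy(frames, COARSE)
            means.append(me.energy[frames.onset_frame + 30:].mean())
        assert np.all(np.diff(means) > 0)

    def test_too_short_stimulus_raises(self):
        frames = _frames(0.5, seed=1)
        frames.xy = frames.xy[:10]
        with pytest.raises(ValueError, match="temporal"):
            compute_motion_energy(frames, COARSE)

    def test_deterministic(self):
        frames = _frames(0.25, seed=3)
        a = compute_motion_energy(frames, COARSE)
        b = compute_motion_energy(frames, COARSE)
        np.testing.assert_array_equal(a.energy, b.energy)

    def test_matches_bruteforce_oracle_on_toy_stimulus(self):
        """Direct correlation-sum oracle on a 32-frame toy volume.

        The oracle builds the four quadrature space-time filter responses
        by brute-force convolution sums (A = even×fast, B = even×slow,
        C = odd×fast, D = odd×slow), combines them into the two oriented
        pairs per direction and forms (R1² + R2²) − (L1² + L2²).
        Compared on interior pixels away from spatial edges.
        """
        p = MotionFilterParams(resolution=0.1, t_support=0.15, x_support=0.4)
        frames = _frames(1.0, seed=2)
        frames.xy = frames.xy[:32]
        vol = rasterize_frames(frames, p).astype(float)
        me = compute_motion_energy(frames, p)

        f_even, f_odd, gauss = _spatial_kernels(p)
        g_fast, g_slow = _temporal_kernels(p, frames.frame_period_ms)

        def filter_response(volume, fx, gy, gt):
            # brute-force causal filtering: out[t,y,x] = Σ v[t-i, y-j, x-k] gt[i] gy[j] fx[k]
            nt, ny, nx = volume.shape
            kt, ky, kx = len(gt), len(gy), len(fx)
            kern = gt[::-1, None, None] * gy[::-1, None] * fx[::-1]
            out = np.zeros_like(volume)
            for t in range(kt - 1, nt):
                for y in range(ky // 2, ny - ky // 2):
                    for x in range(kx // 2, nx - kx // 2):
                        patch = volume[
                            t - kt + 1: t + 1,
                            y - ky // 2: y + ky // 2 + 1,
                            x - kx // 2: x + kx // 2 + 1,
                        ]
                        out[t, y, x] = np.sum(patch * kern)
            return out

        # restrict to a small interior patch to keep the loops cheap
        sub = vol[:, 30:45, 30:45]
        A = filter_response(sub, f_even, gauss, g_fast)
        B = filter_response(sub, f_even, gauss, g_slow)
        C = filter_response(sub, f_odd, gauss, g_fast)
        D = filter_response(sub, f_odd, gauss, g_slow)
        R1, R2 = A + D, C - B
        L1, L2 = A - D, C + B
        opponent = (R1**2 + R2**2) - (L1**2 + L2**2)
        # algebraic identity: opponent energy == 4(AD − BC)
        np.testing.assert_allclose(opponent, 4 * (A * D - B * C), atol=1e-10)
        # interior of the oracle patch must match the pipeline's separable path
        ky, kx = len(gauss) // 2, len(f_even) // 2
        kt = len(g_fast)
        from scipy import ndimage

        ve = ndimage.convolve1d(sub, f_even, axis=2, mode="constant")
        vo = ndimage.convolve1d(sub, f_odd, axis=2, mode="constant")
        ve = ndimage.convolve1d(ve, gauss, axis=1, mode="constant")
        vo = ndimage.convolve1d(vo, gauss, axis=1, mode="constant")

        def causal(v, kern):
            n = len(kern)
            return ndimage.convolve1d(v, kern, axis=0, mode="constant", origin=-(n // 2))

        pipeline_opp = 4 * (
            causal(ve, g_fast) * causal(vo, g_slow)
            - causal(ve, g_slow) * causal(vo, g_fast)
        )
        np.testing.assert_allclose(
            opponent[kt:, ky:-ky, kx:-kx],
            pipeline_opp[kt:, ky:-ky, kx:-kx],
            rtol=1e-8,
            atol=1e-10,
        )


class TestMotionIntegral:
    def _trace(self, energy, dt=10.0):
        energy = np.asarray(energy, dtype=float)
        return MotionEnergyTrace(times_ms=np.arange(len(energy)) * dt, energy=energy)

    def test_constant_trace_terminal_value(self):
        trial = TrialRecord(index=0, foreperiod=1600.0, target="right", rt=400.0, choice="right")
        trace = self._trace(np.full(360, 2.0))
        integ = cumulative_motion_integral(trace, trial, "stimulus")
        # window 100..1600 ms at 10 ms frames -> 151 samples of value 2
        assert integ.terminal == pytest.approx(2.0 * 151)

    def test_premature_response_truncates_window(self):
        trial = TrialRecord(index=0, foreperiod=1600.0, target="right", rt=-700.0, choice="left")
        trace = self._trace(np.ones(360))
        integ = cumulative_motion_integral(trace, trial, "stimulus")
        assert integ.times_ms[0] == 100.0
        assert integ.times_ms[-1] == 900.0

    def test_choice_frame_sign_convention(self):
        trial = TrialRecord(index=0, foreperiod=1600.0, target="right", rt=300.0, choice="left")
        trace = self._trace(-np.ones(360))  # uniformly leftward energy
        integ = cumulative_motion_integral(trace, trial, "choice")
        assert integ.terminal > 0

    def test_response_before_window_start_raises(self):
        trial = TrialRecord(index=0, foreperiod=1600.0, target="right", rt=-1550.0, choice="left")
        trace = self._trace(np.ones(360))
        with pytest.raises(ValueError, match="empty"):
            cumulative_motion_integral(trace, trial, "stimulus")

    def test_slope_of_linear_integral(self):
        # constant energy k -> cumulative is linear with slope k per frame
        trial = TrialRecord(index=0, foreperiod=1600.0, target="right")
        trace = self._trace(np.full(360, 3.0))
        integ = cumulative_motion_integral(trace, trial, "stimulus")
        assert integ.slope == pytest.approx(3.0 / 10.0, rel=1e-9)  # 3 a.u. per 10 ms


class TestSlopeSplit:
    def test_even_split(self):
        shallow, steep = split_by_integral_slope([_FakeIntegral(i, s) for i, s in enumerate(range(10))])
        assert len(shallow) == len(steep) == 5
        assert shallow == [0, 1, 2, 3, 4]

    def test_all_equal_tie_break_by_index(self):
        shallow, steep = split_by_integral_slope([_FakeIntegral(i, 1.0) for i in range(10)])
        assert shallow == [0, 1, 2, 3, 4]
        assert steep == [5, 6, 7, 8, 9]

    def test_odd_count(self):
        shallow, steep = split_by_integral_slope([_FakeIntegral(i, s) for i, s in enumerate(range(9))])
        assert len(shallow) == 4 and len(steep) == 5

    def test_absolute_slope_used(self):
        ints = [_FakeIntegral(0, -10.0), _FakeIntegral(1, 0.1), _FakeIntegral(2, 5.0), _FakeIntegral(3, -0.2)]
        shallow, steep = split_by_integral_slope(ints)
        assert shallow == [1, 3]
        assert steep == [0, 2]

    def test_fewer_than_two_raises(self):
        with pytest.raises(ValueError):
            split_by_integral_slope([_FakeIntegral(0, 1.0)])


class _FakeIntegral:
    def __init__(self, trial_index, slope):
        self.trial_index = trial_index
        self.slope = slope
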