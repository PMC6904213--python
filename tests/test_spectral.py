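import numpy as np
import pandas as pd
import pytest

from premacc.preprocess import EpochSet
from premacc.spectral import (
    FREQ_STEP_HZ,
    mu_beta_lateralisation,
    ssvep_snr,
    stft_amplitude,
)

FS = 512.0


def _epochs(data: np.ndarray, ch_names=None, t0=0.0) -> EpochSet:
    n_trials, n_ch, n_samp = data.shape
    return EpochSet(
        data=data.astype(np.float32),
        times_ms=np.arange(n_samp) * (1000.0 / FS) + t0,
        alignment="stimulus",
        ch_names=ch_names or [f"ch{i}" for i in range(n_ch)],
        fs=FS,
        trial_info=pd.DataFrame({"foreperiod": [800.0] * n_trials}),
        n_valid=np.full(n_trials, n_samp),
    )


def _tone(freq: float, amplitude: float, n_samp: int = 1536, phase: float = 0.0):
    t = np.arange(n_samp) / FS
    return amplitude * np.sin(2 * np.pi * freq * t + phase)


class TestSTFTAmplitude:
    def test_bin_spacing_is_2p5_hz(self):
        tfr = stft_amplitude(_epochs(np.zeros((1, 1, 1024))))
        assert np.allclose(np.diff(tfr.freqs), 2.5)
        assert FREQ_STEP_HZ == 2.5

    def test_segment_labels_spaced_50_ms(self):
        tfr = stft_amplitude(_epochs(np.zeros((1, 1, 1024))))
        assert np.allclose(np.diff(tfr.seg_times_ms), 50.0)
        # labels are segment medians: first spans 0..400 -> label 200
        assert tfr.seg_times_ms[0] == pytest.approx(200.0)

    def test_pure_20hz_tone_recovered_within_1pct(self):
        data = _tone(20.0, 2.0)[None, None, :]
        tfr = stft_amplitude(_epochs(data))
        i20 = int(np.argmin(np.abs(tfr.freqs - 20.0)))
        amps = tfr.amplitude[0, 0, i20, :]
        assert np.nanmean(amps) == pytest.approx(2.0, rel=0.01)

    def test_leakage_into_other_tag_below_1pct(self):
        """One 400 ms segment spans 8 cycles at 20 Hz and 10 at 25 Hz, so
        the tags stay out of each other's bins."""
        data = _tone(20.0, 2.0)[None, None, :]
        tfr = stft_amplitude(_epochs(data))
        i20 = int(np.argmin(np.abs(tfr.freqs - 20.0)))
        i25 = int(np.argmin(np.abs(tfr.freqs - 25.0)))
        assert np.nanmax(tfr.amplitude[0, 0, i25, :]) < 0.01 * np.nanmean(
            tfr.amplitude[0, 0, i20, :]
        )

    def test_integer_cycles_per_segment(self):
        # 400 ms window: 20 Hz * 0.4 s = 8 cycles, 25 Hz * 0.4 s = 10 cycles
        assert 20.0 * 0.4 == pytest.approx(8.0)
        assert 25.0 * 0.4 == pytest.approx(10.0)

    def test_zero_signal_zero_amplitude(self):
        tfr = stft_amplitude(_epochs(np.zeros((2, 3, 1024))))
        assert np.nanmax(tfr.amplitude) == 0.0

    def test_linearity_in_scale(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((1, 2, 1024))
        a1 = stft_amplitude(_epochs(data)).amplitude
        a3 = stft_amplitude(_epochs(3.0 * data)).amplitude
        np.testing.assert_allclose(a3, 3.0 * a1, rtol=1e-5)

    def test_epoch_shorter_than_segment_raises(self):
        with pytest.raises(ValueError, match="segment"):
            stft_amplitude(_epochs(np.zeros((1, 1, 100))))

    def test_nan_padding_gives_nan_segments(self):
        ep = _epochs(np.zeros((1, 1, 1024)))
        ep.data[0, 0, 600:] = np.nan
        tfr = stft_amplitude(ep)
        assert np.isnan(tfr.amplitude[0, 0, 0, -1])
        assert np.isfinite(tfr.amplitude[0, 0, 0, 0])


class TestSSVEPSNR:
    def test_white_noise_snr_near_one(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((40, 1, 1024))
        tfr = stft_amplitude(_epochs(data))
        trace = ssvep_snr(tfr, ["ch0"], np.full(40, 20.0))
        # the ratio-of-amplitudes estimator sits slightly above 1 on white
        # noise (Jensen inflation of 1/mean(adjacent)); ~1.2 is its null level
        assert np.nanmean(trace.snr_target) == pytest.approx(1.0, abs=0.3)

    def test_tone_snr_grows_with_amplitude(self):
        rng = np.random.default_rng(4)
        snrs = []
        for amp in (1.0, 4.0):
            data = (
                _tone(20.0, amp)[None, None, :]
                + 0.5 * rng.standard_normal((10, 1, 1536))
            )
            tfr = stft_amplitude(_epochs(data))
            trace = ssvep_snr(tfr, ["ch0"], np.full(10, 20.0))
            snrs.append(np.nanmean(trace.snr_target))
        assert snrs[0] > 3.0
        assert snrs[1] > snrs[0]

    def test_swapping_roles_negates_d_ssvep(self):
        rng = np.random.default_rng(5)
        data = (
            _tone(20.0, 2.0)[None, None, :]
            + _tone(25.0, 1.0)[None, None, :]
            + 0.3 * rng.standard_normal((6, 1, 1536))
        )
        tfr = stft_amplitude(_epochs(data))
        a = ssvep_snr(tfr, ["ch0"], np.full(6, 20.0))
        b = ssvep_snr(tfr, ["ch0"], np.full(6, 25.0))
        np.testing.assert_allclose(a.d_ssvep, -b.d_ssvep, rtol=1e-6)

    def test_off_grid_tag_raises(self):
        tfr = stft_amplitude(_epochs(np.zeros((1, 1, 1024))))
        with pytest.raises(ValueError, match="bin grid"):
            ssvep_snr(tfr, ["ch0"], np.full(1, 21.3))
        with pytest.raises(ValueError, match="bin grid"):
            ssvep_snr(tfr, ["ch0"], np.full(1, 22.5))

    def test_contrast_step_moves_target_and_nontarget_apart(self, config):
        """Forward-model fixture: after the contrast change the target tag's
        SNR rises and the non-target's falls."""
        from premacc.config import GenerativeParams
        from premacc.synthetic import generate_dataset
        from premacc.pipeline import preprocess_dataset
        from premacc import channels as chan

        params = GenerativeParams(
            cpp_gain=0.0, mubeta_base=0.5, mubeta_dv_gain=0.0,
            sensor_noise_sd=2.0, blink_rate=0.0, channel_pop_rate=0.0,
        )
        ds = generate_dataset(config, params, n_trials=24, seed=8)
        stim, _, _ = preprocess_dataset(ds, reject=False)
        cluster = chan.candidate_cluster("Oz", 4)
        tfr = stft_amplitude(stim, channels=cluster)
        target_freq = np.where(
            stim.trial_info["target"] == "left",
            config.flicker_freqs["left"],
            config.flicker_freqs["right"],
        )
        trace = ssvep_snr(tfr, cluster, target_freq)
        fps = stim.trial_info["foreperiod"].to_numpy(float)
        pre = trace.seg_times_ms < fps[:, None] - 200
        post = (trace.seg_times_ms > fps[:, None] + 400) & (
            trace.seg_times_ms < fps[:, None] + 1800
        )
        d_pre = np.nanmean(np.where(pre, trace.d_ssvep, np.nan))
        d_post = np.nanmean(np.where(post, trace.d_ssvep, np.nan))
        assert d_pre == pytest.approx(0.0, abs=0.5)
        assert d_post > d_pre + 0.5


class TestMuBeta:
    def _tfr_with_band_power(self, left_env, right_env, n_trials=4):
        """Band-limited noise with per-hemisphere envelopes."""
        rng = np.random.default_rng(9)
        from scipy import signal as sg

        n_samp = 1536
        sos = sg.butter(4, (10, 30), btype="bandpass", fs=FS, output="sos")
        data = np.empty((n_trials, 2, n_samp))
        for i in range(n_trials):
            carrier = sg.sosfiltfilt(sos, rng.standard_normal(n_samp))
            carrier /= carrier.std()
            data[i, 0] = left_env * carrier
            data[i, 1] = right_env * carrier
        return stft_amplitude(_epochs(data, ch_names=["L", "R"]))

    def test_identical_hemispheres_zero_lateralisation(self):
        tfr = self._tfr_with_band_power(2.0, 2.0)
        mb = mu_beta_lateralisation(tfr, ["left"] * 4, ["L"], ["R"])
        np.testing.assert_allclose(mb.lateralisation, 0.0, atol=1e-6)

    def test_baseline_segment_is_zero_after_correction(self):
        tfr = self._tfr_with_band_power(2.0, 1.0)
        mb = mu_beta_lateralisation(tfr, ["left"] * 4, ["L"], ["R"])
        b = np.nonzero(np.abs(tfr.seg_times_ms - 550.0) < 1e-6)[0][0]
        np.testing.assert_allclose(mb.contra[:, b], 0.0, atol=1e-6)
        np.testing.assert_allclose(mb.ipsi[:, b], 0.0, atol=1e-6)

    def test_tag_bins_excluded_from_band(self):
        """A pure 20 Hz tone contributes nothing to the Mu/Beta band average."""
        data = np.zeros((1, 2, 1536))
        data[0, 0] = _tone(20.0, 5.0)
        tfr = stft_amplitude(_epochs(data, ch_names=["L", "R"]))
        mb = mu_beta_lateralisation(tfr, ["right"], ["L"], ["R"], baseline_label_ms=None)
        # residual: the 205-sample window is not exactly integer-cycle, so a
        # sliver (<0.1% of the 5 uV tone) leaks into neighbouring band bins
        np.testing.assert_allclose(mb.contra, 0.0, atol=5e-3)

    def test_missing_hand_skipped(self):
        tfr = self._tfr_with_band_power(2.0, 1.0)
        mb = mu_beta_lateralisation(tfr, ["left", None, "right", "left"], ["L"], ["R"])
        assert mb.skipped.tolist() == [False, True, False, False]
        assert np.isnan(mb.lateralisation[1]).all()

    def test_dv_coupled_lateralisation_grows_negative(self, config):
        """Forward model with a motor-preparation gain: the lateralisation
        index heads negative approaching the response."""
        from premacc.config import GenerativeParams
        from premacc.synthetic import generate_dataset
        from premacc.pipeline import preprocess_dataset
        from premacc import channels as chan

        params = GenerativeParams(
            cpp_gain=0.0, ssvep_gain=0.0, sensor_noise_sd=1.0,
            mubeta_base=3.0, mubeta_dv_gain=2.0, blink_rate=0.0, channel_pop_rate=0.0,
        )
        ds = generate_dataset(config, params, n_trials=24, seed=17)
        _, resp, _ = preprocess_dataset(ds, reject=False)
        c3 = chan.candidate_cluster("C3", 4)
        c4 = chan.candidate_cluster("C4", 4)
        tfr = stft_amplitude(resp, channels=c3 + c4)
        hands = resp.trial_info["choice"].to_numpy(object)
        mb = mu_beta_lateralisation(tfr, hands, c3, c4, baseline_label_ms=None)
        early = tfr.seg_times_ms < -600
        late = (tfr.seg_times_ms > -300) & (tfr.seg_times_ms < 0)
        assert np.nanmean(mb.lateralisation[:, late]) < np.nanmean(
            mb.lateralisation[:, early]
        )
        assert np.nanmean(mb.lateralisation[:, late]) < 0
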