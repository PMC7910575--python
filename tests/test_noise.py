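import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fishssm.errors import ClippingError, ConfigurationError
from fishssm.fixtures import make_boat_wav
from fishssm.noise import (
    AudioClip,
    Calibration,
    SplSeries,
    align_noise_to_steps,
    calibrate,
    compute_psd,
    compute_spl,
    detect_noise_peaks,
    estimate_basal,
    read_wav,
    spl_series,
)


class TestCalibrate:
    def test_zero_samples_give_zero_pressure(self):
        clip = calibrate(np.zeros(100, np.int16), sensitivity_db=-170.0)
        assert np.all(clip.samples == 0)

    def test_doubling_gain_halves_pressure(self):
        raw = np.array([1000, -2000, 3000], np.int16)
        a = calibrate(raw, sensitivity_db=-170.0, gain_db=0.0)
        b = calibrate(raw, sensitivity_db=-170.0, gain_db=6.0206)
        assert b.samples == pytest.approx(a.samples / 2, rel=1e-4)

    def test_full_scale_maps_through_sensitivity(self):
        # full-scale sample with -170 dB re 1 V/uPa and 1 V full scale
        clip = calibrate(
            np.array([-32768], np.int16), sensitivity_db=-170.0, full_scale_volts=1.0
        )
        assert abs(clip.samples[0]) == pytest.approx(10 ** (170 / 20), rel=1e-6)

    def test_missing_sensitivity_rejected(self):
        with pytest.raises(ConfigurationError):
            calibrate(np.zeros(10, np.int16))

    def test_out_of_range_samples_rejected(self):
        with pytest.raises(ValueError):
            calibrate(np.array([40000]), sensitivity_db=-170.0)


class TestComputeSpl:
    def test_unit_pressure_is_zero_db(self):
        assert compute_spl(np.ones(44100)) == pytest.approx(0.0, abs=1e-12)

    def test_mean_square_hundred_is_twenty_db(self):
        assert compute_spl(np.full(1000, 10.0)) == pytest.approx(20.0, abs=1e-12)

    def test_sinusoid_rms(self):
        t = np.arange(44100) / 44100
        a = 7.0
        x = a * np.sin(2 * np.pi * 1000 * t)
        assert compute_spl(x) == pytest.approx(20 * np.log10(a / np.sqrt(2)), abs=1e-3)

    def test_silence_returns_floor(self):
        assert compute_spl(np.zeros(100), floor_db=-100.0) == -100.0

    def test_permutation_invariant_and_gain_additive(self, rng):
        x = rng.normal(0, 3.0, 44100)
        assert compute_spl(rng.permutation(x)) == pytest.approx(compute_spl(x))
        assert compute_spl(10 * x) == pytest.approx(compute_spl(x) + 20.0, abs=1e-9)


class TestComputePsd:
    def _clip(self, x, rate=44100):
        return AudioClip(samples=x, rate=rate)

    def test_pure_tone_peaks_at_its_bin(self):
        rate = 44100
        t = np.arange(rate) / rate
        clip = self._clip(np.sin(2 * np.pi * 1000 * t))
        freqs, psd = compute_psd(clip)
        assert freqs[np.argmax(psd[0])] == pytest.approx(1000.0, abs=1.0)

    def test_parseval_holds_on_white_noise(self, rng):
        rate = 44100
        x = rng.normal(0, 2.0, rate * 3)
        clip = self._clip(x)
        freqs, psd = compute_psd(clip)
        df = freqs[1] - freqs[0]
        for seg in range(3):
            lin = np.sum(10 ** (psd[seg] / 10)) * df
            msp = np.mean(x[seg * rate : (seg + 1) * rate] ** 2)
            assert lin == pytest.approx(msp, rel=1e-3)

    def test_short_clip_rejected(self):
        with pytest.raises(ValueError):
            compute_psd(self._clip(np.zeros(1000)))

    def test_silence_floored(self):
        _, psd = compute_psd(self._clip(np.zeros(44100)), floor_db=-100.0)
        assert np.all(psd == -100.0)


class TestDetectNoisePeaks:
    def test_linear_threshold_examples(self):
        basal = 40.0
        spl = basal + 10 * np.log10(np.array([1.9, 1.7, 1.8]))
        flags = detect_noise_peaks(spl, basal, factor=1.8)
        # 1.9x flagged, 1.7x not, exactly at threshold flagged
        assert flags.tolist() == [1, 0, 1]

    @given(f1=st.floats(1.1, 5.0), f2=st.floats(1.1, 5.0))
    def test_raising_factor_never_adds_flags(self, f1, f2):
        spl = np.array([40.0, 42.0, 44.0, 46.0, 48.0])
        lo, hi = sorted((f1, f2))
        a = detect_noise_peaks(spl, 40.0, factor=hi)
        b = detect_noise_peaks(spl, 40.0, factor=lo)
        assert np.all(a <= b)

    def test_db_scale_option(self):
        spl = np.array([71.0, 73.0])
        flags = detect_noise_peaks(spl, 40.0, factor=1.8, scale="db")
        assert flags.tolist() == [0, 1]  # threshold 72 dB


class TestEstimateBasal:
    def test_constant_series(self):
        assert estimate_basal(np.full(100, 37.5)) == 37.5

    def test_robust_to_loud_minority(self, rng):
        quiet = rng.normal(40.0, 0.1, 90)
        loud = rng.normal(60.0, 0.1, 10)
        spl = np.concatenate([quiet, loud])
        assert estimate_basal(spl) == pytest.approx(40.0, abs=0.5)

    def test_reordering_invariant(self, rng):
        spl = rng.normal(40.0, 2.0, 120)
        assert estimate_basal(spl) == estimate_basal(rng.permutation(spl))

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError):
            estimate_basal(np.zeros(59))


class TestAlignNoiseToSteps:
    def _times(self, n, origin="2017-07-24T00:00:00Z"):
        import pandas as pd

        return pd.Timestamp(origin) + pd.to_timedelta(np.arange(n), unit="s")

    def test_no_flags_no_steps(self):
        out = align_noise_to_steps(
            np.zeros(1440, int), self._times(1440), "2017-07-24T00:00:00Z"
        )
        assert out.flags.sum() == 0

    def test_single_flagged_second_marks_its_step(self):
        flags = np.zeros(1440, int)
        flags[800] = 1  # falls in step 1 (720-1439 s)
        out = align_noise_to_steps(flags, self._times(1440), "2017-07-24T00:00:00Z")
        assert out.flags.tolist() == [0, 1]

    def test_flags_in_adjacent_steps(self):
        flags = np.zeros(2160, int)
        flags[700] = flags[730] = 1
        out = align_noise_to_steps(flags, self._times(2160), "2017-07-24T00:00:00Z")
        assert out.flags.tolist() == [1, 1, 0]

    def test_segment_before_origin_rejected(self):
        with pytest.raises(ValueError):
            align_noise_to_steps(
                np.zeros(60, int), self._times(60), "2017-07-24T01:00:00Z"
            )


class TestBoatWavPipeline:
    # Realistic levels: sea ambient ~110 dB re 1 uPa, -170 dB re 1 V/uPa
    # hydrophone with 30 dB recorder gain keeps the signal well inside the
    # 16-bit range without clipping.
    CAL = Calibration(sensitivity_db=-170.0, gain_db=30.0)

    def test_detector_recall_and_false_positives_on_fixture(self, tmp_path):
        path = tmp_path / "boat.wav"
        cal = self.CAL
        # +6 dB and +10 dB events: well above the +2.55 dB (1.8x) threshold
        labels = make_boat_wav(
            path,
            duration=120.0,
            basal_spl=110.0,
            events=[(20.0, 5.0, 6.0), (70.0, 3.0, 10.0)],
            calibration=cal,
            seed=5,
        )
        clip = read_wav(path, cal, start="2017-07-24T00:00:00Z")
        series = spl_series(clip)
        basal = estimate_basal(series)
        flags = detect_noise_peaks(series, basal, factor=1.8)
        truth = labels["flagged"].to_numpy()
        assert np.all(flags[truth == 1] == 1)  # recall 1.0
        assert np.all(flags[truth == 0] == 0)  # no false positives

    def test_event_below_threshold_not_flagged(self, tmp_path):
        path = tmp_path / "quiet.wav"
        cal = self.CAL
        labels = make_boat_wav(
            path,
            duration=90.0,
            basal_spl=110.0,
            events=[(30.0, 4.0, 1.0)],  # +1 dB: below the 2.55 dB threshold
            calibration=cal,
            seed=6,
        )
        clip = read_wav(path, cal, start="2017-07-24T00:00:00Z")
        series = spl_series(clip)
        basal = estimate_basal(series)
        flags = detect_noise_peaks(series, basal, factor=1.8)
        assert flags.sum() == 0

    def test_no_events_nothing_flagged(self, tmp_path):
        path = tmp_path / "calm.wav"
        cal = self.CAL
        make_boat_wav(path, duration=70.0, basal_spl=110.0, events=[], calibration=cal, seed=7)
        clip = read_wav(path, cal, start="2017-07-24T00:00:00Z")
        series = spl_series(clip)
        flags = detect_noise_peaks(series, estimate_basal(series), factor=1.8)
        assert flags.sum() == 0

    def test_clipping_rejected(self, tmp_path):
        with pytest.raises(ClippingError):
            make_boat_wav(
                tmp_path / "loud.wav",
                duration=2.0,
                basal_spl=170.0,
                events=[],
                calibration=Calibration(sensitivity_db=-170.0),
            )
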