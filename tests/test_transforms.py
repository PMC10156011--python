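import numpy as np
import pytest
from scipy import signal as sps

from emovox import pitch_tools as pt
from emovox import transforms as tf
from emovox import voicegen as vg


def band_energy_db(w, lo, hi):
    f, p = sps.welch(w.samples, w.sample_rate, nperseg=4096)
    sel = (f >= lo) & (f <= hi)
    return 10 * np.log10(np.mean(p[sel]))


class TestPitchShift:
    def test_plus_50_cents_measures_within_10(self, vowel_200, contour_200):
        shifted = tf.pitch_shift(vowel_200, 50.0)
        offset = pt.measure_offset(contour_200, pt.estimate_f0(shifted))
        assert offset.median_offset() == pytest.approx(50.0, abs=10.0)

    def test_zero_cents_identity_contour(self, vowel_200, contour_200):
        out = tf.pitch_shift(vowel_200, 0.0)
        offset = pt.measure_offset(contour_200, pt.estimate_f0(out))
        assert abs(offset.median_offset()) < 3.0

    def test_minus_50_on_220_hz(self, vowel_220):
        # 220 * 2^(-50/1200) = 213.76 Hz
        out = tf.pitch_shift(vowel_220, -50.0)
        assert pt.estimate_f0(out).median_f0() == pytest.approx(213.76, abs=1.5)

    def test_duration_preserved(self, vowel_200):
        out = tf.pitch_shift(vowel_200, 300.0)
        assert out.n_samples == vowel_200.n_samples

    def test_shifts_compose_additively(self, vowel_200, contour_200):
        out = tf.pitch_shift(tf.pitch_shift(vowel_200, 30.0), 40.0)
        offset = pt.measure_offset(contour_200, pt.estimate_f0(out))
        assert offset.median_offset() == pytest.approx(70.0, abs=15.0)

    def test_limits(self, vowel_200):
        with pytest.raises(ValueError):
            tf.pitch_shift(vowel_200, 1500.0)


class TestVibrato:
    def test_rate_and_depth_recovered(self, vowel_200, fast_contour_200):
        out = tf.apply_vibrato(vowel_200, 8.5, 30.0, rate_jitter_frac=0.0)
        curve = pt.measure_offset(
            fast_contour_200, pt.estimate_f0(out, fmin=150, fmax=300, frame_step_s=0.005)
        )
        assert curve.dominant_modulation_hz() == pytest.approx(8.5, abs=0.5)
        assert 24.0 <= curve.max_abs_offset() <= 36.0

    def test_jittered_rate_keeps_mean_rate(self, vowel_200, fast_contour_200):
        out = tf.apply_vibrato(vowel_200, 8.5, 30.0, rate_jitter_frac=0.30, seed=1)
        curve = pt.measure_offset(
            fast_contour_200, pt.estimate_f0(out, fmin=150, fmax=300, frame_step_s=0.005)
        )
        # count oscillation cycles via zero crossings of the cents contour
        x = curve.offset_cents[curve.voiced]
        t = curve.times[curve.voiced]
        crossings = np.sum(np.diff(np.signbit(x)))
        mean_rate = crossings / 2 / (t[-1] - t[0])
        assert mean_rate == pytest.approx(8.5, abs=1.0)

    def test_zero_depth_identity(self, vowel_200):
        out = tf.apply_vibrato(vowel_200, 8.5, 0.0)
        np.testing.assert_array_equal(out.samples, vowel_200.samples)

    def test_rate_above_nyquist_rejected(self, vowel_200):
        with pytest.raises(ValueError):
            tf.apply_vibrato(vowel_200, 20000.0, 30.0)

    def test_deterministic_given_seed(self, vowel_200):
        a = tf.apply_vibrato(vowel_200, 8.5, 30.0, 0.3, seed=9)
        b = tf.apply_vibrato(vowel_200, 8.5, 30.0, 0.3, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestInflection:
    def test_attains_extrema_and_returns_to_zero(self, vowel_200, fast_contour_200):
        out = tf.apply_inflection(vowel_200, 500.0, -200.0, 140.0)
        curve = pt.measure_offset(
            fast_contour_200, pt.estimate_f0(out, fmin=100, fmax=350, frame_step_s=0.005)
        )
        window = curve.offset_cents[(curve.times < 0.5) & curve.voiced]
        assert window.min() == pytest.approx(-200.0, abs=15.0)
        assert window.max() == pytest.approx(140.0, abs=15.0)
        # identity after the window
        assert abs(curve.median_offset(t_min=0.55)) < 5.0

    def test_short_window_identity_beyond(self, vowel_200, fast_contour_200):
        out = tf.apply_inflection(vowel_200, 150.0, -200.0, 200.0)
        curve = pt.measure_offset(
            fast_contour_200, pt.estimate_f0(out, fmin=100, fmax=350, frame_step_s=0.005)
        )
        beyond = np.abs(curve.offset_cents[(curve.times > 0.2) & curve.voiced])
        assert np.median(beyond) < 5.0

    def test_null_excursion_identity(self, vowel_200, contour_200):
        out = tf.apply_inflection(vowel_200, 500.0, 0.0, 0.0)
        curve = pt.measure_offset(contour_200, pt.estimate_f0(out))
        assert abs(curve.median_offset()) < 3.0

    def test_invalid_window(self, vowel_200):
        with pytest.raises(ValueError):
            tf.apply_inflection(vowel_200, 500.0, 100.0, -100.0)
        with pytest.raises(ValueError):
            tf.apply_inflection(vowel_200, 5000.0, -200.0, 140.0)


class TestShelfFilter:
    def test_boost_slope_on_white_noise(self, white_noise_44k):
        out = tf.apply_shelf_filter(white_noise_44k, 8000.0, 9.5, "boost")
        f, p_in = sps.welch(white_noise_44k.samples, 44100, nperseg=4096)
        _, p_out = sps.welch(out.samples, 44100, nperseg=4096)
        db = 10 * np.log10(p_out / p_in)
        band = (f >= 8000) & (f <= 16000)
        slope = np.linalg.lstsq(
            np.c_[np.log2(f[band] / 8000), np.ones(band.sum())], db[band], rcond=None
        )[0][0]
        assert slope == pytest.approx(9.5, abs=2.0)
        below = (f > 300) & (f < 7000)
        assert np.max(np.abs(db[below])) < 1.0

    def test_attenuation_reduces_high_band_ratio(self, white_noise_44k):
        out = tf.apply_shelf_filter(white_noise_44k, 8000.0, 12.0, "attenuate")
        ratio_before = band_energy_db(white_noise_44k, 8000, 16000) - band_energy_db(
            white_noise_44k, 1000, 8000
        )
        ratio_after = band_energy_db(out, 8000, 16000) - band_energy_db(out, 1000, 8000)
        assert ratio_after < ratio_before - 3.0

    def test_zero_slope_identity(self, white_noise_44k):
        out = tf.apply_shelf_filter(white_noise_44k, 8000.0, 0.0, "boost")
        np.testing.assert_allclose(out.samples, white_noise_44k.samples, atol=1e-6)

    def test_cutoff_above_nyquist_rejected(self, vowel_200):
        with pytest.raises(ValueError):
            tf.apply_shelf_filter(vowel_200, 12000.0, 9.5, "boost")


class TestEmotionPresets:
    def test_neutral_bit_exact_identity(self, vowel_200):
        out = tf.apply_emotion(vowel_200, "neutral")
        np.testing.assert_array_equal(out.samples, vowel_200.samples)

    def test_happy_steady_offset(self, vowel_200, contour_200):
        out = tf.apply_emotion(vowel_200, "happy", seed=1)
        curve = pt.measure_offset(contour_200, pt.estimate_f0(out))
        # steady region after the 500 ms inflection window
        assert curve.median_offset(t_min=0.6) == pytest.approx(50.0, abs=10.0)

    def test_sad_offset_and_darker_timbre(self, contour_200):
        # filtering effects need bandwidth above the 8 kHz shelf
        w = vg.flat_vowel(200.0, sample_rate=44100, seed=0)
        base = pt.estimate_f0(w)
        out = tf.apply_emotion(w, "sad", seed=1)
        curve = pt.measure_offset(base, pt.estimate_f0(out))
        assert curve.median_offset(t_min=0.3) == pytest.approx(-50.0, abs=10.0)
        hi_before = band_energy_db(w, 9000, 16000)
        hi_after = band_energy_db(out, 9000, 16000)
        assert hi_after < hi_before - 2.0

    def test_afraid_oscillation(self, vowel_200, fast_contour_200):
        out = tf.apply_emotion(vowel_200, "afraid", seed=1)
        curve = pt.measure_offset(
            fast_contour_200, pt.estimate_f0(out, fmin=120, fmax=350, frame_step_s=0.005)
        )
        # measure beyond the 150 ms inflection window
        sel = (curve.times > 0.25) & curve.voiced
        tail = pt.PitchCurve(curve.times[sel], curve.offset_cents[sel])
        assert tail.dominant_modulation_hz() == pytest.approx(8.5, abs=0.5)
        assert tail.max_abs_offset() == pytest.approx(30.0, abs=6.0)

    def test_preset_table_values(self):
        happy = tf.get_preset("happy").spec
        assert happy.pitch_shift_cents == 50.0
        assert (happy.inflection.duration_ms, happy.inflection.min_cents,
                happy.inflection.max_cents) == (500.0, -200.0, 140.0)
        assert (happy.filter.cutoff_hz, happy.filter.signed_slope) == (8000.0, 9.5)
        sad = tf.get_preset("sad").spec
        assert sad.pitch_shift_cents == -50.0
        assert sad.filter.signed_slope == -12.0
        afraid = tf.get_preset("afraid").spec
        assert (afraid.vibrato.rate_hz, afraid.vibrato.depth_cents) == (8.5, 30.0)
        assert (afraid.inflection.min_cents, afraid.inflection.max_cents) == (-200.0, 200.0)
        assert tf.get_preset("neutral").spec.is_identity
        with pytest.raises(KeyError):
            tf.get_preset("angry")

    @pytest.mark.parametrize("name", ["happy", "sad", "afraid", "neutral"])
    def test_every_preset_preserves_duration_and_finiteness(self, vowel_200, name):
        out = tf.apply_emotion(vowel_200, name, seed=0)
        assert out.n_samples == vowel_200.n_samples
        assert np.all(np.isfinite(out.samples))


class TestPitchStep:
    def test_150_cents_at_700_ms(self, vowel_200, contour_200):
        out = tf.apply_pitch_step(vowel_200, tf.PitchStepEvent(700.0, 150.0))
        curve = pt.measure_offset(contour_200, pt.estimate_f0(out))
        assert abs(curve.median_offset(t_max=0.65)) < 5.0
        assert curve.median_offset(t_min=0.78) == pytest.approx(150.0, abs=10.0)

    def test_zero_magnitude_identity(self, vowel_200):
        out = tf.apply_pitch_step(vowel_200, tf.PitchStepEvent(700.0, 0.0))
        np.testing.assert_array_equal(out.samples, vowel_200.samples)

    def test_70_cents_at_500_ms_on_220(self, vowel_220):
        # 220 * 2^(70/1200) = 229.03 Hz after onset
        out = tf.apply_pitch_step(vowel_220, tf.PitchStepEvent(500.0, 70.0))
        c = pt.estimate_f0(out)
        post = c.f0_hz[(c.times > 0.6) & c.voiced]
        assert np.median(post) == pytest.approx(229.03, abs=1.5)

    def test_onset_beyond_duration_rejected(self, vowel_200):
        with pytest.raises(ValueError):
            tf.apply_pitch_step(vowel_200, tf.PitchStepEvent(2000.0, 150.0))
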