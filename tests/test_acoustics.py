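"""Acoustic features: closed forms and invariances."""

import numpy as np
import pytest

from borborygmi.audio_io import AudioRecording, Channel, LabelInterval
from borborygmi.acoustics import (
    EventSpectrum,
    event_spectrum,
    mean_crossing_ratio,
    recording_features,
    spectral_bandwidth_halfmax,
    spectral_centroid,
)

FS = 11025
FULL = LabelInterval(0.0, 1.0, "BS")


def tone(freq, dur=1.0, amp=0.5):
    t = np.arange(int(dur * FS)) / FS
    return AudioRecording(amp * np.sin(2 * np.pi * freq * t), FS)


class TestEventSpectrum:
    def test_tone_peak_at_tone_bin(self):
        spec = event_spectrum(tone(400), FULL)
        assert spec.freqs_hz[spec.amplitude.argmax()] == pytest.approx(400, abs=6)

    def test_white_noise_flat_within_3db(self):
        rng = np.random.default_rng(0)
        rec = AudioRecording(0.3 * rng.standard_normal(int(1.5 * FS)), FS)
        spec = event_spectrum(rec, LabelInterval(0.0, 1.5, "BS"))
        band = (spec.freqs_hz >= 200) & (spec.freqs_hz <= 5000)
        db = 20 * np.log10(spec.amplitude[band])
        assert db.max() - db.min() < 6.0  # +-3 dB around the mean

    def test_silence_gives_zero_spectrum(self):
        rec = AudioRecording(np.zeros(FS), FS)
        spec = event_spectrum(rec, FULL)
        assert np.all(spec.amplitude == 0)

    def test_short_event_single_padded_frame(self):
        rec = tone(400)
        spec = event_spectrum(rec, LabelInterval(0.0, 0.02, "SB"))
        assert spec.amplitude.size == spec.freqs_hz.size

    def test_empty_event_rejected(self):
        # interval shorter than one sample period rounds to zero samples
        with pytest.raises(ValueError):
            event_spectrum(tone(400), LabelInterval(0.50001, 0.50002, "BS"))


class TestSpectralCentroid:
    def test_pure_tone(self):
        assert spectral_centroid(event_spectrum(tone(400), FULL)) == \
            pytest.approx(400, abs=5)

    def test_two_equal_tones_symmetric(self):
        t = np.arange(FS) / FS
        rec = AudioRecording(0.3 * np.sin(2 * np.pi * 300 * t)
                             + 0.3 * np.sin(2 * np.pi * 500 * t), FS)
        assert spectral_centroid(event_spectrum(rec, FULL)) == \
            pytest.approx(400, abs=5)

    def test_uniform_spectrum(self):
        f = np.linspace(0, FS / 2, 513)
        spec = EventSpectrum(f, np.ones_like(f))
        assert spectral_centroid(spec) == pytest.approx(FS / 4, abs=f[1] - f[0])

    def test_scale_invariant(self):
        spec = event_spectrum(tone(700), FULL)
        scaled = EventSpectrum(spec.freqs_hz, 13.0 * spec.amplitude)
        assert spectral_centroid(scaled) == pytest.approx(
            spectral_centroid(spec))

    def test_zero_spectrum_missing(self):
        f = np.linspace(0, FS / 2, 64)
        assert spectral_centroid(EventSpectrum(f, np.zeros_like(f))) is None


class TestSpectralBandwidth:
    def test_pure_tone_near_zero_width(self):
        spec = event_spectrum(tone(400), FULL)
        grid = spec.freqs_hz[1] - spec.freqs_hz[0]
        assert spectral_bandwidth_halfmax(spec) <= 3 * grid

    def test_two_tone_extent(self):
        t = np.arange(FS) / FS
        rec = AudioRecording(0.3 * np.sin(2 * np.pi * 300 * t)
                             + 0.3 * np.sin(2 * np.pi * 500 * t), FS)
        sbw = spectral_bandwidth_halfmax(event_spectrum(rec, FULL))
        # 200 Hz separation plus at most one windowing mainlobe per side
        assert 200 - 10 <= sbw <= 200 + 70

    def test_uniform_spectrum_full_span(self):
        f = np.linspace(0, FS / 2, 513)
        spec = EventSpectrum(f, np.ones_like(f))
        assert spectral_bandwidth_halfmax(spec) == pytest.approx(FS / 2)

    def test_zero_spectrum_missing(self):
        f = np.linspace(0, FS / 2, 64)
        assert spectral_bandwidth_halfmax(EventSpectrum(f, np.zeros_like(f))) is None


class TestMeanCrossingRatio:
    def test_alternating_signal(self):
        rec = AudioRecording(np.tile([1.0, -1.0], 50), FS)
        iv = LabelInterval(0.0, 100 / FS, "BS")
        assert mean_crossing_ratio(rec, iv) == pytest.approx(99 / 100)

    def test_constant_signal_zero(self):
        rec = AudioRecording(np.full(200, 0.4), FS)
        iv = LabelInterval(0.0, 200 / FS, "BS")
        assert mean_crossing_ratio(rec, iv) == 0.0

    def test_400hz_sine_brute_force(self):
        rec = tone(400)
        got = mean_crossing_ratio(rec, FULL)
        assert got == pytest.approx(2 * 400 / FS, abs=1e-3)
        # brute-force oracle: direct crossing count of the demeaned signal
        x = rec.samples - rec.samples.mean()
        brute = np.sum(np.abs(np.diff(np.sign(x)[np.sign(x) != 0])) > 0)
        assert got == pytest.approx(brute / rec.samples.size)

    def test_amplitude_and_offset_invariant(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500) * 0.1
        a = AudioRecording(x, FS)
        b = AudioRecording(0.05 * x + 0.4, FS)
        iv = LabelInterval(0.0, 500 / FS, "BS")
        assert mean_crossing_ratio(a, iv) == mean_crossing_ratio(b, iv)


class TestRecordingFeatures:
    def test_duration_per_min(self):
        rec = AudioRecording(np.zeros(30 * FS) + 0.01, FS)
        events = [LabelInterval(1.0, 2.5, "BS"), LabelInterval(5.0, 6.5, "BS"),
                  LabelInterval(10.0, 11.5, "BS")]
        rf = recording_features(rec, events)
        assert rf.duration_per_min == pytest.approx(9.0)

    def test_zero_events(self):
        rec = AudioRecording(np.zeros(FS), FS)
        rf = recording_features(rec, [])
        assert rf.duration_per_min == 0.0
        assert rf.sc_hz is None and rf.sbw_hz is None and rf.mcr is None

    def test_median_aggregation(self):
        rec = AudioRecording(np.concatenate([
            0.5 * np.sin(2 * np.pi * f * np.arange(FS) / FS)
            for f in (350, 380, 420)]), FS)
        events = [LabelInterval(i + 0.1, i + 0.9, "BS") for i in range(3)]
        rf = recording_features(rec, events)
        assert rf.sc_hz == pytest.approx(380, abs=6)

    def test_ranges_on_simulated_recording(self):
        from borborygmi.simulate import generate_recording, fasted_condition
        sim = generate_recording(40.0, fasted_condition(), FS, seed=8)
        rf = recording_features(sim.audio, sim.truth, channel=Channel.RLQ,
                                state="fasted", subject_id="S01",
                                preprocessed=False)
        assert 0.0 <= rf.duration_per_min <= 60.0
        assert 0.0 <= rf.sc_hz <= FS / 2
        assert 0.0 <= rf.sbw_hz <= FS / 2
        assert 0.0 <= rf.mcr <= 1.0
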