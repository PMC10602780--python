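"""f0 tracking, semitone policy, emphasis, cvint and summaries."""

import numpy as np
import pytest

from prosopath.audio import AudioSignal
from prosopath.prominence import (
    F0Track, IntensityTrack, ProminenceAcoustics, ProminenceSpan,
    cv_intensity, extract_f0, group_summary, hz_to_semitones,
    intensity_track, prominence_profile, select_nucleus_span,
    spectral_emphasis,
)

from conftest import harmonic_tone


class TestSemitones:
    def test_reference_maps_to_zero(self):
        assert hz_to_semitones(220.0, ref_hz=220.0) == pytest.approx(0.0)

    def test_octave_is_twelve(self):
        for f in (55.0, 110.0, 347.0):
            assert hz_to_semitones(2 * f) - hz_to_semitones(f) \
                == pytest.approx(12.0)

    def test_closed_form_100hz(self):
        assert hz_to_semitones(100.0) == pytest.approx(12 * np.log2(100),
                                                       abs=1e-9)
        assert hz_to_semitones(100.0) == pytest.approx(79.73, abs=0.01)

    def test_strictly_increasing(self):
        fs = np.linspace(50, 400, 50)
        st = hz_to_semitones(fs)
        assert np.all(np.diff(st) > 0)

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            hz_to_semitones(0.0)


class TestF0Extraction:
    @pytest.mark.parametrize("f0", [80, 110, 150, 200, 250])
    def test_harmonic_tone_recovered_within_2hz(self, f0):
        track = extract_f0(harmonic_tone(f0, 0.6))
        voiced = track.voiced
        assert voiced.size > 0.9 * track.values.size
        assert np.all(np.abs(voiced - f0) <= 2.0)

    def test_white_noise_mostly_unvoiced(self):
        rng = np.random.default_rng(1)
        sig = AudioSignal(0.3 * rng.standard_normal(16000), 16000)
        track = extract_f0(sig)
        assert track.voiced.size <= 0.1 * track.values.size

    def test_glide_monotone_within_tolerance(self):
        sr = 16000
        tt = np.arange(int(0.8 * sr)) / sr
        f_inst = 100 + 125 * tt  # 100 -> 200 Hz
        phase = 2 * np.pi * np.cumsum(f_inst) / sr
        sig = AudioSignal(0.3 * np.sin(phase), sr)
        voiced = extract_f0(sig).voiced
        assert voiced.size > 10
        diffs = np.diff(voiced)
        assert np.all(diffs > -2.0)  # non-decreasing within tolerance
        assert voiced[-1] > voiced[0] + 60

    def test_silence_has_no_voiced_frames(self):
        track = extract_f0(AudioSignal(np.zeros(16000), 16000))
        assert track.voiced.size == 0


class TestNucleusSelection:
    @staticmethod
    def _track(values, hop=0.01):
        values = np.asarray(values, dtype=float)
        return F0Track(np.arange(values.size) * hop + hop / 2, values)

    def test_rise_peak_fall_maps_to_syllables(self):
        # 1 s contour: flat, rise, peak, fall, flat over 5 syllables
        v = np.concatenate([
            np.full(25, 100.0),
            np.linspace(100, 160, 25),
            np.linspace(160, 100, 25),
            np.full(25, 100.0)])
        syllables = [(i * 0.2, (i + 1) * 0.2) for i in range(5)]
        span = select_nucleus_span(self._track(v), syllables)
        assert not span.flagged
        assert span.start_s == pytest.approx(0.2)  # rise-start syllable
        assert span.end_s == pytest.approx(0.8)    # fall-end syllable
        assert span.n_syllables == 3

    def test_flat_contour_flagged_fallback(self):
        v = np.full(100, 120.0)
        syllables = [(i * 0.2, (i + 1) * 0.2) for i in range(5)]
        span = select_nucleus_span(self._track(v), syllables)
        assert span.flagged

    def test_padding_clamped_to_two_syllables(self):
        v = np.concatenate([
            np.linspace(100, 170, 10),
            np.linspace(170, 100, 10),
            np.full(80, 100.0)])
        syllables = [(i * 0.1, (i + 1) * 0.1) for i in range(10)]
        span_raw = select_nucleus_span(self._track(v), syllables)
        span_pad = select_nucleus_span(self._track(v), syllables,
                                       pad_syllables=9)
        # the requested 9-syllable pad collapses to the 2-syllable maximum
        assert span_pad.end_s - span_raw.end_s == pytest.approx(0.2)

    def test_unvoiced_contour_errors(self):
        v = np.full(50, np.nan)
        with pytest.raises(ValueError):
            select_nucleus_span(self._track(v), [(0.0, 0.5)])


class TestSpectralEmphasis:
    def test_pure_low_tone_is_zero(self):
        sig = harmonic_tone(100, 1.0, n_partials=1)
        assert spectral_emphasis(sig, cutoff_policy="fixed") \
            == pytest.approx(0.0, abs=1e-6)

    def test_equal_power_two_tone_is_3db(self):
        sr = 16000
        tt = np.arange(sr) / sr
        sig = AudioSignal(0.2 * np.sin(2 * np.pi * 100 * tt)
                          + 0.2 * np.sin(2 * np.pi * 1000 * tt), sr)
        assert spectral_emphasis(sig, cutoff_policy="fixed") \
            == pytest.approx(10 * np.log10(2), abs=0.05)

    def test_monotone_in_high_band_power(self):
        sr = 16000
        tt = np.arange(sr) / sr
        prev = None
        for a_hi in (0.05, 0.1, 0.2, 0.4):
            sig = AudioSignal(0.2 * np.sin(2 * np.pi * 100 * tt)
                              + a_hi * np.sin(2 * np.pi * 1000 * tt), sr)
            emph = spectral_emphasis(sig, cutoff_policy="fixed")
            if prev is not None:
                assert emph > prev
            prev = emph

    def test_gain_invariance(self):
        sig = harmonic_tone(120, 0.5)
        louder = AudioSignal(sig.samples * 10 ** (6 / 20), sig.rate)
        assert spectral_emphasis(sig, cutoff_policy="auto") \
            == pytest.approx(spectral_emphasis(louder, cutoff_policy="auto"),
                             abs=1e-6)

    def test_silent_span_errors(self):
        with pytest.raises(ValueError):
            spectral_emphasis(AudioSignal(np.zeros(8000), 16000))


class TestCvInt:
    def test_constant_contour_is_zero(self):
        track = IntensityTrack(np.arange(10) * 0.01, np.full(10, 70.0))
        assert cv_intensity(track) == 0.0

    def test_two_value_closed_form(self):
        track = IntensityTrack(np.array([0.0, 0.01]), np.array([60.0, 80.0]))
        # population sd 10, mean 70
        assert cv_intensity(track) == pytest.approx(100 * 10 / 70, abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        v = 60 + 10 * rng.random(50)
        track = IntensityTrack(np.arange(50) * 0.01, v)
        scaled = IntensityTrack(track.times, v * 3.7)
        assert cv_intensity(track) == pytest.approx(cv_intensity(scaled))

    def test_reciprocal_order(self):
        track = IntensityTrack(np.array([0.0, 0.01]), np.array([60.0, 80.0]))
        assert cv_intensity(track, order="mean_over_sd") \
            == pytest.approx(100 * 70 / 10)


class TestProfile:
    def test_constant_f0_span(self):
        sig = harmonic_tone(150, 0.6)
        span = ProminenceSpan("COM", 0.05, 0.55, 3)
        acou = prominence_profile(sig, span)
        assert acou.f0mean_hz == pytest.approx(150, abs=2.0)
        assert acou.f0sd_hz == pytest.approx(0.0, abs=1.0)
        assert acou.cvint is not None

    def test_per_frame_semitone_policy(self):
        # half the span at 100 Hz, half at 200 Hz
        sr = 16000
        a = harmonic_tone(100, 0.5).samples
        b = harmonic_tone(200, 0.5).samples
        sig = AudioSignal(np.concatenate([a, b]), sr)
        span = ProminenceSpan("COM", 0.0, 1.0, 4)
        acou = prominence_profile(sig, span)
        per_frame = (hz_to_semitones(100) + hz_to_semitones(200)) / 2  # 85.73
        of_mean = hz_to_semitones(acou.f0mean_hz)
        assert acou.f0mean_st == pytest.approx(per_frame, abs=0.6)
        assert of_mean - acou.f0mean_st > 0.5  # policies measurably differ
        assert acou.f0sd_st > 0

    def test_unvoiced_span_keeps_energy_measures(self):
        rng = np.random.default_rng(3)
        sig = AudioSignal(0.2 * rng.standard_normal(16000), 16000)
        span = ProminenceSpan("TOP", 0.1, 0.9, 2)
        acou = prominence_profile(sig, span)
        assert acou.f0mean_hz is None and acou.f0sd_st is None
        assert acou.emph_db is not None and acou.cvint is not None


class TestGroupSummary:
    @staticmethod
    def _acou(f0):
        return ProminenceAcoustics(f0, hz_to_semitones(f0), 0.0, 0.0,
                                   2.0, 3.0)

    def test_two_speakers_pool_to_mean(self):
        profiles = [("A", "COM", self._acou(100.0)),
                    ("B", "COM", self._acou(120.0))]
        df = group_summary(profiles)
        pooled = df[(df.speaker == "ALL") & (df.unit_role == "COM")]
        assert pooled.f0mean_hz.iloc[0] == pytest.approx(110.0)

    def test_pooling_is_prominence_weighted(self):
        profiles = [("A", "COM", self._acou(100.0))] * 3 \
            + [("B", "COM", self._acou(200.0))]
        df = group_summary(profiles)
        pooled = df[(df.speaker == "ALL") & (df.unit_role == "COM")]
        assert pooled.f0mean_hz.iloc[0] == pytest.approx(125.0)
        assert pooled.n.iloc[0] == 4

    def test_planted_top_above_com_ordering(self, cipps_corpus):
        from prosopath.prominence import prominence_profile as profile
        spans = cipps_corpus.truth.spans
        profiles = []
        for s in spans:
            sp = ProminenceSpan(s.unit_role, s.start_s, s.end_s,
                                s.n_syllables, s.speaker)
            profiles.append((s.speaker, s.unit_role,
                             profile(cipps_corpus.audio, sp)))
        df = group_summary(profiles)
        pooled = df[df.speaker == "ALL"].set_index("unit_role")
        assert pooled.loc["TOP", "f0sd_hz"] > pooled.loc["COM", "f0sd_hz"]
        assert pooled.loc["TOP", "f0mean_hz"] > pooled.loc["COM", "f0mean_hz"]
        assert pooled.loc["TOP", "emph_db"] > pooled.loc["COM", "emph_db"]
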