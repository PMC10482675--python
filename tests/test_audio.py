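"""Log-mel front end, patching, embedder contract and acoustic indices."""
from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soundscape import Recording
from soundscape.audio import (
    EMBEDDING_DIM,
    FRAME_LENGTH,
    HOP_LENGTH,
    N_MEL_BINS,
    PATCH_FRAMES,
    AudioBuffer,
    FeatureExtractor,
    LogMelPatch,
    NoMatchedRecordingError,
    RandomProjectionEmbedder,
    acoustic_indices,
    embed_patch,
    log_mel_spectrogram,
    match_recordings_to_point_count,
    mean_features_per_recording,
    mel_filterbank,
    n_frames,
    patch_frames,
    read_wav,
    to_mono_16k,
    write_wav,
)

from conftest import make_point_count


def tone(freq=1000.0, seconds=1.0, rate=16_000, amp=0.5):
    t = np.arange(int(seconds * rate)) / rate
    return AudioBuffer(samples=amp * np.sin(2 * np.pi * freq * t),
                       sample_rate=rate)


class TestToMono16k:
    def test_identity_for_mono_16k(self):
        buf = tone()
        out = to_mono_16k(buf)
        np.testing.assert_array_equal(out.samples, buf.samples)

    def test_stereo_identical_channels(self):
        mono = tone().samples
        stereo = AudioBuffer(samples=np.stack([mono, mono], axis=1),
                             sample_rate=16_000)
        np.testing.assert_allclose(to_mono_16k(stereo).samples, mono)

    def test_48k_resampled_length(self):
        buf = AudioBuffer(samples=np.zeros(48_000), sample_rate=48_000)
        assert to_mono_16k(buf).samples.shape == (16_000,)

    def test_dc_preserved(self):
        buf = AudioBuffer(samples=np.full(44_100, 0.25), sample_rate=44_100)
        out = to_mono_16k(buf)
        mid = out.samples[100:-100]  # away from filter edge effects
        np.testing.assert_allclose(mid, 0.25, atol=1e-3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            AudioBuffer(samples=np.array([]), sample_rate=16_000)


class TestLogMel:
    def test_one_second_gives_98_frames(self):
        frames = log_mel_spectrogram(tone(seconds=1.0))
        assert frames.shape == (98, N_MEL_BINS)

    def test_silence_is_log_offset_everywhere(self):
        buf = AudioBuffer(samples=np.zeros(16_000), sample_rate=16_000)
        frames = log_mel_spectrogram(buf, log_offset=0.01)
        np.testing.assert_allclose(frames, np.log(0.01))

    def test_tone_lands_in_the_right_mel_bin(self):
        """Column argmax is constant over frames and sits in the mel bin
        whose band contains 1 kHz (bin edges computed independently)."""
        frames = log_mel_spectrogram(tone(freq=1000.0, seconds=2.0))
        argmax = frames.argmax(axis=1)
        assert np.all(argmax == argmax[0])
        # independent mel mapping: bin k covers mel edges [k, k+2] of the
        # 66-point grid between mel(125) and mel(7500)
        mel = lambda f: 2595.0 * np.log10(1.0 + f / 700.0)
        edges = np.linspace(mel(125.0), mel(7500.0), N_MEL_BINS + 2)
        k = int(argmax[0])
        assert edges[k] <= mel(1000.0) <= edges[k + 2]

    def test_too_short_rejected(self):
        buf = AudioBuffer(samples=np.zeros(FRAME_LENGTH - 1), sample_rate=16_000)
        with pytest.raises(ValueError, match="shorter"):
            log_mel_spectrogram(buf)

    def test_frame_count_formula_matches_enumeration(self, rng):
        """1 + floor((n - 400)/160) equals brute-force window sliding."""
        for n in rng.integers(FRAME_LENGTH, 50_000, size=50):
            brute = len(range(0, int(n) - FRAME_LENGTH + 1, HOP_LENGTH))
            assert n_frames(int(n)) == brute

    def test_filterbank_has_no_empty_filters(self):
        fb = mel_filterbank()
        assert fb.shape == (257, N_MEL_BINS)
        assert (fb.sum(axis=0) > 0).all()


class TestPatching:
    @pytest.mark.parametrize("frames, expected", [(98, 1), (96, 1), (95, 0),
                                                  (998, 10), (192, 2)])
    def test_patch_counts(self, frames, expected):
        patches = patch_frames(np.zeros((frames, N_MEL_BINS)))
        assert len(patches) == expected

    def test_ten_seconds_is_ten_patches(self):
        frames = log_mel_spectrogram(tone(seconds=10.0))
        assert frames.shape[0] == 998
        assert len(patch_frames(frames)) == 10

    def test_exact_patch_covers_all_frames(self, rng):
        frames = rng.standard_normal((PATCH_FRAMES, N_MEL_BINS))
        (patch,) = patch_frames(frames)
        np.testing.assert_array_equal(patch.values, frames)
        assert patch.start_offset == 0.0

    def test_patch_offsets_are_sequenced(self):
        patches = patch_frames(np.zeros((192, N_MEL_BINS)))
        assert [p.start_offset for p in patches] == [0.0, 0.96]


class TestEmbedder:
    def test_deterministic_and_128_dim(self, rng):
        patch = LogMelPatch(rng.standard_normal((PATCH_FRAMES, N_MEL_BINS)), 0.0)
        emb = RandomProjectionEmbedder(seed=4)
        v1 = embed_patch(patch, emb)
        v2 = embed_patch(patch, RandomProjectionEmbedder(seed=4))
        assert v1.shape == (EMBEDDING_DIM,)
        np.testing.assert_array_equal(v1, v2)

    def test_sensitive_to_single_cell(self, rng):
        values = rng.standard_normal((PATCH_FRAMES, N_MEL_BINS))
        bumped = values.copy()
        bumped[10, 10] += 10.0
        emb = RandomProjectionEmbedder(seed=0)
        a = embed_patch(LogMelPatch(values, 0.0), emb)
        b = embed_patch(LogMelPatch(bumped, 0.0), emb)
        assert not np.array_equal(a, b)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            LogMelPatch(np.zeros((95, N_MEL_BINS)), 0.0)


class TestAcousticIndices:
    def test_silence_is_all_zero(self):
        buf = AudioBuffer(samples=np.zeros(32_000), sample_rate=16_000)
        out = acoustic_indices(buf)
        assert all(v == 0.0 for v in out.values())

    def test_steady_tone_has_zero_complexity(self):
        # 1 kHz at 16 kHz: the 512-sample hop holds exactly 32 cycles, so
        # every frame is identical and frame-to-frame differences vanish
        out = acoustic_indices(tone(freq=1000.0, seconds=2.0))
        assert out["acoustic_complexity"] == pytest.approx(0.0, abs=1e-9)

    def test_white_noise_spectral_entropy_near_one(self):
        rng = np.random.default_rng(0)
        buf = AudioBuffer(samples=0.5 * rng.standard_normal(160_000),
                          sample_rate=16_000)
        out = acoustic_indices(buf)
        assert out["spectral_entropy"] > 0.95

    @given(st.integers(0, 2**31 - 1))
    def test_indices_bounded_and_finite_on_random_audio(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4096, 40_000))
        buf = AudioBuffer(samples=np.clip(rng.standard_normal(n), -1, 1) *
                          rng.random(), sample_rate=16_000)
        out = acoustic_indices(buf)
        assert 0.0 <= out["temporal_entropy"] <= 1.0
        assert 0.0 <= out["spectral_entropy"] <= 1.0
        assert 0.0 <= out["spectrogram_cover"] <= 1.0
        assert all(np.isfinite(v) for v in out.values())


class TestRecordingAggregation:
    def test_mean_equals_bruteforce_average(self, rng):
        buf = AudioBuffer(samples=np.clip(rng.standard_normal(160_000), -1, 1),
                          sample_rate=16_000)
        ex = FeatureExtractor(RandomProjectionEmbedder(seed=1))
        row = mean_features_per_recording(buf, ex)
        patches = patch_frames(log_mel_spectrogram(buf))
        assert len(patches) == 10
        brute = sum(embed_patch(p, ex.embedder) for p in patches) / len(patches)
        np.testing.assert_allclose(row[:EMBEDDING_DIM], brute, atol=1e-12)

    def test_identical_patches_mean_is_the_patch_embedding(self):
        # signal period equal to the hop makes every frame (hence every
        # patch) identical
        block = np.tile(np.sin(np.linspace(0, 2 * np.pi, HOP_LENGTH,
                                           endpoint=False)), 200)
        buf = AudioBuffer(samples=block, sample_rate=16_000)
        ex = FeatureExtractor(RandomProjectionEmbedder(seed=2),
                              with_indices=False)
        row = mean_features_per_recording(buf, ex)
        patches = patch_frames(log_mel_spectrogram(buf))
        first = embed_patch(patches[0], ex.embedder)
        np.testing.assert_allclose(row, first, atol=1e-12)

    def test_too_short_recording_rejected(self):
        buf = AudioBuffer(samples=np.zeros(8_000), sample_rate=16_000)
        with pytest.raises(ValueError, match="patch"):
            mean_features_per_recording(buf, FeatureExtractor())


def _recording(rec_id, start):
    return Recording(id=rec_id, dataset_id="d0", site_id="s0",
                     start_time=start, duration=60.0, sample_rate=16_000)


class TestWindowMatching:
    pc = make_point_count("pc0", {"A"}, start=datetime(2021, 5, 1, 8, 0))

    def test_recording_20min_before_matches_60min_window(self):
        rec = _recording("r1", datetime(2021, 5, 1, 7, 40))
        matched, row = match_recordings_to_point_count(
            self.pc, [rec], {"r1": np.ones(3)}, window_minutes=60)
        assert [r.id for r in matched] == ["r1"]
        np.testing.assert_array_equal(row, [1, 1, 1])

    def test_window_edges_are_closed(self):
        early = _recording("early", datetime(2021, 5, 1, 7, 30))
        late = _recording("late", datetime(2021, 5, 1, 8, 30))
        rows = {"early": np.zeros(2), "late": np.ones(2)}
        matched, row = match_recordings_to_point_count(
            self.pc, [early, late], rows, window_minutes=60)
        assert len(matched) == 2
        np.testing.assert_array_equal(row, [0.5, 0.5])

    def test_zero_window_requires_exact_start(self):
        exact = _recording("exact", self.pc.start_time)
        off = _recording("off", self.pc.start_time + timedelta(seconds=1))
        matched, _ = match_recordings_to_point_count(
            self.pc, [exact, off], {"exact": np.ones(1), "off": np.ones(1)},
            window_minutes=0)
        assert [r.id for r in matched] == ["exact"]

    def test_no_match_raises(self):
        rec = _recording("r1", datetime(2021, 5, 1, 10, 0))
        with pytest.raises(NoMatchedRecordingError):
            match_recordings_to_point_count(self.pc, [rec],
                                            {"r1": np.ones(1)}, 60)

    def test_mean_of_four_recordings_is_bruteforce_average(self, rng):
        starts = [self.pc.start_time + timedelta(minutes=m)
                  for m in (-20, -5, 5, 20)]
        recs = [_recording(f"r{i}", s) for i, s in enumerate(starts)]
        rows = {f"r{i}": rng.standard_normal(6) for i in range(4)}
        _, row = match_recordings_to_point_count(self.pc, recs, rows, 60)
        np.testing.assert_allclose(
            row, np.mean([rows[f"r{i}"] for i in range(4)], axis=0),
            atol=1e-12)


class TestWavIO:
    def test_wav_round_trip(self, tmp_path, rng):
        buf = AudioBuffer(samples=np.clip(rng.standard_normal(8_000), -1, 1),
                          sample_rate=16_000)
        write_wav(buf, tmp_path / "x.wav")
        back = read_wav(tmp_path / "x.wav")
        assert back.sample_rate == 16_000
        np.testing.assert_allclose(back.samples, buf.samples, atol=1e-4)


class TestEndToEndMonotonicity:
    def test_richer_scene_covers_more_spectrogram(self):
        from soundscape import FeatureMapConfig, LandscapeConfig, generate_dataset
        from soundscape.synthetic import AudioRenderConfig, render_audio

        ds = generate_dataset(
            LandscapeConfig(n_sites=2, n_species=10, n_point_counts=4,
                            niche_width=1e6, detection_prob=1.0,
                            max_occupancy=1.0, seed=0),
            FeatureMapConfig(n_lf=4, n_ssi=0, map_seed=0),
        )
        base = ds.point_counts[0]
        cfg = AudioRenderConfig(duration=3.0, noise_amp=0.0, seed=0)
        one = base.__class__(id="a", dataset_id="d", site_id="s",
                             start_time=base.start_time, duration=1.0,
                             species=frozenset({"sp000"}))
        ten = base.__class__(id="b", dataset_id="d", site_id="s",
                             start_time=base.start_time, duration=1.0,
                             species=frozenset(f"sp{j:03d}" for j in range(10)))
        cover1 = acoustic_indices(render_audio(one, ds.truth, cfg))[
            "spectrogram_cover"]
        cover10 = acoustic_indices(render_audio(ten, ds.truth, cfg))[
            "spectrogram_cover"]
        assert cover10 > cover1
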