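"""Audio front end: log-mel patches, a pluggable embedder, acoustic indices.

The preprocessing follows the input contract of general-purpose audio
embedding CNNs: mono 16 kHz audio, 25 ms periodic-Hann windows with a 10 ms
hop, 64 HTK-mel bins spanning 125-7,500 Hz, log compression with a small
additive offset, and non-overlapping 96-frame (0.96 s) patches, each patch
mapping to one 128-dimensional feature vector.  Pretrained network weights
are deliberately out of scope; the embedder is pluggable behind
:class:`Embedder`, with a seeded random-projection stand-in as the default.

A small set of soundscape indices (temporal entropy, spectral entropy,
acoustic complexity, spectrogram cover) is computed analytically per
recording; external index suites can be plugged in through the same
extractor interface.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import timedelta
from typing import Mapping, Protocol, Sequence

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .types import FeatureFamily, FeatureTable, PointCount, Recording

__all__ = [
    "AudioBuffer",
    "LogMelPatch",
    "Embedder",
    "RandomProjectionEmbedder",
    "FeatureExtractor",
    "read_wav",
    "write_wav",
    "to_mono_16k",
    "log_mel_spectrogram",
    "n_frames",
    "patch_frames",
    "embed_patch",
    "acoustic_indices",
    "mean_features_per_recording",
    "match_recordings_to_point_count",
    "NoMatchedRecordingError",
    "TARGET_SAMPLE_RATE",
    "FRAME_LENGTH",
    "HOP_LENGTH",
    "N_MEL_BINS",
    "PATCH_FRAMES",
    "EMBEDDING_DIM",
]

log = logging.getLogger(__name__)

TARGET_SAMPLE_RATE = 16_000
WINDOW_SECONDS = 0.025
HOP_SECONDS = 0.010
FRAME_LENGTH = int(round(WINDOW_SECONDS * TARGET_SAMPLE_RATE))  # 400
HOP_LENGTH = int(round(HOP_SECONDS * TARGET_SAMPLE_RATE))  # 160
N_FFT = 512
N_MEL_BINS = 64
MEL_MIN_HZ = 125.0
MEL_MAX_HZ = 7_500.0
LOG_OFFSET = 0.01
PATCH_FRAMES = 96
EMBEDDING_DIM = 128

INDEX_NAMES = (
    "temporal_entropy",
    "spectral_entropy",
    "acoustic_complexity",
    "spectrogram_cover",
)


class NoMatchedRecordingError(LookupError):
    """No recording started inside the point count's matching window."""


@dataclass(frozen=True)
class AudioBuffer:
    """In-memory audio: shape (n,) mono or (n, channels) multichannel."""

    samples: np.ndarray
    sample_rate: float
    n_channels: int = 1

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.size < 1:
            raise ValueError("empty audio buffer")
        if not np.isfinite(s).all():
            raise ValueError("audio contains non-finite samples")
        if s.ndim == 1:
            object.__setattr__(self, "n_channels", 1)
        elif s.ndim == 2:
            object.__setattr__(self, "n_channels", s.shape[1])
        else:
            raise ValueError("samples must be 1-D or 2-D")
        object.__setattr__(self, "samples", s)

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.sample_rate


@dataclass(frozen=True)
class LogMelPatch:
    """One fixed-size embedder input: 96 frames x 64 mel bins."""

    values: np.ndarray
    start_offset: float  # seconds from recording start

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (PATCH_FRAMES, N_MEL_BINS):
            raise ValueError(
                f"patch must be {PATCH_FRAMES}x{N_MEL_BINS}, got {v.shape}"
            )
        if not np.isfinite(v).all():
            raise ValueError("patch contains non-finite values")
        object.__setattr__(self, "values", v)


def read_wav(path) -> AudioBuffer:
    """Read a WAV file (PCM 8/16/24/32-bit or float) scaled into [-1, 1]."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        if info.min < 0:
            data = data.astype(float) / max(abs(info.min), info.max)
        else:  # unsigned 8-bit: offset binary
            data = (data.astype(float) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    else:
        data = data.astype(float)
    return AudioBuffer(samples=data, sample_rate=float(rate))


def write_wav(buffer: AudioBuffer, path) -> None:
    """Write as 16-bit PCM."""
    clipped = np.clip(buffer.samples, -1.0, 1.0)
    wavfile.write(path, int(buffer.sample_rate), (clipped * 32767.0).astype(np.int16))


def to_mono_16k(audio: AudioBuffer) -> AudioBuffer:
    """Average channels to mono and polyphase-resample to 16 kHz."""
    samples = audio.samples
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    rate = int(round(audio.sample_rate))
    if rate != TARGET_SAMPLE_RATE:
        g = math.gcd(TARGET_SAMPLE_RATE, rate)
        samples = signal.resample_poly(samples, TARGET_SAMPLE_RATE // g, rate // g)
    return AudioBuffer(samples=samples, sample_rate=TARGET_SAMPLE_RATE)


def _hertz_to_mel(f: np.ndarray | float) -> np.ndarray:
    # HTK convention
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_filterbank(
    n_mels: int = N_MEL_BINS,
    n_fft: int = N_FFT,
    sample_rate: float = TARGET_SAMPLE_RATE,
    fmin: float = MEL_MIN_HZ,
    fmax: float = MEL_MAX_HZ,
) -> np.ndarray:
    """(n_fft//2 + 1, n_mels) triangular filters on the HTK mel scale."""
    freqs = np.linspace(0.0, sample_rate / 2.0, n_fft // 2 + 1)
    spec_mel = _hertz_to_mel(freqs)
    edges = np.linspace(_hertz_to_mel(fmin), _hertz_to_mel(fmax), n_mels + 2)
    lower, centre, upper = edges[:-2], edges[1:-1], edges[2:]
    up = (spec_mel[:, None] - lower[None, :]) / (centre - lower)[None, :]
    down = (upper[None, :] - spec_mel[:, None]) / (upper - centre)[None, :]
    weights = np.maximum(0.0, np.minimum(up, down))
    weights[0] = 0.0  # DC never contributes
    return weights


def n_frames(n_samples: int) -> int:
    """Frames produced by 400-sample windows hopped by 160 (no padding)."""
    if n_samples < FRAME_LENGTH:
        return 0
    return 1 + (n_samples - FRAME_LENGTH) // HOP_LENGTH


def log_mel_spectrogram(
    audio: AudioBuffer, log_offset: float = LOG_OFFSET
) -> np.ndarray:
    """(frames, 64) log-mel spectrogram of mono 16 kHz audio.

    Each 25 ms frame is periodic-Hann windowed, its magnitude spectrum mapped
    through the 64-filter HTK mel bank spanning 125-7,500 Hz, and compressed
    as ``log(mel_energy + log_offset)``.
    """
    if audio.n_channels != 1 or audio.samples.ndim != 1:
        raise ValueError("log_mel_spectrogram expects mono audio")
    if int(round(audio.sample_rate)) != TARGET_SAMPLE_RATE:
        raise ValueError("log_mel_spectrogram expects 16 kHz audio")
    x = audio.samples
    frames = n_frames(x.shape[0])
    if frames == 0:
        raise ValueError(
            f"audio shorter than one {FRAME_LENGTH}-sample analysis window"
        )
    idx = np.arange(FRAME_LENGTH)[None, :] + HOP_LENGTH * np.arange(frames)[:, None]
    window = signal.get_window("hann", FRAME_LENGTH, fftbins=True)  # periodic
    spectra = np.abs(np.fft.rfft(x[idx] * window, n=N_FFT, axis=1))
    mel = spectra @ mel_filterbank()
    return np.log(mel + log_offset)


def patch_frames(frames: np.ndarray) -> list[LogMelPatch]:
    """Cut a (n_frames, 64) spectrogram into non-overlapping 96-frame patches.

    The trailing remainder shorter than one patch is discarded; fewer than 96
    frames yields an empty list (with a warning).
    """
    frames = np.asarray(frames, dtype=float)
    n_patches = frames.shape[0] // PATCH_FRAMES
    if n_patches == 0:
        log.warning(
            "only %d frames (< %d): no patches produced", frames.shape[0], PATCH_FRAMES
        )
        return []
    return [
        LogMelPatch(
            values=frames[k * PATCH_FRAMES : (k + 1) * PATCH_FRAMES],
            start_offset=k * PATCH_FRAMES * HOP_SECONDS,
        )
        for k in range(n_patches)
    ]


class Embedder(Protocol):
    """Deterministic map from one 96x64 patch to 128 finite reals."""

    def embed(self, patch: LogMelPatch) -> np.ndarray: ...


class RandomProjectionEmbedder:
    """Seeded random linear projection of the flattened patch, tanh-squashed.

    A stand-in satisfying the embedder contract (fixed 128-dim output,
    deterministic given the seed); it carries no learned acoustic semantics.
    """

    def __init__(self, seed: int = 0, dim: int = EMBEDDING_DIM) -> None:
        rng = np.random.default_rng(seed)
        d_in = PATCH_FRAMES * N_MEL_BINS
        self.weights = rng.standard_normal((dim, d_in)) / np.sqrt(d_in)
        self.bias = rng.standard_normal(dim) * 0.1
        self.dim = dim

    def embed(self, patch: LogMelPatch) -> np.ndarray:
        return np.tanh(self.weights @ patch.values.ravel() + self.bias)


def embed_patch(patch: LogMelPatch, embedder: Embedder) -> np.ndarray:
    vec = np.asarray(embedder.embed(patch), dtype=float)
    if vec.shape != (EMBEDDING_DIM,):
        raise ValueError(f"embedder must return {EMBEDDING_DIM} values, got {vec.shape}")
    if not np.isfinite(vec).all():
        raise ValueError("embedding contains non-finite values")
    return vec


def _shannon_entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def acoustic_indices(audio: AudioBuffer, n_fft: int = 1024) -> dict[str, float]:
    """Analytic soundscape indices of a mono recording.

    temporal_entropy
        Shannon entropy of the normalized amplitude-envelope distribution,
        divided by log(n) so a flat envelope scores 1.
    spectral_entropy
        entropy of the normalized time-averaged magnitude spectrum over
        log(n_bins); white noise approaches 1.
    acoustic_complexity
        per-frequency sum of absolute frame-to-frame magnitude differences
        normalized by that frequency's total magnitude, summed over bins.
    spectrogram_cover
        fraction of spectrogram cells louder than their frequency bin's
        median by 3 dB or more.

    Silence (an all-zero signal) returns 0 for every index with a warning.
    """
    if audio.samples.ndim != 1:
        raise ValueError("acoustic_indices expects mono audio")
    x = audio.samples
    if not np.any(x):
        log.warning("silent input: all acoustic indices set to 0")
        return {name: 0.0 for name in INDEX_NAMES}

    envelope = np.abs(signal.hilbert(x))
    env_sum = envelope.sum()
    p_env = envelope / env_sum
    temporal_entropy = _shannon_entropy(p_env) / np.log(envelope.size)

    hop = n_fft // 2
    nf = 1 + (x.size - n_fft) // hop if x.size >= n_fft else 0
    if nf < 2:
        raise ValueError("recording too short for spectral indices")
    idx = np.arange(n_fft)[None, :] + hop * np.arange(nf)[:, None]
    window = signal.get_window("hann", n_fft, fftbins=True)
    spec = np.abs(np.fft.rfft(x[idx] * window, axis=1)).T  # (bins, frames)
    spec = spec[1:]  # drop DC

    mean_spectrum = spec.mean(axis=1)
    p_spec = mean_spectrum / mean_spectrum.sum()
    spectral_entropy = _shannon_entropy(p_spec) / np.log(p_spec.size)

    totals = spec.sum(axis=1)
    diffs = np.abs(np.diff(spec, axis=1)).sum(axis=1)
    # bins holding no real energy contribute only rounding noise to the
    # ratio; a relative floor keeps them out
    valid = totals > 1e-10 * totals.max()
    aci = float((diffs[valid] / totals[valid]).sum())

    spec_db = 20.0 * np.log10(spec + 1e-12)
    threshold = np.median(spec_db, axis=1, keepdims=True) + 3.0
    cover = float((spec_db > threshold).mean())

    return {
        "temporal_entropy": float(temporal_entropy),
        "spectral_entropy": float(spectral_entropy),
        "acoustic_complexity": aci,
        "spectrogram_cover": cover,
    }


class FeatureExtractor:
    """Bundle the full audio-to-feature-row pipeline for one recording.

    Produces the learned-feature block (mean patch embedding) and, when
    ``with_indices`` is on, the analytic index block, in a fixed column
    order shared across recordings.
    """

    def __init__(
        self,
        embedder: Embedder | None = None,
        log_offset: float = LOG_OFFSET,
        with_indices: bool = True,
        index_fn=acoustic_indices,
    ) -> None:
        self.embedder = embedder if embedder is not None else RandomProjectionEmbedder()
        self.log_offset = log_offset
        self.with_indices = with_indices
        self.index_fn = index_fn

    @property
    def feature_names(self) -> tuple[str, ...]:
        names = tuple(f"LF_{k:03d}" for k in range(EMBEDDING_DIM))
        if self.with_indices:
            names += INDEX_NAMES
        return names

    @property
    def family(self) -> tuple[FeatureFamily, ...]:
        fam: tuple[FeatureFamily, ...] = ("LF",) * EMBEDDING_DIM
        if self.with_indices:
            fam += ("SSI",) * len(INDEX_NAMES)
        return fam

    def __call__(self, audio: AudioBuffer) -> np.ndarray:
        return mean_features_per_recording(audio, self)


def mean_features_per_recording(
    audio: AudioBuffer, extractor: FeatureExtractor
) -> np.ndarray:
    """One feature row per recording.

    The learned-feature block is the arithmetic mean of the per-patch
    embeddings; the index block is computed once on the whole recording.
    """
    mono = to_mono_16k(audio)
    patches = patch_frames(log_mel_spectrogram(mono, extractor.log_offset))
    if not patches:
        raise ValueError("recording too short to produce any 0.96 s patch")
    embeddings = np.stack([embed_patch(p, extractor.embedder) for p in patches])
    row = embeddings.mean(axis=0)
    if extractor.with_indices:
        indices = extractor.index_fn(mono)
        row = np.concatenate([row, [indices[k] for k in INDEX_NAMES]])
    return row


def match_recordings_to_point_count(
    point_count: PointCount,
    recordings: Sequence[Recording],
    feature_rows: Mapping[str, np.ndarray],
    window_minutes: float = 60.0,
) -> tuple[list[Recording], np.ndarray]:
    """Recordings starting within a closed window centred on the point count.

    A recording matches iff its start time lies in
    ``[start - window/2, start + window/2]`` (both edges included); the
    returned row is the mean of the matched recordings' feature rows.
    Raises :class:`NoMatchedRecordingError` when nothing matches — such point
    counts are excluded from feature-based analyses.
    """
    half = timedelta(minutes=window_minutes / 2.0)
    lo, hi = point_count.start_time - half, point_count.start_time + half
    matched = [r for r in recordings if lo <= r.start_time <= hi]
    if not matched:
        raise NoMatchedRecordingError(
            f"no recording within {window_minutes} min window of "
            f"point count {point_count.id}"
        )
    rows = np.stack([np.asarray(feature_rows[r.id], dtype=float) for r in matched])
    return matched, rows.mean(axis=0)


def build_feature_table(
    point_counts: Sequence[PointCount],
    recordings: Sequence[Recording],
    audio_for: Mapping[str, AudioBuffer],
    extractor: FeatureExtractor | None = None,
    window_minutes: float = 60.0,
) -> FeatureTable:
    """Extract and window-match features for a whole dataset.

    Point counts with no recording in their window are dropped with a
    warning (they cannot enter feature-based analyses).
    """
    extractor = extractor or FeatureExtractor()
    rows = {r.id: mean_features_per_recording(audio_for[r.id], extractor)
            for r in recordings}
    ids, values = [], []
    for pc in point_counts:
        try:
            _, row = match_recordings_to_point_count(
                pc, recordings, rows, window_minutes
            )
        except NoMatchedRecordingError:
            log.warning("point count %s: no matched recording, excluded", pc.id)
            continue
        ids.append(pc.id)
        values.append(row)
    if not ids:
        raise ValueError("no point count matched any recording")
    return FeatureTable(
        tuple(ids), extractor.feature_names, extractor.family, np.stack(values)
    )
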