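"""Isochronous audio rendering of syllable streams and amplitude-modulation
spectra.

Syllables are either loaded from user-provided WAV files or synthesized
internally with a deterministic harmonic-plus-noise recipe (consonant and
vowel portions shaped by the phonemes' distinctive features).  The internal
synthesis makes no naturalness claims; it exists so spectra and pitch
contours are testable without recordings.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from .phonology import DEFAULT_CONSONANT_FEATURES, DEFAULT_VOWEL_FEATURES, Syllable
from .streams import Stream


class AudioError(ValueError):
    pass


@dataclass(frozen=True)
class AudioSpec:
    """Rendering parameters.

    ``target_level_db`` is a *nominal* common level: all syllables are scaled
    to one shared RMS (65 dB maps to RMS 0.05 re full scale); calibrated
    sound pressure at playback is the experimenter's responsibility.
    """

    syllable_duration_ms: float = 300.0
    target_level_db: float = 65.0
    sample_rate: int = 44_100

    def __post_init__(self) -> None:
        if self.syllable_duration_ms <= 0:
            raise AudioError("syllable_duration_ms must be positive")
        if self.sample_rate < 8000:
            raise AudioError("sample_rate must be >= 8000 Hz")

    @property
    def n_samples_per_syllable(self) -> int:
        return int(round(self.syllable_duration_ms / 1000.0 * self.sample_rate))

    @property
    def target_rms(self) -> float:
        return 0.05 * 10.0 ** ((self.target_level_db - 65.0) / 20.0)


def _seed_from_symbol(symbol: str) -> int:
    return int.from_bytes(hashlib.sha256(symbol.encode()).digest()[:4], "big")


def _consonant_features(syl: Syllable) -> dict[str, bool]:
    row = 0
    for slot in syl.pattern:
        feats = DEFAULT_VOWEL_FEATURES if slot in "vV" else DEFAULT_CONSONANT_FEATURES
        if slot == "c":
            block = syl.feature_matrix[row:row + len(feats)].any(axis=1)
            return dict(zip(feats, block.tolist()))
        row += len(feats)
    return {}


def _vowel_features(syl: Syllable) -> dict[str, bool]:
    row = 0
    for slot in syl.pattern:
        feats = DEFAULT_VOWEL_FEATURES if slot in "vV" else DEFAULT_CONSONANT_FEATURES
        if slot in "vV":
            block = syl.feature_matrix[row:row + len(feats)].any(axis=1)
            return dict(zip(feats, block.tolist()))
        row += len(feats)
    return {}


def _harmonic(f0_track: np.ndarray, sr: int, n_harmonics: int = 8) -> np.ndarray:
    phase = 2.0 * np.pi * np.cumsum(f0_track) / sr
    out = np.zeros_like(phase)
    for h in range(1, n_harmonics + 1):
        out += np.sin(h * phase) / h
    return out


def _ramp(n: int, sr: int, ms: float = 10.0) -> np.ndarray:
    k = min(n // 2, max(1, int(sr * ms / 1000.0)))
    env = np.ones(n)
    win = 0.5 * (1 - np.cos(np.linspace(0, np.pi, k)))
    env[:k] = win
    env[-k:] = win[::-1]
    return env


def synthesize_syllable(
    syl: Syllable,
    spec: AudioSpec,
    f0_track: np.ndarray | None = None,
    f0: float = 200.0,
) -> np.ndarray:
    """Deterministic harmonic-plus-noise rendering of one syllable.

    The consonant portion's envelope and noise character depend on its
    manner/place features; the vowel portion is a harmonic stack with
    formant-like band emphasis from the vowel's features.  Scaled to the
    spec's common RMS.
    """
    sr = spec.sample_rate
    n = spec.n_samples_per_syllable
    if f0_track is None:
        f0_track = np.full(n, float(f0))
    elif len(f0_track) != n:
        f0_track = np.interp(
            np.linspace(0, 1, n), np.linspace(0, 1, len(f0_track)), f0_track
        )
    rng = np.random.default_rng(_seed_from_symbol(syl.id))

    # consonant portion length varies per syllable: a large, deterministic
    # source of envelope-shape diversity (mirrors natural syllables, which
    # differ in temporal structure even after duration equalization)
    frac = 0.30 + 0.20 * rng.random()
    n_c = int(frac * n)
    n_v = n - n_c
    cf = _consonant_features(syl)
    vf = _vowel_features(syl)

    # consonant portion
    cons = np.zeros(n_c)
    if cf:
        noise = rng.standard_normal(n_c)
        if cf.get("son"):
            # sonorant: voiced, gently rising, nearly continuous with the vowel
            cons = _harmonic(f0_track[:n_c], sr, n_harmonics=3)
            cons *= np.linspace(0.4, 1.0, n_c)
        elif cf.get("cont"):
            # fricative: sustained band-passed noise at reduced amplitude
            lo, hi = (1000, 4000) if cf.get("lab") else (3000, min(8000, sr // 2 - 100))
            sos = signal.butter(4, [lo, hi], btype="band", fs=sr, output="sos")
            cons = 0.5 * signal.sosfilt(sos, noise)
        else:
            # plosive: long closure silence then a sharply decaying burst
            closure = int((0.55 + 0.2 * rng.random()) * n_c)
            burst = noise[closure:] * np.exp(-np.arange(n_c - closure) / (0.012 * sr))
            cons = np.concatenate([np.zeros(closure), burst])
        if cf.get("voi") and not cf.get("son"):
            cons += 0.3 * _harmonic(f0_track[:n_c], sr, n_harmonics=2)

    # vowel portion: harmonic stack with feature-dependent band emphasis
    vow = _harmonic(f0_track[n_c:], sr, n_harmonics=10)
    f1 = 300 + (400 if vf.get("lo") else 0) - (100 if vf.get("hi") else 0)
    f2 = 2200 - (900 if vf.get("back") else 0) - (200 if vf.get("lab") else 0)
    for fc, gain in ((f1, 1.0), (f2, 0.5)):
        sos = signal.butter(2, [max(50, fc - 150), fc + 150], btype="band", fs=sr, output="sos")
        vow = vow + gain * signal.sosfilt(sos, vow)
    # deterministic per-syllable attack/decay variation: natural syllables
    # differ in envelope shape even after duration/level equalization
    attack = 15.0 + 50.0 * rng.random()
    decay = 20.0 + 80.0 * rng.random()
    k_a = max(1, int(sr * attack / 1000.0))
    k_d = max(1, int(sr * decay / 1000.0))
    env = np.ones(n_v)
    k_a = min(k_a, n_v // 2)
    k_d = min(k_d, n_v // 2)
    env[:k_a] = 0.5 * (1 - np.cos(np.linspace(0, np.pi, k_a)))
    env[-k_d:] = 0.5 * (1 + np.cos(np.linspace(0, np.pi, k_d)))
    vow *= env

    wave = np.concatenate([cons, vow]) * _ramp(n, sr, ms=5.0)
    rms = float(np.sqrt(np.mean(wave**2)))
    if rms == 0:
        raise AudioError(f"synthesized syllable {syl.id!r} has zero energy")
    return wave * (spec.target_rms / rms)


def _fit_duration(wave: np.ndarray, n_target: int, sr: int) -> np.ndarray:
    """Uniform time-scaling within +/-20% of target, else pad/truncate with
    10-ms cosine ramps."""
    n = len(wave)
    if n == n_target:
        return wave
    if 0.8 <= n / n_target <= 1.25:
        return signal.resample(wave, n_target)
    if n > n_target:
        out = wave[:n_target].copy()
    else:
        out = np.concatenate([wave, np.zeros(n_target - n)])
    return out * _ramp(n_target, sr, ms=10.0)


def load_syllable_wav(path: str | Path, spec: AudioSpec) -> np.ndarray:
    """Read a mono WAV, resample to the spec rate, fit duration, normalize."""
    sr, data = wavfile.read(path)
    if data.ndim != 1:
        raise AudioError(f"{path}: only mono syllable files are supported")
    data = data.astype(float)
    if np.issubdtype(np.asarray(data).dtype, np.floating) and np.abs(data).max() > 1.5:
        data = data / 32768.0  # integer PCM
    if sr != spec.sample_rate:
        data = signal.resample_poly(data, spec.sample_rate, sr)
    data = _fit_duration(data, spec.n_samples_per_syllable, spec.sample_rate)
    rms = float(np.sqrt(np.mean(data**2)))
    if rms == 0:
        raise AudioError(f"{path}: zero-energy (silent) syllable file")
    return data * (spec.target_rms / rms)


def apply_pitch_contour(
    stream: Stream,
    contour: Sequence[float],
    window: str = "syllable",
    spec: AudioSpec | None = None,
) -> list[np.ndarray]:
    """Resample a pitch contour onto each syllable (or word) window.

    Returns one f0 track per stream syllable, each of the per-syllable
    sample length, linearly interpolated so the contour's endpoints are
    preserved per window.  ``window='word'`` stretches one contour copy over
    each word (annotated streams) or over consecutive chunks of ``S``
    syllables otherwise.
    """
    contour = np.asarray(contour, dtype=float)
    if np.any(contour <= 0):
        raise AudioError("pitch contour must be strictly positive (Hz)")
    if window not in ("syllable", "word"):
        raise AudioError("window must be 'syllable' or 'word'")
    spec = spec or AudioSpec()
    n = spec.n_samples_per_syllable
    T = len(stream)
    if window == "syllable":
        track = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, len(contour)), contour)
        return [track.copy() for _ in range(T)]
    S = stream.lexicon.n_syllables_per_word
    starts = [
        t for t in range(T)
        if (stream.word_position[t] == 0 if stream.word_position[t] is not None else t % S == 0)
    ]
    tracks: list[np.ndarray] = []
    for i, start in enumerate(starts):
        end = starts[i + 1] if i + 1 < len(starts) else T
        width = (end - start) * n
        word_track = np.interp(
            np.linspace(0, 1, width), np.linspace(0, 1, len(contour)), contour
        )
        for s_i in range(end - start):
            tracks.append(word_track[s_i * n:(s_i + 1) * n])
    return tracks


def render_stream_audio(
    stream: Stream,
    spec: AudioSpec | None = None,
    syllable_audio: Mapping[str, str | Path] | None = None,
    pitch_tracks: Sequence[np.ndarray] | None = None,
    f0: float = 200.0,
) -> np.ndarray:
    """Concatenate per-syllable waveforms into one isochronous stream.

    Every syllable occupies exactly ``spec.n_samples_per_syllable`` samples
    at a common RMS; total duration is ``T x syllable_duration``.
    Deterministic for a fixed stream and spec.
    """
    spec = spec or AudioSpec()
    n = spec.n_samples_per_syllable
    out = np.zeros(len(stream) * n)
    syl_by_id = {s.id: s for w in stream.lexicon.words for s in w.syllables}
    cache: dict[str, np.ndarray] = {}
    for t, tok in enumerate(stream.tokens):
        if syllable_audio is not None:
            if tok not in syllable_audio:
                raise AudioError(f"no audio file provided for syllable {tok!r}")
            if tok not in cache:
                cache[tok] = load_syllable_wav(syllable_audio[tok], spec)
            wave = cache[tok]
        elif pitch_tracks is not None:
            syl = syl_by_id[tok]
            wave = synthesize_syllable(syl, spec, f0_track=np.asarray(pitch_tracks[t]))
        else:
            if tok not in cache:
                cache[tok] = synthesize_syllable(syl_by_id[tok], spec, f0=f0)
            wave = cache[tok]
        out[t * n:(t + 1) * n] = wave
    return out


def write_wav(path: str | Path, waveform: np.ndarray, spec: AudioSpec) -> None:
    wavfile.write(path, spec.sample_rate, waveform.astype(np.float32))


@dataclass(frozen=True)
class ModSpectrum:
    """Envelope power spectrum on a uniform frequency grid."""

    frequencies: np.ndarray
    power: np.ndarray
    resolution: float

    def peak_frequency(self, lo: float, hi: float) -> float:
        """Frequency of maximum power within ``[lo, hi]`` Hz."""
        band = (self.frequencies >= lo) & (self.frequencies <= hi)
        if not band.any():
            raise AudioError(f"no spectral bins in [{lo}, {hi}] Hz")
        idx = np.flatnonzero(band)
        return float(self.frequencies[idx[np.argmax(self.power[idx])]])

    def band_power(self, center: float, halfwidth: float = 0.05) -> float:
        band = np.abs(self.frequencies - center) <= halfwidth
        return float(self.power[band].sum())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"freq_hz": self.frequencies, "power": self.power}).to_csv(
            path, index=False
        )


def amplitude_modulation_spectrum(
    waveform: np.ndarray, sample_rate: int, env_rate: int = 1000
) -> ModSpectrum:
    """Power spectrum of the slow amplitude envelope.

    Envelope = magnitude of the analytic signal, low-passed at 30 Hz,
    downsampled to ``env_rate``, mean-removed; spectrum via an un-windowed
    DFT of the whole envelope (resolution = 1/duration).
    """
    duration = len(waveform) / sample_rate
    if duration < 10.0:
        raise AudioError("waveform too short for modulation spectrum (need >= 10 s)")
    env = np.abs(signal.hilbert(waveform))
    sos = signal.butter(4, 30.0, btype="low", fs=sample_rate, output="sos")
    env = signal.sosfiltfilt(sos, env)
    env = signal.resample_poly(env, env_rate, sample_rate)
    env = env - env.mean()
    spec = np.fft.rfft(env)
    freqs = np.fft.rfftfreq(len(env), d=1.0 / env_rate)
    return ModSpectrum(
        frequencies=freqs,
        power=np.abs(spec) ** 2,
        resolution=float(freqs[1] - freqs[0]) if len(freqs) > 1 else 0.0,
    )
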