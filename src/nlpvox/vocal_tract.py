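"""Vocal-tract filtering: formants, diphthong morphing, envelope transplantation.

The filter side of the source-filter model.  Vowels are realized by
multiplying STFT frames of the source with a spectral envelope built from
resonance peaks at the formant frequencies; diphthongs morph the formant
targets linearly over the token.  For resynthesis of recorded material the
smoothed spectral envelope (300 Hz frequency window) and amplitude envelope
(200 ms time window) of the original are transplanted onto the synthetic
source.  A simple Hilbert-envelope compressor evens out level differences
within a token.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert, istft, stft

from .source_synthesis import Waveform

# STFT geometry shared by the filter and the envelope machinery
NPERSEG = 1024
NOVERLAP = 768
NFFT = 2048

FREQ_SMOOTH_HZ = 300.0   # spectral-envelope smoothing window
TIME_SMOOTH_S = 0.2      # amplitude-envelope smoothing window
COMPRESS_WINDOW_S = 0.05


@dataclass
class VowelFormants:
    """First four formant frequencies and bandwidths of one vowel."""

    label: str
    formants: np.ndarray      # F1..F4, Hz
    bandwidths: np.ndarray    # B1..B4, Hz

    def __post_init__(self) -> None:
        self.formants = np.asarray(self.formants, dtype=float)
        self.bandwidths = np.asarray(self.bandwidths, dtype=float)
        if np.any(np.diff(self.formants) <= 0) or np.any(self.formants <= 0):
            raise ValueError("formants must be positive and strictly increasing")
        if np.any(self.bandwidths <= 0):
            raise ValueError("bandwidths must be positive")


def default_bandwidth(f: np.ndarray) -> np.ndarray:
    """Default formant bandwidth: 50 + 0.05 F (Hz), rising with frequency."""
    return 50.0 + 0.05 * np.asarray(f, dtype=float)


def _vowel(label: str, f: tuple[float, ...]) -> VowelFormants:
    f = np.array(f, dtype=float)
    return VowelFormants(label, f, default_bandwidth(f))


#: typical adult-male formant targets; user-overridable via load_vowel_table
DEFAULT_VOWELS: dict[str, VowelFormants] = {
    "a": _vowel("a", (730, 1090, 2440, 3400)),
    "o": _vowel("o", (500, 850, 2400, 3300)),
    "e": _vowel("e", (530, 1840, 2480, 3500)),
    "i": _vowel("i", (270, 2290, 3010, 3700)),
    "u": _vowel("u", (300, 870, 2240, 3400)),
}


def load_vowel_table(path_or_buf) -> dict[str, VowelFormants]:
    """Read a vowel table CSV with columns label, F1..F4, B1..B4."""
    df = pd.read_csv(path_or_buf)
    table = {}
    for _, row in df.iterrows():
        f = row[["F1", "F2", "F3", "F4"]].to_numpy(float)
        b = row[["B1", "B2", "B3", "B4"]].to_numpy(float)
        table[str(row["label"])] = VowelFormants(str(row["label"]), f, b)
    return table


def save_vowel_table(table: dict[str, VowelFormants], path) -> None:
    rows = []
    for label, v in table.items():
        rows.append(
            {"label": label}
            | {f"F{i+1}": v.formants[i] for i in range(4)}
            | {f"B{i+1}": v.bandwidths[i] for i in range(4)}
        )
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class DiphthongSpec:
    """Morph between two vowels: 0 = monophthong, 1 = full diphthong."""

    vowel_from: VowelFormants
    vowel_to: VowelFormants
    morph: float = 0.0
    duration: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 <= self.morph <= 1.0:
            raise ValueError("morph must be in [0, 1]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class SpectralEnvelope:
    """Smoothed time-frequency magnitude surface on an STFT grid."""

    times: np.ndarray
    freqs: np.ndarray
    magnitudes: np.ndarray  # (n_freqs, n_times), non-negative

    def __post_init__(self) -> None:
        if np.any(self.magnitudes < 0):
            raise ValueError("envelope magnitudes must be non-negative")


@dataclass
class AmplitudeEnvelope:
    times: np.ndarray
    values: np.ndarray


# ---------------------------------------------------------------------------
# formants
# ---------------------------------------------------------------------------

def extend_formants(formants: np.ndarray, nyquist: float) -> np.ndarray:
    """Extend F1..F4 up to Nyquist using the mean inter-formant spacing."""
    f = np.asarray(formants, dtype=float)
    if f.size < 4:
        raise ValueError("need four formants to estimate spacing")
    if np.any(f >= nyquist):
        raise ValueError("input formants must lie below Nyquist")
    delta = float(np.mean(np.diff(f[:4])))
    if delta <= 0:
        raise ValueError("non-positive formant spacing")
    extra = []
    nxt = f[3] + delta
    while nxt < nyquist:
        extra.append(nxt)
        nxt += delta
    return np.concatenate([f, extra]) if extra else f.copy()


def morph_formant_tracks(spec: DiphthongSpec, n_frames: int) -> np.ndarray:
    """Linear formant trajectories: (n_frames, 4) from vowel_from toward vowel_to.

    At time fraction tau the i-th formant is
    ``F_from_i + tau * morph * (F_to_i - F_from_i)``; a morph of 0 keeps the
    tracks static and a morph of 1 reaches the second vowel at the end.
    """
    tau = np.linspace(0.0, 1.0, n_frames)[:, None]
    f_from = spec.vowel_from.formants[None, :]
    f_to = spec.vowel_to.formants[None, :]
    return f_from + tau * spec.morph * (f_to - f_from)


def resonance_envelope(
    freqs: np.ndarray, formants: np.ndarray, bandwidths: np.ndarray
) -> np.ndarray:
    """Sum of Lorentzian resonance peaks (unit gain at each formant)."""
    env = np.zeros_like(freqs, dtype=float)
    for f0, bw in zip(formants, bandwidths):
        hw = bw / 2.0
        env += hw**2 / ((freqs - f0) ** 2 + hw**2)
    return env


def formant_filter(
    source: Waveform,
    formant_tracks: np.ndarray,
    bandwidths: np.ndarray | None = None,
    extend_to_nyquist: bool = True,
) -> Waveform:
    """Impose time-varying formant resonances on a source waveform.

    ``formant_tracks`` has shape (n_track_frames, n_formants); tracks are
    interpolated to the STFT frame times, optionally extended above F4 with
    the mean-spacing rule, converted to a sum-of-resonances envelope per
    frame, and multiplied onto the STFT of the source.
    """
    sr = source.sample_rate
    nyq = sr / 2.0
    tracks = np.atleast_2d(np.asarray(formant_tracks, dtype=float))
    if np.any(tracks >= nyq):
        raise ValueError("formant frequency at or above Nyquist")
    f_axis, t_axis, Z = stft(source.samples, fs=sr, nperseg=NPERSEG,
                             noverlap=NOVERLAP, nfft=NFFT)
    n_frames = t_axis.size
    # resample tracks to the STFT frame grid
    src_tau = np.linspace(0.0, 1.0, tracks.shape[0]) if tracks.shape[0] > 1 else [0.0]
    tau = np.linspace(0.0, 1.0, n_frames)
    frame_tracks = np.column_stack(
        [np.interp(tau, src_tau, tracks[:, j]) for j in range(tracks.shape[1])]
    )
    env_frames = np.empty((f_axis.size, n_frames))
    for i in range(n_frames):
        f = frame_tracks[i]
        if extend_to_nyquist and f.size >= 4:
            f = extend_formants(f, nyq)
        b = default_bandwidth(f) if bandwidths is None else np.resize(
            np.asarray(bandwidths, dtype=float), f.size
        )
        if bandwidths is not None and f.size > np.asarray(bandwidths).size:
            b[np.asarray(bandwidths).size:] = default_bandwidth(
                f[np.asarray(bandwidths).size:]
            )
        env_frames[:, i] = resonance_envelope(f_axis, f, b)
    _, y = istft(Z * env_frames, fs=sr, nperseg=NPERSEG, noverlap=NOVERLAP, nfft=NFFT)
    y = y[: source.samples.size]
    if y.size < source.samples.size:
        y = np.pad(y, (0, source.samples.size - y.size))
    return Waveform(y, sr)


# ---------------------------------------------------------------------------
# envelope extraction / transplantation
# ---------------------------------------------------------------------------

def extract_envelopes(
    audio: Waveform,
    freq_window_hz: float = FREQ_SMOOTH_HZ,
    time_window_s: float = TIME_SMOOTH_S,
) -> tuple[SpectralEnvelope, AmplitudeEnvelope]:
    """Smoothed spectral and amplitude envelopes of a waveform.

    The STFT magnitude is smoothed along frequency with a moving-average
    kernel of ``freq_window_hz``; the amplitude envelope is the per-frame
    RMS magnitude smoothed over ``time_window_s``.
    """
    if audio.rms() == 0:
        raise ValueError("cannot extract envelopes from silent audio")
    sr = audio.sample_rate
    f_axis, t_axis, Z = stft(audio.samples, fs=sr, nperseg=NPERSEG,
                             noverlap=NOVERLAP, nfft=NFFT)
    mag = np.abs(Z)
    df = f_axis[1] - f_axis[0]
    k_freq = max(1, int(round(freq_window_hz / df)))
    smooth = uniform_filter1d(mag, size=k_freq, axis=0, mode="nearest")
    frame_dt = (NPERSEG - NOVERLAP) / sr
    k_time = max(1, int(round(time_window_s / frame_dt)))
    amp = np.sqrt(np.mean(mag**2, axis=0))
    amp = uniform_filter1d(amp, size=k_time, mode="nearest")
    return (
        SpectralEnvelope(t_axis, f_axis, smooth),
        AmplitudeEnvelope(t_axis, amp),
    )


def transplant_envelopes(
    source: Waveform,
    env: SpectralEnvelope,
    amp_env: AmplitudeEnvelope | None = None,
    max_gain_db: float = 40.0,
) -> Waveform:
    """Copy a target's smoothed spectral/amplitude envelopes onto a source.

    Per STFT frame the source spectrum is multiplied by the ratio of the
    target envelope to the source's own smoothed envelope (gain clamped to
    +-``max_gain_db``); the amplitude envelope is then imposed by frame-wise
    rescaling.  Transplanting a signal's own envelopes is a fixed point.
    """
    sr = source.sample_rate
    dur_ratio = source.duration / max(env.times[-1], 1e-9)
    if not 0.9 <= dur_ratio <= 1.1:
        raise ValueError("source and envelope durations differ by more than 10%")
    f_axis, t_axis, Z = stft(source.samples, fs=sr, nperseg=NPERSEG,
                             noverlap=NOVERLAP, nfft=NFFT)
    own_env, own_amp = extract_envelopes(source)
    # resample target envelope onto the source frame grid (frequency grids match)
    target = np.empty((f_axis.size, t_axis.size))
    for i in range(f_axis.size):
        target[i] = np.interp(t_axis, env.times, env.magnitudes[i])
    lim = 10.0 ** (max_gain_db / 20.0)
    gain = np.clip(target / np.maximum(own_env.magnitudes, 1e-12), 1.0 / lim, lim)
    # ignore essentially silent frames
    frame_energy = np.sqrt(np.mean(np.abs(Z) ** 2, axis=0))
    silent = frame_energy < 1e-6 * max(frame_energy.max(), 1e-12)
    gain[:, silent] = 1.0
    _, y = istft(Z * gain, fs=sr, nperseg=NPERSEG, noverlap=NOVERLAP, nfft=NFFT)
    y = y[: source.samples.size]
    if y.size < source.samples.size:
        y = np.pad(y, (0, source.samples.size - y.size))
    out = Waveform(y, sr)
    if amp_env is not None:
        _, cur_amp = extract_envelopes(out)
        t_samples = np.arange(out.samples.size) / sr
        target_amp = np.interp(t_samples, amp_env.times, amp_env.values)
        current = np.interp(t_samples, cur_amp.times, cur_amp.values)
        scale = np.clip(target_amp / np.maximum(current, 1e-12), 0.0, lim)
        out = Waveform(out.samples * scale, sr)
    return out


def compress_dynamics(
    wave: Waveform,
    window: float = COMPRESS_WINDOW_S,
    floor_frac: float = 0.01,
) -> Waveform:
    """Even out the amplitude envelope using a smoothed Hilbert envelope.

    The signal is divided by its Hilbert envelope (smoothed over ``window``
    seconds, floored at ``floor_frac`` of its peak to avoid blowing up
    silences) and rescaled to the input RMS.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rms_in = wave.rms()
    if rms_in == 0:
        raise ValueError("cannot compress silent audio")
    env = np.abs(hilbert(wave.samples))
    k = max(1, int(round(window * wave.sample_rate)))
    env = uniform_filter1d(env, size=k, mode="nearest")
    floor = floor_frac * env.max()
    y = wave.samples / np.maximum(env, floor)
    y *= rms_in / np.sqrt(np.mean(y**2))
    return Waveform(y, wave.sample_rate)
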