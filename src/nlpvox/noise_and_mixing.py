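"""Masking-noise generation, SNR mixing and token concatenation.

Masking noise is built in the frequency domain — a magnitude profile that
is flat up to a corner frequency and falls off linearly in dB per kHz above
it, combined with random phases — and converted to the time domain by
inverse FFT.  Speech and noise are mixed after RMS normalization at a
target signal-to-noise ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .source_synthesis import DEFAULT_SAMPLE_RATE, Waveform


@dataclass
class NoiseProfile:
    """Spectral profile of the masking noise."""

    corner: float = 1200.0      # Hz, flat below
    slope: float = -6.0         # dB per kHz above the corner
    duration: float = 4.0       # seconds
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        if self.corner <= 0:
            raise ValueError("corner must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.corner >= self.sample_rate / 2:
            raise ValueError("corner frequency at or above Nyquist")


@dataclass
class MixSpec:
    snr: float                  # dB, RMS-based
    normalization: str = "rms"

    def __post_init__(self) -> None:
        if not np.isfinite(self.snr):
            raise ValueError("snr must be finite")


def generate_masking_noise(
    profile: NoiseProfile, rng: np.random.Generator
) -> Waveform:
    """Noise with a flat spectrum below the corner and a linear dB/kHz slope above.

    The target magnitude is laid out on the rFFT grid, random phases are
    drawn from ``rng``, and the result is inverse-transformed; a fixed seed
    reproduces the noise bit-exactly.
    """
    n = int(round(profile.duration * profile.sample_rate))
    freqs = np.fft.rfftfreq(n, 1.0 / profile.sample_rate)
    mag_db = np.where(
        freqs <= profile.corner,
        0.0,
        profile.slope * (freqs - profile.corner) / 1000.0,
    )
    mag = 10.0 ** (mag_db / 20.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    spectrum = mag * np.exp(1j * phases)
    spectrum[0] = 0.0  # no DC
    if n % 2 == 0:
        spectrum[-1] = spectrum[-1].real
    x = np.fft.irfft(spectrum, n=n)
    x /= np.sqrt(np.mean(x**2))
    return Waveform(x, profile.sample_rate)


def mix_at_snr(signal: Waveform, noise: Waveform, snr: float) -> Waveform:
    """Mix signal and noise at an RMS signal-to-noise ratio in dB.

    The noise is truncated to the signal length, scaled so the realized
    20*log10(RMS_signal / RMS_noise) equals ``snr``, and the sum is
    peak-normalized when it would otherwise clip.
    """
    if signal.sample_rate != noise.sample_rate:
        raise ValueError("sample rates differ")
    if noise.samples.size < signal.samples.size:
        raise ValueError("noise must be at least as long as the signal")
    s_rms = signal.rms()
    n_seg = noise.samples[: signal.samples.size]
    n_rms = float(np.sqrt(np.mean(n_seg**2)))
    if s_rms == 0 or n_rms == 0:
        raise ValueError("silent signal or noise")
    scale = s_rms / (n_rms * 10.0 ** (snr / 20.0))
    mixed = signal.samples + scale * n_seg
    peak = np.max(np.abs(mixed))
    if peak > 1.0:
        mixed = mixed / peak
    return Waveform(mixed, signal.sample_rate)


def concatenate_with_pauses(
    tokens: list[Waveform],
    pause_range: tuple[float, float] = (0.05, 0.2),
    rng: np.random.Generator | None = None,
) -> tuple[Waveform, pd.DataFrame]:
    """Concatenate tokens with uniform random pauses; return audio + boundary log.

    The boundary log has one row per token (token_index, start_s, end_s),
    so every token's position is recoverable from the output.
    """
    if not tokens:
        raise ValueError("empty token list")
    sr = tokens[0].sample_rate
    if any(t.sample_rate != sr for t in tokens):
        raise ValueError("all tokens must share a sample rate")
    rng = np.random.default_rng() if rng is None else rng
    pieces = []
    rows = []
    pos = 0
    for i, tok in enumerate(tokens):
        if i > 0:
            pause = rng.uniform(*pause_range)
            n_pause = int(round(pause * sr))
            pieces.append(np.zeros(n_pause))
            pos += n_pause
        pieces.append(tok.samples)
        rows.append(
            {"token_index": i, "start_s": pos / sr, "end_s": (pos + tok.samples.size) / sr}
        )
        pos += tok.samples.size
    return Waveform(np.concatenate(pieces), sr), pd.DataFrame(rows)
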