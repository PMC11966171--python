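"""Glottal-source synthesis: additive harmonics with spectral rolloff plus noise.

The voice source is modelled as a sum of continuous sine waves, one per
harmonic of the fundamental-frequency (f0) contour, with harmonic k
attenuated by ``rolloff`` dB per octave relative to the fundamental, and an
optional white-noise component at a fixed level (dB) relative to the
harmonic part.  A fully aperiodic "whisper" source (noise only) is also
provided.  All synthesis is phase-continuous: the phase of each harmonic is
the cumulative integral of its instantaneous frequency, so slowly varying
f0 contours produce no clicks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.io import wavfile

DEFAULT_SAMPLE_RATE = 22_050
#: guard band (Hz) below Nyquist: harmonics are dropped once they get this close
NYQUIST_GUARD_HZ = 50.0
#: admissible fundamental-frequency range (Hz) for voiced anchors
F0_MIN, F0_MAX = 30.0, 3000.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class F0Contour:
    """Time-stamped fundamental-frequency trajectory.

    Parameters
    ----------
    times
        Anchor times in seconds, strictly increasing.
    values
        f0 at each anchor in Hz; must lie in (30, 3000) for voiced anchors.
    voiced
        Boolean flag per anchor; unvoiced anchors delimit silent spans.
    """

    times: np.ndarray
    values: np.ndarray
    voiced: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.voiced is None:
            self.voiced = np.ones(self.times.shape, dtype=bool)
        self.voiced = np.asarray(self.voiced, dtype=bool)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("contour must have at least one anchor")
        if self.times.size != self.values.size or self.times.size != self.voiced.size:
            raise ValueError("times, values and voiced must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("anchor times must be strictly increasing")
        v = self.values[self.voiced]
        if v.size and (np.any(v <= F0_MIN) or np.any(v >= F0_MAX)):
            raise ValueError(f"voiced f0 values must lie in ({F0_MIN}, {F0_MAX}) Hz")

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def scaled(self, factor: float) -> "F0Contour":
        """Return a copy with every f0 value multiplied by ``factor``."""
        return F0Contour(self.times.copy(), self.values * factor, self.voiced.copy())

    @classmethod
    def constant(cls, f0: float, duration: float, n_anchors: int = 2) -> "F0Contour":
        t = np.linspace(0.0, duration, max(2, n_anchors))
        return cls(t, np.full(t.shape, float(f0)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.times, "f0_hz": self.values, "voiced": self.voiced.astype(int)}
        )

    @classmethod
    def from_frame(cls, df) -> "F0Contour":
        return cls(
            df["time_s"].to_numpy(float),
            df["f0_hz"].to_numpy(float),
            df["voiced"].to_numpy(bool),
        )


@dataclass
class SourceSpec:
    """Parameters of the glottal source for one token."""

    f0: F0Contour
    rolloff: float = 9.0          # dB/octave attenuation of harmonic k re harmonic 1
    noise_level: float = -np.inf  # dB of white noise re harmonic component
    sample_rate: int = DEFAULT_SAMPLE_RATE
    duration: float | None = None

    def __post_init__(self) -> None:
        if self.rolloff < 0:
            raise ValueError("rolloff must be >= 0 dB/octave")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class Waveform:
    """Mono audio buffer with its sample rate."""

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2))) if self.samples.size else 0.0

    def peak(self) -> float:
        return float(np.max(np.abs(self.samples))) if self.samples.size else 0.0

    def normalized(self, peak: float = 0.95) -> "Waveform":
        """Scale so that max |amplitude| equals ``peak`` (<= 1)."""
        p = self.peak()
        if p == 0:
            return Waveform(self.samples.copy(), self.sample_rate)
        return Waveform(self.samples * (peak / p), self.sample_rate)

    def write_wav(self, path) -> None:
        """Write mono 16-bit PCM; peak-normalizes only if clipping would occur."""
        x = self.samples
        p = np.max(np.abs(x)) if x.size else 0.0
        if p > 1.0:
            x = x / p
        wavfile.write(path, self.sample_rate, (x * 32767).astype(np.int16))

    @classmethod
    def read_wav(cls, path) -> "Waveform":
        sr, data = wavfile.read(path)
        if data.ndim > 1:
            data = data.mean(axis=1)
        if np.issubdtype(data.dtype, np.integer):
            data = data / np.iinfo(data.dtype).max
        return cls(np.asarray(data, dtype=float), int(sr))


# ---------------------------------------------------------------------------
# f0 interpolation
# ---------------------------------------------------------------------------

def interpolate_f0(
    contour: F0Contour,
    sample_rate: float,
    duration: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate an anchor contour to a smooth per-sample f0 track.

    Voiced runs of anchors are interpolated with a shape-preserving cubic
    (PCHIP), which is monotone between anchors and has a continuous first
    derivative, giving smooth pitch contours at the audio rate.  Samples
    outside any voiced run are marked unvoiced and carry f0 = 0.

    Returns
    -------
    f0_track, voiced_mask
        Arrays of length ``round(duration * sample_rate)``.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if duration is None:
        duration = contour.duration
    n = int(round(duration * sample_rate))
    if n <= 0:
        raise ValueError("duration too short for the given sample rate")
    t = np.arange(n) / sample_rate
    f0 = np.zeros(n)
    mask = np.zeros(n, dtype=bool)

    for start, stop in _voiced_runs(contour.voiced):
        ts = contour.times[start:stop]
        vs = contour.values[start:stop]
        sel = (t >= ts[0]) & (t <= ts[-1])
        if stop - start == 1:
            f0[sel] = vs[0]
        else:
            interp = PchipInterpolator(ts, vs, extrapolate=False)
            f0[sel] = interp(t[sel])
        mask[sel] = True
    return f0, mask


def _voiced_runs(voiced: np.ndarray) -> list[tuple[int, int]]:
    """Index ranges [start, stop) of consecutive voiced anchors."""
    runs = []
    start = None
    for i, v in enumerate(voiced):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(voiced)))
    return runs


# ---------------------------------------------------------------------------
# additive harmonic synthesis
# ---------------------------------------------------------------------------

def harmonic_amplitude(k: np.ndarray | int, rolloff: float) -> np.ndarray | float:
    """Amplitude of harmonic ``k`` relative to the fundamental.

    A spectral rolloff of r dB/octave attenuates harmonic k (at frequency
    k*f0, i.e. log2(k) octaves above f0) by r*log2(k) dB.
    """
    return 10.0 ** (-rolloff * np.log2(k) / 20.0)


def synth_harmonics(
    f0_track: np.ndarray,
    rolloff: float,
    sample_rate: float,
    voiced_mask: np.ndarray | None = None,
    *,
    extra_partials: list[tuple[float, float]] | None = None,
    phase_rng: np.random.Generator | None = None,
) -> Waveform:
    """Additive synthesis of all harmonics of a per-sample f0 track.

    Every harmonic k with k*f0 below Nyquist minus a 50 Hz guard band is
    synthesized as a continuous sine whose phase is the cumulative integral
    of k * f0(t); its amplitude follows the rolloff law.  Harmonics whose
    instantaneous frequency momentarily exceeds the guard limit are muted
    for those samples, which prevents aliasing at contour peaks.

    Parameters
    ----------
    extra_partials
        Optional list of ``(freq_ratio, amplitude)`` pairs adding inharmonic
        partials at ``freq_ratio * f0`` (used for subharmonics).
    phase_rng
        If given, each harmonic starts at an independent random phase;
        by default all phases start at 0.
    """
    f0_track = np.asarray(f0_track, dtype=float)
    if voiced_mask is None:
        voiced_mask = f0_track > 0
    limit = sample_rate / 2.0 - NYQUIST_GUARD_HZ
    f0_voiced = f0_track[voiced_mask]
    if f0_voiced.size == 0:
        return Waveform(np.zeros_like(f0_track), int(sample_rate))
    if np.min(f0_voiced) >= sample_rate / 2.0:
        raise ValueError("f0 at or above Nyquist")
    n_harm = int(limit // np.min(f0_voiced))
    if n_harm < 1:
        raise ValueError("fundamental exceeds the Nyquist guard limit")

    # phase of the fundamental (0 at sample 0); harmonics use integer multiples
    phase1 = 2.0 * np.pi * (np.cumsum(f0_track) - f0_track) / sample_rate
    out = np.zeros_like(f0_track)
    ratios = [(float(k), harmonic_amplitude(k, rolloff)) for k in range(1, n_harm + 1)]
    if extra_partials:
        ratios += [(float(r), float(a)) for r, a in extra_partials]
    for ratio, amp in ratios:
        freq = ratio * f0_track
        active = voiced_mask & (freq < limit)
        if not active.any():
            continue
        phi0 = phase_rng.uniform(0, 2 * np.pi) if phase_rng is not None else 0.0
        out[active] += amp * np.sin(ratio * phase1[active] + phi0)
    return Waveform(out, int(sample_rate))


def add_source_noise(
    harmonic: Waveform,
    noise_level: float,
    rng: np.random.Generator | None = None,
) -> Waveform:
    """Add white noise at ``noise_level`` dB relative to the harmonic RMS."""
    if noise_level == -np.inf:
        return Waveform(harmonic.samples.copy(), harmonic.sample_rate)
    if not np.isfinite(noise_level):
        raise ValueError("noise_level must be finite or -inf")
    h_rms = harmonic.rms()
    if h_rms == 0:
        raise ValueError("harmonic component is silent: noise ratio undefined")
    rng = np.random.default_rng() if rng is None else rng
    noise = rng.standard_normal(harmonic.samples.size)
    noise *= h_rms * 10.0 ** (noise_level / 20.0) / np.sqrt(np.mean(noise**2))
    return Waveform(harmonic.samples + noise, harmonic.sample_rate)


def whisper_source(
    duration: float,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    rng: np.random.Generator | None = None,
) -> Waveform:
    """Aperiodic turbulent-noise source with no harmonic component."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng() if rng is None else rng
    n = int(round(duration * sample_rate))
    return Waveform(rng.standard_normal(n), int(sample_rate))


def synth_source(spec: SourceSpec, rng: np.random.Generator | None = None) -> Waveform:
    """Render a full glottal source (harmonics + noise) from a SourceSpec."""
    f0, mask = interpolate_f0(spec.f0, spec.sample_rate, spec.duration)
    wave = synth_harmonics(f0, spec.rolloff, spec.sample_rate, mask)
    if spec.noise_level != -np.inf and wave.rms() > 0:
        wave = add_source_noise(wave, spec.noise_level, rng)
    return wave
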