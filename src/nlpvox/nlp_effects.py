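"""Nonlinear-phonation manipulations applied at the voice-source level.

Five manipulations emulate the main classes of nonlinear vocal phenomena:

* amplitude modulation (AM) — low-frequency sidebands around each harmonic;
* subharmonics — period doubling: extra partials at multiples of f0/ratio;
* "chaos" — very rapid, strong jitter of the f0 track (an imitation of
  deterministic chaos, not a chaotic oscillator);
* frequency jumps — abrupt octave-fraction discontinuities in the contour;
* whisper — the harmonic source replaced by aperiodic noise.

Each manipulation can be applied continuously or within episodes given as
(start, end) fractions of the total duration; episode edges are crossfaded
with 5 ms raised-cosine ramps so gating never clicks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .source_synthesis import (
    F0Contour,
    Waveform,
    harmonic_amplitude,
    synth_harmonics,
    NYQUIST_GUARD_HZ,
)

#: sentinel: manipulation covers the whole stimulus
CONTINUOUS: tuple[tuple[float, float], ...] = ((0.0, 1.0),)

EDGE_RAMP_S = 0.005  # raised-cosine crossfade at episode boundaries

NLP_KINDS = ("none", "am", "subharmonics", "chaos", "frequency_jump", "whisper")


@dataclass
class NLPManipulation:
    """One manipulation's type, parameters and episode windows."""

    kind: str = "none"
    am_freq: float = 100.0
    am_depth: float = 0.5
    sub_ratio: int = 2
    sub_depth: float = 0.5
    jitter_depth: float = 2.0      # total width, semitones
    jitter_rate: float = 1000.0    # Hz
    jump_magnitude: float = 6.0    # semitones
    jump_point: float = 0.5        # fraction of duration
    jump_direction: str = "up"
    episodes: tuple[tuple[float, float], ...] = CONTINUOUS

    def __post_init__(self) -> None:
        if self.kind not in NLP_KINDS:
            raise ValueError(f"unknown NLP kind {self.kind!r}")
        for name in ("am_depth", "sub_depth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        eps = tuple((float(a), float(b)) for a, b in self.episodes)
        prev_end = -1.0
        for a, b in eps:
            if not (0.0 <= a < b <= 1.0):
                raise ValueError("episode windows must satisfy 0 <= start < end <= 1")
            if a < prev_end:
                raise ValueError("episodes must be ascending and non-overlapping")
            prev_end = b
        self.episodes = eps


def episode_gate(
    n_samples: int,
    episodes: tuple[tuple[float, float], ...],
    sample_rate: float,
    ramp_s: float = EDGE_RAMP_S,
) -> np.ndarray:
    """Per-sample weight in [0, 1]: 1 inside episodes, raised-cosine edges."""
    gate = np.zeros(n_samples)
    ramp_n = max(1, int(round(ramp_s * sample_rate)))
    ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp_n)))
    for a, b in episodes:
        i0, i1 = int(round(a * n_samples)), int(round(b * n_samples))
        gate[i0:i1] = 1.0
        if i0 > 0:
            k = min(ramp_n, i1 - i0)
            gate[i0 : i0 + k] = ramp[:k]
        if i1 < n_samples:
            k = min(ramp_n, i1 - i0)
            gate[i1 - k : i1] = ramp[:k][::-1]
    return gate


# ---------------------------------------------------------------------------
# amplitude modulation
# ---------------------------------------------------------------------------

def apply_am(
    wave: Waveform,
    freq: float,
    depth: float,
    episodes: tuple[tuple[float, float], ...] = CONTINUOUS,
) -> Waveform:
    """Sinusoidal amplitude modulation with peak-to-trough fraction ``depth``.

    Within episodes the samples are multiplied by
    ``1 - depth/2 + (depth/2) * cos(2 pi freq t)``, i.e. the envelope swings
    between 1 and 1 - depth around the carrier level, producing sidebands at
    +-freq around every harmonic at depth/4 of the carrier amplitude.
    """
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must be in [0, 1]")
    if freq >= wave.sample_rate / 2:
        raise ValueError("AM frequency at or above Nyquist")
    n = wave.samples.size
    t = np.arange(n) / wave.sample_rate
    mod = 1.0 - depth / 2.0 + (depth / 2.0) * np.cos(2 * np.pi * freq * t)
    gate = episode_gate(n, episodes, wave.sample_rate)
    gain = 1.0 + gate * (mod - 1.0)
    return Waveform(wave.samples * gain, wave.sample_rate)


# ---------------------------------------------------------------------------
# subharmonics
# ---------------------------------------------------------------------------

def subharmonic_partials(
    rolloff: float,
    ratio: int,
    depth: float,
    max_ratio: float,
) -> list[tuple[float, float]]:
    """Frequency ratios and amplitudes of inserted subharmonic partials.

    Partials appear at m * f0 / ratio for every m not divisible by ``ratio``
    (so for ratio 2 they interleave the harmonics at (k + 1/2) f0).  Each
    has amplitude ``depth`` times the rolloff-curve amplitude at its
    frequency, capped at the fundamental's amplitude.
    """
    if ratio < 2 or int(ratio) != ratio:
        raise ValueError("subharmonic ratio must be an integer >= 2")
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must be in [0, 1]")
    partials = []
    m = 1
    while m / ratio <= max_ratio:
        if m % ratio:
            r = m / ratio
            amp = depth * min(1.0, harmonic_amplitude(r, rolloff))
            partials.append((r, amp))
        m += 1
    return partials


def apply_subharmonics(
    f0_track: np.ndarray,
    rolloff: float,
    sample_rate: float,
    ratio: int = 2,
    depth: float = 0.5,
    episodes: tuple[tuple[float, float], ...] = CONTINUOUS,
    voiced_mask: np.ndarray | None = None,
) -> Waveform:
    """Harmonic synthesis with period-doubling partials gated by episodes.

    The waveform's period becomes ratio / f0 wherever the subharmonics are
    active, with a new spectral peak at f0 / ratio.
    """
    f0_track = np.asarray(f0_track, dtype=float)
    if voiced_mask is None:
        voiced_mask = f0_track > 0
    base = synth_harmonics(f0_track, rolloff, sample_rate, voiced_mask)
    if depth == 0.0:
        return base
    f0_voiced = f0_track[voiced_mask]
    if f0_voiced.size and np.min(f0_voiced) / ratio < 20.0:
        raise ValueError("subharmonic below 20 Hz")
    limit_ratio = (sample_rate / 2 - NYQUIST_GUARD_HZ) / max(np.min(f0_voiced), 1.0)
    partials = subharmonic_partials(rolloff, ratio, depth, limit_ratio)
    # synthesize only the inserted partials, then gate them by episode
    phase1 = 2.0 * np.pi * (np.cumsum(f0_track) - f0_track) / sample_rate
    extra = np.zeros_like(f0_track)
    limit = sample_rate / 2 - NYQUIST_GUARD_HZ
    for r, amp in partials:
        active = voiced_mask & (r * f0_track < limit)
        if active.any():
            extra[active] += amp * np.sin(r * phase1[active])
    gate = episode_gate(f0_track.size, episodes, sample_rate)
    return Waveform(base.samples + gate * extra, int(sample_rate))


# ---------------------------------------------------------------------------
# jitter ("chaos")
# ---------------------------------------------------------------------------

def apply_jitter(
    f0_track: np.ndarray,
    depth: float,
    rate: float,
    sample_rate: float,
    rng: np.random.Generator,
    episodes: tuple[tuple[float, float], ...] = CONTINUOUS,
    interp: str = "linear",
) -> np.ndarray:
    """Multiply the f0 track by 2**(u(t)/12) with rapid random u(t).

    ``u(t)`` is zero-mean noise, uniform in [-depth/2, +depth/2] semitones,
    drawn at ``rate`` update points per second and interpolated linearly
    (or held, with ``interp='hold'``) between updates.  The log-ratio to the
    nominal track therefore never exceeds depth/2 semitones.
    """
    if depth < 0:
        raise ValueError("jitter depth must be >= 0")
    if rate > sample_rate / 2:
        raise ValueError("jitter rate above Nyquist")
    if interp not in ("linear", "hold"):
        raise ValueError("interp must be 'linear' or 'hold'")
    f0_track = np.asarray(f0_track, dtype=float)
    n = f0_track.size
    if depth == 0 or n == 0:
        return f0_track.copy()
    n_updates = max(2, int(np.ceil(n * rate / sample_rate)) + 1)
    u_points = rng.uniform(-depth / 2.0, depth / 2.0, n_updates)
    t_points = np.arange(n_updates) * sample_rate / rate
    t = np.arange(n, dtype=float)
    if interp == "linear":
        u = np.interp(t, t_points, u_points)
    else:
        idx = np.minimum((t / (sample_rate / rate)).astype(int), n_updates - 1)
        u = u_points[idx]
    gate = episode_gate(n, episodes, sample_rate)
    return f0_track * 2.0 ** (gate * u / 12.0)


# ---------------------------------------------------------------------------
# frequency jumps
# ---------------------------------------------------------------------------

def apply_frequency_jump(
    contour: F0Contour,
    point: float,
    magnitude: float,
    direction: str = "up",
) -> F0Contour:
    """Shift every f0 anchor after ``point`` (fraction of duration) by
    ``magnitude`` semitones, preserving the discontinuity.

    Anchors are inserted just before and at the jump time so that later
    interpolation cannot smooth across the break.
    """
    if not 0.0 < point < 1.0:
        raise ValueError("jump point must lie strictly inside (0, 1)")
    if magnitude < 0:
        raise ValueError("jump magnitude must be >= 0")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    factor = 2.0 ** ((magnitude if direction == "up" else -magnitude) / 12.0)
    t_jump = contour.times[0] + point * (contour.times[-1] - contour.times[0])
    eps = 1e-4

    times = list(contour.times)
    values = list(contour.values)
    voiced = list(contour.voiced)

    # value of the original contour at the jump time (within its local run)
    at_jump = float(np.interp(t_jump, contour.times, contour.values))
    jump_voiced = bool(
        contour.voiced[min(np.searchsorted(contour.times, t_jump), len(times) - 1)]
    )

    keep = [i for i, t in enumerate(times) if abs(t - t_jump) > eps and abs(t - (t_jump - eps)) > eps]
    times = [times[i] for i in keep]
    values = [values[i] for i in keep]
    voiced = [voiced[i] for i in keep]

    new_times, new_values, new_voiced = [], [], []
    for t, v, vo in zip(times, values, voiced):
        if t < t_jump:
            new_times.append(t); new_values.append(v); new_voiced.append(vo)
    new_times.append(t_jump - eps); new_values.append(at_jump); new_voiced.append(jump_voiced)
    new_times.append(t_jump); new_values.append(at_jump * factor); new_voiced.append(jump_voiced)
    for t, v, vo in zip(times, values, voiced):
        if t > t_jump:
            new_times.append(t); new_values.append(v * factor); new_voiced.append(vo)
    return F0Contour(np.array(new_times), np.array(new_values), np.array(new_voiced))


@dataclass
class JumpSpec:
    time_frac: float
    magnitude: float
    direction: str


def plan_jumps_alternating(
    contour: F0Contour,
    n_jumps: int,
    magnitude_range: tuple[float, float],
    rng: np.random.Generator,
    alternate_prob: float = 0.9,
) -> list[JumpSpec]:
    """Plan stochastic frequency jumps that favour alternating directions.

    Jump times are drawn uniformly within voiced spans of the contour.
    The direction of each jump is opposite to the previous one with
    probability ``alternate_prob``; additionally, whenever applying a jump
    would push the cumulative shift past +-1 octave (keeping the shifted
    contour within [min/2, 2*max] of its original range), the direction is
    forced back toward zero, which prevents f0 drifting to extreme values.
    """
    if n_jumps < 1:
        raise ValueError("n_jumps must be >= 1")
    lo, hi = magnitude_range
    total = contour.times[-1] - contour.times[0]
    spans = []
    for i in range(len(contour.times) - 1):
        if contour.voiced[i] and contour.voiced[i + 1]:
            spans.append((contour.times[i], contour.times[i + 1]))
    if not spans:
        raise ValueError("no voiced span available for jump placement")
    lengths = np.array([b - a for a, b in spans])
    # keep jumps off the exact endpoints of the stimulus
    margin = 0.02 * total

    times = []
    for _ in range(n_jumps):
        k = rng.choice(len(spans), p=lengths / lengths.sum())
        a, b = spans[k]
        times.append(rng.uniform(a, b))
    times = np.clip(np.sort(times), contour.times[0] + margin, contour.times[-1] - margin)

    jumps: list[JumpSpec] = []
    cum = 0.0  # cumulative shift, semitones
    prev_dir = None
    for t in times:
        mag = rng.uniform(lo, hi)
        if prev_dir is None:
            d = "up" if rng.random() < 0.5 else "down"
        elif rng.random() < alternate_prob:
            d = "down" if prev_dir == "up" else "up"
        else:
            d = prev_dir
        # anti-drift guard: stay within one octave of the original contour
        if d == "up" and cum + mag > 12.0:
            d = "down"
        elif d == "down" and cum - mag < -12.0:
            d = "up"
        cum += mag if d == "up" else -mag
        prev_dir = d
        frac = (t - contour.times[0]) / total
        jumps.append(JumpSpec(float(frac), float(mag), d))
    return jumps


def apply_planned_jumps(contour: F0Contour, jumps: list[JumpSpec]) -> F0Contour:
    """Apply a list of planned jumps sequentially to a contour."""
    out = contour
    for j in jumps:
        out = apply_frequency_jump(out, j.time_frac, j.magnitude, j.direction)
    return out


# ---------------------------------------------------------------------------
# episode placement & pitch shift
# ---------------------------------------------------------------------------

def place_episodes(
    duration: float,
    mode: str,
    rng: np.random.Generator | None = None,
    n_episodes_mean: float = 5.0,
    coverage_range: tuple[float, float] = (0.25, 0.7),
) -> tuple[tuple[float, float], ...]:
    """Episode windows (fractions of duration) for one stimulus.

    ``continuous`` returns the single window (0, 1).  ``intermittent``
    draws the episode count from a Poisson(5) truncated to [2, 8], a total
    coverage fraction uniform in ``coverage_range`` (within the 0.2-0.8
    band), and splits coverage and gaps with Dirichlet weights, yielding
    non-overlapping ascending windows.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if mode == "continuous":
        return CONTINUOUS
    if mode != "intermittent":
        raise ValueError("mode must be 'continuous' or 'intermittent'")
    rng = np.random.default_rng() if rng is None else rng
    n = int(rng.poisson(n_episodes_mean))
    while not 2 <= n <= 8:
        n = int(rng.poisson(n_episodes_mean))
    coverage = rng.uniform(*coverage_range)
    lengths = rng.dirichlet(np.full(n, 2.0)) * coverage
    lengths = np.maximum(lengths, 0.02)
    lengths *= coverage / lengths.sum()
    gaps = rng.dirichlet(np.full(n + 1, 2.0)) * (1.0 - coverage)
    windows = []
    pos = gaps[0]
    for i in range(n):
        windows.append((float(pos), float(pos + lengths[i])))
        pos += lengths[i] + gaps[i + 1]
    return tuple(windows)


def apply_pitch_shift(contour: F0Contour, octaves: float) -> F0Contour:
    """Shift the whole contour by ``octaves`` (multiplicative, shape-preserving)."""
    factor = 2.0**octaves
    if np.max(contour.values * factor) > 3000.0:
        raise ValueError("pitch shift would push f0 above 3000 Hz")
    return contour.scaled(factor)
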