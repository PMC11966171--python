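"""Stimulus manifests for the three experiments and manifest-row rendering.

Each experiment's full stimulus set is described by a manifest: one row per
stimulus with every synthesis parameter explicit plus a per-record seed, so
any stimulus is exactly reproducible from its row alone.

* Experiment 1 — 999 isolated vowel/diphthong prototypes (700 ms, f0 drawn
  log-uniformly between 110 and 880 Hz, half diphthongs with morph in
  0.1..1.0) crossed with five source conditions (tonal, AM, subharmonics,
  chaos, whisper) = 4995 stimuli.
* Experiment 2 — 1300 six-digit sequences (digits 1-9), eight synthetic
  speakers, an 18-cell grid of six NLP conditions x three pitch levels
  (no pitch shift is applied in the whisper condition), SNR uniform in
  [-6, 15] dB against profile-shaped masking noise.
* Experiment 3 — 100 sentence prototypes x 12 conditions: original,
  resynthesized no-NLP, frequency jumps, mixed, and {whisper, AM,
  subharmonics, chaos} x {continuous, intermittent}.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .nlp_effects import (
    CONTINUOUS,
    apply_am,
    apply_frequency_jump,
    apply_jitter,
    apply_pitch_shift,
    apply_planned_jumps,
    apply_subharmonics,
    episode_gate,
    place_episodes,
    plan_jumps_alternating,
)
from .noise_and_mixing import (
    NoiseProfile,
    concatenate_with_pauses,
    generate_masking_noise,
    mix_at_snr,
)
from .source_synthesis import (
    DEFAULT_SAMPLE_RATE,
    F0Contour,
    Waveform,
    add_source_noise,
    interpolate_f0,
    synth_harmonics,
    whisper_source,
)
from .vocal_tract import (
    DEFAULT_VOWELS,
    DiphthongSpec,
    compress_dynamics,
    formant_filter,
    morph_formant_tracks,
)
from .synthetic_data import SyntheticMaterial, material_envelopes
from .vocal_tract import transplant_envelopes

EXP1_CONDITIONS = ("tonal", "am", "subharmonics", "chaos", "whisper")
EXP2_CONDITIONS = ("none", "frequency_jump", "am", "subharmonics", "chaos", "whisper")
EXP2_PITCH_LEVELS = (0.0, 1.0, 1.5)
EXP3_CONDITIONS = (
    "original", "no_nlp", "frequency_jumps", "mixed",
    "whisper_continuous", "whisper_intermittent",
    "am_continuous", "am_intermittent",
    "subharmonics_continuous", "subharmonics_intermittent",
    "chaos_continuous", "chaos_intermittent",
)

EXP1_ROLLOFF = 3.0
EXP23_ROLLOFF = 9.0
EXP23_NOISE_DB = -30.0
EXP1_DURATION = 0.7


def record_seed(master_seed: int, experiment: int, index: int) -> int:
    """Splittable per-record seed: deterministic in (master, experiment, index)."""
    ss = np.random.SeedSequence([int(master_seed), int(experiment), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def build_exp1_manifest(seed: int) -> pd.DataFrame:
    """999 vowel prototypes x 5 source conditions = 4995 stimulus records."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    vowel_labels = list(DEFAULT_VOWELS)
    rows = []
    idx = 0
    for i in range(999):
        f0 = float(10.0 ** rng.uniform(np.log10(110.0), np.log10(880.0)))
        pair = rng.choice(len(vowel_labels), size=2, replace=False)
        is_diph = rng.random() < 0.5
        morph = float(rng.choice(np.round(np.arange(0.1, 1.01, 0.1), 1))) if is_diph else 0.0
        am_freq = float(rng.uniform(50.0, 150.0))
        am_depth = float(rng.uniform(0.4, 0.6))
        sub_depth = float(rng.uniform(0.4, 0.6))
        jitter_depth = float(rng.uniform(2.0, 4.0))
        for cond in EXP1_CONDITIONS:
            rows.append({
                "stimulus_id": f"exp1-{i:04d}-{cond}",
                "experiment": 1,
                "prototype": i,
                "condition": cond,
                "f0_hz": f0,
                "is_diphthong": int(is_diph),
                "morph": morph,
                "vowel_from": vowel_labels[pair[0]],
                "vowel_to": vowel_labels[pair[1]],
                "am_freq_hz": am_freq,
                "am_depth": am_depth,
                "sub_depth": sub_depth,
                "jitter_depth_st": jitter_depth,
                "jitter_rate_hz": 1000.0,
                "duration_s": EXP1_DURATION,
                "seed": record_seed(seed, 1, idx),
            })
            idx += 1
    return pd.DataFrame(rows)


def build_exp2_manifest(seed: int, speaker_ids: tuple[str, ...] | None = None) -> pd.DataFrame:
    """1300 six-digit sequences over the 18-cell NLP x pitch grid."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    if speaker_ids is None:
        speaker_ids = tuple(f"{s}{i}" for s in "mf" for i in range(1, 5))
    cells = [(c, p) for c in EXP2_CONDITIONS for p in EXP2_PITCH_LEVELS]
    rows = []
    for i in range(1300):
        digits = "".join(str(d) for d in rng.integers(1, 10, size=6))
        cond, pitch_level = cells[rng.integers(len(cells))]
        rows.append({
            "stimulus_id": f"exp2-{i:04d}",
            "experiment": 2,
            "condition": cond,
            "pitch_level": pitch_level,
            # the whispered source has no f0 contour to shift
            "pitch_shift_octaves": 0.0 if cond == "whisper" else pitch_level,
            "snr_db": float(rng.uniform(-6.0, 15.0)),
            "digits": digits,
            "speaker_id": str(rng.choice(speaker_ids)),
            "am_freq_hz": float(rng.uniform(50.0, 150.0)),
            "am_depth": float(rng.uniform(0.3, 0.6)),
            "sub_depth": float(rng.uniform(0.3, 0.5)),
            "jitter_depth_st": float(rng.uniform(1.0, 4.0)),
            "jitter_rate_hz": 1000.0,
            "seed": record_seed(seed, 2, i),
        })
    return pd.DataFrame(rows)


def build_exp3_manifest(seed: int, material: SyntheticMaterial | None = None) -> pd.DataFrame:
    """100 sentence prototypes x 12 conditions = 1200 stimulus records.

    Both noise arms (quiet / SNR 0 dB) reuse the same records; noise is
    added at render or scoring time, not duplicated in the manifest.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    rows = []
    idx = 0
    for sid in range(100):
        text = material.sentences[sid].text if material is not None else ""
        dur = material.sentences[sid].duration if material is not None else np.nan
        for cond in EXP3_CONDITIONS:
            n_jumps = 0
            if cond in ("frequency_jumps", "mixed"):
                n_jumps = int(np.clip(rng.poisson(5.0), 1, 8))
            rows.append({
                "stimulus_id": f"exp3-{sid:03d}-{cond}",
                "experiment": 3,
                "sentence_id": sid,
                "condition": cond,
                "text": text,
                "duration_s": dur,
                "n_jumps": n_jumps,
                "jump_min_st": 0.5,
                "jump_max_st": 12.0,
                "seed": record_seed(seed, 3, idx),
            })
            idx += 1
    return pd.DataFrame(rows)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"digits": str})


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _voiced_source(
    contour: F0Contour,
    rolloff: float,
    sample_rate: int,
    duration: float | None = None,
    noise_level: float = -np.inf,
    rng: np.random.Generator | None = None,
) -> tuple[Waveform, np.ndarray, np.ndarray]:
    f0, mask = interpolate_f0(contour, sample_rate, duration)
    wave = synth_harmonics(f0, rolloff, sample_rate, mask)
    if noise_level != -np.inf and wave.rms() > 0:
        wave = add_source_noise(wave, noise_level, rng)
    return wave, f0, mask


def _nlp_source(
    contour: F0Contour,
    kind: str,
    rec,
    rng: np.random.Generator,
    rolloff: float,
    sample_rate: int,
    noise_level: float = -np.inf,
    episodes=CONTINUOUS,
    duration: float | None = None,
) -> Waveform:
    """Voice source for one token under a given NLP condition."""
    dur = duration if duration is not None else contour.duration
    if kind == "whisper" and episodes == CONTINUOUS:
        return whisper_source(dur, sample_rate, rng)
    if kind == "frequency_jump":
        point = float(rng.uniform(0.25, 0.75))
        mag = float(rng.uniform(3.0, 12.0))
        direction = "up" if rng.random() < 0.5 else "down"
        contour = apply_frequency_jump(contour, point, mag, direction)
        return _voiced_source(contour, rolloff, sample_rate, dur, noise_level, rng)[0]

    f0, mask = interpolate_f0(contour, sample_rate, dur)
    if kind == "chaos":
        f0 = apply_jitter(f0, float(rec["jitter_depth_st"]), float(rec["jitter_rate_hz"]),
                          sample_rate, rng, episodes)
    if kind == "subharmonics":
        wave = apply_subharmonics(f0, rolloff, sample_rate, 2, float(rec["sub_depth"]),
                                  episodes, mask)
    else:
        wave = synth_harmonics(f0, rolloff, sample_rate, mask)
    if kind == "am":
        wave = apply_am(wave, float(rec["am_freq_hz"]), float(rec["am_depth"]), episodes)
    if kind == "whisper":  # intermittent whisper: replace source within episodes
        noise = whisper_source(max(dur, wave.duration), sample_rate, rng)
        h_rms = wave.rms() or 1.0
        gate = episode_gate(wave.samples.size, episodes, sample_rate)
        mixed = wave.samples * (1 - gate) + gate * noise.samples[: wave.samples.size] * h_rms
        wave = Waveform(mixed, sample_rate)
    if noise_level != -np.inf and wave.rms() > 0:
        wave = add_source_noise(wave, noise_level, rng)
    return wave


def render_exp1_stimulus(rec, vowel_table=None, sample_rate: int = DEFAULT_SAMPLE_RATE) -> Waveform:
    """Render one Experiment 1 vowel/diphthong record to audio."""
    vowels = DEFAULT_VOWELS if vowel_table is None else vowel_table
    rng = np.random.default_rng(int(rec["seed"]))
    dur = float(rec["duration_s"])
    contour = F0Contour.constant(float(rec["f0_hz"]), dur)
    kind = {"tonal": "none"}.get(rec["condition"], rec["condition"])
    source = _nlp_source(contour, kind, rec, rng, EXP1_ROLLOFF, sample_rate,
                         duration=dur)
    spec = DiphthongSpec(vowels[rec["vowel_from"]], vowels[rec["vowel_to"]],
                         float(rec["morph"]), dur)
    tracks = morph_formant_tracks(spec, 40)
    out = formant_filter(source, tracks)
    out = compress_dynamics(out)
    return out.normalized()


def render_exp2_stimulus(
    rec,
    material: SyntheticMaterial,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    with_noise: bool = True,
) -> Waveform:
    """Render one six-digit sequence: per-digit source synthesis with NLP,
    envelope transplantation, concatenation with pauses, and SNR mixing."""
    if material is None:
        raise ValueError("missing asset: synthetic speaker material for experiment 2")
    rng = np.random.default_rng(int(rec["seed"]))
    speaker = material.speaker(str(rec["speaker_id"]))
    shift = float(rec["pitch_shift_octaves"])
    tokens = []
    for ch in str(rec["digits"]):
        tok = material.digit_tokens[(speaker.speaker_id, int(ch))]
        contour = apply_pitch_shift(tok.contour, shift) if shift else tok.contour
        source = _nlp_source(contour, str(rec["condition"]), rec, rng,
                             EXP23_ROLLOFF, sample_rate, EXP23_NOISE_DB,
                             duration=tok.duration)
        env, amp = material_envelopes(tok.formants, tok.duration, sample_rate,
                                      tok.attack, tok.decay)
        shaped = transplant_envelopes(source, env, amp)
        tokens.append(shaped.normalized(0.7))
    seq, _ = concatenate_with_pauses(tokens, (0.05, 0.2), rng)
    if with_noise:
        profile = NoiseProfile(duration=seq.duration + 0.1, sample_rate=sample_rate)
        noise = generate_masking_noise(profile, rng)
        seq = mix_at_snr(seq, noise, float(rec["snr_db"]))
    return seq.normalized()


def render_exp3_stimulus(
    rec,
    material: SyntheticMaterial,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    snr_db: float | None = None,
) -> Waveform:
    """Render one sentence record in its NLP condition, optionally in noise."""
    if material is None:
        raise ValueError("missing asset: synthetic sentence material for experiment 3")
    rng = np.random.default_rng(int(rec["seed"]))
    sent = material.sentences[int(rec["sentence_id"])]
    cond = str(rec["condition"])
    contour = sent.contour
    dur = sent.duration

    defaults = {"am_freq_hz": float(rng.uniform(50, 150)),
                "am_depth": float(rng.uniform(0.3, 0.6)),
                "sub_depth": float(rng.uniform(0.3, 0.5)),
                "jitter_depth_st": float(rng.uniform(1.0, 4.0)),
                "jitter_rate_hz": 1000.0}

    if cond in ("original", "no_nlp"):
        source = _voiced_source(contour, EXP23_ROLLOFF, sample_rate, dur,
                                EXP23_NOISE_DB, rng)[0]
    elif cond == "frequency_jumps":
        jumps = plan_jumps_alternating(contour, max(int(rec["n_jumps"]), 1),
                                       (float(rec["jump_min_st"]), float(rec["jump_max_st"])),
                                       rng)
        jumped = apply_planned_jumps(contour, jumps)
        source = _voiced_source(jumped, EXP23_ROLLOFF, sample_rate, dur,
                                EXP23_NOISE_DB, rng)[0]
    elif cond == "mixed":
        jumps = plan_jumps_alternating(contour, max(int(rec["n_jumps"]), 1),
                                       (float(rec["jump_min_st"]), float(rec["jump_max_st"])),
                                       rng)
        jumped = apply_planned_jumps(contour, jumps)
        episodes = place_episodes(dur, "intermittent", rng)
        kind = ("am", "subharmonics", "chaos")[rng.integers(3)]
        source = _nlp_source(jumped, kind, defaults, rng, EXP23_ROLLOFF,
                             sample_rate, EXP23_NOISE_DB, episodes, dur)
    else:
        kind, mode = cond.rsplit("_", 1)
        episodes = place_episodes(dur, mode, rng)
        source = _nlp_source(contour, kind, defaults, rng, EXP23_ROLLOFF,
                             sample_rate, EXP23_NOISE_DB, episodes, dur)

    env, amp = material_envelopes(sent.formants, dur, sample_rate, 0.03, 0.05)
    out = transplant_envelopes(source, env, amp)
    if snr_db is not None:
        profile = NoiseProfile(duration=out.duration + 0.1, sample_rate=sample_rate)
        noise = generate_masking_noise(profile, rng)
        out = mix_at_snr(out, noise, snr_db)
    return out.normalized()


def render_stimulus(
    rec,
    material: SyntheticMaterial | None = None,
    vowel_table=None,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    **kwargs,
) -> Waveform:
    """Render any manifest row to audio (pure function of the row + material)."""
    exp = int(rec["experiment"])
    if exp == 1:
        return render_exp1_stimulus(rec, vowel_table, sample_rate)
    if exp == 2:
        return render_exp2_stimulus(rec, material, sample_rate, **kwargs)
    if exp == 3:
        return render_exp3_stimulus(rec, material, sample_rate, **kwargs)
    raise ValueError(f"unknown experiment {exp}")
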