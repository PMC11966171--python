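"""Synthetic speaker material and simulated listeners.

The pipeline was designed around recorded digits and sentences; this module
generates stand-ins for that material — speaker profiles, per-token f0
contours with declination, parametric spectral/amplitude envelopes — and
simulated listener responses with a controlled psychometric structure, so
every stage of the pipeline can be exercised end to end without any
external audio.  All material and responses are deterministic functions of
a seed.

The listener models are illustrative: their parameters are chosen to have
the qualitative shape of human data (accuracy rising with SNR,
discrimination thresholds rising with pitch fastest when no nonlinear
phenomena are present) and are not estimates of any real listener
population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .source_synthesis import DEFAULT_SAMPLE_RATE, F0Contour
from .vocal_tract import (
    NFFT,
    NOVERLAP,
    NPERSEG,
    AmplitudeEnvelope,
    SpectralEnvelope,
    extend_formants,
    resonance_envelope,
)

DIGITS = tuple(range(1, 10))  # zero is not used in the digit task

#: fixed example sentences (single-clause, Harvard-sentence style); the rest
#: of the 100-sentence set is generated from a small vocabulary.
FIXTURE_SENTENCES = (
    "the jacket hung on the back of the wide chair",
    "at that high level the air is pure",
    "drop the two when you add the figures",
    "an abrupt start does not win the prize",
)

_VOCAB = (
    "the a this that his her our your old new big small red blue dark cold warm "
    "man boy girl dog bird fish boat ship road town house door wall floor glass "
    "stone water bread fruit salt rice tea milk wind rain snow light night day "
    "ran walked stood fell took gave found kept held made saw heard came went "
    "near far here there soon often never always once twice again"
).split()


# ---------------------------------------------------------------------------
# speaker material
# ---------------------------------------------------------------------------

@dataclass
class SpeakerProfile:
    speaker_id: str
    sex: str                 # "m" or "f"
    base_f0: float           # Hz
    formant_scale: float     # multiplies the vowel formant table


@dataclass
class TokenMaterial:
    """One spoken-digit token: contour plus parametric envelope description."""

    duration: float
    contour: F0Contour
    formants: np.ndarray       # F1..F4 after speaker scaling
    attack: float = 0.08       # fraction of duration
    decay: float = 0.15


@dataclass
class SentenceMaterial:
    sentence_id: int
    text: str
    duration: float
    contour: F0Contour         # voiced word spans separated by unvoiced gaps
    formants: np.ndarray


@dataclass
class SyntheticMaterial:
    """Stand-in for the recorded speaker material (synthetic, seed-derived)."""

    seed: int
    speakers: list[SpeakerProfile]
    digit_tokens: dict[tuple[str, int], TokenMaterial]
    sentences: dict[int, SentenceMaterial]

    def speaker(self, speaker_id: str) -> SpeakerProfile:
        for s in self.speakers:
            if s.speaker_id == speaker_id:
                return s
        raise KeyError(f"unknown speaker {speaker_id!r}")


def _digit_contour(base_f0: float, duration: float, rng: np.random.Generator) -> F0Contour:
    """Short rising-falling contour with declination, unvoiced edges."""
    v0, v1 = 0.05 * duration, 0.95 * duration
    t = np.concatenate([[0.0], np.linspace(v0, v1, 5), [duration]])
    hump = np.array([1.04, 1.08, 1.05, 0.98, 0.90]) * rng.uniform(0.96, 1.04, 5)
    vals = np.concatenate([[base_f0], base_f0 * hump, [base_f0]])
    voiced = np.array([False, True, True, True, True, True, False])
    return F0Contour(t, vals, voiced)


def _sentence_contour(
    base_f0: float, duration: float, n_words: int, rng: np.random.Generator
) -> F0Contour:
    """Word-sized voiced spans with sentence-level declination and gaps."""
    gap = rng.uniform(0.04, 0.08, n_words - 1) if n_words > 1 else np.array([])
    total_gap = gap.sum()
    word_lens = rng.dirichlet(np.full(n_words, 4.0)) * (duration - total_gap - 0.1)
    times, vals, voiced = [0.0], [base_f0], [False]
    pos = 0.05
    for w in range(n_words):
        t0, t1 = pos, pos + word_lens[w]
        decl = 1.15 - 0.3 * (t0 / duration)  # declination across the sentence
        mod = rng.uniform(0.95, 1.05)
        for frac, shape in ((0.0, 1.0), (0.4, 1.06), (1.0, 0.94)):
            times.append(t0 + frac * (t1 - t0))
            vals.append(base_f0 * decl * mod * shape)
            voiced.append(True)
        pos = t1
        if w < n_words - 1:
            pos += gap[w]
            times.append(t0 + (t1 - t0) + gap[w] / 2)
            vals.append(base_f0)
            voiced.append(False)
    times.append(duration)
    vals.append(base_f0)
    voiced.append(False)
    return F0Contour(np.array(times), np.array(vals), np.array(voiced))


def make_material(seed: int, n_sentences: int = 100) -> SyntheticMaterial:
    """Generate the full synthetic speaker material for all experiments.

    Eight computer-voice profiles (four male, four female), one token per
    speaker and digit 1-9 with durations drawn so that six-digit sequences
    (with 50-200 ms pauses) land in the 2.6-4.4 s range, and ``n_sentences``
    sentence prototypes 1.8-3.5 s long.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 90]))
    speakers = []
    for i in range(4):
        speakers.append(
            SpeakerProfile(f"m{i+1}", "m", float(rng.uniform(100, 140)),
                           float(rng.uniform(0.95, 1.05)))
        )
    for i in range(4):
        speakers.append(
            SpeakerProfile(f"f{i+1}", "f", float(rng.uniform(180, 235)),
                           float(rng.uniform(1.10, 1.20)))
        )

    base_formants = np.array([600.0, 1200.0, 2500.0, 3500.0])
    tokens: dict[tuple[str, int], TokenMaterial] = {}
    for sp in speakers:
        for d in DIGITS:
            dur = float(rng.uniform(0.40, 0.55))
            contour = _digit_contour(sp.base_f0 * rng.uniform(0.97, 1.03), dur, rng)
            f = base_formants * sp.formant_scale * rng.uniform(0.93, 1.07, 4)
            f = np.sort(f)
            tokens[(sp.speaker_id, d)] = TokenMaterial(dur, contour, f)

    sent_speaker = SpeakerProfile("sent-f", "f", 205.0, 1.15)
    sentences: dict[int, SentenceMaterial] = {}
    for sid in range(n_sentences):
        if sid < len(FIXTURE_SENTENCES):
            text = FIXTURE_SENTENCES[sid]
        else:
            n_words = int(rng.integers(5, 10))
            text = " ".join(rng.choice(_VOCAB, n_words))
        n_words = len(text.split())
        dur = float(np.clip(0.33 * n_words + rng.uniform(0.2, 0.6), 1.8, 3.5))
        contour = _sentence_contour(sent_speaker.base_f0, dur, n_words, rng)
        f = base_formants * sent_speaker.formant_scale * rng.uniform(0.95, 1.05, 4)
        sentences[sid] = SentenceMaterial(sid, text, dur, contour, np.sort(f))
    return SyntheticMaterial(seed, speakers, tokens, sentences)


def material_envelopes(
    formants: np.ndarray,
    duration: float,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    attack: float = 0.08,
    decay: float = 0.15,
    tilt_db_per_khz: float = -2.0,
) -> tuple[SpectralEnvelope, AmplitudeEnvelope]:
    """Parametric spectral/amplitude envelopes on the pipeline's STFT grid.

    The spectral envelope is a sum of formant resonances (extended to
    Nyquist) with a gentle spectral tilt; the amplitude envelope is a
    raised-cosine attack/decay shape.  These emulate the smoothed envelopes
    that would be extracted from a recording.
    """
    freqs = np.fft.rfftfreq(NFFT, 1.0 / sample_rate)
    hop = (NPERSEG - NOVERLAP) / sample_rate
    n_frames = max(2, int(np.ceil(duration / hop)) + 1)
    times = np.linspace(0.0, duration, n_frames)
    full = extend_formants(formants, sample_rate / 2.0)
    from .vocal_tract import default_bandwidth

    env_f = resonance_envelope(freqs, full, default_bandwidth(full))
    env_f = env_f * 10.0 ** (tilt_db_per_khz * freqs / 1000.0 / 20.0) + 1e-4
    mags = np.tile(env_f[:, None], (1, n_frames))

    tau = times / duration
    amp = np.ones(n_frames)
    a = max(attack, 1e-3)
    d = max(decay, 1e-3)
    rising = tau < a
    falling = tau > 1 - d
    amp[rising] = 0.5 * (1 - np.cos(np.pi * tau[rising] / a))
    amp[falling] = 0.5 * (1 - np.cos(np.pi * (1 - tau[falling]) / d))
    amp = 0.05 + 0.95 * amp
    return SpectralEnvelope(times, freqs, mags), AmplitudeEnvelope(times, amp)


# ---------------------------------------------------------------------------
# listener models
# ---------------------------------------------------------------------------

@dataclass
class ListenerModel:
    """Generative psychometric model of a listener population.

    For the diphthong task, condition c at pitch p has a 50% point at
    ``base + rise * x(p)`` on the morph axis, where ``x(p)`` is log-pitch
    normalized to [0, 1] over 110-880 Hz; the response curve is a logistic
    with steepness ``slope`` plus a symmetric lapse and normal subject
    intercepts (s.d. ``subject_sd`` on the logit scale).

    For the digit and sentence tasks, per-unit (digit/word) error
    probabilities follow a logistic curve in SNR with per-condition offsets.
    """

    condition_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "tonal": (0.25, 0.45),
            "am": (0.25, 0.31),
            "subharmonics": (0.25, 0.27),
            "chaos": (0.25, 0.22),
            "whisper": (0.25, 0.17),
        }
    )
    slope: float = 12.0
    subject_sd: float = 0.5
    lapse: float = 0.02
    # digit/word tasks: P(unit correct) = expit(acc_base + acc_snr_slope*snr + offset)
    acc_base: float = 1.6
    acc_snr_slope: float = 0.22
    acc_offsets: dict[str, float] = field(
        default_factory=lambda: {
            "none": 0.0, "am": 0.0, "subharmonics": 0.0,
            "chaos": -0.1, "whisper": -0.2, "frequency_jump": -0.3,
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse rate must be in [0, 0.1]")

    @staticmethod
    def pitch_x(pitch_hz: float | np.ndarray) -> float | np.ndarray:
        return np.log2(np.asarray(pitch_hz, dtype=float) / 110.0) / 3.0

    def threshold_core(self, condition: str, pitch_hz: float) -> float:
        base, rise = self.condition_params[condition]
        return base + rise * float(self.pitch_x(pitch_hz))

    def p_diphthong(
        self,
        condition: str,
        morph: np.ndarray | float,
        pitch_hz: np.ndarray | float,
        subject_intercept: np.ndarray | float = 0.0,
    ) -> np.ndarray:
        base, rise = self.condition_params[condition]
        thr = base + rise * self.pitch_x(pitch_hz)
        core = expit(self.slope * (np.asarray(morph, float) - thr) + subject_intercept)
        return self.lapse + (1.0 - 2.0 * self.lapse) * core

    def pooled_curve(
        self, condition: str, pitch_hz: float, morph: np.ndarray, n_quad: int = 31
    ) -> np.ndarray:
        """Population response curve, averaging over subject intercepts."""
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
        weights = weights / weights.sum()
        p = np.zeros_like(np.asarray(morph, float))
        for b, w in zip(nodes * self.subject_sd, weights):
            p = p + w * self.p_diphthong(condition, morph, pitch_hz, b)
        return p

    def true_threshold(self, condition: str, pitch_hz: float) -> float:
        """Halfway-rise point of the pooled curve (the recovery estimand)."""
        grid = np.linspace(0.0, 1.0, 2001)
        p = self.pooled_curve(condition, pitch_hz, grid)
        target = 0.5 * (p[0] + p[-1])
        return float(np.interp(target, p, grid))

    def p_unit_correct(self, condition: str, snr: float | np.ndarray) -> np.ndarray:
        off = self.acc_offsets.get(condition, 0.0)
        return expit(self.acc_base + self.acc_snr_slope * np.asarray(snr, float) + off)


def null_listener_model(**kwargs) -> ListenerModel:
    """A model with identical parameters in every condition (zero effects)."""
    params = {c: (0.3, 0.3) for c in ("tonal", "am", "subharmonics", "chaos", "whisper")}
    offs = {c: 0.0 for c in ("none", "am", "subharmonics", "chaos", "whisper",
                             "frequency_jump")}
    return ListenerModel(condition_params=params, acc_offsets=offs, **kwargs)


# ---------------------------------------------------------------------------
# response simulation
# ---------------------------------------------------------------------------

def simulate_exp1_listeners(
    manifest: pd.DataFrame,
    model: ListenerModel,
    n_subjects: int,
    seed: int,
    trials_per_subject: int = 200,
) -> pd.DataFrame:
    """Binary diphthong/monophthong responses from the listener model.

    Each subject draws ``trials_per_subject`` stimuli from the manifest
    (without replacement) and responds according to the model's logistic
    surface with their own intercept and the model's lapse rate.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 91]))
    rows = []
    for s in range(n_subjects):
        b = rng.normal(0.0, model.subject_sd)
        idx = rng.choice(len(manifest), size=min(trials_per_subject, len(manifest)),
                         replace=False)
        sub = manifest.iloc[idx]
        for cond, grp in sub.groupby("condition"):
            p = model.p_diphthong(cond, grp["morph"].to_numpy(),
                                  grp["f0_hz"].to_numpy(), b)
            resp = rng.random(len(grp)) < p
            for sid, r in zip(grp["stimulus_id"], resp):
                rows.append({"stimulus_id": sid, "subject_id": f"s{s:03d}",
                             "response": int(r),
                             "rt_s": float(rng.lognormal(np.log(1.5), 0.4))})
    return pd.DataFrame(rows)


def simulate_exp23_listeners(
    manifest: pd.DataFrame,
    model: ListenerModel,
    n_subjects: int,
    seed: int,
    trials_per_subject: int = 100,
    noise_arm: bool = True,
) -> pd.DataFrame:
    """Digit-string or free-text responses for the word/sentence tasks.

    Digit sequences: each digit independently correct with the model's
    SNR x condition probability, errors uniform over the eight wrong
    digits.  Sentences: each target word is kept, deleted or substituted
    with condition-dependent probabilities.  Response times are lognormal
    latencies added to the nominal stimulus duration.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    experiment = int(manifest["experiment"].iloc[0])
    if experiment not in (2, 3):
        raise ValueError("manifest must come from experiment 2 or 3")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 92 + experiment]))
    rows = []
    for s in range(n_subjects):
        idx = rng.choice(len(manifest), size=min(trials_per_subject, len(manifest)),
                         replace=False)
        skill = rng.normal(0.0, 0.3)  # subject-level ability on the logit scale
        for _, rec in manifest.iloc[idx].iterrows():
            if experiment == 2:
                target = str(rec["digits"])
                p = float(np.clip(
                    model.p_unit_correct(rec["condition"], rec["snr_db"])
                    + skill * 0.05, 0.01, 0.999))
                out = []
                for ch in target:
                    if rng.random() < p:
                        out.append(ch)
                    else:
                        wrong = [d for d in "123456789" if d != ch]
                        out.append(wrong[rng.integers(len(wrong))])
                resp = "".join(out)
                dur = 3.6
            else:
                words = str(rec["text"]).split()
                snr = 0.0 if noise_arm else 12.0
                p = float(np.clip(
                    model.p_unit_correct(_exp3_model_condition(rec["condition"]), snr)
                    + skill * 0.05, 0.01, 0.999))
                out = []
                for w in words:
                    r = rng.random()
                    if r < p:
                        out.append(w)
                    elif r < p + (1 - p) / 2:
                        pass  # deletion
                    else:
                        out.append(_VOCAB[rng.integers(len(_VOCAB))])
                resp = " ".join(out)
                dur = float(rec.get("duration_s", 2.5))
            rows.append({
                "stimulus_id": rec["stimulus_id"], "subject_id": f"s{s:03d}",
                "response": resp,
                "rt_s": dur + float(rng.lognormal(np.log(2.5), 0.4)),
            })
    return pd.DataFrame(rows)


def _exp3_model_condition(condition: str) -> str:
    """Map the 12 sentence conditions onto the model's base NLP kinds."""
    if condition in ("original", "no_nlp"):
        return "none"
    if condition == "frequency_jumps":
        return "frequency_jump"
    if condition == "mixed":
        return "frequency_jump"
    return condition.rsplit("_", 1)[0]  # e.g. whisper_intermittent -> whisper
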