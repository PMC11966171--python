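# Methods

`nlpvox` synthesizes speech-like stimuli in which nonlinear vocal phenomena
(NLP) — subharmonics, amplitude modulation (AM), rapid jitter ("chaos"),
frequency jumps and whisper — are manipulated at the voice-source level,
and scores how well (simulated or real) listeners understand them.  This
note documents the models, the defaults and why, the numerical choices, and
what the synthetic listener does and does not show.

## Source-filter synthesis

The voice source is additive: one continuous sine per harmonic of the f0
contour, harmonic *k* attenuated by `rolloff · log2(k)` dB (rolloff in
dB/octave: 3 for the isolated-vowel experiment, 9 for word/sentence
resynthesis), plus optional white noise at a fixed level relative to the
harmonic RMS (−30 dB for resynthesis; the vowel experiment has none).
Phase is the cumulative integral of instantaneous frequency, starting at 0,
so slowly varying contours are click-free.  Harmonics are truncated 50 Hz
below Nyquist; a harmonic whose instantaneous frequency crosses that limit
is muted for those samples rather than allowed to alias.  Anchored f0
contours are interpolated to the audio rate (22 050 Hz everywhere) with
shape-preserving cubics (PCHIP), which keeps contours monotone between
anchors with a continuous first derivative.  Unvoiced anchor spans
synthesize as silence at the source level; envelope transplantation later
restores obstruent energy.

The vocal tract is a frame-wise spectral envelope applied to STFT frames
(1024-sample windows, 75 % overlap, 2048-point FFT).  Vowels use a
sum-of-resonances envelope (unit-gain Lorentzian peaks) at formant
frequencies F1–F4, extended to Nyquist by repeating the mean inter-formant
spacing.  The shipped vowel table (/a o e i u/) holds typical adult-male
formant values and is overridable via CSV; bandwidths default to
`50 + 0.05·F` Hz.  Diphthongs morph formant targets linearly over the
token; `morph` scales how far the glide travels (0 = monophthong,
1 = full diphthong).  A Hilbert-envelope compressor (50 ms smoothing
window, floor at 1 % of the envelope peak, output rescaled to input RMS)
evens out loudness across the glide.

For resynthesis, smoothed spectral envelopes (300 Hz frequency window) and
amplitude envelopes (200 ms time window) are measured from the reference
material and multiplied onto the synthetic source's STFT frames (gain
clamped to ±40 dB; frames with negligible energy are passed through).
Transplanting a signal's own envelopes is a fixed point to < 1 dB.

## NLP manipulations

"Depth" is not uniquely defined in the literature, so the package fixes one
reading per effect and leaves both as plain scalars:

* **AM** — gain `1 − d/2 + (d/2)·cos(2π f t)`: *d* is the peak-to-trough
  fraction of the carrier level.  This places sidebands at ±f around every
  harmonic at `(d/4)/(1 − d/2)` relative to the (modulated) carrier, e.g.
  −15.6 dB at d = 0.5.
* **Subharmonics** — partials inserted at `m·f0/ratio` (m not divisible by
  the ratio), each at `depth` times the rolloff-curve amplitude at its
  frequency, capped at the fundamental's amplitude so a subharmonic never
  exceeds f0.  Ratio 2 doubles the waveform period.
* **Chaos** — multiplicative jitter `2^(u(t)/12)` with u uniform in
  ±depth/2 semitones, redrawn at 1 kHz and linearly interpolated
  (sample-and-hold behind a flag).  The bound |u| ≤ depth/2 is exact.
* **Frequency jumps** — all anchors after the jump point multiplied by
  `2^(±magnitude/12)`; anchor pairs are inserted at the discontinuity so
  later interpolation cannot smooth it.  Sentence-level planning draws jump
  times inside voiced spans, alternates direction with probability 0.9 and
  forces a reversal whenever the cumulative shift would exceed ±1 octave,
  which keeps the shifted contour inside [min/2, 2·max] of the original.
* **Whisper** — the harmonic source is replaced by white noise (everywhere,
  or inside episodes with RMS matched to the voiced part).

Episodes are (start, end) fractions of the stimulus; edges get 5 ms
raised-cosine crossfades.  Intermittent placement draws the episode count
from Poisson(5) truncated to [2, 8] and a total coverage fraction uniform
in [0.25, 0.7] (inside the designed 0.2–0.8 band), splitting lengths and
gaps with Dirichlet(2) weights — the qualitative target is "about five
separate episodes", the exact law being a package choice.  In the *mixed*
sentence condition each episode's NLP kind is drawn uniformly from
{am, subharmonics, chaos} and frequency jumps are added independently.

## Masking noise and mixing

Masking noise is built on the rFFT grid — unit magnitude up to the 1.2 kHz
corner, then −6 dB/kHz — with uniform random phases, inverse-transformed
and RMS-normalized.  Mixing scales the noise so that
`20·log10(RMS_signal/RMS_noise)` equals the target SNR exactly (RMS over
the full duration; a voiced-frames weighting is deliberately not the
default), then peak-normalizes only if the sum would clip.

## Experiment designs

Manifests are pure functions of a master seed; every row carries a derived
per-record seed (`SeedSequence([master, experiment, index])`, reduced below
2³¹) so any stimulus re-renders bit-identically from its row alone.

* **Experiment 1** — 999 prototypes: f0 log-uniform in [110, 880] Hz, 50 %
  diphthongs with morph drawn from {0.1, …, 1.0}, distinct vowel pairs,
  700 ms; NLP parameters per prototype (AM 50–150 Hz at depth 0.4–0.6,
  subharmonic depth 0.4–0.6, jitter 2–4 st at 1 kHz); crossed with
  {tonal, am, subharmonics, chaos, whisper} → 4995 records.
* **Experiment 2** — 1300 six-digit sequences (digits 1–9, no zero), eight
  synthetic speakers, condition uniform over the 18-cell grid of six NLP
  kinds × pitch shifts {0, +1, +1.5} octaves (the whispered source has no
  f0 to shift, so its records carry shift 0), SNR uniform in [−6, 15] dB,
  AM depth 0.3–0.6, subharmonic depth 0.3–0.5, jitter 1–4 st; per-digit
  jump point uniform in 25–75 % of the token at 3–12 st.  Tokens are
  concatenated with 50–200 ms pauses and mixed against profile noise.
* **Experiment 3** — 100 sentences × 12 conditions: original,
  resynthesized no-NLP, frequency jumps (Poisson(5)-truncated count,
  0.5–12 st, alternating), mixed, and {whisper, am, subharmonics, chaos} ×
  {continuous, intermittent}.  The two noise arms (quiet / 0 dB SNR) reuse
  the same records at render or scoring time.

## Synthetic material and listeners

The original recordings are replaced by generated stand-ins: eight speaker
profiles (four male, base f0 100–140 Hz; four female, 180–235 Hz, formant
scale 1.10–1.20), per-digit tokens 0.40–0.55 s (six digits plus pauses land
in 2.6–4.4 s by construction) with rising–falling contours and declination,
and 100 sentence prototypes 1.8–3.5 s with word-sized voiced spans
separated by 40–80 ms unvoiced gaps.  Four example sentences are fixed
texts; the rest are word strings from a small vocabulary.  Spectral
envelopes of the material are parametric formant stacks with a −2 dB/kHz
tilt, built directly on the pipeline's STFT grid.

The listener model is explicitly illustrative.  For the diphthong task the
population response is a logistic in morph with steepness 12, a 50 % point
at `base + rise · x(pitch)` (x = log-pitch normalized over 110–880 Hz),
normal subject intercepts (s.d. 0.5 logits) and a 2 % symmetric lapse rate.
Default rises are steepest with no NLP and shallowest for whisper, matching
the qualitative ordering of human data; the numbers are not estimates of
any real population.  For digit/sentence tasks, per-unit accuracy follows a
logistic in SNR with per-condition offsets (jumps and whisper hardest);
digit confusions are uniform over the eight wrong digits — a documented
simplification with no phonetic confusability.

What passing tests show: the pipeline's estimators recover the parameters
of this generative family at realistic sample sizes.  What they do not
show: anything about human effect sizes, phonetic confusions, attention,
or learning — real listeners are not exchangeable logistic responders.

## Scoring and psychometrics

Free-text responses are lowercased, stripped to alphanumerics and spaces,
and whitespace-collapsed before scoring.  Metrics: positional digit
matching (0–6 errors; short responses pad as errors); symbol-level DTW with
0/1 local cost, minimized lexicographically in (cost, path length) and
normalized by the optimal path length (the divisor is a package decision —
"normalized distance" alone does not fix one); word error rate = word-level
edit distance / target word count, clamped to [0, 1] (insertion-heavy
responses can exceed 1); normalized Levenshtein (character edits / target
length); Jaro distance with the standard matching window clamped to ≥ 0.
Response times are adjusted by subtracting stimulus duration and may go
negative (typing may start during playback).

Binary diphthong responses are fit with a fixed-effects binomial model:
per-condition cell-means design in (1, morph, pitch, morph·pitch) —
equivalent to a full condition × morph × pitch interaction — wrapped in a
shared symmetric lapse, `P = λ + (1 − 2λ)·σ(Xβ)` with λ ∈ [0, 0.1],
maximized directly (L-BFGS with analytic gradients, warm-started from the
plain GLM).  The lapse term matters: listeners guess on a small fraction of
trials, and fitting a pure logistic to a lapse-flattened curve biases the
halfway-point threshold; with the symmetric lapse the halfway point of the
full curve equals that of the core logistic, so thresholds are read off the
core coefficients in closed form.  The 50 % discrimination threshold for a
condition × pitch curve solves `P(m*) = (P(0) + P(1))/2`; a curve rising
less than 0.05 between morph 0 and 1, or a solution outside [0, 1], is
flagged unattained.  Multilevel (random-effects) machinery is deliberately
out of scope; subject clustering is handled by a cluster bootstrap —
resampling subjects with replacement and refitting (200 refits by default)
— giving percentile CIs for thresholds.  Condition contrasts are mean
differences with a subject-cluster bootstrap (2000 resamples, percentile).

The recovery estimand is the halfway-rise point of the *pooled* generative
curve (subject intercepts integrated out by Gauss–Hermite quadrature),
computed numerically from the listener model itself — lapse and
heterogeneity shift the pooled curve relative to the core midpoint, and the
coverage check must compare like with like.

## Problem sizes

The recovery study simulates 40 listeners × 200 trials per replicate, fits
with 150 bootstrap refits, and runs 100 seeded replicates (thresholds
probed at 220 Hz, where the design is densest); null-contrast coverage uses
the same replicate count with 2000-resample contrast bootstraps.  Metric
oracle checks are exhaustive over all 3-symbol string pairs up to length 4
(14 641 pairs) plus thousands of seeded random pairs up to length 8 — the
full length-8 cross product (~10⁸ pairs) adds nothing beyond cost.

## Known limitations

* The formant filter is zero-phase envelope multiplication, not a resonator
  cascade; formant bandwidths shape the envelope but not group delay.
* "Chaos" is rapid bounded jitter, an imitation — no deterministic-chaos
  dynamics, and jitter perturbs f0 only, not harmonic amplitudes.
* Source noise is white before filtering; the masking-noise substitute for
  street noise keeps only the stated spectrum and the SNR contract.
* Exp 2 condition assignment is uniform over the 18 cells (not balanced);
  cell counts fluctuate around 1300/18.
* The synthetic material has no consonant structure; digit tokens are
  vowel-like, so acoustic intelligibility of renders is not meaningful —
  intelligibility enters only through the simulated listeners.
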