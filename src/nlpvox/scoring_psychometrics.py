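"""Intelligibility scoring and psychometric-threshold estimation.

String metrics
    * positional digit matching (0-6 errors per six-digit sequence);
    * symbol-level dynamic time warping with 0/1 local cost, normalized by
      the optimal warping-path length;
    * word error rate (word-level edit distance / target word count,
      clamped to [0, 1]; accuracy = 1 - WER);
    * normalized Levenshtein distance (character edits / target length);
    * Jaro distance (1 - Jaro similarity).

Psychometrics
    Binary diphthong responses are fit with a fixed-effects logistic model
    of condition x morph x pitch; subject clustering is handled by a
    cluster bootstrap (resampling subjects and refitting).  The 50%
    discrimination threshold of a fitted curve is the morph value at which
    the response probability lies halfway between the curve's floor
    (morph = 0) and ceiling (morph = 1).  Condition contrasts are mean
    differences with subject-cluster bootstrap percentile intervals.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit


# ---------------------------------------------------------------------------
# response normalization & digit matching
# ---------------------------------------------------------------------------

def normalize_response(text: str) -> str:
    """Lowercase, strip non-alphanumerics, collapse runs of whitespace."""
    text = str(text).lower()
    text = re.sub(r"[^a-z0-9\s]+", "", text)
    return re.sub(r"\s+", " ", text).strip()


def digit_match(target: str, response: str) -> int:
    """Positional error count (0-6) between six-digit strings.

    Missing positions in a short response count as errors; characters
    beyond the target length are ignored.
    """
    target = normalize_response(target).replace(" ", "")
    response = normalize_response(response).replace(" ", "")
    if len(target) != 6 or not target.isdigit():
        raise ValueError("target must be exactly six digits")
    if response and not response.isdigit():
        raise ValueError("response contains non-digit characters")
    errors = 0
    for i, t in enumerate(target):
        if i >= len(response) or response[i] != t:
            errors += 1
    return errors


def adjust_rt(rt: float, stimulus_duration: float) -> float:
    """Response time minus stimulus duration (may be negative: typing can
    start during playback)."""
    if rt <= 0:
        raise ValueError("rt must be positive")
    return rt - stimulus_duration


# ---------------------------------------------------------------------------
# sequence / string distances
# ---------------------------------------------------------------------------

def dtw_sequence_distance(target, response) -> float:
    """Symbol-level DTW distance with 0/1 local cost, path-length normalized.

    The accumulated cost is minimized with a lexicographic (cost, length)
    dynamic program, so among all minimum-cost warping paths the shortest
    is used as the normalization divisor.  Identical sequences give 0;
    insertions and deletions are penalized less than substitutions or
    inversions because repeats along the path can absorb them at no cost.
    """
    a, b = list(target), list(response)
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    INF = (np.inf, np.inf)
    cost = np.empty((n, m))
    length = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            c = 0.0 if a[i] == b[j] else 1.0
            if i == 0 and j == 0:
                best = (0.0, 0.0)
            else:
                best = INF
                for pi, pj in ((i - 1, j - 1), (i - 1, j), (i, j - 1)):
                    if pi >= 0 and pj >= 0:
                        cand = (cost[pi, pj], length[pi, pj])
                        if cand < best:
                            best = cand
            cost[i, j] = best[0] + c
            length[i, j] = best[1] + 1
    return float(cost[-1, -1] / length[-1, -1])


def _edit_distance(a: list, b: list) -> int:
    """Levenshtein distance between two symbol sequences (vectorized rows)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = np.arange(len(b) + 1)
    bb = np.asarray(b, dtype=object)
    for i, ai in enumerate(a, start=1):
        cur = np.empty(len(b) + 1, dtype=int)
        cur[0] = i
        sub = prev[:-1] + (bb != ai)
        for j in range(1, len(b) + 1):
            cur[j] = min(sub[j - 1], prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return int(prev[-1])


def wer(target: str, response: str) -> float:
    """Word error rate: word-level edits / target word count, clamped to [0, 1]."""
    t_words = normalize_response(target).split()
    r_words = normalize_response(response).split()
    if not t_words:
        raise ValueError("empty target")
    return min(1.0, _edit_distance(t_words, r_words) / len(t_words))


def levenshtein_norm(target: str, response: str) -> float:
    """Character-level edit distance divided by the target length."""
    target = normalize_response(target)
    response = normalize_response(response)
    if not target:
        raise ValueError("empty target")
    return _edit_distance(list(target), list(response)) / len(target)


def jaro_distance(a: str, b: str) -> float:
    """1 - Jaro similarity with the standard matching window and
    half-transposition count."""
    a, b = str(a), str(b)
    if a == b:
        return 0.0
    if not a or not b:
        return 1.0
    window = max(0, max(len(a), len(b)) // 2 - 1)
    match_a = [False] * len(a)
    match_b = [False] * len(b)
    matches = 0
    for i, ca in enumerate(a):
        lo, hi = max(0, i - window), min(len(b), i + window + 1)
        for j in range(lo, hi):
            if not match_b[j] and b[j] == ca:
                match_a[i] = match_b[j] = True
                matches += 1
                break
    if matches == 0:
        return 1.0
    sa = [c for c, m in zip(a, match_a) if m]
    sb = [c for c, m in zip(b, match_b) if m]
    transpositions = sum(x != y for x, y in zip(sa, sb)) / 2.0
    sim = (matches / len(a) + matches / len(b) + (matches - transpositions) / matches) / 3.0
    return 1.0 - sim


METRICS = {
    "wer": wer,
    "lev": levenshtein_norm,
    "jaro": lambda t, r: jaro_distance(normalize_response(t), normalize_response(r)),
    "dtw": dtw_sequence_distance,
}


def score_responses(
    manifest: pd.DataFrame,
    responses: pd.DataFrame,
    metrics: tuple[str, ...] = ("wer", "lev", "jaro"),
) -> pd.DataFrame:
    """Join responses to their manifest rows and compute per-trial metrics.

    Experiment 2 rows additionally get ``digit_errors`` and ``dtw``;
    experiment 3 rows are scored against the sentence text.
    """
    df = responses.merge(manifest, on="stimulus_id", how="inner")
    experiment = int(df["experiment"].iloc[0])
    out = df.copy()
    if experiment == 2:
        out["digit_errors"] = [
            digit_match(t, r) for t, r in zip(df["digits"], df["response"])
        ]
        out["dtw"] = [
            dtw_sequence_distance(str(t), normalize_response(r).replace(" ", "") or "0")
            for t, r in zip(df["digits"], df["response"])
        ]
    else:
        for name in metrics:
            fn = METRICS[name]
            out[name] = [fn(str(t), str(r)) for t, r in zip(df["text"], df["response"])]
        if "wer" in metrics:
            out["accuracy"] = 1.0 - out["wer"]
    return out


# ---------------------------------------------------------------------------
# psychometric fitting
# ---------------------------------------------------------------------------

PITCH_REF_HZ = 110.0
PITCH_SPAN_OCT = 3.0  # 110 -> 880 Hz


def _pitch_x(pitch_hz: np.ndarray) -> np.ndarray:
    return np.log2(np.asarray(pitch_hz, dtype=float) / PITCH_REF_HZ) / PITCH_SPAN_OCT


def _design(condition: np.ndarray, morph: np.ndarray, x: np.ndarray,
            levels: list[str]) -> np.ndarray:
    """Cell-means design: per condition [1, morph, pitch, morph*pitch].

    Equivalent to a full condition*morph*pitch interaction model.
    """
    n = condition.size
    X = np.zeros((n, 4 * len(levels)))
    for k, lev in enumerate(levels):
        m = condition == lev
        X[m, 4 * k] = 1.0
        X[m, 4 * k + 1] = morph[m]
        X[m, 4 * k + 2] = x[m]
        X[m, 4 * k + 3] = morph[m] * x[m]
    return X


def _fit_glm(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
    return np.asarray(res.params)


MAX_LAPSE = 0.1


def _fit_lapse_logistic(
    X: np.ndarray, y: np.ndarray, start: np.ndarray | None = None
) -> np.ndarray:
    """ML fit of a logistic with a shared symmetric lapse rate.

    P(y=1) = lam + (1 - 2 lam) * expit(X beta), lam in [0, 0.1].  Listeners
    lapse — respond at random on a small fraction of trials — which flattens
    the response curve's floor and ceiling; ignoring this biases the
    halfway-point threshold, while a symmetric lapse leaves it invariant.
    Returns the concatenated vector [beta, lam].
    """
    from scipy.optimize import minimize

    if start is None:
        beta0 = _fit_glm(X, y)
    else:
        beta0 = start[:-1]
    s0 = logit(max(min(start[-1] / MAX_LAPSE, 0.99), 0.01)) if start is not None else logit(0.2)
    theta0 = np.concatenate([beta0, [s0]])

    def negll_grad(theta):
        beta, s = theta[:-1], theta[-1]
        lam = MAX_LAPSE * expit(s)
        q = expit(X @ beta)
        p = np.clip(lam + (1.0 - 2.0 * lam) * q, 1e-12, 1.0 - 1e-12)
        ll = np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p))
        w = y / p - (1.0 - y) / (1.0 - p)
        g_beta = X.T @ (w * (1.0 - 2.0 * lam) * q * (1.0 - q))
        dlam_ds = MAX_LAPSE * expit(s) * (1.0 - expit(s))
        g_s = np.sum(w * (1.0 - 2.0 * q)) * dlam_ds
        return -ll, -np.concatenate([g_beta, [g_s]])

    res = minimize(negll_grad, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 200})
    beta, s = res.x[:-1], res.x[-1]
    return np.concatenate([beta, [MAX_LAPSE * expit(s)]])


@dataclass
class PsychometricFit:
    """Fitted lapse-logistic response surface with bootstrap coefficient draws.

    ``params`` holds the per-condition logit coefficients followed by the
    fitted shared lapse rate.
    """

    levels: list[str]
    params: np.ndarray
    boot_params: np.ndarray            # (n_boot, p); empty if n_boot = 0
    n_trials: int
    skipped_cells: list[str] = field(default_factory=list)

    @property
    def lapse_rate(self) -> float:
        return float(self.params[-1])

    def curve_coefs(self, condition: str, pitch_hz: float,
                    params: np.ndarray | None = None) -> tuple[float, float]:
        """Core-logit intercept and morph slope at a given condition and pitch."""
        if condition not in self.levels:
            raise KeyError(f"condition {condition!r} not in fit")
        p = self.params if params is None else params
        k = self.levels.index(condition)
        x = float(_pitch_x(pitch_hz))
        a = p[4 * k] + p[4 * k + 2] * x
        b = p[4 * k + 1] + p[4 * k + 3] * x
        return float(a), float(b)

    def predict(self, condition: str, morph, pitch_hz: float) -> np.ndarray:
        a, b = self.curve_coefs(condition, pitch_hz)
        lam = self.lapse_rate
        return lam + (1.0 - 2.0 * lam) * expit(a + b * np.asarray(morph, dtype=float))


def fit_psychometric(
    data: pd.DataFrame,
    n_boot: int = 200,
    seed: int = 0,
    min_trials_per_cell: int = 50,
) -> PsychometricFit:
    """Fit the logistic response surface P(diphthong | condition, morph, pitch).

    ``data`` needs columns condition, morph, f0_hz (or pitch_hz), response
    (0/1) and subject_id.  The full condition x morph x pitch interaction is
    fit as a fixed-effects binomial GLM; ``n_boot`` subject-cluster
    bootstrap refits provide the sampling distribution used for threshold
    and contrast intervals.  Conditions observed in fewer than
    ``min_trials_per_cell`` trials are flagged and excluded.
    """
    df = data.copy()
    if "pitch_hz" not in df and "f0_hz" in df:
        df["pitch_hz"] = df["f0_hz"]
    counts = df.groupby("condition").size()
    skipped = [c for c in counts.index if counts[c] < min_trials_per_cell]
    if skipped:
        df = df[~df["condition"].isin(skipped)]
    levels = sorted(df["condition"].unique())
    if not levels:
        raise ValueError("no condition has enough trials to fit")
    cond = df["condition"].to_numpy()
    morph = df["morph"].to_numpy(float)
    x = _pitch_x(df["pitch_hz"].to_numpy(float))
    y = df["response"].to_numpy(float)
    X = _design(cond, morph, x, levels)
    params = _fit_lapse_logistic(X, y)

    boot = np.empty((0, params.size))
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        subjects = df["subject_id"].to_numpy()
        uniq = np.unique(subjects)
        by_subj = {s: np.flatnonzero(subjects == s) for s in uniq}
        draws = []
        for _ in range(n_boot):
            pick = rng.choice(uniq, size=uniq.size, replace=True)
            idx = np.concatenate([by_subj[s] for s in pick])
            try:
                draws.append(_fit_lapse_logistic(X[idx], y[idx], start=params))
            except Exception:
                continue  # singular resample (e.g. a cell vanished): drop it
        if draws:
            boot = np.vstack(draws)
    return PsychometricFit(levels, params, boot, len(df), skipped)


@dataclass
class ThresholdEstimate:
    value: float
    ci: tuple[float, float]
    attained: bool


#: a curve rising less than this between morph 0 and 1 is treated as flat
MIN_CURVE_RISE = 0.05


def _threshold_from_coefs(a: float, b: float) -> float:
    """Halfway-rise morph of the logistic curve expit(a + b*m) on [0, 1].

    The halfway point is invariant to a symmetric lapse, so the core-logit
    coefficients determine it for the full lapse-augmented curve too.
    """
    p0, p1 = expit(a), expit(a + b)
    if abs(p1 - p0) < MIN_CURVE_RISE or b == 0:
        return np.nan  # ceiling ~ floor: halfway point undefined
    target = 0.5 * (p0 + p1)
    return (logit(target) - a) / b


def threshold50(
    fit: PsychometricFit, condition: str, pitch_hz: float,
    ci_level: float = 0.95,
) -> ThresholdEstimate:
    """50% discrimination threshold for one condition x pitch curve.

    Solves P(m*) = (P(0) + P(1)) / 2 on the fitted logistic; the bootstrap
    coefficient draws give a percentile CI.  A flat curve (ceiling = floor)
    or a solution outside [0, 1] is flagged as unattained.
    """
    a, b = fit.curve_coefs(condition, pitch_hz)
    m = _threshold_from_coefs(a, b)
    attained = bool(np.isfinite(m) and 0.0 <= m <= 1.0)
    lo = hi = np.nan
    if fit.boot_params.size:
        draws = []
        for p in fit.boot_params:
            ab = fit.curve_coefs(condition, pitch_hz, p)
            draws.append(_threshold_from_coefs(*ab))
        draws = np.asarray(draws)
        draws = draws[np.isfinite(draws)]
        if draws.size >= 10:
            alpha = (1.0 - ci_level) / 2.0
            lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return ThresholdEstimate(float(m), (float(lo), float(hi)), attained)


@dataclass
class ContrastEstimate:
    difference: float
    ci: tuple[float, float]


def condition_contrast(
    data: pd.DataFrame,
    metric: str,
    condition_a: str,
    condition_b: str,
    subject_col: str = "subject_id",
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> ContrastEstimate:
    """Difference in mean metric between two conditions with a
    subject-cluster bootstrap percentile CI."""
    df = data[data["condition"].isin([condition_a, condition_b])]
    subjects = df[subject_col].unique()
    if subjects.size < 2:
        raise ValueError("cluster bootstrap requires at least two subjects")
    is_a = (df["condition"] == condition_a).to_numpy()
    vals = df[metric].to_numpy(float)
    subj = df[subject_col].to_numpy()
    # per-subject sufficient statistics
    sums_a = np.zeros(subjects.size); n_a = np.zeros(subjects.size)
    sums_b = np.zeros(subjects.size); n_b = np.zeros(subjects.size)
    index = {s: i for i, s in enumerate(subjects)}
    si = np.fromiter((index[s] for s in subj), int, len(subj))
    np.add.at(sums_a, si[is_a], vals[is_a]); np.add.at(n_a, si[is_a], 1)
    np.add.at(sums_b, si[~is_a], vals[~is_a]); np.add.at(n_b, si[~is_a], 1)
    point = sums_a.sum() / max(n_a.sum(), 1) - sums_b.sum() / max(n_b.sum(), 1)

    rng = np.random.default_rng(seed)
    picks = rng.integers(0, subjects.size, size=(n_boot, subjects.size))
    ra = sums_a[picks].sum(axis=1) / np.maximum(n_a[picks].sum(axis=1), 1)
    rb = sums_b[picks].sum(axis=1) / np.maximum(n_b[picks].sum(axis=1), 1)
    diffs = ra - rb
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    return ContrastEstimate(float(point), (float(lo), float(hi)))
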