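"""String and sequence metrics checked against independent brute-force oracles."""

import itertools
from functools import lru_cache

import numpy as np
import pytest

from nlpvox.scoring_psychometrics import (
    adjust_rt,
    digit_match,
    dtw_sequence_distance,
    jaro_distance,
    levenshtein_norm,
    normalize_response,
    wer,
)


# ---------------------------------------------------------------------------
# independent oracles (recursive, memoized; no shared code with the package)
# ---------------------------------------------------------------------------

def oracle_edit_distance(a: str, b: str) -> int:
    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        return min(rec(i - 1, j - 1) + cost, rec(i - 1, j) + 1, rec(i, j - 1) + 1)

    return rec(len(a), len(b))


def oracle_dtw(a: str, b: str) -> float:
    """Enumerate every monotone warping path; lexicographic (cost, length) min."""
    n, m = len(a), len(b)
    best = (float("inf"), float("inf"))
    stack = [(0, 0, 1 if a[0] != b[0] else 0, 1)]
    while stack:
        i, j, cost, length = stack.pop()
        if cost > best[0]:
            continue
        if i == n - 1 and j == m - 1:
            best = min(best, (cost, length))
            continue
        for ni, nj in ((i + 1, j + 1), (i + 1, j), (i, j + 1)):
            if ni < n and nj < m:
                c = 0 if a[ni] == b[nj] else 1
                stack.append((ni, nj, cost + c, length + 1))
    return best[0] / best[1]


def oracle_jaro_similarity(a: str, b: str) -> float:
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    window = max(0, max(len(a), len(b)) // 2 - 1)
    used = [False] * len(b)
    ma, mb = [], []
    for i, ca in enumerate(a):
        for j in range(max(0, i - window), min(len(b), i + window + 1)):
            if not used[j] and b[j] == ca:
                used[j] = True
                ma.append(ca)
                break
    for j, cb in enumerate(b):
        if used[j]:
            mb.append(cb)
    if not ma:
        return 0.0
    t = sum(x != y for x, y in zip(ma, mb)) / 2
    m = len(ma)
    return (m / len(a) + m / len(b) + (m - t) / m) / 3


ALPHABET = "abc"


def all_strings(max_len):
    for n in range(max_len + 1):
        for tup in itertools.product(ALPHABET, repeat=n):
            yield "".join(tup)


class TestMetricOracleEquivalence:
    def test_exhaustive_small_strings(self):
        """Exact agreement with the oracles over every pair up to length 4."""
        strings = list(all_strings(4))
        for a in strings:
            for b in strings:
                assert jaro_distance(a, b) == pytest.approx(
                    1 - oracle_jaro_similarity(a, b), abs=1e-12
                )
                if a:
                    assert levenshtein_norm(a, b) == pytest.approx(
                        oracle_edit_distance(a, b) / len(a), abs=1e-12
                    )
                if a and b:
                    assert dtw_sequence_distance(a, b) == pytest.approx(
                        oracle_dtw(a, b), abs=1e-12
                    )

    def test_random_pairs_up_to_length_8(self):
        """Seeded random coverage of longer pairs over the 3-symbol alphabet."""
        rng = np.random.default_rng(2024)
        for _ in range(1500):
            la, lb = rng.integers(1, 9, 2)
            a = "".join(rng.choice(list(ALPHABET), la))
            b = "".join(rng.choice(list(ALPHABET), lb))
            assert levenshtein_norm(a, b) == pytest.approx(
                oracle_edit_distance(a, b) / len(a), abs=1e-12
            )
            assert jaro_distance(a, b) == pytest.approx(
                1 - oracle_jaro_similarity(a, b), abs=1e-12
            )
            assert dtw_sequence_distance(a, b) == pytest.approx(oracle_dtw(a, b), abs=1e-12)

    def test_wer_equals_word_level_oracle(self):
        rng = np.random.default_rng(7)
        vocab = ["ab", "cd", "ef", "gh"]
        for _ in range(400):
            t = " ".join(rng.choice(vocab, rng.integers(1, 8)))
            r = " ".join(rng.choice(vocab, rng.integers(0, 8)))
            # words are symbols: reuse the character oracle on a symbol encoding
            enc = {w: chr(65 + i) for i, w in enumerate(vocab)}
            et = "".join(enc[w] for w in t.split())
            er = "".join(enc[w] for w in r.split())
            assert wer(t, r) == pytest.approx(
                min(1.0, oracle_edit_distance(et, er) / len(et)), abs=1e-12
            )

    def test_edlib_cross_check(self):
        """Independent library agreement for the character edit distance."""
        edlib = pytest.importorskip("edlib")
        rng = np.random.default_rng(99)
        for _ in range(300):
            a = "".join(rng.choice(list("abcde"), rng.integers(1, 15)))
            b = "".join(rng.choice(list("abcde"), rng.integers(0, 15)))
            expected = edlib.align(b, a)["editDistance"] / len(a)
            assert levenshtein_norm(a, b) == pytest.approx(expected, abs=1e-12)


class TestKnownValues:
    def test_kitten_sitting(self):
        assert levenshtein_norm("kitten", "sitting") == pytest.approx(3 / 6)

    def test_martha_marhta_jaro(self):
        assert jaro_distance("martha", "marhta") == pytest.approx(1 - 17 / 18, abs=1e-9)

    def test_disjoint_strings_jaro_is_one(self):
        assert jaro_distance("abc", "xyz") == 1.0

    def test_wer_fig_sentence_one_substitution(self):
        t = "an abrupt start does not win the prize"
        r = "an abrupt start does not win a prize"
        assert wer(t, r) == pytest.approx(1 / 8)

    def test_wer_empty_response_is_one(self):
        assert wer("some target words", "") == 1.0

    def test_single_char_levenshtein(self):
        assert levenshtein_norm("a", "b") == 1.0

    def test_all_metrics_zero_on_identical(self):
        s = "the jacket hung on the back of the wide chair"
        assert wer(s, s) == 0.0
        assert levenshtein_norm(s, s) == 0.0
        assert jaro_distance(s, s) == 0.0
        assert dtw_sequence_distance("123456", "123456") == 0.0
        assert digit_match("123456", "123456") == 0

    def test_dtw_deletion_not_worse_than_substitution(self):
        """For every length-6 target: dropping one symbol costs no more than
        substituting one (DTW absorbs deletions by repeats)."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            t = "".join(rng.choice(list("123456789"), 6))
            i = rng.integers(6)
            deletion = t[:i] + t[i + 1 :]
            wrong = str((int(t[i]) % 9) + 1)
            substitution = t[:i] + wrong + t[i + 1 :]
            assert dtw_sequence_distance(t, deletion) <= dtw_sequence_distance(
                t, substitution
            ) + 1e-12


class TestNormalization:
    def test_stated_rule(self):
        assert normalize_response("The  Jacket, hung!") == "the jacket hung"

    def test_idempotent(self):
        s = normalize_response("Drop the two… when you ADD the figures!!")
        assert normalize_response(s) == s
        assert "…" not in s and s == s.lower()

    def test_empty_in_empty_out(self):
        assert normalize_response("") == ""
        assert normalize_response("!!!") == ""


class TestDigitMatch:
    @pytest.mark.parametrize(
        "target,response,errors",
        [("123456", "123456", 0), ("123456", "123455", 1),
         ("123456", "654321", 6), ("123456", "123", 3), ("123456", "", 6)],
    )
    def test_positional_errors(self, target, response, errors):
        assert digit_match(target, response) == errors

    def test_errors_plus_correct_conserves_six(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            t = "".join(rng.choice(list("123456789"), 6))
            r = "".join(rng.choice(list("123456789"), 6))
            e = digit_match(t, r)
            correct = sum(a == b for a, b in zip(t, r))
            assert e + correct == 6

    def test_non_digit_rejected(self):
        with pytest.raises(ValueError):
            digit_match("123456", "12a456")
        with pytest.raises(ValueError):
            digit_match("12345", "123456")


class TestResponseTime:
    def test_subtraction(self):
        assert adjust_rt(6.3, 3.6) == pytest.approx(2.7)
        assert adjust_rt(3.6, 3.6) == 0.0

    def test_negative_allowed_nonpositive_rt_rejected(self):
        assert adjust_rt(2.0, 3.0) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            adjust_rt(0.0, 1.0)
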