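"""NLP manipulations: identity at zero depth, spectral signatures, bounds."""

import numpy as np
import pytest

import nlpvox as nv
from nlpvox.nlp_effects import episode_gate
from nlpvox.source_synthesis import F0Contour, interpolate_f0, synth_harmonics

from conftest import peak_level_db


def _tone(f0=200.0, dur=1.0, rolloff=60.0, sr=22050):
    track = np.full(int(dur * sr), f0)
    return synth_harmonics(track, rolloff, sr)


class TestAmplitudeModulation:
    def test_zero_depth_is_identity(self):
        w = _tone()
        out = nv.apply_am(w, 100.0, 0.0)
        assert np.max(np.abs(out.samples - w.samples)) <= 1e-12

    def test_sidebands_at_am_frequency(self):
        """AM at 100 Hz on a 200 Hz carrier puts sidebands at 100 and 300 Hz
        at (depth/4)/(1 - depth/2) relative to the modulated carrier."""
        depth = 0.5
        w = nv.apply_am(_tone(200.0, rolloff=90.0), 100.0, depth)
        carrier = peak_level_db(w, 200.0)
        expected = 20 * np.log10((depth / 4) / (1 - depth / 2))
        assert peak_level_db(w, 100.0) - carrier == pytest.approx(expected, abs=0.5)
        assert peak_level_db(w, 300.0) - carrier == pytest.approx(expected, abs=0.5)

    def test_sideband_spacing_tracks_am_freq(self):
        for am_freq in (60.0, 130.0):
            w = nv.apply_am(_tone(500.0, rolloff=90.0), am_freq, 0.5)
            lo = peak_level_db(w, 500.0 - am_freq)
            mid_gap = peak_level_db(w, 500.0 - am_freq / 2, half_width=5.0)
            assert lo - mid_gap > 20  # sideband stands clear of the gap

    def test_episode_gating_leaves_outside_unchanged(self):
        w = _tone(dur=1.0)
        out = nv.apply_am(w, 100.0, 0.5, episodes=((0.4, 0.6),))
        n = w.samples.size
        np.testing.assert_array_equal(out.samples[: int(0.35 * n)], w.samples[: int(0.35 * n)])
        assert not np.allclose(out.samples[int(0.45 * n) : int(0.55 * n)],
                               w.samples[int(0.45 * n) : int(0.55 * n)])

    def test_am_freq_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            nv.apply_am(_tone(), 12000.0, 0.5)


class TestSubharmonics:
    def test_zero_depth_matches_plain_synthesis(self):
        f0 = np.full(22050, 220.0)
        plain = synth_harmonics(f0, 9.0, 22050)
        sub = nv.apply_subharmonics(f0, 9.0, 22050, 2, 0.0)
        assert np.max(np.abs(sub.samples - plain.samples)) <= 1e-12

    def test_period_doubling_peak_and_autocorrelation(self):
        """Ratio 2 at 220 Hz inserts a peak at 110 Hz; the period doubles."""
        f0 = np.full(22050, 220.0)
        w = nv.apply_subharmonics(f0, 9.0, 22050, 2, 0.5)
        assert peak_level_db(w, 110.0) - peak_level_db(w, 220.0) == pytest.approx(
            20 * np.log10(0.5), abs=0.5
        )
        x = w.samples - w.samples.mean()
        ac = np.correlate(x, x, "full")[x.size - 1 :]
        lo, hi = int(22050 / 150), int(22050 / 80)
        lag = lo + np.argmax(ac[lo:hi])
        assert lag == pytest.approx(22050 / 110, abs=2)

    def test_subharmonic_spacing_is_f0_over_ratio(self):
        f0 = np.full(22050, 300.0)
        w = nv.apply_subharmonics(f0, 9.0, 22050, 3, 0.5)
        for freq in (100.0, 200.0, 400.0):
            assert peak_level_db(w, freq) > peak_level_db(w, freq + 50, half_width=5) + 20

    def test_subharmonic_below_20hz_rejected(self):
        with pytest.raises(ValueError):
            nv.apply_subharmonics(np.full(1000, 35.0), 9.0, 22050, 2, 0.5)


class TestJitter:
    def test_zero_depth_is_identity(self, rng):
        f0 = np.full(10000, 220.0)
        out = nv.apply_jitter(f0, 0.0, 1000.0, 22050, rng)
        np.testing.assert_array_equal(out, f0)

    def test_semitone_bound_never_violated(self, rng):
        """Deviation stays within depth/2 semitones over 10^6 samples."""
        f0 = np.full(1_000_000, 220.0)
        out = nv.apply_jitter(f0, 4.0, 1000.0, 22050, rng)
        dev = np.abs(12.0 * np.log2(out / f0))
        assert dev.max() <= 2.0 + 1e-9

    def test_deviation_spread_grows_with_depth(self, rng):
        f0 = np.full(200_000, 220.0)
        spreads = []
        for depth in (1.0, 2.0, 4.0):
            out = nv.apply_jitter(f0, depth, 1000.0, 22050,
                                  np.random.default_rng(1))
            spreads.append(np.std(12 * np.log2(out / f0)))
        assert spreads[0] < spreads[1] < spreads[2]

    def test_negative_depth_rejected(self, rng):
        with pytest.raises(ValueError):
            nv.apply_jitter(np.full(100, 220.0), -1.0, 1000.0, 22050, rng)

    def test_hold_interpolation_available(self, rng):
        f0 = np.full(50_000, 220.0)
        out = nv.apply_jitter(f0, 2.0, 1000.0, 22050, rng, interp="hold")
        dev = 12 * np.log2(out / f0)
        assert np.abs(dev).max() <= 1.0 + 1e-9
        # held segments: many exact repeats
        assert np.mean(np.diff(dev) == 0) > 0.5


class TestFrequencyJump:
    def test_zero_magnitude_keeps_values(self):
        c = F0Contour(np.linspace(0, 1, 5), np.full(5, 220.0))
        out = nv.apply_frequency_jump(c, 0.5, 0.0, "up")
        f0_in, _ = interpolate_f0(c, 1000)
        f0_out, _ = interpolate_f0(out, 1000)
        np.testing.assert_allclose(f0_out, f0_in, rtol=1e-9)

    def test_octave_jump_doubles_post_jump_f0(self):
        c = F0Contour(np.linspace(0, 1, 5), np.full(5, 220.0))
        out = nv.apply_frequency_jump(c, 0.5, 12.0, "up")
        f0, _ = interpolate_f0(out, 1000)
        np.testing.assert_allclose(f0[:480], 220.0, rtol=1e-6)
        np.testing.assert_allclose(f0[520:], 440.0, rtol=1e-6)

    def test_discontinuity_not_smoothed(self):
        c = F0Contour(np.linspace(0, 1, 5), np.full(5, 200.0))
        out = nv.apply_frequency_jump(c, 0.5, 6.0, "down")
        f0, _ = interpolate_f0(out, 10000)
        ratios = f0[1:] / f0[:-1]
        assert ratios.min() == pytest.approx(2 ** (-6 / 12), rel=1e-3)

    def test_point_outside_unit_interval_rejected(self):
        c = F0Contour(np.linspace(0, 1, 3), np.full(3, 220.0))
        for point in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                nv.apply_frequency_jump(c, point, 6.0, "up")


class TestJumpPlanning:
    def _contour(self):
        return F0Contour(np.linspace(0, 3, 30), np.full(30, 200.0))

    def test_single_jump(self, rng):
        jumps = nv.plan_jumps_alternating(self._contour(), 1, (0.5, 12.0), rng)
        assert len(jumps) == 1
        assert jumps[0].direction in ("up", "down")

    def test_alternation_probability_at_least_080(self):
        rng = np.random.default_rng(0)
        alt = tot = 0
        for _ in range(300):
            jumps = nv.plan_jumps_alternating(self._contour(), 5, (0.5, 12.0), rng)
            for a, b in zip(jumps, jumps[1:]):
                alt += a.direction != b.direction
                tot += 1
        assert alt / tot >= 0.8

    def test_anti_drift_mean_cumulative_below_mean_single(self):
        """Alternation keeps |cumulative shift| below the mean |single jump|."""
        rng = np.random.default_rng(1)
        cums, singles = [], []
        for _ in range(1000):
            jumps = nv.plan_jumps_alternating(self._contour(), 5, (0.5, 12.0), rng)
            mags = [(j.magnitude if j.direction == "up" else -j.magnitude) for j in jumps]
            cums.append(abs(sum(mags)))
            singles.extend(abs(m) for m in mags)
        assert np.mean(cums) < np.mean(singles)

    def test_shifted_contour_stays_within_octave_band(self):
        rng = np.random.default_rng(2)
        c = self._contour()
        for _ in range(100):
            jumps = nv.plan_jumps_alternating(c, 6, (0.5, 12.0), rng)
            out = nv.apply_planned_jumps(c, jumps)
            assert out.values.min() >= c.values.min() / 2 - 1e-6
            assert out.values.max() <= c.values.max() * 2 + 1e-6

    def test_unvoiced_contour_rejected(self, rng):
        c = F0Contour(np.array([0.0, 1.0]), np.array([200.0, 200.0]),
                      np.array([False, False]))
        with pytest.raises(ValueError):
            nv.plan_jumps_alternating(c, 3, (0.5, 12.0), rng)


class TestEpisodes:
    def test_continuous_is_full_window(self, rng):
        assert nv.place_episodes(2.0, "continuous", rng) == ((0.0, 1.0),)

    def test_intermittent_windows_valid_and_covering(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            eps = nv.place_episodes(2.5, "intermittent", rng)
            assert 2 <= len(eps) <= 8
            prev = 0.0
            for a, b in eps:
                assert 0.0 <= a < b <= 1.0
                assert a >= prev - 1e-12
                prev = b
            coverage = sum(b - a for a, b in eps)
            assert 0.2 <= coverage <= 0.8

    def test_gate_ramps_and_plateau(self):
        gate = episode_gate(10000, ((0.2, 0.6),), 22050)
        assert gate[:2000].max() == 0.0      # silent before the episode
        assert gate[6001:].max() == 0.0      # silent after
        assert np.allclose(gate[2200:5800], 1.0)  # plateau between the ramps
        assert 0.0 < gate[2050] < 1.0        # raised-cosine edges
        assert 0.0 < gate[5950] < 1.0
        assert np.all((gate >= 0.0) & (gate <= 1.0))


class TestPitchShift:
    def test_identity_and_octave(self):
        c = F0Contour.constant(220.0, 1.0)
        assert np.array_equal(nv.apply_pitch_shift(c, 0.0).values, c.values)
        np.testing.assert_allclose(nv.apply_pitch_shift(c, 1.0).values, 440.0)

    def test_one_and_a_half_octaves(self):
        c = F0Contour.constant(200.0, 1.0)
        np.testing.assert_allclose(
            nv.apply_pitch_shift(c, 1.5).values, 200.0 * 2**1.5
        )
        assert nv.apply_pitch_shift(c, 1.5).values[0] == pytest.approx(565.685, abs=1e-3)

    def test_log_shape_preserved(self):
        c = F0Contour(np.linspace(0, 1, 4), np.array([180.0, 220, 260, 210]))
        out = nv.apply_pitch_shift(c, 1.0)
        np.testing.assert_allclose(
            np.diff(np.log(out.values)), np.diff(np.log(c.values)), rtol=1e-12
        )

    def test_excessive_shift_rejected(self):
        c = F0Contour.constant(880.0, 1.0)
        with pytest.raises(ValueError):
            nv.apply_pitch_shift(c, 2.0)


def test_zero_depth_identities_all_kinds(rng):
    """Every manipulation at zero depth/magnitude is the identity."""
    f0 = np.full(22050, 220.0)
    w = synth_harmonics(f0, 9.0, 22050)
    assert np.max(np.abs(nv.apply_am(w, 100.0, 0.0).samples - w.samples)) == 0.0
    assert np.max(np.abs(nv.apply_subharmonics(f0, 9.0, 22050, 2, 0.0).samples
                         - w.samples)) == 0.0
    np.testing.assert_array_equal(nv.apply_jitter(f0, 0.0, 1000.0, 22050, rng), f0)
    c = F0Contour.constant(220.0, 1.0)
    out = nv.apply_frequency_jump(c, 0.5, 0.0, "up")
    np.testing.assert_allclose(interpolate_f0(out, 22050)[0],
                               interpolate_f0(c, 22050)[0], rtol=1e-12)
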