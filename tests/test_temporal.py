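"""Temporal feature tests: windowing, wavelet transform, Gini sparsity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sozloc import synthetic as syn
from sozloc import temporal as tp


def _ts(x, tr=2.0):
    return tp.BoldTimecourse(samples=np.asarray(x, float), tr_seconds=tr)


class TestWindowing:
    def test_600_samples_give_two_windows(self):
        ws = tp.window_signal(_ts(np.arange(600.0)))
        assert len(ws) == 2
        assert all(len(w) == 256 for w in ws)

    def test_windows_are_mean_centered_and_consecutive(self):
        x = np.sin(np.linspace(0, 20, 600)) + 5.0
        ws = tp.window_signal(_ts(x))
        for k, w in enumerate(ws):
            assert abs(w.mean()) < 1e-12
            seg = x[k * 256 : (k + 1) * 256]
            np.testing.assert_allclose(w, seg - seg.mean())

    @pytest.mark.parametrize("n,expected", [(256, 1), (511, 1), (512, 2)])
    def test_window_count(self, n, expected):
        assert len(tp.window_signal(_ts(np.random.default_rng(0).normal(size=n)))) == expected

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            tp.window_signal(_ts(np.zeros(255)))


class TestActivelet:
    def test_four_levels_shift_invariant_lengths(self):
        w = np.random.default_rng(1).normal(size=256)
        coeffs = tp.activelet_coeffs(w)
        assert len(coeffs) == tp.ACTIVELET_LEVELS
        for ca, cd in coeffs:
            assert len(ca) == 256 and len(cd) == 256

    def test_linearity(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=256)
        c1 = tp.activelet_coeffs(w)
        c2 = tp.activelet_coeffs(3.5 * w)
        for (a1, d1), (a2, d2) in zip(c1, c2):
            np.testing.assert_allclose(3.5 * d1, d2, atol=1e-9)

    def test_zero_window_gives_zero_coefficients(self):
        for ca, cd in tp.activelet_coeffs(np.zeros(256)):
            assert np.all(ca == 0) and np.all(cd == 0)

    def test_round_trip_reconstruction(self):
        w = np.random.default_rng(3).normal(size=256)
        rec = tp.activelet_reconstruct(tp.activelet_coeffs(w))
        assert np.max(np.abs(rec - w)) < 1e-6 * max(1.0, np.max(np.abs(w)))


class TestSineDictionary:
    def test_in_band_bin_count_for_study_geometry(self):
        # 256 samples at TR 2 s, band 0.01-0.1 Hz -> bins k = 6..51
        mags = tp.sine_coeffs(np.zeros(256), tr_seconds=2.0)
        assert mags.size == 46

    def test_on_bin_tone_dominates(self):
        t = np.arange(256) * 2.0
        f = 25 / 512.0  # exactly on a Fourier bin, inside the band
        tone = np.sin(2 * np.pi * f * t)
        mags = tp.sine_coeffs(tone - tone.mean(), 2.0)
        order = np.sort(mags)
        assert order[-2] < 0.01 * order[-1]

    def test_out_of_band_tone_leaves_little_in_band_energy(self):
        t = np.arange(256) * 2.0
        tone = np.sin(2 * np.pi * 0.2 * t)
        mags = tp.sine_coeffs(tone - tone.mean(), 2.0)
        assert mags.max() < 0.01 * 128  # << half the window length (full tone)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            tp.sine_coeffs(np.zeros(256), 2.0, band=(0.01, 0.3))


class TestGini:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 1, 1, 1], 0.0),
            ([0, 0, 0, 5], 0.75),  # (n-1)/n
            ([1, 2, 3, 4], 0.25),
            ([0, 0, 0, 0], 0.0),  # all-zero convention
        ],
    )
    def test_reference_values(self, values, expected):
        assert tp.gini_index(np.array(values)) == pytest.approx(expected, abs=1e-12)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            tp.gini_index(np.array([1.0, -0.5]))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1e6, allow_nan=False), min_size=1, max_size=60),
        st.floats(1e-3, 1e3),
    )
    def test_matches_pairwise_difference_formula_and_is_scale_invariant(self, xs, c):
        x = np.asarray(xs)
        g = tp.gini_index(x)
        if x.sum() > 0:
            n = x.size
            pairwise = np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * x.mean())
            assert g == pytest.approx(pairwise, abs=1e-9)
            assert tp.gini_index(c * x) == pytest.approx(g, abs=1e-9)
        assert 0.0 <= g <= 1.0 - 1.0 / x.size + 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.random(50)
        assert tp.gini_index(x) == pytest.approx(
            tp.gini_index(rng.permutation(x)), abs=1e-12
        )


class TestSparsitySummary:
    def test_soz_spectra_sparser_than_rsn_paired(self):
        cfg = syn.SyntheticConfig(seed=0)
        rng = np.random.default_rng(12)
        wins = 0
        for _ in range(10):
            soz = syn.generate_timecourse("SOZ", rng, cfg)
            rsn = syn.generate_timecourse("RSN", rng, cfg)
            s = tp.sparsity_summary(soz)
            r = tp.sparsity_summary(rsn)
            wins += s.sine_gini > r.sine_gini
        assert wins == 10

    def test_two_identical_windows_equal_single_window_summary(self):
        w = np.random.default_rng(5).normal(size=256)
        double = tp.sparsity_summary(_ts(np.concatenate([w, w])))
        single = tp.sparsity_summary(_ts(w))
        assert double.n_windows == 2
        assert double.activelet_gini == pytest.approx(single.activelet_gini, abs=1e-12)
        assert double.sine_gini == pytest.approx(single.sine_gini, abs=1e-12)

    def test_degenerate_near_constant_input_does_not_crash(self):
        x = np.full(600, 7.0) + np.random.default_rng(6).normal(0, 1e-9, 600)
        s = tp.sparsity_summary(_ts(x))
        assert np.isfinite(s.sine_gini) and np.isfinite(s.activelet_gini)

    def test_dominant_frequency_is_in_band_diagnostic(self):
        cfg = syn.SyntheticConfig(seed=0)
        ts = syn.generate_timecourse("SOZ", np.random.default_rng(7), cfg)
        s = tp.sparsity_summary(ts)
        assert 0.01 <= s.dominant_frequency_hz <= 0.1
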