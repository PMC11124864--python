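"""Harmonic references, CCA scoring, and exact-frequency spectral features."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssvepchair.decode import (
    ReferenceSet,
    build_reference,
    cca_correlation,
    classify_by_cca,
    fft_features,
    single_freq_amplitude,
)
from ssvepchair.preprocess import EpochWindow, sliding_windows
from ssvepchair.simulate import LABEL_FREQS, TrialSpec, generate_trial

FS = 250.0


def _projection_r(x, ref_matrix):
    """Independent oracle: sqrt(R^2) of least-squares projection of the
    centered window onto the centered reference rows."""
    xc = x - x.mean()
    yc = (ref_matrix - ref_matrix.mean(axis=1, keepdims=True)).T
    beta, *_ = np.linalg.lstsq(yc, xc, rcond=None)
    fitted = yc @ beta
    return np.sqrt(np.sum(fitted**2) / np.sum(xc**2))


class TestBuildReference:
    def test_first_column_is_sin0_cos1(self):
        ref = build_reference(11.0, FS, 100)
        np.testing.assert_allclose(ref.matrix[0::2, 0], 0.0, atol=1e-15)
        np.testing.assert_allclose(ref.matrix[1::2, 0], 1.0, atol=1e-15)

    def test_shape_eight_by_250(self):
        ref = build_reference(10.0, FS, 250, n_harmonics=4)
        assert ref.matrix.shape == (8, 250)

    def test_rows_match_closed_form(self):
        ref = build_reference(12.0, FS, 250, n_harmonics=3)
        t = np.arange(250) / FS
        np.testing.assert_allclose(ref.matrix[2], np.sin(2 * np.pi * 24 * t),
                                   atol=1e-14)
        np.testing.assert_allclose(ref.matrix[5], np.cos(2 * np.pi * 36 * t),
                                   atol=1e-14)

    def test_full_period_orthogonality(self):
        # over complete cycles the sampled sin/cos rows are orthogonal with
        # squared norm n/2
        ref = build_reference(10.0, FS, 250, n_harmonics=4)
        gram = ref.matrix @ ref.matrix.T
        np.testing.assert_allclose(np.diag(gram), 125.0, atol=1e-8)
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_aliasing_rejected(self):
        with pytest.raises(ValueError, match="alias"):
            build_reference(15.0, 100.0, 100, n_harmonics=4)


class TestCcaCorrelation:
    def test_window_in_reference_span_scores_one(self, refs, tone_window):
        assert cca_correlation(tone_window(10.0), refs[10.0]) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_zero_window_scores_zero(self, refs, caplog):
        w = EpochWindow(np.zeros(250), FS, 0.0)
        with caplog.at_level("WARNING"):
            assert cca_correlation(w, refs[10.0]) == 0.0
        assert "zero-variance" in caplog.text

    def test_matches_projection_oracle_on_harmonic_mixture(self, refs):
        t = np.arange(250) / FS
        rng = np.random.default_rng(123)
        x = (0.8 * np.sin(2 * np.pi * 12 * t)
             + 0.6 * np.cos(2 * np.pi * 24 * t)
             + rng.standard_normal(250))
        w = EpochWindow(x, FS, 0.0)
        got = cca_correlation(w, refs[12.0])
        assert got == pytest.approx(_projection_r(x, refs[12.0].matrix), abs=1e-10)

    def test_length_mismatch_rejected(self, refs):
        with pytest.raises(ValueError, match="length"):
            cca_correlation(EpochWindow(np.zeros(100), FS, 0.0), refs[10.0])

    @given(
        a=st.floats(min_value=-5.0, max_value=5.0).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(min_value=-10.0, max_value=10.0),
        seed=st.integers(min_value=0, max_value=1000),
    )
    def test_affine_invariance(self, refs, a, b, seed):
        x = np.random.default_rng(seed).standard_normal(250)
        base = cca_correlation(EpochWindow(x, FS, 0.0), refs[7.5])
        scaled = cca_correlation(EpochWindow(a * x + b, FS, 0.0), refs[7.5])
        assert scaled == pytest.approx(base, abs=1e-9)

    @pytest.mark.parametrize("label", ["F7.5", "F10", "F12", "F15"])
    @pytest.mark.parametrize("window_s", [0.6, 0.8, 1.0, 1.5, 2.0])
    def test_true_class_dominates_noise_free(self, label, window_s,
                                             noise_free_trials):
        n = round(window_s * FS)
        refs = ReferenceSet.for_frequencies(n_samples=n)
        w = sliding_windows(noise_free_trials[label], window_s=window_s)[0]
        corrs = {f: cca_correlation(w, refs[f]) for f in refs}
        true_f = LABEL_FREQS[label]
        assert all(corrs[true_f] > c for f, c in corrs.items() if f != true_f)


class TestFftFeatures:
    def test_on_grid_tone(self, tone_window):
        amps = fft_features(tone_window(10.0)).fft_amps
        assert amps[1] == pytest.approx(1.0, abs=1e-12)  # 10 Hz
        assert amps[2] < 1e-12 and amps[3] < 1e-12  # 12, 15 Hz

    def test_off_grid_7_5hz_matches_naive_dft_oracle(self, tone_window):
        w = tone_window(7.5)
        got = fft_features(w).fft_amps[0]
        # oracle: naive correlation sums against quadrature sinusoids
        t = np.arange(250) / FS
        c = np.sum(w.samples * np.cos(2 * np.pi * 7.5 * t))
        s = np.sum(w.samples * np.sin(2 * np.pi * 7.5 * t))
        expected = 2 / 250 * np.hypot(c, s)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_zero_window_zero_features(self):
        amps = fft_features(EpochWindow(np.zeros(250), FS, 0.0)).fft_amps
        assert np.all(amps == 0)

    def test_target_at_nyquist_rejected(self, tone_window):
        with pytest.raises(ValueError, match="Nyquist"):
            fft_features(tone_window(10.0), target_freqs=(7.5, 10.0, 12.0, 125.0))

    @given(seed=st.integers(min_value=0, max_value=500),
           bin_idx=st.integers(min_value=1, max_value=124))
    def test_on_grid_equals_scaled_fft_coefficient(self, seed, bin_idx):
        # at integer-cycle frequencies the estimate must equal 2/n * |FFT bin|
        x = np.random.default_rng(seed).standard_normal(250)
        got = single_freq_amplitude(x, float(bin_idx), FS)
        expected = 2 / 250 * np.abs(np.fft.rfft(x)[bin_idx])
        assert got == pytest.approx(expected, rel=1e-9)


class TestClassifyByCca:
    def test_noise_free_trial_decoded(self, refs, noise_free_trials):
        w = sliding_windows(noise_free_trials["F12"])[0]
        assert classify_by_cca(w, refs, rest_threshold=0.5) == "F12"

    def test_rest_noise_windows_mostly_rest(self, refs):
        hits = 0
        for seed in range(100):
            rec = generate_trial(
                TrialSpec(label="REST", duration_s=1.0, powerline_amp=0.0,
                          seed=seed)
            )
            w = EpochWindow(rec.samples, FS, 0.0)
            if classify_by_cca(w, refs, rest_threshold=0.5) == "REST":
                hits += 1
        assert hits >= 90

    def test_tie_breaks_to_lowest_frequency(self, refs):
        # equal-power mixture of two reference-span tones ties exactly
        t = np.arange(250) / FS
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 12 * t)
        w = EpochWindow(x, FS, 0.0)
        corr_10 = cca_correlation(w, refs[10.0])
        corr_12 = cca_correlation(w, refs[12.0])
        assert corr_10 == pytest.approx(corr_12, abs=1e-9)
        assert classify_by_cca(w, refs, rest_threshold=0.0) == "F10"
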