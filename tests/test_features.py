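"""Feature oracles (brute-force sample entropy, closed forms), invariance
properties, and feature-matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emotqwt.features import (
    DegenerateSignalError,
    FeatureMatrix,
    TQWTFeatureExtractor,
    extract_features,
    fuse,
    hjorth_complexity,
    hjorth_mobility,
    norm_second_diff_mean,
    sample_entropy,
    second_diff_mean,
)
from emotqwt.io import EEGRecording
from emotqwt.tqwt import TQWTParams, tqwt_decompose


def sampen_bruteforce(x, m=2, u=None):
    """O(N^2) direct template-pair enumeration (independent oracle)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if u is None:
        u = 0.2 * np.std(x)
    nt = n - m

    def pairs(mm):
        c = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                if np.max(np.abs(x[i : i + mm] - x[j : j + mm])) <= u:
                    c += 1
        return c

    b = pairs(m)
    a = pairs(m + 1)
    return -np.log(a / b)


class TestSampleEntropy:
    def test_periodic_sequence_matches_bruteforce(self):
        x = np.array([1, 2, 3, 1, 2, 3, 1, 2, 3, 1], dtype=float)
        assert sample_entropy(x) == pytest.approx(sampen_bruteforce(x))

    def test_random_sequences_match_bruteforce(self, rng):
        for _ in range(10):
            x = rng.standard_normal(60)
            assert sample_entropy(x) == pytest.approx(sampen_bruteforce(x))

    def test_huge_tolerance_gives_zero(self, rng):
        x = rng.standard_normal(50)
        u = np.ptp(x) + 1.0  # exceeds every pairwise distance
        assert sample_entropy(x, u=u) == 0.0

    def test_nonnegative(self, rng):
        """A <= B by embedding nesting, so SampEn >= 0."""
        for _ in range(10):
            assert sample_entropy(rng.standard_normal(80)) >= 0.0

    def test_constant_signal_convention(self):
        with pytest.warns(UserWarning, match="constant"):
            assert sample_entropy(np.ones(50)) == 0.0

    def test_no_m1_matches_is_inf(self):
        # (0,0) templates match at i=0 and i=3 but their (m+1) extensions
        # (0,0,1) vs (0,0,2) differ beyond tolerance: B > 0, A = 0
        x = np.array([0, 0, 1, 0, 0, 2.0, 5, 9, 3, 7])
        with pytest.warns(UserWarning, match="inf"):
            v = sample_entropy(x, u=0.1)
        assert np.isinf(v)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.zeros(3), m=2)


class TestDifferenceFeatures:
    def test_ramp(self):
        assert second_diff_mean(np.arange(10.0)) == pytest.approx(2.0)

    def test_constant(self):
        assert second_diff_mean(np.full(10, 3.3)) == 0.0

    def test_telescoping_closed_form(self, rng):
        x = rng.standard_normal(100)
        n = len(x)
        expected = (x[-1] + x[-2] - x[1] - x[0]) / (n - 2)
        assert second_diff_mean(x) == pytest.approx(expected)

    def test_signed_not_absolute(self):
        x = np.array([0.0, 0, 1, 0, 0, 1])  # lag-2 diffs: 1, 0, -1, 1
        assert second_diff_mean(x) == pytest.approx(0.25)
        assert second_diff_mean(x, absolute=True) == pytest.approx(0.75)

    def test_normalized_ramp(self):
        x = np.arange(10.0)
        assert norm_second_diff_mean(x) == pytest.approx(2.0 / np.std(x))

    def test_normalized_scale_invariance(self, rng):
        x = rng.standard_normal(50)
        assert norm_second_diff_mean(5 * x) == pytest.approx(
            norm_second_diff_mean(x)
        )

    def test_normalized_constant_rejected(self):
        with pytest.raises(DegenerateSignalError):
            norm_second_diff_mean(np.ones(10))


class TestHjorth:
    def test_mobility_sinusoid_closed_form(self):
        w0 = 0.1
        x = np.sin(w0 * np.arange(10_000))
        assert hjorth_mobility(x) == pytest.approx(2 * np.sin(w0 / 2), rel=0.02)

    def test_mobility_white_noise(self, rng):
        x = rng.standard_normal(10_000)
        assert hjorth_mobility(x) == pytest.approx(np.sqrt(2), rel=0.05)

    def test_mobility_scale_invariance(self, rng):
        x = rng.standard_normal(100)
        assert hjorth_mobility(3.5 * x) == pytest.approx(hjorth_mobility(x))

    def test_complexity_sinusoid_is_one(self):
        x = np.sin(0.2 * np.arange(10_000))
        assert hjorth_complexity(x) == pytest.approx(1.0, rel=0.02)

    def test_complexity_composition_oracle(self, rng):
        x = rng.standard_normal(500)
        d = np.diff(x)
        expected = hjorth_mobility(d) / hjorth_mobility(x)
        assert hjorth_complexity(x) == pytest.approx(expected)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateSignalError):
            hjorth_mobility(np.zeros(10))
        with pytest.raises(DegenerateSignalError):
            hjorth_complexity(np.arange(10.0))  # first difference constant


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(min_value=0, max_value=2**16),
    shift=st.floats(min_value=-50, max_value=50),
    scale=st.floats(min_value=0.1, max_value=100),
)
def test_shift_and_scale_invariance(seed, shift, scale):
    """2dif is shift-invariant exactly; 2ndif, HM, HC and SampEn (relative
    tolerance) are scale-invariant."""
    x = np.random.default_rng(seed).standard_normal(80)
    assert second_diff_mean(x + shift) == pytest.approx(second_diff_mean(x))
    for f in (norm_second_diff_mean, hjorth_mobility, hjorth_complexity):
        assert f(scale * x) == pytest.approx(f(x + shift if f is None else x))
        assert f(x + shift) == pytest.approx(f(x))
    assert sample_entropy(scale * x) == pytest.approx(sample_entropy(x))


class TestExtraction:
    def _tiny_recording(self, rng, n_trials=2, n_channels=2, n=512):
        data = rng.standard_normal((n_trials, n_channels, n))
        return EEGRecording("t01", data, channel_names=["A", "B"][:n_channels])

    def test_column_count(self, rng):
        rec = self._tiny_recording(rng)
        mats = extract_features(rec, TQWTParams(3, 3, 4))
        for mat in mats.values():
            assert mat.shape == (2, 5 * 2)
            assert len(set(mat.column_index)) == 10

    def test_zero_recording_degenerate_conventions(self):
        rec = EEGRecording("z", np.zeros((1, 2, 256)), channel_names=["A", "B"])
        mats = extract_features(rec, TQWTParams(3, 3, 2))
        for f in ("SampEn", "2dif"):
            assert np.all(mats[f].values == 0.0)

    def test_compositional_equivalence(self, rng):
        """Matrix cells equal direct scalar calls on each sub-band."""
        rec = self._tiny_recording(rng, n_trials=2, n_channels=2, n=512)
        p = TQWTParams(3, 3, 2)
        mats = extract_features(rec, p)
        scalar = {
            "SampEn": sample_entropy,
            "2dif": second_diff_mean,
            "2ndif": norm_second_diff_mean,
            "HM": hjorth_mobility,
            "HC": hjorth_complexity,
        }
        for t in range(2):
            for c in range(2):
                bands = tqwt_decompose(rec.data[t, c], p).subbands
                for sb, band in enumerate(bands):
                    col = sb * 2 + c
                    for f, op in scalar.items():
                        assert mats[f].values[t, col] == pytest.approx(op(band))

    def test_deterministic_across_runs(self, rng):
        rec = self._tiny_recording(rng)
        a = extract_features(rec, TQWTParams(3, 3, 3))
        b = extract_features(rec, TQWTParams(3, 3, 3))
        for f in a:
            np.testing.assert_array_equal(a[f].values, b[f].values)

    def test_transformer_sklearn_surface(self, rng):
        from sklearn.base import clone

        est = TQWTFeatureExtractor(J=2, features=("HM", "2dif"))
        est2 = clone(est)
        X = rng.standard_normal((3, 2, 256))
        out = est2.fit(X).transform(X)
        assert out.shape == (3, 2 * 3 * 2)  # feats * subbands * channels
        assert est2.get_params()["J"] == 2


class TestFusion:
    def _matrix(self, subject, n_trials=4, n_ch=3, n_sb=2, seed=0):
        rng = np.random.default_rng(seed)
        cols = [(sb + 1, f"c{c}") for sb in range(n_sb) for c in range(n_ch)]
        rows = [(subject, t) for t in range(n_trials)]
        return FeatureMatrix(
            rng.standard_normal((n_trials, n_sb * n_ch)), "HM", cols, rows
        )

    def test_per_subject_mode(self):
        m = self._matrix("s01")
        assert fuse([m], "per_subject_subband_fused") is m

    def test_all_fused_shape(self):
        mats = [self._matrix(f"s{i}", seed=i) for i in range(4)]
        fused = fuse(mats, "all_fused")
        assert fused.shape == (16, 6)
        assert fused.row_index[0] == ("s0", 0)

    def test_per_subband_shape(self):
        mats = [self._matrix(f"s{i}", seed=i) for i in range(4)]
        fused = fuse(mats, "per_subband_subject_fused", subband=2)
        assert fused.shape == (16, 3)
        assert all(sb == 2 for sb, _ in fused.column_index)

    def test_row_collision_rejected(self):
        m = self._matrix("s01")
        with pytest.raises(ValueError, match="collision"):
            fuse([m, m], "all_fused")

    def test_reference_cohort_shapes(self):
        """32 subjects x 40 trials x (5 sub-bands x 32 channels) fuse to
        the canonical 40x160 / 1280x32 / 1280x160 layouts."""
        mats = [
            FeatureMatrix(
                np.zeros((40, 160)),
                "HM",
                [(sb + 1, f"c{c}") for sb in range(5) for c in range(32)],
                [(f"s{i:02d}", t) for t in range(40)],
            )
            for i in range(32)
        ]
        assert fuse([mats[0]], "per_subject_subband_fused").shape == (40, 160)
        assert fuse(mats, "per_subband_subject_fused", subband=1).shape == (1280, 32)
        assert fuse(mats, "all_fused").shape == (1280, 160)
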