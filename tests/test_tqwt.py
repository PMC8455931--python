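"""Filter-bank correctness: scaling factors, stage responses, perfect
reconstruction, energy conservation, stage-depth bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emotqwt.tqwt import (
    StageDepthError,
    SubbandSet,
    TQWTParams,
    max_stages,
    scaling_factors,
    stage_frequency_responses,
    stage_lengths,
    tqwt_decompose,
    tqwt_reconstruct,
)


class TestScalingFactors:
    @pytest.mark.parametrize(
        "Q, r, l, h",
        [
            (3, 3, 5 / 6, 0.5),
            (1, 3, 2 / 3, 1.0),
            (5, 3, 8 / 9, 1 / 3),
        ],
    )
    def test_values(self, Q, r, l, h):
        got_l, got_h = scaling_factors(Q, r)
        assert got_h == pytest.approx(h)
        assert got_l == pytest.approx(l)
        assert got_l + got_h > 1  # oversampled bank

    @pytest.mark.parametrize("Q, r", [(0.5, 3), (3, 1), (3, 0.5), (0, 3)])
    def test_invalid_parameters(self, Q, r):
        with pytest.raises(ValueError):
            scaling_factors(Q, r)

    def test_params_expose_factors(self):
        p = TQWTParams(3, 3, 4)
        assert (p.l, p.h) == scaling_factors(3, 3)


class TestStageResponses:
    def test_lowpass_support_bound(self):
        p = TQWTParams(3, 3, 1)
        H0, _ = stage_frequency_responses(p, 256)
        w = 2 * np.pi * np.fft.fftfreq(256)
        assert np.all(H0[np.abs(w) > p.l * np.pi] == 0)

    def test_dc_preserved(self):
        for Q, J in [(1, 2), (3, 4), (5, 3)]:
            H0, _ = stage_frequency_responses(TQWTParams(Q, 3, J), 512)
            assert H0[0] == pytest.approx(1.0)

    def test_highpass_edges_shrink_geometrically(self):
        p = TQWTParams(3, 3, 4)
        _, highs = stage_frequency_responses(p, 4096)
        w = np.abs(2 * np.pi * np.fft.fftfreq(4096))
        uppers = [w[h > 1e-12].max() for h in highs]
        for j in range(1, len(uppers)):
            assert uppers[j] / uppers[j - 1] == pytest.approx(p.l, rel=0.01)
        # sub-band j supported within [(1-h) l^(j-1) pi, l^(j-1) pi]
        for j, hj in enumerate(highs, start=1):
            lo = (1 - p.h) * p.l ** (j - 1) * np.pi
            hi = p.l ** (j - 1) * np.pi
            assert np.all(hj[(w < lo - 1e-9) | (w > hi + 1e-9)] == 0)

    def test_bank_is_power_complementary(self):
        p = TQWTParams(2, 3, 3)
        H0, highs = stage_frequency_responses(p, 1024)
        total = H0**2 + sum(h**2 for h in highs)
        assert np.allclose(total, 1.0, atol=1e-12)


class TestMaxStages:
    def test_reference_setting_feasible(self):
        assert max_stages(TQWTParams(3, 3, 1), 8064) >= 4

    def test_monotone_in_length(self):
        p = TQWTParams(3, 3, 1)
        for n in [64, 128, 256, 1024, 8064]:
            assert max_stages(p, 2 * n) >= max_stages(p, n)

    @pytest.mark.parametrize("Q, n", [(1, 64), (3, 128), (5, 256)])
    def test_boundary_probe(self, Q, n, rng):
        """Decomposition succeeds exactly up to max_stages."""
        jmax = max_stages(TQWTParams(Q, 3, 1), n)
        x = rng.standard_normal(n)
        tqwt_decompose(x, TQWTParams(Q, 3, jmax))
        with pytest.raises(StageDepthError):
            tqwt_decompose(x, TQWTParams(Q, 3, jmax + 1))


class TestDecomposeReconstruct:
    def test_subband_count_reference_setting(self, rng):
        s = tqwt_decompose(rng.standard_normal(8064), TQWTParams(3, 3, 4))
        assert len(s) == 5

    def test_zero_signal(self):
        s = tqwt_decompose(np.zeros(512), TQWTParams(3, 3, 3))
        assert all(np.all(b == 0) for b in s.subbands)
        assert np.all(tqwt_reconstruct(s) == 0)

    def test_nonfinite_rejected(self):
        x = np.zeros(256)
        x[10] = np.nan
        with pytest.raises(ValueError):
            tqwt_decompose(x, TQWTParams(3, 3, 2))

    def test_roundtrip_random_signal(self, rng):
        x = rng.standard_normal(1024)
        s = tqwt_decompose(x, TQWTParams(3, 3, 4))
        err = np.linalg.norm(tqwt_reconstruct(s) - x) / np.linalg.norm(x)
        assert err < 1e-8

    def test_roundtrip_odd_length(self, rng):
        x = rng.standard_normal(501)
        xr = tqwt_reconstruct(tqwt_decompose(x, TQWTParams(2, 3, 3)))
        assert xr.shape == x.shape
        assert np.linalg.norm(xr - x) / np.linalg.norm(x) < 1e-8

    def test_synthesis_superposition(self, rng):
        """Summing single-band reconstructions recovers the signal."""
        x = rng.standard_normal(1024)
        p = TQWTParams(3, 3, 3)
        s = tqwt_decompose(x, p)
        total = np.zeros_like(x)
        for k in range(len(s)):
            bands = [b if i == k else np.zeros_like(b)
                     for i, b in enumerate(s.subbands)]
            total += tqwt_reconstruct(SubbandSet(bands, p, s.original_length))
        assert np.linalg.norm(total - x) / np.linalg.norm(x) < 1e-8

    def test_energy_conservation_white_noise(self, rng):
        x = rng.standard_normal(2048)
        s = tqwt_decompose(x, TQWTParams(3, 3, 4))
        assert sum(s.energies) == pytest.approx(np.sum(x * x), rel=1e-8)

    def test_stage_length_recursion_and_redundancy_bound(self, rng):
        p = TQWTParams(3, 3, 4)
        n = 8064
        s = tqwt_decompose(rng.standard_normal(n), p)
        chain = stage_lengths(n, p)
        for (n_in, n0, n1), band in zip(chain, s.subbands):
            assert len(band) == n1 == 2 * round(p.h * n_in / 2)
            assert n0 == 2 * round(p.l * n_in / 2)
        assert len(s.subbands[-1]) == chain[-1][1]
        # total coefficient count is bounded by the asymptotic redundancy r*N
        assert sum(len(b) for b in s.subbands) <= p.r * n

    def test_inconsistent_subband_lengths_rejected(self, rng):
        s = tqwt_decompose(rng.standard_normal(512), TQWTParams(3, 3, 2))
        s.subbands[0] = s.subbands[0][:-2]
        with pytest.raises(ValueError):
            tqwt_reconstruct(s)

    def test_even_shift_changes_energies_little(self, rng):
        """Near shift-invariance: even-shift energy change below 1%."""
        x = rng.standard_normal(4096)
        p = TQWTParams(3, 3, 4)
        e0 = tqwt_decompose(x, p).energies
        e1 = tqwt_decompose(np.roll(x, 16), p).energies
        assert np.all(np.abs(e1 - e0) / e0 < 0.01)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    Q=st.integers(min_value=1, max_value=5),
    J=st.integers(min_value=1, max_value=6),
    n=st.integers(min_value=300, max_value=1200),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_perfect_reconstruction_property(Q, J, n, seed):
    """Decompose-reconstruct is the identity for any feasible (Q, J, n)."""
    p = TQWTParams(Q, 3, J)
    if J > max_stages(p, n):
        return
    x = np.random.default_rng(seed).standard_normal(n)
    err = np.linalg.norm(tqwt_reconstruct(tqwt_decompose(x, p)) - x)
    assert err / np.linalg.norm(x) < 1e-8
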