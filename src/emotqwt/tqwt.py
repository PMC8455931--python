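"""Tunable-Q wavelet transform (TQWT).

The TQWT is an oversampled two-channel iterated filter bank with three free
parameters: the quality factor ``Q`` (center frequency over bandwidth of the
wavelet atoms), the redundancy ``r`` (total oversampling rate of the bank),
and the number of stages ``J``.  Each stage splits its input into a low-pass
part (fed to the next stage) and a high-pass part (emitted as a sub-band);
after ``J`` stages the transform yields ``J + 1`` sub-bands: the ``J``
high-pass outputs plus the final low-pass residue.

The per-stage frequency-scaling factors derive from (Q, r)::

    h = 2 / (Q + 1)        # high-pass scaling
    l = 1 - h / r          # low-pass scaling

The filters are realized directly in the DFT domain with even sub-band
lengths ``N0 = 2 round(l N / 2)`` and ``N1 = 2 round(h N / 2)`` and the
two-vanishing-moment Daubechies transition function
``theta(w) = 0.5 (1 + cos w) sqrt(2 - cos w)``, which makes the low/high
pair power complementary.  Sub-band spectra are scaled by ``sqrt(N_sub/N)``
so the bank is a Parseval frame: sub-band energies sum to the signal energy
and reconstruction is exact to floating-point round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.fft import fft, ifft

__all__ = [
    "TQWTParams",
    "SubbandSet",
    "scaling_factors",
    "max_stages",
    "stage_lengths",
    "stage_frequency_responses",
    "tqwt_decompose",
    "tqwt_reconstruct",
]


class StageDepthError(ValueError):
    """Requested decomposition depth J exceeds what the signal length allows."""


def scaling_factors(Q: float, r: float) -> tuple[float, float]:
    """Return the per-stage scaling factors ``(l, h)`` for quality factor
    ``Q`` and redundancy ``r``.

    ``h = 2/(Q+1)`` is the high-pass scaling factor and ``l = 1 - h/r`` the
    low-pass scaling factor; ``l + h > 1`` whenever ``r > 1`` (oversampled
    bank).
    """
    if Q < 1:
        raise ValueError(f"Q must be >= 1, got {Q}")
    if r <= 1:
        raise ValueError(f"r must be > 1, got {r}")
    h = 2.0 / (Q + 1.0)
    l = 1.0 - h / r
    return l, h


@dataclass(frozen=True)
class TQWTParams:
    """Transform parameters (Q, r, J) with the derived scaling factors.

    Attributes
    ----------
    Q : quality factor, dimensionless, >= 1.  Higher Q gives more
        oscillatory, narrower-band atoms.
    r : redundancy (total oversampling rate), > 1; 3 is the customary value.
    J : number of filter-bank stages, >= 1; yields J + 1 sub-bands.
    """

    Q: float = 3.0
    r: float = 3.0
    J: int = 4

    def __post_init__(self) -> None:
        scaling_factors(self.Q, self.r)  # validates Q, r
        if int(self.J) != self.J or self.J < 1:
            raise ValueError(f"J must be a positive integer, got {self.J}")
        object.__setattr__(self, "J", int(self.J))

    @property
    def l(self) -> float:
        return scaling_factors(self.Q, self.r)[0]

    @property
    def h(self) -> float:
        return scaling_factors(self.Q, self.r)[1]


@dataclass
class SubbandSet:
    """The J+1 sub-band coefficient sequences for one signal.

    ``subbands[0:J]`` are the high-pass outputs of stages 1..J (descending
    center frequency); ``subbands[J]`` is the final low-pass output.
    ``original_length`` records the pre-padding input length so odd-length
    signals round-trip exactly.
    """

    subbands: list[np.ndarray]
    params: TQWTParams
    original_length: int

    def __len__(self) -> int:
        return len(self.subbands)

    @property
    def energies(self) -> np.ndarray:
        return np.array([float(np.sum(b * b)) for b in self.subbands])


def _even(x: float) -> int:
    return 2 * int(round(x / 2.0))


def _stage_dims(N: int, l: float, h: float) -> tuple[int, int, int, int, int]:
    """Sub-band lengths and DFT-bin band sizes (N0, N1, P, T, S) for one
    stage acting on an even-length-N spectrum."""
    N0 = _even(l * N)
    N1 = _even(h * N)
    P = (N - N1) // 2          # pure pass-band bins of the low-pass
    T = (N0 + N1 - N) // 2 - 1  # transition-band bins
    S = (N - N0) // 2          # pure pass-band bins of the high-pass
    return N0, N1, P, T, S


def _stage_feasible(N: int, l: float, h: float) -> bool:
    N0, N1, P, T, S = _stage_dims(N, l, h)
    return N0 >= 4 and N1 >= 4 and T >= 0 and P >= 0


def stage_lengths(N: int, params: TQWTParams) -> list[tuple[int, int, int]]:
    """Per-stage (input length, low-pass length, high-pass length) chain for
    an even input length ``N``."""
    l, h = scaling_factors(params.Q, params.r)
    chain = []
    n = N
    for j in range(params.J):
        if not _stage_feasible(n, l, h):
            raise StageDepthError(
                f"stage {j + 1} infeasible for length {N}: "
                f"max_stages = {max_stages(params, N)}"
            )
        N0, N1, *_ = _stage_dims(n, l, h)
        chain.append((n, N0, N1))
        n = N0
    return chain

def max_stages(params: TQWTParams, N: int) -> int:
    """Largest feasible J for an (even) signal length N: every stage's
    sub-band lengths must stay large enough to carry a transition band.
    Monotone non-decreasing in N."""
    if N % 2:
        N += 1
    l, h = scaling_factors(params.Q, params.r)
    j, n = 0, N
    while _stage_feasible(n, l, h):
        n = _stage_dims(n, l, h)[0]
        j += 1
    return j


def _transition(T: int) -> tuple[np.ndarray, np.ndarray]:
    """Sampled transition-band gains (low-pass, high-pass) on T interior
    bins; power complementary: g0^2 + g1^2 = 1."""
    v = np.arange(1, T + 1) * np.pi / (T + 1)
    c = np.cos(v)
    g0 = 0.5 * (1.0 + c) * np.sqrt(2.0 - c)
    g1 = 0.5 * (1.0 - c) * np.sqrt(2.0 + c)
    return g0, g1


def _afb(X: np.ndarray, l: float, h: float) -> tuple[np.ndarray, np.ndarray]:
    """One analysis stage in the DFT domain: split spectrum X (even length)
    into low-pass V0 and high-pass V1 spectra of even lengths N0, N1."""
    N = len(X)
    N0, N1, P, T, S = _stage_dims(N, l, h)
    g0, g1 = _transition(T)

    V0 = np.zeros(N0, dtype=complex)
    V0[0] = X[0]
    V0[1 : P + 1] = X[1 : P + 1]
    V0[P + 1 : P + T + 1] = X[P + 1 : P + T + 1] * g0
    # Nyquist bin of V0 (index N0/2 = P+T+1) falls in the stop band: stays 0.
    k = np.arange(1, P + T + 1)
    V0[N0 - k] = X[N - k] * np.concatenate([np.ones(P), g0])[k - 1]

    V1 = np.zeros(N1, dtype=complex)
    V1[1 : T + 1] = X[P + 1 : P + T + 1] * g1
    V1[T + 1 : T + S + 1] = X[P + T + 1 : P + T + S + 1]
    V1[N1 // 2] = X[N // 2]
    k = np.arange(1, T + S + 1)
    V1[N1 - k] = X[N - P - k] * np.concatenate([g1, np.ones(S)])[k - 1]

    # unitary-energy scaling: makes the iterated bank a Parseval frame
    V0 *= np.sqrt(N0 / N)
    V1 *= np.sqrt(N1 / N)
    return V0, V1


def _sfb(V0: np.ndarray, V1: np.ndarray, N: int, l: float, h: float) -> np.ndarray:
    """One synthesis stage: exact inverse of :func:`_afb`."""
    N0, N1, P, T, S = _stage_dims(N, l, h)
    if len(V0) != N0 or len(V1) != N1:
        raise ValueError(
            f"inconsistent sub-band lengths: expected ({N0}, {N1}), "
            f"got ({len(V0)}, {len(V1)})"
        )
    g0, g1 = _transition(T)
    W0 = V0 / np.sqrt(N0 / N)
    W1 = V1 / np.sqrt(N1 / N)

    Y = np.zeros(N, dtype=complex)
    Y[0] = W0[0]
    Y[1 : P + 1] = W0[1 : P + 1]
    Y[P + 1 : P + T + 1] = W0[P + 1 : P + T + 1] * g0 + W1[1 : T + 1] * g1
    Y[P + T + 1 : P + T + S + 1] = W1[T + 1 : T + S + 1]
    Y[N // 2] = W1[N1 // 2]
    k = np.arange(1, P + T + 1)
    Y[N - k] = W0[N0 - k] * np.concatenate([np.ones(P), g0])[k - 1]
    k = np.arange(1, T + S + 1)
    Y[N - P - k] += W1[N1 - k] * np.concatenate([g1, np.ones(S)])[k - 1]
    # transition bins receive contributions from both branches; the slice
    # assignments above are disjoint except on those mirrored bins, handled
    # by the += on the high-pass mirror.
    return Y


def tqwt_decompose(signal: np.ndarray, params: TQWTParams) -> SubbandSet:
    """Decompose a 1-D signal into ``J + 1`` sub-bands.

    Odd-length inputs are zero-padded by one sample (recorded and stripped
    on reconstruction).  Raises :class:`StageDepthError` when ``params.J``
    exceeds :func:`max_stages` for the signal length.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    n_orig = len(x)
    if n_orig % 2:
        x = np.concatenate([x, [0.0]])
    N = len(x)
    jmax = max_stages(params, N)
    if params.J > jmax:
        raise StageDepthError(
            f"J={params.J} too deep for length {n_orig}: max_stages={jmax}"
        )
    l, h = scaling_factors(params.Q, params.r)

    subbands: list[np.ndarray] = []
    X = fft(x)
    for _ in range(params.J):
        V0, V1 = _afb(X, l, h)
        subbands.append(ifft(V1).real)
        X = V0
    subbands.append(ifft(X).real)
    return SubbandSet(subbands=subbands, params=params, original_length=n_orig)


def tqwt_reconstruct(subbands: SubbandSet) -> np.ndarray:
    """Invert :func:`tqwt_decompose`; exact up to floating-point round-off."""
    params = subbands.params
    if len(subbands.subbands) != params.J + 1:
        raise ValueError(
            f"expected {params.J + 1} sub-bands, got {len(subbands.subbands)}"
        )
    n_orig = subbands.original_length
    N = n_orig + (n_orig % 2)
    chain = stage_lengths(N, params)
    for (n_in, N0, N1), band in zip(chain, subbands.subbands):
        if len(band) != N1:
            raise ValueError(
                f"sub-band length {len(band)} inconsistent with expected {N1}"
            )
    if len(subbands.subbands[-1]) != chain[-1][1]:
        raise ValueError("final low-pass sub-band has inconsistent length")

    l, h = scaling_factors(params.Q, params.r)
    V = fft(subbands.subbands[-1])
    for (n_in, N0, N1), band in zip(reversed(chain), reversed(subbands.subbands[:-1])):
        V = _sfb(V, fft(band), n_in, l, h)
    x = ifft(V).real
    return x[:n_orig]


def stage_frequency_responses(
    params: TQWTParams, N: int
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Equivalent frequency responses of the iterated bank on the N-point
    DFT grid.

    Returns ``(H0J, [H11, ..., H1J])`` where ``H0J`` is the depth-J low-pass
    response (product of the scaled single-stage low-pass responses) and
    ``H1j`` the response feeding sub-band j.  ``H0J`` is supported on
    ``|w| <= l^J pi`` and ``H1j`` on ``(1-h) l^(j-1) pi <= |w| <= l^(j-1) pi``.
    """
    if N % 2:
        raise ValueError("N must be even")
    if params.J > max_stages(params, N):
        raise StageDepthError(f"J={params.J} too deep for N={N}")
    l, h = scaling_factors(params.Q, params.r)
    w = 2.0 * np.pi * np.fft.fftfreq(N)  # in (-pi, pi]

    def h0(w_: np.ndarray) -> np.ndarray:
        aw = np.abs(w_)
        out = np.zeros_like(aw)
        out[aw <= (1 - h) * np.pi] = 1.0
        mid = (aw > (1 - h) * np.pi) & (aw < l * np.pi)
        u = (aw[mid] + (h - 1) * np.pi) / (l + h - 1)
        out[mid] = 0.5 * (1 + np.cos(u)) * np.sqrt(2 - np.cos(u))
        return out

    def h1(w_: np.ndarray) -> np.ndarray:
        aw = np.abs(w_)
        out = np.zeros_like(aw)
        out[(aw >= l * np.pi) & (aw <= np.pi)] = 1.0
        mid = (aw > (1 - h) * np.pi) & (aw < l * np.pi)
        u = np.pi - (aw[mid] + (h - 1) * np.pi) / (l + h - 1)
        out[mid] = 0.5 * (1 + np.cos(u)) * np.sqrt(2 - np.cos(u))
        return out

    low = np.ones(N)
    highs: list[np.ndarray] = []
    for j in range(1, params.J + 1):
        scale = l ** (j - 1)
        hp = h1(w / scale) * low
        hp[np.abs(w) > scale * np.pi] = 0.0
        highs.append(hp)
        low = low * h0(w / scale)
        low[np.abs(w) > l ** j * np.pi] = 0.0
    return low, highs
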