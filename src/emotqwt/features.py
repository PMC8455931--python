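"""Per-sub-band time-domain and non-linear features.

Five scalar descriptors are computed for every (sub-band, channel) cell of
a decomposed trial:

- ``SampEn`` — sample entropy, -ln(A/B) with A, B the self-match-excluded
  counts of (m+1)- and m-length template pairs within Chebyshev tolerance
  ``u`` (defaults m = 2, u = 0.2 * std of the sequence);
- ``2dif`` — signed mean of lag-2 differences, (1/(N-2)) sum x(n+2) - x(n);
- ``2ndif`` — the same normalized by the standard deviation;
- ``HM`` — Hjorth mobility, sqrt(var(dx)/var(x)) with dx the first
  difference;
- ``HC`` — Hjorth complexity, mobility(dx)/mobility(x).

All standard deviations and variances are population (divisor N)
throughout.  ``2dif`` is the signed mean as defined; much of the literature
uses the mean absolute lag-2 difference, available via ``absolute=True``.

Sample entropy uses KD-tree range counting (O(N log N)-ish); the exact
O(N^2) enumeration lives in the test suite as an independent oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

from .io import EEGRecording
from .tqwt import TQWTParams, tqwt_decompose

logger = logging.getLogger(__name__)

FEATURE_TYPES = ("SampEn", "2dif", "2ndif", "HM", "HC")

__all__ = [
    "FEATURE_TYPES",
    "FeatureMatrix",
    "DegenerateSignalError",
    "sample_entropy",
    "second_diff_mean",
    "norm_second_diff_mean",
    "hjorth_mobility",
    "hjorth_complexity",
    "extract_features",
    "fuse",
    "TQWTFeatureExtractor",
]


class DegenerateSignalError(ValueError):
    """Feature undefined on this signal (flat signal / zero variance)."""


def _std(x: np.ndarray) -> float:
    return float(np.std(x))  # population (divisor N)


def sample_entropy(x: np.ndarray, m: int = 2, u: float | None = None) -> float:
    """Sample entropy of a 1-D sequence.

    Parameters
    ----------
    x : sequence
    m : embedding dimension (template length), default 2
    u : similarity tolerance; defaults to 0.2 * std(x)

    Returns ``-ln(A/B)`` where B (A) counts distinct template pairs i != j
    whose m-length ((m+1)-length) embeddings are within Chebyshev distance
    ``u``; both counts run over the N - m templates starting at
    i = 0..N-m-1.  Returns ``+inf`` (with a warning) when A = 0; a constant
    signal returns 0 by convention (with a warning); B = 0 raises
    :class:`DegenerateSignalError`.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= m + 1:
        raise ValueError(f"sequence length {n} too short for m={m}")
    if u is None:
        u = 0.2 * _std(x)
    if u < 0:
        raise ValueError("tolerance u must be >= 0")
    if _std(x) == 0.0:
        warnings.warn("constant signal: sample entropy set to 0 by convention")
        return 0.0

    n_templates = n - m  # same template count for both embedding lengths
    emb_m = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    emb_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n_templates]

    def _pairs(emb: np.ndarray) -> int:
        tree = cKDTree(emb)
        total = tree.count_neighbors(tree, u, p=np.inf)
        return (int(total) - len(emb)) // 2  # drop self-matches, unordered

    b = _pairs(emb_m)
    a = _pairs(emb_m1)
    if b == 0:
        raise DegenerateSignalError("no m-length template matches (B = 0)")
    if a == 0:
        warnings.warn("no (m+1)-length template matches: sample entropy is +inf")
        return float("inf")
    return float(-np.log(a / b))


def second_diff_mean(x: np.ndarray, absolute: bool = False) -> float:
    """Mean of lag-2 differences; signed by default (``absolute=True`` for
    the mean-absolute variant common elsewhere in the literature)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    d = x[2:] - x[:-2]
    return float(np.mean(np.abs(d) if absolute else d))


def norm_second_diff_mean(x: np.ndarray, absolute: bool = False) -> float:
    """Lag-2 difference mean normalized by the standard deviation."""
    x = np.asarray(x, dtype=float)
    s = _std(x)
    if s == 0.0:
        raise DegenerateSignalError("constant signal: normalized difference undefined")
    return second_diff_mean(x, absolute=absolute) / s


def hjorth_mobility(x: np.ndarray) -> float:
    """sqrt(var(dx)/var(x)); estimates the mean frequency of the signal."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    v = np.var(x)
    if v == 0.0:
        raise DegenerateSignalError("constant signal: mobility undefined")
    return float(np.sqrt(np.var(np.diff(x)) / v))


def hjorth_complexity(x: np.ndarray) -> float:
    """mobility(dx)/mobility(x); estimates bandwidth (1 for a pure tone)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    d = np.diff(x)
    if np.var(x) == 0.0 or np.var(d) == 0.0:
        raise DegenerateSignalError("degenerate variances: complexity undefined")
    return hjorth_mobility(d) / hjorth_mobility(x)


_SCALAR_OPS = {
    "SampEn": lambda x, m, u_coeff: sample_entropy(x, m=m, u=u_coeff * _std(x)),
    "2dif": lambda x, m, u_coeff: second_diff_mean(x),
    "2ndif": lambda x, m, u_coeff: norm_second_diff_mean(x),
    "HM": lambda x, m, u_coeff: hjorth_mobility(x),
    "HC": lambda x, m, u_coeff: hjorth_complexity(x),
}


@dataclass
class FeatureMatrix:
    """Observations x (sub-band, channel) feature values with provenance.

    ``column_index`` pairs each column with its (sub-band, channel) cell
    (sub-bands numbered from 1); ``row_index`` pairs each row with its
    (subject, trial).
    """

    values: np.ndarray
    feature_type: str
    column_index: list[tuple[int, str]]
    row_index: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_index), len(self.column_index)):
            raise ValueError("values shape inconsistent with indices")
        if len(set(self.column_index)) != len(self.column_index):
            raise ValueError("duplicate columns in column_index")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column_names(self) -> list[str]:
        return [f"SB{sb}_{ch}" for sb, ch in self.column_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.MultiIndex.from_tuples(self.row_index, names=["subject", "trial"]),
            columns=self.column_names(),
        )


def extract_features(
    recording: EEGRecording,
    params: TQWTParams | None = None,
    features: tuple[str, ...] = FEATURE_TYPES,
    m: int = 2,
    u_coeff: float = 0.2,
) -> dict[str, FeatureMatrix]:
    """Decompose every (trial, channel) signal and compute the requested
    features per sub-band.

    Returns one :class:`FeatureMatrix` per feature type with shape
    (n_trials, (J+1) * n_channels).  Cells where a feature is undefined
    (flat sub-band) or non-finite are imputed to 0; the count is logged.
    """
    extractor = TQWTFeatureExtractor(
        Q=params.Q if params else 3.0,
        r=params.r if params else 3.0,
        J=params.J if params else 4,
        features=features,
        m=m,
        u_coeff=u_coeff,
    )
    return extractor.extract(recording)


class TQWTFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer turning (n_trials, n_channels, n_samples) EEG tensors
    into per-sub-band feature matrices.

    ``transform`` returns the horizontal concatenation of the requested
    feature types, each block laid out sub-band-major then channel, so it
    drops straight into an sklearn pipeline; :meth:`extract` returns the
    per-feature-type :class:`FeatureMatrix` map with full provenance.

    Parameters
    ----------
    Q, r, J : TQWT parameters (defaults 3, 3, 4 -> five sub-bands).
    features : subset of ``FEATURE_TYPES`` to compute.
    m, u_coeff : sample-entropy embedding dimension and tolerance
        coefficient (u = u_coeff * std per sub-band sequence).
    """

    def __init__(
        self,
        Q: float = 3.0,
        r: float = 3.0,
        J: int = 4,
        features: tuple[str, ...] = FEATURE_TYPES,
        m: int = 2,
        u_coeff: float = 0.2,
    ):
        self.Q = Q
        self.r = r
        self.J = J
        self.features = features
        self.m = m
        self.u_coeff = u_coeff

    def _params(self) -> TQWTParams:
        return TQWTParams(Q=self.Q, r=self.r, J=self.J)

    def fit(self, X=None, y=None):
        unknown = set(self.features) - set(FEATURE_TYPES)
        if unknown:
            raise ValueError(f"unknown feature types: {sorted(unknown)}")
        self.n_imputed_ = 0
        return self

    def extract(self, recording: EEGRecording) -> dict[str, FeatureMatrix]:
        """Per-feature-type matrices for one recording."""
        self.fit()
        params = self._params()
        n_trials, n_ch, _ = recording.data.shape
        n_sb = params.J + 1
        cols = [
            (sb + 1, recording.channel_names[c] if c < len(recording.channel_names) else f"ch{c}")
            for sb in range(n_sb)
            for c in range(n_ch)
        ]
        rows = [(recording.subject_id, t) for t in range(n_trials)]
        out = {f: np.zeros((n_trials, n_sb * n_ch)) for f in self.features}

        for t in range(n_trials):
            for c in range(n_ch):
                try:
                    sbs = tqwt_decompose(recording.data[t, c], params)
                except Exception as exc:
                    raise RuntimeError(
                        f"decomposition failed for trial {t}, channel {c}"
                    ) from exc
                for sb, band in enumerate(sbs.subbands):
                    col = sb * n_ch + c
                    for f in self.features:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            try:
                                val = _SCALAR_OPS[f](band, self.m, self.u_coeff)
                            except DegenerateSignalError:
                                val = np.nan
                        if not np.isfinite(val):
                            self.n_imputed_ += 1
                            val = 0.0
                        out[f][t, col] = val
        if self.n_imputed_:
            logger.info("imputed %d degenerate feature cells to 0", self.n_imputed_)
        return {
            f: FeatureMatrix(out[f], f, list(cols), list(rows)) for f in self.features
        }

    def transform(self, X) -> np.ndarray:
        """X: array (n_trials, n_channels, n_samples) -> 2-D feature array,
        feature types concatenated in ``self.features`` order."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected a (n_trials, n_channels, n_samples) tensor")
        rec = EEGRecording(subject_id="_", data=X, channel_names=[f"ch{i}" for i in range(X.shape[1])])
        mats = self.extract(rec)
        return np.hstack([mats[f].values for f in self.features])

    def get_feature_names_out(self, input_features=None):
        params = self._params()
        names = []
        for f in self.features:
            for sb in range(1, params.J + 2):
                for c in range(32):
                    names.append(f"{f}_SB{sb}_ch{c}")
        return np.asarray(names, dtype=object)


def fuse(
    matrices: list[FeatureMatrix],
    mode: str,
    subband: int | None = None,
) -> FeatureMatrix:
    """Assemble one of the three fusion layouts from per-subject matrices
    of a single feature type.

    - ``per_subject_subband_fused``: one subject, all sub-band columns
      (40 x 160 at the reference cohort dimensions);
    - ``per_subband_subject_fused``: all subjects stacked, one sub-band's
      channel columns (1280 x 32); requires ``subband``;
    - ``all_fused``: all subjects stacked, all columns (1280 x 160).
    """
    if not matrices:
        raise ValueError("no matrices to fuse")
    ftype = matrices[0].feature_type
    cols = matrices[0].column_index
    for mat in matrices:
        if mat.feature_type != ftype:
            raise ValueError("cannot fuse different feature types")
        if mat.column_index != cols:
            raise ValueError("column indices differ across subjects")

    if mode == "per_subject_subband_fused":
        if len(matrices) != 1:
            raise ValueError("per-subject mode takes exactly one subject's matrix")
        return matrices[0]

    values = np.vstack([m.values for m in matrices])
    rows = [rt for m in matrices for rt in m.row_index]
    if len(set(rows)) != len(rows):
        raise ValueError("row index collision across subjects")

    if mode == "all_fused":
        return FeatureMatrix(values, ftype, list(cols), rows)
    if mode == "per_subband_subject_fused":
        if subband is None:
            raise ValueError("per-sub-band mode requires a sub-band number")
        keep = [i for i, (sb, _) in enumerate(cols) if sb == subband]
        if not keep:
            raise ValueError(f"no columns for sub-band {subband}")
        return FeatureMatrix(
            values[:, keep], ftype, [cols[i] for i in keep], rows
        )
    raise ValueError(f"unknown fusion mode: {mode}")
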