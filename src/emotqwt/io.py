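"""Reading and writing DEAP-layout EEG recordings.

A DEAP-layout per-subject file holds two arrays: ``data`` with shape
(40 trials, 40 channels, 8064 samples) — the first 32 channels are EEG in
the standard 10-20 montage, the remaining 8 are peripheral signals — and
``labels`` with shape (40, 4) holding the self-assessment ratings
(valence, arousal, dominance, liking), each on a 1-9 scale.

Files are stored as HDF5 with those two datasets; the synthetic generator
writes the same layout, so fixtures and real data go through one reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

N_TRIALS = 40
N_RAW_CHANNELS = 40
N_EEG_CHANNELS = 32
N_SAMPLES = 8064
FS = 128.0

#: 32-channel EEG montage (international 10-20 selection used by DEAP).
CHANNEL_NAMES = [
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
]


class FormatError(ValueError):
    """File contents do not match the expected DEAP layout."""


@dataclass
class RatingRecord:
    """One trial's self-assessment ratings, each on the 1-9 scale."""

    valence: float
    arousal: float
    dominance: float = 5.0
    liking: float = 5.0

    def __post_init__(self) -> None:
        for name in ("valence", "arousal", "dominance", "liking"):
            v = getattr(self, name)
            if not 1.0 <= v <= 9.0:
                raise ValueError(f"{name}={v} outside the 1-9 rating scale")


@dataclass
class EEGRecording:
    """One subject's trial tensor (trials x channels x samples) at 128 Hz."""

    subject_id: str
    data: np.ndarray
    fs: float = FS
    channel_names: list[str] = field(default_factory=lambda: list(CHANNEL_NAMES))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"data must be 3-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("data contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def load_recording(path: str | Path, subject_id: str | None = None):
    """Read a DEAP-layout file; return ``(EEGRecording, [RatingRecord])``.

    Only the first 32 (EEG) channels are kept.  Raises :class:`FormatError`
    if shapes differ from (40, 40 or 32, 8064) / (40, 4).
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem
    with h5py.File(path, "r") as f:
        if "data" not in f or "labels" not in f:
            raise FormatError("file must contain 'data' and 'labels' datasets")
        data = np.asarray(f["data"], dtype=float)
        ratings = np.asarray(f["labels"], dtype=float)

    if data.ndim != 3 or data.shape[0] != N_TRIALS or data.shape[2] != N_SAMPLES:
        raise FormatError(
            f"expected data shape ({N_TRIALS}, {N_RAW_CHANNELS} or "
            f"{N_EEG_CHANNELS}, {N_SAMPLES}), found {data.shape}"
        )
    if data.shape[1] not in (N_RAW_CHANNELS, N_EEG_CHANNELS):
        raise FormatError(
            f"expected {N_RAW_CHANNELS} or {N_EEG_CHANNELS} channels, "
            f"found {data.shape[1]}"
        )
    if ratings.shape != (N_TRIALS, 4):
        raise FormatError(
            f"expected ratings shape ({N_TRIALS}, 4), found {ratings.shape}"
        )

    rec = EEGRecording(subject_id=subject_id, data=data[:, :N_EEG_CHANNELS, :])
    records = [RatingRecord(*row) for row in ratings]
    return rec, records


def write_recording(
    path: str | Path,
    recording: EEGRecording,
    ratings: list[RatingRecord],
) -> None:
    """Write a recording plus ratings in the DEAP layout.

    32-channel recordings are padded with 8 zero peripheral channels so the
    file round-trips through :func:`load_recording`.
    """
    data = recording.data
    if data.shape[1] == N_EEG_CHANNELS:
        pad = np.zeros((data.shape[0], N_RAW_CHANNELS - N_EEG_CHANNELS, data.shape[2]))
        data = np.concatenate([data, pad], axis=1)
    arr = np.array(
        [[r.valence, r.arousal, r.dominance, r.liking] for r in ratings], dtype=float
    )
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data)
        f.create_dataset("labels", data=arr)


def labels_to_csv(
    path: str | Path,
    subject_id: str,
    ratings: list[RatingRecord],
    classes: np.ndarray,
) -> pd.DataFrame:
    """Export per-trial ratings, discretized levels and emotion class."""
    from .preprocess import map_rating_to_level

    rows = []
    for t, (r, c) in enumerate(zip(ratings, classes)):
        rows.append(
            {
                "subject": subject_id,
                "trial": t,
                "valence": r.valence,
                "arousal": r.arousal,
                "level_v": map_rating_to_level(r.valence),
                "level_a": map_rating_to_level(r.arousal),
                "class": int(c),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
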