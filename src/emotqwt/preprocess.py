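"""Preprocessing and valence-arousal label mapping.

The preprocessing chain mirrors the standard preparation of the DEAP
release: resample to 128 Hz, band-pass to 4-45 Hz, and re-reference each
trial to the whole-brain (common) average.  Ratings on the 1-9 scale are
discretized per axis into three levels (-1 / 0 / +1 for the 1-3 / 4-6 /
7-9 bins) and the two levels combined into five emotion classes:

====== ======= ======= =======
class  name    valence arousal
====== ======= ======= =======
1      happy   +1      +1
2      anger   +1      -1
3      sad     -1      -1
4      relax   -1      +1
5      neutral  either axis 0
====== ======= ======= =======

Note the anger/relax quadrant assignment above is taken verbatim from the
labelling rules this pipeline reproduces; it is the transpose of the
conventional circumplex placement (anger = low valence / high arousal).
Pass ``circumplex=True`` to :func:`map_levels_to_emotion` to swap them.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io import EEGRecording, RatingRecord

EMOTION_NAMES = {1: "happy", 2: "anger", 3: "sad", 4: "relax", 5: "neutral"}


def resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase anti-aliased downsampling from ``fs_in`` to ``fs_out``.

    Output length is ``round(len(x) * fs_out / fs_in)``.  Upsampling is not
    supported (the pipeline only ever reduces rate).
    """
    if fs_out <= 0 or fs_in <= 0:
        raise ValueError("sampling rates must be positive")
    if fs_out > fs_in:
        raise ValueError(f"upsampling not supported ({fs_in} -> {fs_out} Hz)")
    if fs_out == fs_in:
        return np.asarray(x, dtype=float).copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    y = sps.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator, axis=-1)
    n_target = int(round(np.asarray(x).shape[-1] * fs_out / fs_in))
    return y[..., :n_target]


def bandpass(
    x: np.ndarray, fs: float, lo: float = 4.0, hi: float = 45.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (two passes of an order-``order``
    filter via ``filtfilt``); length-preserving."""
    if not 0 < lo < hi:
        raise ValueError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= fs / 2:
        raise ValueError(f"hi={hi} Hz must be below Nyquist {fs / 2} Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def average_reference(trial: np.ndarray) -> np.ndarray:
    """Common-average re-referencing: subtract the instantaneous mean over
    channels.  Idempotent; output channel means are 0 per sample."""
    trial = np.asarray(trial, dtype=float)
    if trial.ndim < 2 or trial.shape[-2] < 2:
        raise ValueError("need at least 2 channels to re-reference")
    return trial - trial.mean(axis=-2, keepdims=True)


def map_rating_to_level(rating: float) -> int:
    """Discretize a 1-9 rating into a level: [1,4) -> -1, [4,7) -> 0,
    [7,9] -> +1 (the continuous extension of the 1-3/4-6/7-9 bins)."""
    if not 1.0 <= rating <= 9.0:
        raise ValueError(f"rating {rating} outside [1, 9]")
    if rating < 4:
        return -1
    if rating < 7:
        return 0
    return 1


def map_levels_to_emotion(v_level: int, a_level: int, circumplex: bool = False) -> int:
    """Combine valence/arousal levels into one of the five emotion classes.

    With ``circumplex=True`` the anger and relax quadrants are swapped to
    the conventional circumplex placement.
    """
    if v_level not in (-1, 0, 1) or a_level not in (-1, 0, 1):
        raise ValueError(f"levels must be in {{-1, 0, 1}}, got ({v_level}, {a_level})")
    if v_level == 0 or a_level == 0:
        return 5
    quadrants = {(1, 1): 1, (1, -1): 2, (-1, -1): 3, (-1, 1): 4}
    if circumplex:
        quadrants = {(1, 1): 1, (-1, 1): 2, (-1, -1): 3, (1, -1): 4}
    return quadrants[(v_level, a_level)]


def ratings_to_classes(
    ratings: list[RatingRecord], circumplex: bool = False
) -> np.ndarray:
    """Vectorized rating -> five-class mapping over a trial list."""
    return np.array(
        [
            map_levels_to_emotion(
                map_rating_to_level(r.valence),
                map_rating_to_level(r.arousal),
                circumplex=circumplex,
            )
            for r in ratings
        ],
        dtype=int,
    )


def preprocess_recording(
    recording: EEGRecording, lo: float = 4.0, hi: float = 45.0
) -> EEGRecording:
    """Band-pass (4-45 Hz) and common-average-reference every trial.

    Input is assumed to already be at 128 Hz (use :func:`resample` first
    otherwise).
    """
    out = bandpass(recording.data, recording.fs, lo=lo, hi=hi)
    out = average_reference(out)
    return EEGRecording(
        subject_id=recording.subject_id,
        data=out,
        fs=recording.fs,
        channel_names=list(recording.channel_names),
    )
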