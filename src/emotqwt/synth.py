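"""Synthetic DEAP-shaped EEG cohorts with class-conditioned band power.

Each trial is a 1/f (pink) background plus four band-limited oscillatory
components (theta 4-8, alpha 8-13, beta 13-30, gamma 30-45 Hz).  A trial's
latent emotion class modulates the band amplitudes through a fixed
class -> band template:

- happy: beta and gamma up
- anger: beta up, alpha down
- sad: theta up
- relax: alpha up
- neutral: baseline

The modulation strength is ``effect_size`` (relative amplitude change; 0
makes classes statistically indistinguishable).  Ratings are emitted at
the level-bin centers (2 / 5 / 8), so the rating -> level -> class mapping
recovers the latent class exactly.  These signals are test fixtures for
the pipeline, not physiological models: there is no dipole/forward
modeling, no artifacts, and the class templates are chosen for
identifiability, not neuroscientific fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix
from .io import CHANNEL_NAMES, EEGRecording, RatingRecord

__all__ = ["SynthConfig", "generate_cohort", "planted_feature_matrix", "BANDS"]

BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0),
         "beta": (13.0, 30.0), "gamma": (30.0, 45.0)}

#: class -> band modulation sign (band amplitude factor = 1 + effect * sign)
CLASS_TEMPLATES = {
    1: {"beta": +1, "gamma": +1},            # happy
    2: {"beta": +1, "alpha": -1},            # anger
    3: {"theta": +1},                        # sad
    4: {"alpha": +1},                        # relax
    5: {},                                   # neutral
}

#: class -> (valence, arousal) ratings at bin centers
CLASS_RATINGS = {1: (8.0, 8.0), 2: (8.0, 2.0), 3: (2.0, 2.0),
                 4: (2.0, 8.0), 5: (5.0, 5.0)}

_BAND_BASE_AMP = 0.6   # band component std relative to unit pink background


@dataclass
class SynthConfig:
    """Cohort dimensions and signal-model knobs (defaults mirror one
    DEAP-layout subject file: 40 trials x 32 channels x 63 s at 128 Hz)."""

    n_subjects: int = 4
    n_trials: int = 40
    n_channels: int = 32
    fs: float = 128.0
    duration: float = 63.0
    class_distribution: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    effect_size: float = 0.5
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.class_distribution, dtype=float)
        if len(p) != 5 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("class_distribution must be 5 probabilities summing to 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_subjects < 1 or self.n_trials < 1 or self.n_channels < 1:
            raise ValueError("cohort dimensions must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def _shaped_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    fs: float,
    amplitude: np.ndarray,
) -> np.ndarray:
    """Real signals from a given one-sided spectral amplitude profile with
    randomized phases; each channel normalized to unit standard deviation."""
    n_freq = n_samples // 2 + 1
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_channels, n_freq))
    spec = amplitude * np.exp(1j * phases)
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    std = x.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return x / std


def _trial_signal(
    rng: np.random.Generator, cfg: SynthConfig, emotion_class: int
) -> np.ndarray:
    n = cfg.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / cfg.fs)
    pink_amp = np.zeros_like(freqs)
    pink_amp[1:] = freqs[1:] ** (-cfg.noise_exponent / 2.0)
    x = _shaped_noise(rng, cfg.n_channels, n, cfg.fs, pink_amp)

    template = CLASS_TEMPLATES[emotion_class]
    for band, (lo, hi) in BANDS.items():
        factor = max(0.0, 1.0 + cfg.effect_size * template.get(band, 0))
        if factor == 0.0:
            continue
        band_amp = ((freqs >= lo) & (freqs < hi)).astype(float)
        xb = _shaped_noise(rng, cfg.n_channels, n, cfg.fs, band_amp)
        x = x + _BAND_BASE_AMP * factor * xb

    gains = rng.uniform(0.8, 1.2, size=(cfg.n_channels, 1))
    return 10.0 * gains * x  # microvolt-ish scale


def generate_cohort(config: SynthConfig):
    """Generate ``(recordings, ratings)`` for the configured cohort.

    ``recordings[s]`` is an :class:`EEGRecording` of shape
    (n_trials, n_channels, n_samples); ``ratings[s]`` the matching list of
    :class:`RatingRecord` placed at level-bin centers so the label mapping
    recovers each trial's latent class exactly.
    """
    rng = np.random.default_rng(config.seed)
    classes = np.arange(1, 6)
    recordings: list[EEGRecording] = []
    ratings: list[list[RatingRecord]] = []
    names = (
        list(CHANNEL_NAMES[: config.n_channels])
        if config.n_channels <= len(CHANNEL_NAMES)
        else [f"ch{i}" for i in range(config.n_channels)]
    )
    for s in range(config.n_subjects):
        latent = rng.choice(classes, size=config.n_trials,
                            p=np.asarray(config.class_distribution))
        data = np.empty((config.n_trials, config.n_channels, config.n_samples))
        subj_ratings = []
        for t in range(config.n_trials):
            data[t] = _trial_signal(rng, config, int(latent[t]))
            v, a = CLASS_RATINGS[int(latent[t])]
            subj_ratings.append(RatingRecord(valence=v, arousal=a))
        recordings.append(
            EEGRecording(subject_id=f"s{s + 1:02d}", data=data, fs=config.fs,
                         channel_names=names)
        )
        ratings.append(subj_ratings)
    return recordings, ratings


def planted_feature_matrix(
    n_rows: int,
    n_informative: int,
    n_noise: int,
    effect: float,
    seed: int = 0,
    n_classes: int = 5,
):
    """Gaussian fixture with known informative columns for selector tests.

    Informative columns carry class-dependent mean shifts of magnitude
    ``effect`` standard deviations (per-class means drawn once from
    N(0, effect^2)); noise columns are standard normal.  Returns
    ``(FeatureMatrix, labels)``; informative columns come first.
    """
    if n_informative < 1:
        raise ValueError("need at least one informative column")
    rng = np.random.default_rng(seed)
    labels = rng.integers(1, n_classes + 1, size=n_rows)
    class_means = effect * rng.standard_normal((n_classes, n_informative))
    X = rng.standard_normal((n_rows, n_informative + n_noise))
    X[:, :n_informative] += class_means[labels - 1]
    cols = [(1, f"inf{j}") for j in range(n_informative)] + [
        (1, f"noise{j}") for j in range(n_noise)
    ]
    rows = [("synth", i) for i in range(n_rows)]
    return FeatureMatrix(X, "planted", cols, rows), labels
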