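"""Binary grey-wolf wrapper feature selection (BGWO, sigmoid-transfer
variant).

Grey-wolf optimization evolves a pack of candidate solutions guided by its
three best members (the alpha, beta and delta wolves); every other wolf
moves toward a combination of the three.  The binary variant used here
keeps positions as 0/1 feature masks: the continuous GWO step for each
leader (``A = 2 a rand - a``, ``C = 2 rand``, ``D = |C X_leader - X|``,
candidate ``X_leader - A D`` with the control scalar ``a`` decaying
linearly 2 -> 0 over iterations) is squashed through the steep sigmoid

    S(a) = 1 / (1 + exp(-10 (a - 0.5)))

and stochastically binarized into three donor bit-vectors Y1, Y2, Y3; the
new bit is then 1 iff ``S((Y1 + Y2 + Y3) / 3) >= r0`` with r0 uniform per
bit.

The default wrapper objective is ``w * cv_error + (1 - w) * n_selected /
n_features`` (w = 0.99) with the error from stratified k-fold SVM
cross-validation on the selected columns, so fitness is minimized and
sparsity breaks ties.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "sigmoid_transfer",
    "binary_update",
    "donor_bits",
    "default_fitness",
    "bgwo_select",
    "SelectionResult",
    "WolfPackState",
    "BGWOSelector",
]


def sigmoid_transfer(a):
    """Steep sigmoid S(a) = 1/(1 + e^(-10(a-0.5))); S(0.5) = 0.5."""
    return 1.0 / (1.0 + np.exp(-10.0 * (np.asarray(a, dtype=float) - 0.5)))


def binary_update(y1, y2, y3, r0):
    """New bit(s): 1 iff S(mean donor bit) >= r0."""
    mean = (np.asarray(y1) + np.asarray(y2) + np.asarray(y3)) / 3.0
    return (sigmoid_transfer(mean) >= np.asarray(r0)).astype(np.int8)


def donor_bits(
    position: np.ndarray, leader: np.ndarray, a: float, rng: np.random.Generator
) -> np.ndarray:
    """Binary donor vector for one leader: the continuous GWO step toward
    the leader, squashed and stochastically binarized per dimension."""
    position = np.asarray(position, dtype=float)
    leader = np.asarray(leader, dtype=float)
    if position.shape != leader.shape:
        raise ValueError("position and leader dimensions differ")
    d = position.shape[0]
    A = 2.0 * a * rng.random(d) - a
    C = 2.0 * rng.random(d)
    D = np.abs(C * leader - position)
    y_cont = leader - A * D
    return (sigmoid_transfer(y_cont) >= rng.random(d)).astype(np.int8)


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Guarantee at least one selected bit by flipping one at random."""
    if mask.sum() == 0:
        mask = mask.copy()
        mask[rng.integers(mask.shape[0])] = 1
        logger.debug("repaired empty mask")
    return mask


def default_fitness(
    mask: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 6,
    w: float = 0.99,
    seed: int = 0,
    C: float = 1.0,
    gamma: str | float = "scale",
) -> float:
    """Wrapper objective: ``w * SVM CV error + (1-w) * selection fraction``.

    Deterministic for fixed (mask, X, y, folds, seed).  An empty mask is
    repaired to a single random bit (logged) before evaluation.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        mask = _repair(mask.astype(np.int8), np.random.default_rng(seed)).astype(bool)
    classes, counts = np.unique(np.asarray(y), return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes for wrapper fitness")
    folds_eff = int(min(folds, counts.min()))
    if folds_eff < 2:
        raise ValueError("smallest class has fewer than 2 members")
    if folds_eff < folds:
        warnings.warn(
            f"reduced CV folds {folds} -> {folds_eff}: smallest class has "
            f"{counts.min()} members"
        )
    pipe = make_pipeline(StandardScaler(), SVC(C=C, kernel="rbf", gamma=gamma))
    cv = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
    acc = cross_val_score(pipe, np.asarray(X)[:, mask], y, cv=cv).mean()
    return float(w * (1.0 - acc) + (1.0 - w) * mask.sum() / mask.shape[0])


@dataclass
class WolfPackState:
    """Pack positions/fitness plus the three best-so-far leaders."""

    positions: np.ndarray
    fitness: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    delta: np.ndarray
    f_alpha: float
    f_beta: float
    f_delta: float
    t: int
    T: int
    a: float
    rng_seed: int


@dataclass
class SelectionResult:
    """Outcome of a BGWO run: final mask, fitness trace, configuration."""

    mask: np.ndarray
    best_fitness: float
    fitness_trace: np.ndarray
    config: dict = field(default_factory=dict)
    state: WolfPackState | None = None

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def bgwo_select(
    X: np.ndarray,
    y: np.ndarray,
    pack_size: int = 8,
    T: int = 70,
    fitness: Callable[[np.ndarray], float] | None = None,
    seed: int = 0,
    fitness_kwargs: dict | None = None,
) -> SelectionResult:
    """Run BGWO over the columns of X; returns the best mask found.

    ``fitness`` maps a binary mask to a scalar (lower is better); by
    default :func:`default_fitness` bound to (X, y) with ``seed``.
    Evaluations are memoized by mask, so revisited masks are free.  The
    best-so-far fitness trace is monotone non-increasing; the whole run is
    reproducible from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be 2-D with at least 2 columns")
    if len(y) != X.shape[0]:
        raise ValueError("labels not aligned to rows")
    if fitness is None:
        if len(np.unique(y)) < 2:
            raise ValueError("labels contain a single class")
        kw = dict(seed=seed)
        kw.update(fitness_kwargs or {})
        fitness = lambda mask: default_fitness(mask, X, y, **kw)  # noqa: E731

    d = X.shape[1]
    rng = np.random.default_rng(seed)
    cache: dict[bytes, float] = {}

    def evaluate(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = float(fitness(mask))
        return cache[key]

    positions = rng.integers(0, 2, size=(pack_size, d), dtype=np.int8)
    for i in range(pack_size):
        positions[i] = _repair(positions[i], rng)
    fit = np.array([evaluate(p) for p in positions])

    # best-so-far leaders (strict improvement => first-evaluated wins ties)
    f_a = f_b = f_d = np.inf
    alpha = beta = delta = positions[0]
    for p, f in zip(positions, fit):
        if f < f_a:
            f_a, f_b, f_d = f, f_a, f_b
            alpha, beta, delta = p.copy(), alpha, beta
        elif f < f_b:
            f_b, f_d = f, f_b
            beta, delta = p.copy(), beta
        elif f < f_d:
            f_d, delta = f, p.copy()

    trace = np.empty(T)
    for t in range(T):
        a = 2.0 * (1.0 - t / T)
        for i in range(pack_size):
            y1 = donor_bits(positions[i], alpha, a, rng)
            y2 = donor_bits(positions[i], beta, a, rng)
            y3 = donor_bits(positions[i], delta, a, rng)
            new = binary_update(y1, y2, y3, rng.random(d))
            positions[i] = _repair(new.astype(np.int8), rng)
            f = evaluate(positions[i])
            fit[i] = f
            if f < f_a:
                f_a, f_b, f_d = f, f_a, f_b
                alpha, beta, delta = positions[i].copy(), alpha, beta
            elif f < f_b:
                f_b, f_d = f, f_b
                beta, delta = positions[i].copy(), beta
            elif f < f_d:
                f_d, delta = f, positions[i].copy()
        trace[t] = f_a

    state = WolfPackState(
        positions=positions,
        fitness=fit,
        alpha=alpha,
        beta=beta,
        delta=delta,
        f_alpha=f_a,
        f_beta=f_b,
        f_delta=f_d,
        t=T,
        T=T,
        a=0.0,
        rng_seed=seed,
    )
    return SelectionResult(
        mask=alpha.astype(np.int8),
        best_fitness=f_a,
        fitness_trace=trace,
        config={"pack_size": pack_size, "T": T, "seed": seed},
        state=state,
    )


class BGWOSelector(SelectorMixin, BaseEstimator):
    """sklearn-style feature selector backed by :func:`bgwo_select`.

    Parameters
    ----------
    pack_size, n_iter : pack size and iteration count (defaults 8, 70).
    w : error/sparsity trade-off of the wrapper objective.
    cv_folds : folds of the internal stratified SVM cross-validation.
    random_state : seed controlling the whole run (bit-reproducible).

    Attributes (after fit)
    ----------------------
    support_mask_ : boolean mask over input columns.
    result_ : the full :class:`SelectionResult` (trace, config, pack state).
    """

    def __init__(
        self,
        pack_size: int = 8,
        n_iter: int = 70,
        w: float = 0.99,
        cv_folds: int = 6,
        random_state: int = 0,
    ):
        self.pack_size = pack_size
        self.n_iter = n_iter
        self.w = w
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.n_features_in_ = X.shape[1]
        self.result_ = bgwo_select(
            X,
            y,
            pack_size=self.pack_size,
            T=self.n_iter,
            seed=self.random_state,
            fitness_kwargs={"folds": self.cv_folds, "w": self.w},
        )
        self.support_mask_ = self.result_.mask.astype(bool)
        return self

    def _get_support_mask(self):
        return self.support_mask_

    def __sklearn_is_fitted__(self):
        return hasattr(self, "support_mask_")
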