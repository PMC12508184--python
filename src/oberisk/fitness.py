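"""Wrapper fitness for binary feature masks.

A candidate mask is scored by

    Fitness(x) = w * Error(x) + (1 - w) * |x| / d

where Error(x) is the hold-out misclassification rate of a k-nearest-neighbor
classifier restricted to the masked columns and |x|/d penalizes subset size.
With the default trade-off w = 0.99 the error term dominates and the size
penalty only separates masks with (near-)equal error.

The KNN evaluator is written out explicitly rather than delegated, because
the optimizer's determinism contract needs exact tie-break rules: neighbor
distance ties go to the lower training-row index, vote ties to the smallest
class label.  The hold-out split is drawn once per optimizer run and frozen,
so fitness is a pure function of the mask within a run; results are cached
by mask bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import train_test_split


@dataclass
class FitnessConfig:
    """Trade-off weight, KNN size, and the frozen hold-out split."""

    w: float = 0.99
    k: int = 5
    holdout_fraction: float = 0.3
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must be in [0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must be in (0, 1)")


def knn_error(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_eval: np.ndarray,
    y_eval: np.ndarray,
    mask: np.ndarray,
    k: int = 5,
) -> float:
    """Hold-out error of majority-vote KNN under Euclidean distance on masked columns.

    Distance ties are broken by the lower training-row index (stable sort);
    vote ties by the smallest class label.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no features")
    if k > X_train.shape[0]:
        raise ValueError(f"k={k} exceeds the {X_train.shape[0]} training rows")
    Xt = np.asarray(X_train, dtype=float)[:, mask]
    Xe = np.asarray(X_eval, dtype=float)[:, mask]
    yt = np.asarray(y_train)
    dist = cdist(Xe, Xt, metric="euclidean")
    # stable argsort: equal distances resolve to the lower training index
    nn = np.argsort(dist, axis=1, kind="stable")[:, :k]
    errors = 0
    for i in range(Xe.shape[0]):
        votes = np.bincount(yt[nn[i]].astype(int))
        pred = int(np.argmax(votes))  # argmax -> smallest tied label
        errors += pred != y_eval[i]
    return errors / Xe.shape[0]


class SubsetFitness:
    """Cached fitness function over masks with a frozen stratified hold-out split.

    Instances are callables: ``fitness = SubsetFitness(X, y, cfg); fitness(mask)``.
    An all-zero mask scores Error := 1 by convention, hence fitness = w.
    An alternative evaluator with signature
    ``(X_train, y_train, X_eval, y_eval, mask) -> error`` may replace KNN.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        cfg: FitnessConfig | None = None,
        evaluator=None,
    ) -> None:
        self.cfg = cfg or FitnessConfig()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.shape[1] == 0:
            raise ValueError("table has no feature columns")
        self.d = X.shape[1]
        strat = y if self.cfg.stratified else None
        try:
            tr, ev = train_test_split(
                np.arange(len(y)),
                test_size=self.cfg.holdout_fraction,
                random_state=self.cfg.seed,
                stratify=strat,
            )
        except ValueError:  # a class too small to stratify
            tr, ev = train_test_split(
                np.arange(len(y)),
                test_size=self.cfg.holdout_fraction,
                random_state=self.cfg.seed,
            )
        self.X_train, self.y_train = X[tr], y[tr]
        self.X_eval, self.y_eval = X[ev], y[ev]
        self._evaluator = evaluator
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0  # unique (uncached) evaluations

    def error(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return 1.0
        if self._evaluator is not None:
            return float(
                self._evaluator(self.X_train, self.y_train, self.X_eval, self.y_eval, mask)
            )
        return knn_error(
            self.X_train, self.y_train, self.X_eval, self.y_eval, mask, k=self.cfg.k
        )

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape[0] != self.d:
            raise ValueError(f"mask length {mask.shape[0]} != {self.d} features")
        key = np.packbits(mask).tobytes()
        if key in self._cache:
            return self._cache[key]
        w = self.cfg.w
        fit = w * self.error(mask) + (1.0 - w) * mask.sum() / self.d
        self._cache[key] = float(fit)
        self.n_evaluations += 1
        return float(fit)
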