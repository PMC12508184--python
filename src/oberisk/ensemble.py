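"""Prediction stage: seven base classifiers combined by hard majority vote.

The base family is fixed: a logistic linear model (LR), LightGBM, XGBoost,
AdaBoost, a multi-layer perceptron, KNN, and an RBF-kernel SVM.  Each is
trained on the selected feature columns; a prediction is the plurality class
of the seven votes, with ties resolved by the vote of the most accurate base
model (validation accuracy recorded at fit time) among those voting for a
tied class.

Hyperparameters default to a fixed table (LGBM 100 trees at learning rate
0.05; XGB depth 6 at 0.01; AdaBoost 100 estimators at 0.01; KNN with 10
Minkowski neighbors; MLP (100, 50) relu/adam at 0.001; SVM C=2 RBF).  An
optional simplified tree-structured Parzen estimator (TPE) tunes any model
with a declared search space: past trials are split at a score quantile into
good/bad groups, one-dimensional Parzen densities l(x) and g(x) are fitted
per hyperparameter, and candidates maximizing l/g are evaluated next.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import AdaBoostClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y
from xgboost import XGBClassifier

MODEL_NAMES = ("LR", "LGBM", "XGB", "AdaBoost", "MLP", "KNN", "SVM")


@dataclass
class ModelSpec:
    """One base model: family name, fixed hyperparameters, optional search space.

    Search-space entries are ``("choice", [options])``,
    ``("uniform", lo, hi)``, ``("lognormal", mu, sigma)`` or
    ``("int_range", lo, hi)`` (hi exclusive).
    """

    name: str
    fixed_hyperparameters: dict[str, Any] = field(default_factory=dict)
    search_space: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model name {self.name!r}; expected one of {MODEL_NAMES}")


def build_model_specs(overrides: dict[str, dict[str, Any]] | None = None) -> list[ModelSpec]:
    """The seven default model specs, optionally overriding per-model hyperparameters.

    ``overrides`` maps model name -> {hyperparameter: value}; an empty dict of
    models is rejected.
    """
    specs = [
        ModelSpec(
            "LR",
            {"solver": "lbfgs", "max_iter": 1000},
            {"C": ("lognormal", 0.0, 1.0)},
        ),
        ModelSpec(
            "LGBM",
            {"n_estimators": 100, "learning_rate": 0.05},
            {"max_depth": ("int_range", 1, 17)},
        ),
        ModelSpec(
            "XGB",
            {"n_estimators": 100, "max_depth": 6, "learning_rate": 0.01},
            {"subsample": ("uniform", 0.1, 1.0)},
        ),
        ModelSpec("AdaBoost", {"n_estimators": 100, "learning_rate": 0.01}),
        ModelSpec(
            "MLP",
            {
                "hidden_layer_sizes": (100, 50),
                "activation": "relu",
                "solver": "adam",
                "learning_rate_init": 0.001,
                "max_iter": 300,
            },
        ),
        ModelSpec(
            "KNN",
            {"n_neighbors": 10, "metric": "minkowski"},
            {
                "weights": ("choice", ["uniform", "distance"]),
                "algorithm": ("choice", ["ball_tree", "kd_tree", "brute"]),
            },
        ),
        ModelSpec("SVM", {"C": 2, "kernel": "rbf", "gamma": "auto"}),
    ]
    if overrides is not None:
        known = {s.name for s in specs}
        for name in overrides:
            if name not in known:
                raise ValueError(f"unknown model name {name!r} in overrides")
        specs = [
            replace(
                s,
                fixed_hyperparameters={**s.fixed_hyperparameters, **overrides.get(s.name, {})},
            )
            for s in specs
        ]
    return specs


def make_estimator(spec: ModelSpec, random_state: int = 0):
    """Instantiate the sklearn/LightGBM/XGBoost estimator for a spec."""
    p = dict(spec.fixed_hyperparameters)
    if spec.name == "LR":
        return LogisticRegression(random_state=random_state, **p)
    if spec.name == "LGBM":
        return LGBMClassifier(random_state=random_state, n_jobs=1, verbose=-1, **p)
    if spec.name == "XGB":
        return XGBClassifier(
            random_state=random_state, n_jobs=1, verbosity=0, eval_metric="mlogloss", **p
        )
    if spec.name == "AdaBoost":
        return AdaBoostClassifier(random_state=random_state, **p)
    if spec.name == "MLP":
        return MLPClassifier(random_state=random_state, **p)
    if spec.name == "KNN":
        return KNeighborsClassifier(**p)
    if spec.name == "SVM":
        return SVC(random_state=random_state, **p)
    raise ValueError(f"unknown model name {spec.name!r}")


# ---------------------------------------------------------------------------
# Simplified TPE
# ---------------------------------------------------------------------------


@dataclass
class TpeTrial:
    params: dict[str, Any]
    score: float
    group: str = ""  # "good" | "bad" once split


def split_trials(trials: list[TpeTrial], gamma_tpe: float = 0.25) -> tuple[list, list]:
    """Partition trials at the (1 − γ) score quantile: top γ fraction is 'good'."""
    n_good = max(1, int(np.ceil(gamma_tpe * len(trials))))
    order = sorted(range(len(trials)), key=lambda i: -trials[i].score)
    for rank, i in enumerate(order):
        trials[i].group = "good" if rank < n_good else "bad"
    good = [t for t in trials if t.group == "good"]
    bad = [t for t in trials if t.group == "bad"]
    return good, bad


def _sample_param(kind: tuple, rng: np.random.Generator):
    if kind[0] == "choice":
        return kind[1][int(rng.integers(len(kind[1]))) ]
    if kind[0] == "uniform":
        return float(rng.uniform(kind[1], kind[2]))
    if kind[0] == "lognormal":
        return float(np.exp(rng.normal(kind[1], kind[2])))
    if kind[0] == "int_range":
        return int(rng.integers(kind[1], kind[2]))
    raise ValueError(f"unknown search-space kind {kind[0]!r}")


def _bandwidth(kind: tuple, n: int) -> float:
    if kind[0] == "lognormal":
        span = 2.0 * kind[2]
    else:
        span = kind[2] - kind[1]
    # a quarter of the Scott-style span/sqrt(n) keeps early proposals local
    # instead of piling clipped mass at the range boundaries
    return max(span / (4.0 * max(np.sqrt(n), 1.0)), 1e-6)


def _sample_around(kind: tuple, values: list, rng: np.random.Generator):
    """Parzen sample: a random donor observation plus bandwidth noise."""
    if kind[0] == "choice":
        opts = kind[1]
        counts = np.array([sum(v == o for v in values) for o in opts], float) + 1.0
        return opts[int(rng.choice(len(opts), p=counts / counts.sum()))]
    donor = values[int(rng.integers(len(values)))]
    bw = _bandwidth(kind, len(values))
    if kind[0] == "lognormal":
        return float(np.exp(np.log(donor) + rng.normal(0.0, bw)))
    x = float(donor) + rng.normal(0.0, bw)
    if kind[0] == "int_range":
        return int(np.clip(round(x), kind[1], kind[2] - 1))
    return float(np.clip(x, kind[1], kind[2]))


def _parzen_logdensity(kind: tuple, values: list, x) -> float:
    """1-D Parzen estimate: mixture of normals (continuous) or smoothed counts."""
    if kind[0] == "choice":
        opts = kind[1]
        counts = np.array([sum(v == o for v in values) for o in opts], dtype=float) + 1.0
        probs = counts / counts.sum()
        return float(np.log(probs[opts.index(x)]))
    vals = np.array(
        [np.log(v) for v in values] if kind[0] == "lognormal" else [float(v) for v in values]
    )
    q = np.log(x) if kind[0] == "lognormal" else float(x)
    bw = _bandwidth(kind, len(vals))
    dens = np.mean(np.exp(-0.5 * ((q - vals) / bw) ** 2)) / (bw * np.sqrt(2 * np.pi))
    return float(np.log(max(dens, 1e-300)))


def tpe_optimize(
    spec: ModelSpec,
    X_train,
    y_train,
    X_val,
    y_val,
    budget: int = 16,
    gamma_tpe: float = 0.25,
    n_candidates: int = 20,
    seed: int = 0,
    objective=None,
) -> ModelSpec:
    """Tune a spec's search-space parameters by simplified 1-D-factorized TPE.

    Each round samples candidates from the good-group Parzen densities and
    evaluates the one maximizing Σ log l(x) − log g(x) on the validation
    split.  Returns a spec whose fixed hyperparameters include the
    best-scoring configuration.  A budget below 4 falls back to the fixed
    hyperparameters with a warning.  ``objective(params) -> score`` replaces
    the model-fitting evaluation when given (higher is better).
    """
    if not spec.search_space:
        return spec
    if budget < 4:
        warnings.warn(
            f"TPE budget {budget} < 4: keeping fixed hyperparameters for {spec.name}",
            stacklevel=2,
        )
        return spec
    rng = np.random.default_rng(seed)

    def evaluate(params: dict) -> float:
        if objective is not None:
            return float(objective(params))
        trial_spec = replace(
            spec, fixed_hyperparameters={**spec.fixed_hyperparameters, **params}
        )
        model = make_estimator(trial_spec, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X_train, y_train)
            return float(np.mean(model.predict(X_val) == y_val))

    # degenerate single-point space: one evaluation
    if all(k[0] == "choice" and len(k[1]) == 1 for k in spec.search_space.values()):
        params = {n: k[1][0] for n, k in spec.search_space.items()}
        evaluate(params)
        return replace(
            spec, fixed_hyperparameters={**spec.fixed_hyperparameters, **params}
        )

    n_startup = max(4, budget // 4)
    trials: list[TpeTrial] = []
    for _ in range(min(n_startup, budget)):
        params = {n: _sample_param(k, rng) for n, k in spec.search_space.items()}
        trials.append(TpeTrial(params=params, score=evaluate(params)))
    while len(trials) < budget:
        good, bad = split_trials(trials, gamma_tpe)
        best_cand, best_ei = None, -np.inf
        for _ in range(n_candidates):
            cand = {}
            for name, kind in spec.search_space.items():
                # Parzen sample around the good group most of the time,
                # fresh uniform draw otherwise (exploration floor)
                if good and rng.random() < 0.8:
                    cand[name] = _sample_around(
                        kind, [t.params[name] for t in good], rng
                    )
                else:
                    cand[name] = _sample_param(kind, rng)
            ei = 0.0
            for name, kind in spec.search_space.items():
                lg = _parzen_logdensity(kind, [t.params[name] for t in good], cand[name])
                lb = _parzen_logdensity(kind, [t.params[name] for t in bad], cand[name]) if bad else 0.0
                ei += lg - lb
            if ei > best_ei:
                best_ei, best_cand = ei, cand
        trials.append(TpeTrial(params=best_cand, score=evaluate(best_cand)))
    best = max(trials, key=lambda t: t.score)
    return replace(
        spec, fixed_hyperparameters={**spec.fixed_hyperparameters, **best.params}
    )


# ---------------------------------------------------------------------------
# Majority-voting ensemble
# ---------------------------------------------------------------------------


@dataclass
class VotingResult:
    """One prediction with its provenance."""

    per_model_label: dict[str, int]
    tally: dict[int, int]
    final_label: int
    tie_broken: bool = False
    tie_breaker_model: str | None = None


class MajorityVoteEnsemble(BaseEstimator, ClassifierMixin):
    """Hard majority vote over the seven base classifiers.

    ``fit`` holds out a stratified validation split, trains every base model
    on the remainder, and records per-model validation accuracies used as the
    tie-break order.  With ``tune=True`` models carrying a search space are
    TPE-tuned on that split first.

    Attributes: ``models_`` (name -> fitted estimator),
    ``validation_accuracy_`` (name -> accuracy), ``classes_``.
    """

    def __init__(
        self,
        specs: list[ModelSpec] | None = None,
        validation_fraction: float = 0.2,
        tune: bool = False,
        tpe_budget: int = 16,
        random_state: int = 0,
    ) -> None:
        self.specs = specs
        self.validation_fraction = validation_fraction
        self.tune = tune
        self.tpe_budget = tpe_budget
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        y = y.astype(int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain a single class")
        specs = self.specs if self.specs is not None else build_model_specs()
        if not specs:
            raise ValueError("empty model list")
        try:
            X_fit, X_val, y_fit, y_val = train_test_split(
                X, y, test_size=self.validation_fraction,
                random_state=self.random_state, stratify=y,
            )
        except ValueError:
            X_fit, X_val, y_fit, y_val = train_test_split(
                X, y, test_size=self.validation_fraction, random_state=self.random_state
            )
        self.models_: dict[str, Any] = {}
        self.validation_accuracy_: dict[str, float] = {}
        self.tuned_specs_ = []
        for spec in specs:
            if self.tune and spec.search_space:
                spec = tpe_optimize(
                    spec, X_fit, y_fit, X_val, y_val,
                    budget=self.tpe_budget, seed=self.random_state,
                )
            self.tuned_specs_.append(spec)
            model = make_estimator(spec, random_state=self.random_state)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X_fit, y_fit)
            self.models_[spec.name] = model
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.validation_accuracy_[spec.name] = float(
                    np.mean(model.predict(X_val) == y_val)
                )
        return self

    def _votes(self, X) -> dict[str, np.ndarray]:
        check_is_fitted(self, "models_")
        X = check_array(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return {
                name: m.predict(X).astype(int) for name, m in self.models_.items()
            }

    def predict_with_votes(self, X) -> list[VotingResult]:
        """Per-row votes, tallies, and the tie-break provenance."""
        votes = self._votes(X)
        names = list(votes)
        n = len(next(iter(votes.values())))
        results = []
        for i in range(n):
            per_model = {name: int(votes[name][i]) for name in names}
            tally: dict[int, int] = {}
            for lab in per_model.values():
                tally[lab] = tally.get(lab, 0) + 1
            top = max(tally.values())
            tied = sorted(lab for lab, c in tally.items() if c == top)
            if len(tied) == 1:
                results.append(
                    VotingResult(per_model, tally, final_label=tied[0])
                )
                continue
            # tie: most accurate model among those voting for a tied class
            best_name = max(
                (nm for nm in names if per_model[nm] in tied),
                key=lambda nm: self.validation_accuracy_[nm],
            )
            results.append(
                VotingResult(
                    per_model,
                    tally,
                    final_label=per_model[best_name],
                    tie_broken=True,
                    tie_breaker_model=best_name,
                )
            )
        return results

    def predict(self, X) -> np.ndarray:
        return np.array([r.final_label for r in self.predict_with_votes(X)])


def train_ensemble(
    specs: list[ModelSpec], X, y, random_state: int = 0, tune: bool = False
) -> MajorityVoteEnsemble:
    """Fit a :class:`MajorityVoteEnsemble` on the selected-feature table."""
    return MajorityVoteEnsemble(specs=specs, tune=tune, random_state=random_state).fit(X, y)


def majority_vote_predict(ensemble: MajorityVoteEnsemble, X) -> list[VotingResult]:
    return ensemble.predict_with_votes(X)
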