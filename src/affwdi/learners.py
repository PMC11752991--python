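"""Uniform adapter over the four base learners: LR, SVM, BPNN, XGBoost.

Each learner exposes the same contract — ``train`` on a finite feature
matrix with binary labels, then ``predict_proba`` for the positive-class
(poor prognosis) probability — together with a declared, documented
hyperparameter search space so the joint optimizer can tune any of them
through identical [0, 1] genes.

The BPNN is a single-hidden-layer perceptron (2-32 ReLU units, Adam, fixed
epoch budget and seed).  The gradient-boosted-tree role is filled by
xgboost's sklearn estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = ["HyperParam", "LearnerSpec", "LearnerState", "get_spec",
           "decode_hyperparameters", "train", "predict_proba", "LEARNER_KINDS"]

LEARNER_KINDS = ("lr", "svm", "bpnn", "xgboost")


@dataclass(frozen=True)
class HyperParam:
    """One tunable hyperparameter with its range and scale."""

    name: str
    low: float
    high: float
    scale: str = "linear"  # or "log"
    integer: bool = False

    def __post_init__(self):
        if self.low >= self.high:
            raise ValueError(f"{self.name}: degenerate range")
        if self.scale == "log" and self.low <= 0:
            raise ValueError(f"{self.name}: log-scaled range must be positive")

    def from_unit(self, gene: float) -> float:
        g = min(max(float(gene), 0.0), 1.0)
        if self.scale == "log":
            value = np.exp(np.log(self.low) + g * (np.log(self.high) - np.log(self.low)))
        else:
            value = self.low + g * (self.high - self.low)
        return int(round(value)) if self.integer else float(value)


@dataclass(frozen=True)
class LearnerSpec:
    """A learner kind, its hyperparameter space and the training seed."""

    kind: str
    params: tuple
    seed: int = 0

    @property
    def n_hyperparameters(self) -> int:
        return len(self.params)


_SPACES = {
    "lr": (HyperParam("C", 1e-3, 1e3, scale="log"),),
    "svm": (HyperParam("C", 1e-2, 1e3, scale="log"),
            HyperParam("gamma", 1e-4, 10.0, scale="log")),
    "bpnn": (HyperParam("hidden_units", 2, 32, integer=True),
             HyperParam("learning_rate", 1e-4, 1e-1, scale="log")),
    "xgboost": (HyperParam("n_estimators", 50, 500, integer=True),
                HyperParam("max_depth", 2, 8, integer=True),
                HyperParam("learning_rate", 0.01, 0.3),
                HyperParam("subsample", 0.5, 1.0)),
}


def get_spec(kind: str, seed: int = 0) -> LearnerSpec:
    key = kind.lower()
    if key not in _SPACES:
        raise ValueError(f"unknown learner kind {kind!r}; expected one of "
                         f"{LEARNER_KINDS}")
    return LearnerSpec(kind=key, params=_SPACES[key], seed=seed)


def decode_hyperparameters(spec: LearnerSpec, genes: Sequence[float]) -> dict:
    """Map [0, 1] genes onto the learner's documented ranges."""
    genes = np.asarray(genes, float)
    if genes.size != spec.n_hyperparameters:
        raise ValueError(f"{spec.kind} expects {spec.n_hyperparameters} "
                         f"hyperparameter genes, got {genes.size}")
    return {p.name: p.from_unit(g) for p, g in zip(spec.params, genes)}


def default_hyperparameters(spec: LearnerSpec) -> dict:
    """Mid-range settings (every gene at 0.5)."""
    return decode_hyperparameters(spec, np.full(spec.n_hyperparameters, 0.5))


@dataclass
class LearnerState:
    """A trained base learner plus enough context to validate prediction inputs."""

    kind: str
    estimator: object
    n_features: int
    columns: Optional[tuple] = None
    seed: int = 0


def _build(spec: LearnerSpec, hp: dict):
    if spec.kind == "lr":
        return LogisticRegression(C=hp["C"], max_iter=2000, solver="lbfgs")
    if spec.kind == "svm":
        return SVC(C=hp["C"], gamma=hp["gamma"], kernel="rbf",
                   probability=True, random_state=spec.seed)
    if spec.kind == "bpnn":
        return MLPClassifier(hidden_layer_sizes=(int(hp["hidden_units"]),),
                             learning_rate_init=hp["learning_rate"],
                             max_iter=300, random_state=spec.seed)
    if spec.kind == "xgboost":
        return XGBClassifier(n_estimators=int(hp["n_estimators"]),
                             max_depth=int(hp["max_depth"]),
                             learning_rate=hp["learning_rate"],
                             subsample=hp["subsample"],
                             n_jobs=1, tree_method="hist",
                             random_state=spec.seed, eval_metric="logloss",
                             verbosity=0)
    raise ValueError(f"unknown learner kind {spec.kind!r}")


def train(spec: LearnerSpec, features, labels,
          hyperparameters: Optional[dict] = None) -> LearnerState:
    """Train the configured learner; deterministic given ``spec.seed``."""
    columns = tuple(features.columns) if hasattr(features, "columns") else None
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain missing or non-finite values")
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class; a classifier needs both")
    hp = hyperparameters if hyperparameters is not None \
        else default_hyperparameters(spec)
    est = _build(spec, hp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return LearnerState(kind=spec.kind, estimator=est, n_features=X.shape[1],
                        columns=columns, seed=spec.seed)


def predict_proba(state: LearnerState, features) -> np.ndarray:
    """Positive-class probability per row."""
    columns = tuple(features.columns) if hasattr(features, "columns") else None
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != state.n_features:
        raise ValueError(f"expected {state.n_features} feature columns, got "
                         f"{X.shape[1] if X.ndim == 2 else 'a non-matrix'}")
    if state.columns is not None and columns is not None and columns != state.columns:
        raise ValueError(f"feature columns {columns} do not match the "
                         f"training columns {state.columns}")
    return state.estimator.predict_proba(X)[:, 1]
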