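"""AFFWDI: joint feature selection, feature weighting and hyperparameter tuning.

The Automatic Feature Filtering and Weight Determination Integrated model
encodes, in a single chromosome of genes in [0, 1]:

* one *mask* gene per candidate feature (gene >= 0.5 selects the feature;
  if nothing passes the threshold the single largest mask gene is selected),
* one *weight* gene per candidate feature, affinely mapped to a
  multiplicative scaling coefficient in [0.01, 1] applied to the
  standardized feature, and
* one gene per tunable hyperparameter of the chosen base learner, mapped to
  the learner's documented range.

A chromosome's fitness is the mean accuracy of a stratified k-fold
cross-validation of the base learner trained on Z-scored, weight-scaled,
selected features, so subsets, weights and hyperparameters are optimized
synchronously rather than in separate passes.  The improved Prairie Dog
Optimizer searches the chromosome space (maximizing fitness by minimizing
its negative).

Standardization parameters are always computed on the training side of each
fold (and, for the final refit, on the full training partition) and reused
verbatim on held-out data — never on the data being scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from . import learners as bl
from .metrics import confusion_metrics
from .pdo import OptimizerConfig, minimize

__all__ = ["Chromosome", "DecodedSolution", "decode", "cv_fitness",
           "AFFWDIClassifier", "WEIGHT_LOW", "WEIGHT_HIGH", "MASK_THRESHOLD"]

MASK_THRESHOLD = 0.5
WEIGHT_LOW = 0.01
WEIGHT_HIGH = 1.0


@dataclass(frozen=True)
class Chromosome:
    """Concatenated mask, weight and hyperparameter genes, all in [0, 1]."""

    genes: np.ndarray
    n_features: int
    n_hyperparameters: int

    def __post_init__(self):
        g = np.asarray(self.genes, float)
        expected = 2 * self.n_features + self.n_hyperparameters
        if g.size != expected:
            raise ValueError(f"chromosome needs {expected} genes "
                             f"(2 x {self.n_features} features + "
                             f"{self.n_hyperparameters} hyperparameters), "
                             f"got {g.size}")
        if np.any(g < 0) or np.any(g > 1):
            raise ValueError("genes must lie in [0, 1]")
        object.__setattr__(self, "genes", g)

    @property
    def mask_genes(self) -> np.ndarray:
        return self.genes[:self.n_features]

    @property
    def weight_genes(self) -> np.ndarray:
        return self.genes[self.n_features:2 * self.n_features]

    @property
    def hyper_genes(self) -> np.ndarray:
        return self.genes[2 * self.n_features:]


@dataclass(frozen=True)
class DecodedSolution:
    """A chromosome made concrete: which features, their weights, the settings."""

    selected_features: tuple
    selected_indices: tuple
    feature_weights: dict
    hyperparameters: dict


def decode(chromosome: Chromosome, feature_names: Sequence[str],
           learner_spec: bl.LearnerSpec) -> DecodedSolution:
    """Decode a chromosome against a feature list and a learner space.

    Mask genes at or above 0.5 select their feature; an empty selection is
    repaired by taking the single largest mask gene.  Weight genes map
    affinely onto [0.01, 1].
    """
    names = list(feature_names)
    if chromosome.n_features != len(names):
        raise ValueError(f"chromosome encodes {chromosome.n_features} features "
                         f"but {len(names)} names were given")
    if chromosome.n_hyperparameters != learner_spec.n_hyperparameters:
        raise ValueError(f"chromosome encodes {chromosome.n_hyperparameters} "
                         f"hyperparameters but {learner_spec.kind} has "
                         f"{learner_spec.n_hyperparameters}")
    mask = chromosome.mask_genes >= MASK_THRESHOLD
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(chromosome.mask_genes))] = True
    idx = tuple(int(i) for i in np.flatnonzero(mask))
    weights = WEIGHT_LOW + chromosome.weight_genes * (WEIGHT_HIGH - WEIGHT_LOW)
    return DecodedSolution(
        selected_features=tuple(names[i] for i in idx),
        selected_indices=idx,
        feature_weights={names[i]: float(weights[i]) for i in idx},
        hyperparameters=bl.decode_hyperparameters(learner_spec,
                                                  chromosome.hyper_genes),
    )


def _zscore_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)  # constant columns pass through centred
    return mu, sd


def cv_fitness(chromosome: Chromosome, X, y,
               learner_spec: bl.LearnerSpec,
               feature_names: Sequence[str],
               cv_folds: int = 5, seed: int = 0) -> float:
    """Mean stratified k-fold CV accuracy of the decoded solution in [0, 1]."""
    Xm = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(Xm)):
        raise ValueError("features contain missing or non-finite values")
    classes, counts = np.unique(yv, return_counts=True)
    if classes.size < 2:
        raise ValueError("training partition holds a single class")
    if counts.min() < cv_folds:
        raise ValueError(
            f"the rarer class has only {counts.min()} members — fewer than "
            f"{cv_folds} folds — so stratified folds would lose a class")
    sol = decode(chromosome, feature_names, learner_spec)
    cols = list(sol.selected_indices)
    w = np.array([sol.feature_weights[feature_names[i]] for i in cols])
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(Xm, yv):
        mu, sd = _zscore_params(Xm[np.ix_(tr, cols)])
        Xtr = (Xm[np.ix_(tr, cols)] - mu) / sd * w
        Xte = (Xm[np.ix_(te, cols)] - mu) / sd * w
        state = bl.train(learner_spec, Xtr, yv[tr], sol.hyperparameters)
        pred = (bl.predict_proba(state, Xte) >= 0.5).astype(int)
        accs.append(float(np.mean(pred == yv[te])))
    return float(np.mean(accs))


class AFFWDIClassifier(BaseEstimator, ClassifierMixin):
    """Joint feature-selection / weighting / tuning classifier.

    Parameters
    ----------
    base_learner : {"lr", "svm", "bpnn", "xgboost"}
        The base learner whose hyperparameters join the chromosome.
    cv_folds : int
        Folds of the stratified cross-validation that defines fitness.
    population_size, max_iterations, variant, mutation_probability, tent_alpha
        Forwarded to the prairie-dog optimizer; ``variant="ipdo"`` enables
        Tent chaotic initialization plus t-distribution mutation.
    patience : int or None
        Stop the search when the best fitness has not improved for this many
        iterations (fitness is also capped at 1, which always terminates the
        run early when reached).
    random_state : int
        Seeds the optimizer, the fold shuffling and the base learner.

    Attributes (after ``fit``)
    --------------------------
    selected_features_, feature_weights_, hyperparameters_ : the decoded
        best solution; ``mean_`` / ``scale_`` the Z-score parameters of the
        selected features on the fitted data; ``best_fitness_`` the best CV
        accuracy found; ``estimator_`` the refitted base learner.
    """

    def __init__(self, base_learner: str = "xgboost", cv_folds: int = 5,
                 population_size: int = 30, max_iterations: int = 200,
                 variant: str = "ipdo", mutation_probability: float = 0.5,
                 tent_alpha: float = 0.5, patience: Optional[int] = 20,
                 random_state: int = 0):
        self.base_learner = base_learner
        self.cv_folds = cv_folds
        self.population_size = population_size
        self.max_iterations = max_iterations
        self.variant = variant
        self.mutation_probability = mutation_probability
        self.tent_alpha = tent_alpha
        self.patience = patience
        self.random_state = random_state

    # -- internal -----------------------------------------------------------

    def _coerce_X(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), [str(c) for c in X.columns]
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        return Xm, [f"x{j}" for j in range(Xm.shape[1])]

    def _training_f1(self, chrom: Chromosome, Xm, yv, spec, names) -> float:
        sol = decode(chrom, names, spec)
        cols = list(sol.selected_indices)
        w = np.array([sol.feature_weights[names[i]] for i in cols])
        mu, sd = _zscore_params(Xm[:, cols])
        Xs = (Xm[:, cols] - mu) / sd * w
        state = bl.train(spec, Xs, yv, sol.hyperparameters)
        pred = (bl.predict_proba(state, Xs) >= 0.5).astype(int)
        rep = confusion_metrics(yv, pred)
        return rep.F1 if np.isfinite(rep.F1) else 0.0

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y) -> "AFFWDIClassifier":
        Xm, names = self._coerce_X(X)
        yv = np.asarray(y, dtype=int).ravel()
        if yv.size != Xm.shape[0]:
            raise ValueError("X and y have different lengths")
        if np.unique(yv).size < 2:
            raise ValueError("y holds a single class; nothing to discriminate")
        spec = bl.get_spec(self.base_learner, seed=self.random_state)
        n_feat = Xm.shape[1]
        n_genes = 2 * n_feat + spec.n_hyperparameters

        cache: dict[bytes, float] = {}
        records: list[tuple[np.ndarray, float]] = []

        def objective(genes: np.ndarray) -> float:
            g = np.clip(genes, 0.0, 1.0)
            key = np.round(g, 10).tobytes()
            if key not in cache:
                chrom = Chromosome(g.copy(), n_feat, spec.n_hyperparameters)
                fit_val = cv_fitness(chrom, Xm, yv, spec, names,
                                     cv_folds=self.cv_folds,
                                     seed=self.random_state)
                cache[key] = fit_val
                records.append((g.copy(), fit_val))
            return -cache[key]

        cfg = OptimizerConfig(
            dimension=n_genes, lower_bounds=np.zeros(n_genes),
            upper_bounds=np.ones(n_genes),
            population_size=self.population_size,
            max_iterations=self.max_iterations,
            seed=self.random_state, variant=self.variant,
            tent_alpha=self.tent_alpha,
            mutation_probability=self.mutation_probability,
            patience=self.patience, target_fitness=-1.0)
        result = minimize(objective, cfg)

        best_fit = max(f for _, f in records)
        # tie-break equal-fitness chromosomes: fewer selected features,
        # then higher full-training F1, then evaluation order
        ties = [(g, f) for g, f in records if f >= best_fit - 1e-12]
        chroms = [Chromosome(g, n_feat, spec.n_hyperparameters) for g, _ in ties]
        n_sel = [len(decode(c, names, spec).selected_indices) for c in chroms]
        fewest = min(n_sel)
        finalists = [c for c, k in zip(chroms, n_sel) if k == fewest][:20]
        if len(finalists) > 1:
            f1s = [self._training_f1(c, Xm, yv, spec, names) for c in finalists]
            best_chrom = finalists[int(np.argmax(f1s))]
        else:
            best_chrom = finalists[0]

        sol = decode(best_chrom, names, spec)
        cols = list(sol.selected_indices)
        mu, sd = _zscore_params(Xm[:, cols])
        w = np.array([sol.feature_weights[names[i]] for i in cols])
        Xs = (Xm[:, cols] - mu) / sd * w
        self.learner_state_ = bl.train(spec, Xs, yv, sol.hyperparameters)
        self.estimator_ = self.learner_state_.estimator
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = n_feat
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.best_chromosome_ = best_chrom
        self.selected_features_ = sol.selected_features
        self.selected_indices_ = sol.selected_indices
        self.feature_weights_ = dict(sol.feature_weights)
        self.hyperparameters_ = dict(sol.hyperparameters)
        self.mean_ = mu
        self.scale_ = sd
        self.best_fitness_ = best_fit
        self.n_evaluations_ = len(records)
        self.convergence_trace_ = -result.convergence_trace
        return self

    def _transform(self, X) -> np.ndarray:
        if not hasattr(self, "estimator_"):
            raise ValueError("this AFFWDIClassifier instance is not fitted yet")
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.selected_features_ if f not in X.columns]
            if missing:
                raise ValueError(f"missing selected feature(s): {missing}")
            sub = X[list(self.selected_features_)].to_numpy(dtype=float)
        else:
            Xm = np.asarray(X, dtype=float)
            if Xm.ndim != 2 or Xm.shape[1] != self.n_features_in_:
                raise ValueError(f"expected {self.n_features_in_} columns")
            sub = Xm[:, list(self.selected_indices_)]
        w = np.array([self.feature_weights_[f] for f in self.selected_features_])
        return (sub - self.mean_) / self.scale_ * w

    def predict_proba(self, X) -> np.ndarray:
        p1 = bl.predict_proba(self.learner_state_, self._transform(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        # the 0.5 boundary is labelled poor (class 1)
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def predict_record(self, record: dict) -> tuple[float, int]:
        """Risk probability and label for one patient record (a mapping).

        Raises ``ValueError`` naming any selected feature the record lacks.
        """
        missing = [f for f in self.selected_features_ if f not in record]
        if missing:
            raise ValueError(f"patient record is missing selected feature(s): "
                             f"{missing}")
        row = pd.DataFrame([{f: float(record[f])
                             for f in self.selected_features_}])
        prob = float(self.predict_proba(row)[0, 1])
        return prob, int(prob >= 0.5)
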