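"""Cohort-level training protocol: stratified split, fit, metric tables.

The protocol mirrors the study design the package emulates: 80% of the
cohort, stratified on outcome, trains the AFFWDI model (fitness = stratified
5-fold CV accuracy on the training partition only); the held-out 20% scores
generalization.  The test side of the split takes ``floor((1 - train_fraction)
* n_class)`` patients per class, so the default 207/96 cohort yields a test
partition of exactly 60 patients (41 good, 19 poor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd

from .cohort import OUTCOME_COLUMN
from .estimator import AFFWDIClassifier
from .metrics import METRIC_COLUMNS, MetricsReport, full_report

__all__ = ["stratified_split", "FittedModel", "train_evaluate", "predict_risk",
           "evaluate_all_learners", "save_model", "load_model", "model_card"]


def stratified_split(cohort: pd.DataFrame, train_fraction: float = 0.8,
                     outcome: str = OUTCOME_COLUMN,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outcome-stratified train/test split with floor rounding on the test side."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls, sub in cohort.groupby(outcome):
        n_test = int(np.floor((1.0 - train_fraction) * len(sub)))
        perm = rng.permutation(sub.index.to_numpy())
        test_idx.extend(perm[:n_test])
    test_mask = cohort.index.isin(test_idx)
    return cohort[~test_mask].copy(), cohort[test_mask].copy()


@dataclass
class FittedModel:
    """A trained AFFWDI classifier plus the protocol's bookkeeping."""

    classifier: AFFWDIClassifier
    feature_names: tuple
    train_metrics: MetricsReport
    test_metrics: MetricsReport
    best_fitness: float
    n_train: int
    n_test: int
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def selected_features(self) -> tuple:
        return self.classifier.selected_features_

    @property
    def feature_weights(self) -> dict:
        return self.classifier.feature_weights_

    @property
    def hyperparameters(self) -> dict:
        return self.classifier.hyperparameters_


def _partition_report(clf: AFFWDIClassifier, frame: pd.DataFrame,
                      outcome: str) -> MetricsReport:
    y = frame[outcome].to_numpy(dtype=int)
    scores = clf.predict_proba(frame.drop(columns=[outcome]))[:, 1]
    return full_report(y, scores)


def train_evaluate(cohort: pd.DataFrame, base_learner: str = "xgboost",
                   train_fraction: float = 0.8, cv_folds: int = 5,
                   population_size: int = 30, max_iterations: int = 200,
                   variant: str = "ipdo", patience: Optional[int] = 20,
                   seed: int = 0,
                   outcome: str = OUTCOME_COLUMN) -> FittedModel:
    """Run the full protocol on a cohort table and return the fitted model."""
    if outcome not in cohort.columns:
        raise ValueError(f"cohort has no outcome column {outcome!r}")
    if cohort[outcome].nunique() < 2:
        raise ValueError("cohort outcome holds a single class")
    if cohort.isna().any().any():
        raise ValueError("cohort contains missing values")
    train_df, test_df = stratified_split(cohort, train_fraction,
                                         outcome=outcome, seed=seed)
    clf = AFFWDIClassifier(base_learner=base_learner, cv_folds=cv_folds,
                           population_size=population_size,
                           max_iterations=max_iterations, variant=variant,
                           patience=patience, random_state=seed)
    clf.fit(train_df.drop(columns=[outcome]), train_df[outcome])
    return FittedModel(
        classifier=clf,
        feature_names=tuple(c for c in cohort.columns if c != outcome),
        train_metrics=_partition_report(clf, train_df, outcome),
        test_metrics=_partition_report(clf, test_df, outcome),
        best_fitness=clf.best_fitness_,
        n_train=len(train_df), n_test=len(test_df), seed=seed,
        config={"base_learner": base_learner, "train_fraction": train_fraction,
                "cv_folds": cv_folds, "population_size": population_size,
                "max_iterations": max_iterations, "variant": variant,
                "patience": patience, "seed": seed})


def predict_risk(model: FittedModel, patient_record: dict) -> tuple[float, int]:
    """Poor-prognosis probability and label (1 = poor; the 0.5 boundary is poor)."""
    return model.classifier.predict_record(patient_record)


def evaluate_all_learners(cohort: pd.DataFrame,
                          learner_kinds: Sequence[str] = ("lr", "svm", "bpnn",
                                                          "xgboost"),
                          **kwargs) -> tuple[pd.DataFrame, dict]:
    """Train every base learner under the same protocol.

    Returns a tidy metrics table (partition x learner x the seven metric
    columns) and the fitted models keyed by learner kind.
    """
    rows, models = [], {}
    for kind in learner_kinds:
        model = train_evaluate(cohort, base_learner=kind, **kwargs)
        models[kind] = model
        for partition, rep in (("train", model.train_metrics),
                               ("test", model.test_metrics)):
            rows.append({"learner": kind, "partition": partition,
                         **{k: getattr(rep, k) for k in METRIC_COLUMNS}})
    return pd.DataFrame(rows), models


def model_card(model: FittedModel) -> dict:
    """JSON-serializable summary of a fitted model."""
    def rep_dict(rep: MetricsReport) -> dict:
        return {k: (None if not np.isfinite(v) else float(v)) if
                isinstance(v, float) else v for k, v in rep.to_dict().items()}

    clf = model.classifier
    return {
        "selected_features": list(model.selected_features),
        "feature_weights": {k: float(v) for k, v in model.feature_weights.items()},
        "hyperparameters": {k: (int(v) if isinstance(v, (int, np.integer))
                                else float(v))
                            for k, v in model.hyperparameters.items()},
        "standardization": {
            "features": list(model.selected_features),
            "mean": [float(v) for v in clf.mean_],
            "sd": [float(v) for v in clf.scale_],
        },
        "best_cv_fitness": float(model.best_fitness),
        "n_train": model.n_train, "n_test": model.n_test,
        "seed": model.seed, "config": model.config,
        "train_metrics": rep_dict(model.train_metrics),
        "test_metrics": rep_dict(model.test_metrics),
    }


def save_model(model: FittedModel, path_prefix: str) -> tuple[str, str]:
    """Persist the model card (JSON) and the learner state (joblib)."""
    card_path = f"{path_prefix}.card.json"
    state_path = f"{path_prefix}.model.joblib"
    with open(card_path, "w") as fh:
        json.dump(model_card(model), fh, indent=2)
    joblib.dump(model, state_path)
    return card_path, state_path


def load_model(state_path: str) -> FittedModel:
    return joblib.load(state_path)
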