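"""Leakage-free model comparison and validation for FMA-UL prediction.

Eight standard regressors are compared on the development cohort with a
5-fold outer cross-validation; within every outer training partition a
5-fold grid search tunes hyperparameters on R2.  Standardization (and any
feature selection) is part of the pipeline, so it is refit on each training
partition only — the held-out fold and the independent test cohort are
always transformed with training-fit parameters.  The winning model is then
refit on the full development cohort with its hyperparameters fixed and
evaluated once on the independent test cohort.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import RFE
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeRegressor

from . import schema
from .errors import ConfigurationError, InsufficientDataError, LeakageError

__all__ = [
    "ModelSpec",
    "ModelEvaluation",
    "default_model_specs",
    "design_matrix",
    "kfold_split",
    "fit_fold_pipeline",
    "cross_validate",
    "select_best",
    "fit_final",
    "evaluate",
    "save_model",
    "load_model",
]

#: tie-break preference when models tie on mean R2: sparser / simpler first.
PREFERENCE_ORDER = (
    "lasso",
    "elastic_net",
    "ridge",
    "linear",
    "decision_tree",
    "extra_trees",
    "random_forest",
    "gradient_boosting",
)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate regressor: estimator factory plus hyperparameter grid.

    Grid keys use sklearn pipeline addressing (``model__<param>``).  With
    ``use_rfe`` a recursive-feature-elimination step (linear-regression
    ranked) is inserted between the scaler and the model.
    """

    name: str
    make: Callable[[int], object]
    grid: dict = field(default_factory=dict)
    use_rfe: bool = False
    rfe_n_features: int = 20

    def build(self, seed: int) -> Pipeline:
        steps = [("scaler", StandardScaler())]
        if self.use_rfe:
            steps.append(
                ("select", RFE(LinearRegression(), n_features_to_select=self.rfe_n_features))
            )
        steps.append(("model", self.make(seed)))
        return Pipeline(steps)


def default_model_specs(names: list[str] | None = None) -> dict[str, ModelSpec]:
    """The eight-regressor comparison set with its documented default grids."""
    specs = {
        "linear": ModelSpec("linear", lambda seed: LinearRegression()),
        "ridge": ModelSpec(
            "ridge",
            lambda seed: Ridge(),
            {"model__alpha": list(np.logspace(-2, 3, 20))},
        ),
        "lasso": ModelSpec(
            "lasso",
            lambda seed: Lasso(max_iter=100_000),
            {"model__alpha": list(np.logspace(-3, 1, 30))},
        ),
        "elastic_net": ModelSpec(
            "elastic_net",
            lambda seed: ElasticNet(max_iter=100_000),
            {
                "model__alpha": list(np.logspace(-3, 1, 10)),
                "model__l1_ratio": [0.2, 0.5, 0.8],
            },
        ),
        "decision_tree": ModelSpec(
            "decision_tree",
            lambda seed: DecisionTreeRegressor(random_state=seed),
            {"model__max_depth": [2, 3, 5, None]},
        ),
        "extra_trees": ModelSpec(
            "extra_trees",
            lambda seed: ExtraTreesRegressor(n_estimators=200, random_state=seed),
            {"model__max_depth": [5, None]},
        ),
        "random_forest": ModelSpec(
            "random_forest",
            lambda seed: RandomForestRegressor(n_estimators=200, random_state=seed),
            {"model__max_depth": [5, None]},
        ),
        "gradient_boosting": ModelSpec(
            "gradient_boosting",
            lambda seed: GradientBoostingRegressor(random_state=seed),
            {
                "model__n_estimators": [200],
                "model__learning_rate": [0.05, 0.1],
                "model__max_depth": [2, 3],
            },
        ),
    }
    if names is None:
        return specs
    unknown = set(names) - set(specs)
    if unknown:
        raise ConfigurationError(f"unknown model names: {sorted(unknown)}")
    return {n: specs[n] for n in names}


@dataclass
class ModelEvaluation:
    name: str
    seed: int
    internal_r2: float
    internal_mse: float
    internal_mae: float
    fold_metrics: list[dict]
    chosen_params: dict
    test_r2: float | None = None
    test_mse: float | None = None
    test_mae: float | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "seed": self.seed,
            "internal": {
                "r2": self.internal_r2,
                "mse": self.internal_mse,
                "mae": self.internal_mae,
                "folds": self.fold_metrics,
            },
            "chosen_params": {k: _plain(v) for k, v in self.chosen_params.items()},
            "test": None
            if self.test_r2 is None
            else {"r2": self.test_r2, "mse": self.test_mse, "mae": self.test_mae},
        }


def _plain(v):
    return v.item() if isinstance(v, np.generic) else v


# ---------------------------------------------------------------------------


def design_matrix(table: pd.DataFrame):
    """Split a labelled feature table into (subject_ids, X, y)."""
    missing = sorted(set(schema.FEATURE_NAMES) - set(table.columns))
    if missing:
        raise ConfigurationError(f"feature table lacks columns: {missing}")
    if table["fma_ul"].isna().any():
        raise ConfigurationError("labels (fma_ul) missing for some subjects")
    ids = table["subject_id"].to_list()
    X = table[list(schema.FEATURE_NAMES)].to_numpy(float)
    y = table["fma_ul"].to_numpy(float)
    return ids, X, y


def kfold_split(subject_ids, k: int = 5, seed: int = 0):
    """Seeded shuffled k-fold partition of subject ids; fold sizes differ by
    at most one, validation folds are disjoint and cover all subjects."""
    ids = list(subject_ids)
    if len(ids) < k:
        raise InsufficientDataError(f"cannot split {len(ids)} subjects into {k} folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        ([ids[i] for i in train], [ids[i] for i in val])
        for train, val in kf.split(ids)
    ]


def fit_fold_pipeline(
    train_X, train_y, spec: ModelSpec, params: dict | None = None, seed: int = 0
) -> Pipeline:
    """Fit scaler (+ optional selector) + model on the training partition only.

    A zero-variance training feature gets unit scale (the sklearn scaler
    convention), with a warning rather than an error.
    """
    train_X = np.asarray(train_X, float)
    if train_X.shape[0] < 2:
        raise InsufficientDataError("need at least 2 training subjects")
    pipe = spec.build(seed)
    if params:
        pipe.set_params(**params)
    if np.any(train_X.std(axis=0) == 0.0):
        warnings.warn("zero-variance training feature: scale fixed at 1", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        pipe.fit(train_X, np.asarray(train_y, float))
    return pipe


def _tune(spec: ModelSpec, X, y, inner_k: int, seed: int) -> dict:
    """Grid search on R2 within the given partition; {} for untuned models."""
    if not spec.grid:
        return {}
    cv = KFold(n_splits=min(inner_k, len(y)), shuffle=True, random_state=seed + 1)
    gs = GridSearchCV(spec.build(seed), spec.grid, scoring="r2", cv=cv, n_jobs=None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gs.fit(X, y)
    return dict(gs.best_params_)


def cross_validate(
    table: pd.DataFrame,
    specs: dict[str, ModelSpec] | None = None,
    k: int = 5,
    seed: int = 0,
    inner_k: int = 5,
) -> dict[str, ModelEvaluation]:
    """Nested cross-validation of every candidate model on the development table.

    Outer k-fold held-out metrics (mean R2 / MSE / MAE) are the internal
    validation performance; hyperparameters are re-tuned by an inner grid
    search inside each outer training partition, so no held-out fold ever
    influences tuning.  ``chosen_params`` (used for the final refit) come
    from a grid search over the whole development table.
    """
    specs = specs if specs is not None else default_model_specs()
    ids, X, y = design_matrix(table)
    if len(ids) < k:
        raise InsufficientDataError(f"{len(ids)} subjects cannot form {k} folds")
    outer = KFold(n_splits=k, shuffle=True, random_state=seed)

    results: dict[str, ModelEvaluation] = {}
    for name, spec in specs.items():
        fold_metrics = []
        for fold_i, (tr, va) in enumerate(outer.split(X)):
            params = _tune(spec, X[tr], y[tr], inner_k, seed)
            pipe = fit_fold_pipeline(X[tr], y[tr], spec, params, seed)
            pred = pipe.predict(X[va])
            fold_metrics.append(
                {
                    "fold": fold_i,
                    "r2": float(r2_score(y[va], pred)),
                    "mse": float(mean_squared_error(y[va], pred)),
                    "mae": float(mean_absolute_error(y[va], pred)),
                    "params": {p: _plain(v) for p, v in params.items()},
                }
            )
        chosen = _tune(spec, X, y, inner_k, seed)
        results[name] = ModelEvaluation(
            name=name,
            seed=seed,
            internal_r2=float(np.mean([m["r2"] for m in fold_metrics])),
            internal_mse=float(np.mean([m["mse"] for m in fold_metrics])),
            internal_mae=float(np.mean([m["mae"] for m in fold_metrics])),
            fold_metrics=fold_metrics,
            chosen_params=chosen,
        )
    return results


def select_best(results: dict[str, ModelEvaluation]) -> str:
    """Winner by mean held-out R2; exact ties go to the sparser/simpler model
    class in :data:`PREFERENCE_ORDER`."""
    def sort_key(name):
        pref = (
            PREFERENCE_ORDER.index(name)
            if name in PREFERENCE_ORDER
            else len(PREFERENCE_ORDER)
        )
        return (-results[name].internal_r2, pref)

    return min(results, key=sort_key)


def fit_final(
    table: pd.DataFrame, spec: ModelSpec, params: dict, seed: int = 0
) -> Pipeline:
    """Refit the winning pipeline on the entire development cohort with its
    hyperparameters fixed."""
    _, X, y = design_matrix(table)
    return fit_fold_pipeline(X, y, spec, params, seed)


def evaluate(
    model: Pipeline,
    test_table: pd.DataFrame,
    dev_subject_ids: list[str] | None = None,
) -> dict:
    """Independent-test metrics: R2 (about the test-set mean), MSE, MAE, and
    per-subject absolute errors.  Raises :class:`LeakageError` if any test
    subject also appears in the development cohort."""
    ids, X, y = design_matrix(test_table)
    if dev_subject_ids is not None:
        overlap = sorted(set(ids) & set(dev_subject_ids))
        if overlap:
            raise LeakageError(f"test subjects overlap development cohort: {overlap}")
    pred = model.predict(X)
    return {
        "r2": float(r2_score(y, pred)),
        "mse": float(mean_squared_error(y, pred)),
        "mae": float(mean_absolute_error(y, pred)),
        "per_subject": [
            {"subject_id": s, "y": float(yy), "pred": float(pp), "abs_err": float(abs(yy - pp))}
            for s, yy, pp in zip(ids, y, pred)
        ],
    }


# ---------------------------------------------------------------------------
# persistence (linear pipelines only: scaler parameters + coefficients)


def save_model(model: Pipeline, path: str | Path, meta: dict | None = None) -> None:
    """Persist a fitted scaler + linear-model pipeline as plain JSON."""
    scaler: StandardScaler = model.named_steps["scaler"]
    est = model.named_steps["model"]
    if not hasattr(est, "coef_"):
        raise ConfigurationError("only linear pipelines are persisted as JSON")
    payload = {
        "kind": type(est).__name__,
        "params": {k: _plain(v) for k, v in est.get_params().items()},
        "scaler_mean": scaler.mean_.tolist(),
        "scaler_scale": scaler.scale_.tolist(),
        "coef": np.asarray(est.coef_).tolist(),
        "intercept": float(np.atleast_1d(est.intercept_)[0]),
        "feature_names": list(schema.FEATURE_NAMES),
        "meta": meta or {},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_model(path: str | Path) -> Pipeline:
    """Reconstruct a persisted linear pipeline."""
    payload = json.loads(Path(path).read_text())
    kinds = {
        "Lasso": Lasso,
        "Ridge": Ridge,
        "ElasticNet": ElasticNet,
        "LinearRegression": LinearRegression,
    }
    est = kinds[payload["kind"]](**payload["params"])
    est.coef_ = np.asarray(payload["coef"], float)
    est.intercept_ = payload["intercept"]
    if hasattr(est, "n_iter_"):
        est.n_iter_ = 0
    est.n_features_in_ = len(payload["coef"])
    scaler = StandardScaler()
    scaler.mean_ = np.asarray(payload["scaler_mean"], float)
    scaler.scale_ = np.asarray(payload["scaler_scale"], float)
    scaler.var_ = scaler.scale_**2
    scaler.n_features_in_ = len(scaler.mean_)
    scaler.n_samples_seen_ = 1
    pipe = Pipeline([("scaler", scaler), ("model", est)])
    return pipe
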