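"""Exact SHAP attributions for the final linear model.

For a linear model f(x) = beta . x~ + b fitted on standardized features x~,
the interventional Shapley value of feature j for subject i has the closed
form

    phi[i, j] = beta_j * (x~[i, j] - mean_background(x~[., j]))

and the base value is the mean prediction over the background set, so
``base + sum_j phi[i, j]`` reconstructs every prediction to machine
precision.  This exactness is what makes the attributions auditable; no
sampling estimator is involved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline

from . import schema
from .errors import SchemaError

__all__ = [
    "ShapExplanation",
    "linear_shap",
    "shap_summary",
    "force_breakdown",
    "coefficient_ranking",
    "support",
]


class ShapExplanation:
    """Per-subject exact linear SHAP attributions.

    Attributes
    ----------
    base_value : float
        Mean model prediction over the background set.
    phi : ndarray, shape (n_subjects, n_features)
        Signed contributions in score units (FMA-UL points).
    predictions : ndarray, shape (n_subjects,)
        Model predictions for the query rows; ``base_value + phi.sum(1)``.
    """

    def __init__(self, base_value, phi, predictions, subject_ids, feature_names, query_X):
        self.base_value = float(base_value)
        self.phi = np.asarray(phi, float)
        self.predictions = np.asarray(predictions, float)
        self.subject_ids = list(subject_ids)
        self.feature_names = list(feature_names)
        self.query_X = np.asarray(query_X, float)

    def mean_abs_phi(self) -> np.ndarray:
        return np.abs(self.phi).mean(axis=0)

    def ranking(self) -> list[str]:
        order = np.argsort(self.mean_abs_phi())[::-1]
        return [self.feature_names[i] for i in order]

    def to_dict(self) -> dict:
        return {
            "base_value": self.base_value,
            "feature_names": self.feature_names,
            "mean_abs_phi": self.mean_abs_phi().tolist(),
            "subjects": [
                {
                    "subject_id": sid,
                    "prediction": float(self.predictions[i]),
                    "phi": self.phi[i].tolist(),
                }
                for i, sid in enumerate(self.subject_ids)
            ],
        }


def _linear_parts(model: Pipeline):
    scaler = model.named_steps["scaler"]
    est = model.named_steps["model"]
    if not hasattr(est, "coef_"):
        raise SchemaError("linear SHAP requires a linear model in the pipeline")
    return scaler, est


def linear_shap(
    model: Pipeline, background: pd.DataFrame, query: pd.DataFrame
) -> ShapExplanation:
    """Exact interventional SHAP values of a fitted linear pipeline.

    ``background`` defines the expectation (here: the development cohort);
    ``query`` holds the subjects to explain.  Both are per-subject feature
    tables with the full 112-biomarker schema.
    """
    scaler, est = _linear_parts(model)
    if len(background) == 0:
        raise SchemaError("background set must be non-empty")
    bg_ids, bg_X, _ = _features_only(background)
    q_ids, q_X, _ = _features_only(query)
    bg_std = scaler.transform(bg_X)
    q_std = scaler.transform(q_X)
    beta = np.asarray(est.coef_, float)
    bg_mean = bg_std.mean(axis=0)
    phi = beta * (q_std - bg_mean)
    base = float(est.intercept_ + beta @ bg_mean)
    preds = model.predict(q_X)
    return ShapExplanation(base, phi, preds, q_ids, list(schema.FEATURE_NAMES), q_X)


def _features_only(table: pd.DataFrame):
    """Like design_matrix but labels are not required (explanations need no y)."""
    missing = sorted(set(schema.FEATURE_NAMES) - set(table.columns))
    if missing:
        raise SchemaError(f"feature table lacks columns: {missing}")
    ids = (
        table["subject_id"].to_list()
        if "subject_id" in table
        else [str(i) for i in table.index]
    )
    return ids, table[list(schema.FEATURE_NAMES)].to_numpy(float), None


def shap_summary(expl: ShapExplanation, top_k: int = 10) -> pd.DataFrame:
    """Global importance table: features ranked by mean |phi| (descending),
    with the correlation between feature value and phi as the
    sign-association summary (negative: high values push the score down)."""
    mean_abs = expl.mean_abs_phi()
    order = np.argsort(mean_abs)[::-1][:top_k]
    rows = []
    for i in order:
        vals = expl.query_X[:, i]
        phis = expl.phi[:, i]
        if np.ptp(vals) > 0 and np.ptp(phis) > 0:
            assoc = float(np.corrcoef(vals, phis)[0, 1])
        else:
            assoc = 0.0
        rows.append(
            {
                "feature": expl.feature_names[i],
                "mean_abs_phi": float(mean_abs[i]),
                "value_phi_corr": assoc,
            }
        )
    return pd.DataFrame(rows)


def force_breakdown(expl: ShapExplanation, subject_id: str, top_k: int = 6) -> dict:
    """Instance explanation: f(x), base value, the top-k signed contributions
    by |phi| and the aggregated remainder; base + listed + remainder = f(x)
    exactly."""
    if subject_id not in expl.subject_ids:
        raise KeyError(f"unknown subject {subject_id!r}")
    i = expl.subject_ids.index(subject_id)
    phi = expl.phi[i]
    order = np.argsort(np.abs(phi))[::-1]
    listed = [
        {
            "feature": expl.feature_names[j],
            "value": float(expl.query_X[i, j]),
            "phi": float(phi[j]),
        }
        for j in order[:top_k]
    ]
    remainder = float(phi[order[top_k:]].sum()) if top_k < len(phi) else 0.0
    return {
        "subject_id": subject_id,
        "f_x": float(expl.predictions[i]),
        "base_value": expl.base_value,
        "contributions": listed,
        "remainder": remainder,
    }


def coefficient_ranking(model: Pipeline, top_k: int = 10) -> list[tuple[str, float]]:
    """Nonzero model coefficients (standardized scale) sorted by |beta|
    descending; at most ``top_k`` entries."""
    _, est = _linear_parts(model)
    beta = np.asarray(est.coef_, float)
    nz = np.flatnonzero(beta != 0.0)
    order = nz[np.argsort(np.abs(beta[nz]))[::-1]]
    return [(schema.FEATURE_NAMES[i], float(beta[i])) for i in order[:top_k]]


def support(model: Pipeline, tol: float = 1e-8) -> set[str]:
    """Feature names with |coefficient| above ``tol`` (standardized scale)."""
    _, est = _linear_parts(model)
    beta = np.asarray(est.coef_, float)
    return {schema.FEATURE_NAMES[i] for i in np.flatnonzero(np.abs(beta) > tol)}
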