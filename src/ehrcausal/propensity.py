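"""Propensity-score models, IPTW weights, and covariate balance diagnostics.

Two model families, one per confounder representation:

* ``lr``: L1-penalized (sparse) logistic regression for the high-dimensional
  one-hot matrix; the penalty strength is picked from a small fixed grid by
  3-fold cross-validated log-loss;
* ``rf``: random forest for the dense embedding matrix, where a sparse
  linear model is no longer the natural fit.

Predicted scores are clipped symmetrically away from 0 and 1 (positivity),
then converted to unstabilized inverse-probability weights: 1/p for treated,
1/(1-p) for comparators. Normalization happens inside the Hajek estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

DEFAULT_C_GRID = (0.3, 3.0)


@dataclass
class PropensityModelSpec:
    """Hyperparameters for one propensity fit; family is fixed per fit."""

    family: str = "lr"  # "lr" | "rf"
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    cv_folds: int = 3
    tol: float = 1e-2  # liblinear stopping tolerance; loose is plenty for weighting
    n_trees: int = 200
    max_depth: int | None = None
    min_leaf: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("lr", "rf"):
            raise ValueError(f"unknown model family {self.family!r}")
        if any(c <= 0 for c in self.C_grid) or self.n_trees <= 0 or self.min_leaf <= 0:
            raise ValueError("hyperparameters must be strictly positive")


def _check_matrix(matrix, labels) -> None:
    if matrix.shape[0] != len(labels):
        raise ValueError("matrix row count must equal label count")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class; propensity model needs both arms")
    data = matrix.data if sp.issparse(matrix) else matrix
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite feature values")


def fit_propensity(matrix, labels, spec: PropensityModelSpec):
    """Fit the treatment-assignment model P(treated | covariates).

    For ``lr`` with more than one grid value, the L1 strength is chosen by
    3-fold cross-validated log-loss with a fold split fixed by the spec seed;
    a length-1 grid skips the search (the reduced-grid mode used inside
    bootstrap replicates).
    """
    _check_matrix(matrix, labels)
    labels = np.asarray(labels)
    if spec.family == "lr":
        if len(spec.C_grid) > 1:
            cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
            losses = []
            for C in spec.C_grid:
                fold_losses = []
                for tr, te in cv.split(matrix, labels):
                    m = LogisticRegression(
                        l1_ratio=1.0, C=C, solver="liblinear", tol=spec.tol, random_state=spec.seed
                    )
                    m.fit(matrix[tr], labels[tr])
                    fold_losses.append(
                        log_loss(labels[te], m.predict_proba(matrix[te])[:, 1], labels=[0, 1])
                    )
                losses.append(np.mean(fold_losses))
            best_C = spec.C_grid[int(np.argmin(losses))]
        else:
            best_C = spec.C_grid[0]
        model = LogisticRegression(
            l1_ratio=1.0, C=best_C, solver="liblinear", tol=spec.tol, random_state=spec.seed
        )
        model.fit(matrix, labels)
        return model
    model = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_depth=spec.max_depth,
        min_samples_leaf=spec.min_leaf,
        random_state=spec.seed,
        n_jobs=1,
    )
    model.fit(matrix, labels)
    return model


def predict_propensity(model, matrix, eps: float = 0.01) -> np.ndarray:
    """Predicted P(treated | x), clipped into [eps, 1 - eps] (positivity)."""
    if not (0 < eps < 0.5):
        raise ValueError("eps must be in (0, 0.5)")
    n_feat = getattr(model, "n_features_in_", None)
    if n_feat is not None and matrix.shape[1] != n_feat:
        raise ValueError(
            f"matrix has {matrix.shape[1]} columns but model was trained on {n_feat}"
        )
    p = model.predict_proba(matrix)[:, 1]
    return np.clip(p, eps, 1.0 - eps)


def compute_weights(scores: np.ndarray, labels) -> np.ndarray:
    """Unstabilized IPTW weights: treated 1/p, comparator 1/(1-p)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    if np.any(scores <= 0) or np.any(scores >= 1):
        raise ValueError("propensity scores must lie in (0, 1); clip before weighting")
    return np.where(labels == 1, 1.0 / scores, 1.0 / (1.0 - scores))


def balance_diagnostics(matrix, labels, weights=None):
    """Per-covariate standardized mean differences, weighted and unweighted.

    SMD = (weighted treated mean - weighted comparator mean) / pooled
    unweighted SD. Zero-variance covariates are reported as SMD 0 with a
    flag. Returns ``(smd_before, smd_after, zero_variance_mask)``.
    """
    labels = np.asarray(labels)
    X = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix, dtype=float)
    if weights is None:
        weights = np.ones(len(labels))
    weights = np.asarray(weights, dtype=float)
    t, c = labels == 1, labels == 0

    var_t = X[t].var(axis=0, ddof=1)
    var_c = X[c].var(axis=0, ddof=1)
    pooled_sd = np.sqrt((var_t + var_c) / 2.0)
    zero_var = pooled_sd == 0

    def _wmean(mask):
        w = weights[mask]
        return (w[:, None] * X[mask]).sum(axis=0) / w.sum()

    with np.errstate(invalid="ignore", divide="ignore"):
        before = (X[t].mean(axis=0) - X[c].mean(axis=0)) / pooled_sd
        after = (_wmean(t) - _wmean(c)) / pooled_sd
    before[zero_var] = 0.0
    after[zero_var] = 0.0
    return before, after, zero_var
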