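"""ATE estimation: unadjusted and IPTW point estimates, bootstrap inference,
negative-control suite, and the all-pairs active-comparator matrix.

The estimand is a risk difference: mean hospitalization probability under
treatment minus under no treatment. The weighted estimator is the Hajek
(normalized) form

    ATE_w = sum_T(w h) / sum_T(w) - sum_C(w h) / sum_C(w),

which reduces exactly to the unadjusted difference in means when all weights
are equal. Confidence intervals come from a stratified nonparametric
bootstrap (resampling persons with replacement within each arm, arm sizes
preserved) in which the propensity model is refit on every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm

from .cohort import (
    CohortPair,
    build_active_comparator_cohorts,
)
from .features import Vocabulary, build_design_matrices
from .propensity import PropensityModelSpec, compute_weights, fit_propensity, predict_propensity


@dataclass
class ATEEstimate:
    """Point estimate with bootstrap CI and p-values for one contrast/method."""

    contrast_name: str
    method: str  # "one_hot_lr" | "embedding_rf" | "unadjusted"
    ate: float
    ci_low: float
    ci_high: float
    p_value: float  # headline: normal approximation from the bootstrap SE
    p_sign: float  # sign-count bootstrap p with continuity correction
    n_treated: int
    n_comparator: int
    n_bootstrap: int
    se: float = float("nan")
    estimable: bool = True

    def covers_zero(self) -> bool:
        return self.ci_low <= 0.0 <= self.ci_high

    @property
    def significant(self) -> bool:
        return self.estimable and not self.covers_zero()


def unadjusted_ate(outcomes, labels) -> float:
    """Difference in mean outcomes: treated minus comparator."""
    outcomes = np.asarray(outcomes, dtype=float)
    labels = np.asarray(labels)
    t, c = labels == 1, labels == 0
    if not t.any() or not c.any():
        raise ValueError("both arms must be nonempty")
    return float(outcomes[t].mean() - outcomes[c].mean())


def iptw_ate(outcomes, labels, weights, normalized: bool = True) -> float:
    """Weighted risk difference; Hajek-normalized by default.

    ``normalized=False`` gives the Horvitz-Thompson form, dividing each arm's
    weighted outcome sum by the arm size rather than the weight total.
    """
    outcomes = np.asarray(outcomes, dtype=float)
    labels = np.asarray(labels)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be strictly positive")
    t, c = labels == 1, labels == 0
    if not t.any() or not c.any():
        raise ValueError("both arms must be nonempty")
    wt, wc = weights[t], weights[c]
    if normalized:
        return float((wt * outcomes[t]).sum() / wt.sum() - (wc * outcomes[c]).sum() / wc.sum())
    return float((wt * outcomes[t]).sum() / t.sum() - (wc * outcomes[c]).sum() / c.sum())


def _pvalues(point: float, boots: np.ndarray) -> tuple[float, float, float]:
    B = len(boots)
    n_le = int(np.sum(boots <= 0.0))
    n_ge = int(np.sum(boots >= 0.0))
    p_sign = min(1.0, 2.0 * min(n_le + 1, n_ge + 1) / (B + 1))
    se = float(np.std(boots, ddof=1)) if B > 1 else float("nan")
    if se > 0:
        p_norm = float(2.0 * norm.sf(abs(point) / se))
        p_norm = max(p_norm, 1e-300)
    else:
        p_norm = 1.0 if point == 0.0 else 1e-300
    return p_norm, p_sign, se


def bootstrap_estimate(
    estimator,
    labels,
    B: int = 100,
    seed: int = 0,
    point: float | None = None,
    contrast_name: str = "",
    method: str = "",
) -> ATEEstimate:
    """Stratified bootstrap around an estimator closure.

    ``estimator(idx)`` must return the ATE computed on rows ``idx`` —
    including refitting the propensity model on the resampled rows. Each
    replicate resamples persons with replacement within each arm, keeping
    arm sizes fixed. A replicate whose estimator fails (e.g. a degenerate
    refit) is redrawn, with a cap of 10*B attempts. CI is the 2.5/97.5
    percentile interval of the B replicate estimates.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    labels = np.asarray(labels)
    t_idx = np.flatnonzero(labels == 1)
    c_idx = np.flatnonzero(labels == 0)
    rng = np.random.default_rng(seed)
    if point is None:
        point = estimator(np.arange(len(labels)))
    boots = []
    attempts = 0
    while len(boots) < B:
        if attempts >= 10 * B:
            raise RuntimeError(f"bootstrap failed to obtain {B} replicates in {attempts} draws")
        attempts += 1
        idx = np.concatenate(
            [rng.choice(t_idx, size=len(t_idx)), rng.choice(c_idx, size=len(c_idx))]
        )
        try:
            boots.append(estimator(idx))
        except (ValueError, RuntimeError):
            continue
    boots = np.asarray(boots)
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    p_norm, p_sign, se = _pvalues(point, boots)
    return ATEEstimate(
        contrast_name=contrast_name,
        method=method,
        ate=float(point),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p_norm,
        p_sign=p_sign,
        n_treated=len(t_idx),
        n_comparator=len(c_idx),
        n_bootstrap=B,
        se=se,
    )


def estimate_contrast(
    matrix,
    labels,
    outcomes,
    method: str = "one_hot_lr",
    spec: PropensityModelSpec | None = None,
    B: int = 100,
    seed: int = 0,
    eps: float = 0.01,
    contrast_name: str = "",
    refit: bool = True,
    normalized: bool = True,
) -> ATEEstimate:
    """Full estimation for one contrast: point ATE plus bootstrap CI.

    For the weighted methods the full-sample fit (with the full model grid
    for ``lr``) gives the point estimate; bootstrap replicates refit the
    model on the resampled rows with the selected penalty strength only
    (reduced grid), which keeps refit-per-replicate honest and affordable.
    ``refit=False`` reuses the full-sample weights in replicates — a fast
    mode for testing, never for reported CIs.
    """
    labels = np.asarray(labels)
    outcomes = np.asarray(outcomes, dtype=float)
    if method == "unadjusted":
        est = bootstrap_estimate(
            lambda idx: unadjusted_ate(outcomes[idx], labels[idx]),
            labels,
            B=B,
            seed=seed,
            contrast_name=contrast_name,
            method=method,
        )
        return est

    if spec is None:
        spec = PropensityModelSpec(family="lr" if method == "one_hot_lr" else "rf", seed=seed)
    model = fit_propensity(matrix, labels, spec)
    p = predict_propensity(model, matrix, eps=eps)
    w = compute_weights(p, labels)
    point = iptw_ate(outcomes, labels, w, normalized=normalized)

    if spec.family == "lr":
        best_C = float(model.C)
        rep_spec = PropensityModelSpec(
            family="lr", C_grid=(best_C,), seed=spec.seed, cv_folds=spec.cv_folds
        )
    else:
        rep_spec = spec

    def replicate(idx):
        Xi = matrix[idx]
        li = labels[idx]
        if refit:
            mi = fit_propensity(Xi, li, rep_spec)
            pi = predict_propensity(mi, Xi, eps=eps)
            wi = compute_weights(pi, li)
        else:
            wi = w[idx]
        return iptw_ate(outcomes[idx], li, wi, normalized=normalized)

    return bootstrap_estimate(
        replicate,
        labels,
        B=B,
        seed=seed,
        point=point,
        contrast_name=contrast_name,
        method=method,
    )


def _inestimable(contrast_name: str, method: str, n_t: int, n_c: int) -> ATEEstimate:
    nan = float("nan")
    return ATEEstimate(
        contrast_name=contrast_name,
        method=method,
        ate=nan,
        ci_low=nan,
        ci_high=nan,
        p_value=1.0,
        p_sign=1.0,
        n_treated=n_t,
        n_comparator=n_c,
        n_bootstrap=0,
        estimable=False,
    )


def negative_control_suite(
    cohort: CohortPair,
    persons: pd.DataFrame,
    code_events: pd.DataFrame,
    vocab: Vocabulary,
    nc_codes,
    method: str = "one_hot_lr",
    spec: PropensityModelSpec | None = None,
    table=None,
    B: int = 100,
    seed: int = 0,
    eps: float = 0.01,
) -> list[ATEEstimate]:
    """Run the identical estimation pipeline on each negative-control outcome.

    For each control code the outcome is presence of that code in the
    person's history, and the code itself is removed from the confounder set
    (its vocabulary column, and the code itself from embedding averages) so
    the analysis never conditions on its own outcome. Controls with zero or
    full prevalence in the cohort are reported as inestimable rather than
    raised.
    """
    results = []
    for k, nc in enumerate(nc_codes):
        name = f"nc:{nc}"
        ev = code_events[code_events["code"] != nc]
        voc = vocab.drop([nc])
        X, labels, ids = build_design_matrices(
            cohort, "one_hot" if method == "one_hot_lr" else "embedding",
            persons, ev, voc, table=table,
        )
        has_nc = set(code_events.loc[code_events["code"] == nc, "person_id"])
        outcomes = np.fromiter((pid in has_nc for pid in ids), dtype=float, count=len(ids))
        n_t = int(labels.sum())
        n_c = int(len(labels) - n_t)
        if outcomes.sum() in (0.0, float(len(outcomes))):
            results.append(_inestimable(name, method, n_t, n_c))
            continue
        results.append(
            estimate_contrast(
                X, labels, outcomes,
                method=method, spec=spec, B=B, seed=seed + 1000 * (k + 1), eps=eps,
                contrast_name=name,
            )
        )
    return results


@dataclass
class ComparatorMatrix:
    """Square grid of head-to-head estimates; cell (A, B) treats A against B."""

    drugs: list[str]
    cells: dict = field(default_factory=dict)  # (drug_a, drug_b) -> ATEEstimate | None

    def get(self, a: str, b: str):
        return self.cells.get((a, b))

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: rows treated drug, columns comparator drug, ATE values."""
        mat = pd.DataFrame(index=self.drugs, columns=self.drugs, dtype=float)
        for (a, b), est in self.cells.items():
            if est is not None and est.estimable:
                mat.loc[a, b] = est.ate
        return mat

    def antisymmetry_report(self) -> pd.DataFrame:
        """|ate(A,B) + ate(B,A)| per unordered pair; reported, not enforced
        (independent refits break exact antisymmetry)."""
        rows = []
        for i, a in enumerate(self.drugs):
            for b in self.drugs[i + 1 :]:
                ab, ba = self.get(a, b), self.get(b, a)
                if ab is not None and ba is not None and ab.estimable and ba.estimable:
                    rows.append({"drug_a": a, "drug_b": b, "asym": abs(ab.ate + ba.ate)})
        return pd.DataFrame(rows)


def comparator_matrix(
    eligible: set,
    exposures: pd.DataFrame,
    persons: pd.DataFrame,
    code_events: pd.DataFrame,
    vocab: Vocabulary,
    outcomes_by_person: pd.Series,
    drugs,
    method: str = "one_hot_lr",
    spec: PropensityModelSpec | None = None,
    table=None,
    B: int = 100,
    seed: int = 0,
    eps: float = 0.01,
) -> ComparatorMatrix:
    """All ordered head-to-head contrasts among ``drugs`` (diagonal empty).

    16 drugs give 240 cells. Cells whose cohort construction fails (an empty
    arm after excluding dual users) are flagged missing rather than raised.
    """
    drugs = list(drugs)
    if len(drugs) < 2:
        raise ValueError("need at least two drugs for an active-comparator matrix")
    out = ComparatorMatrix(drugs=drugs)
    for i, a in enumerate(drugs):
        for j, b in enumerate(drugs):
            if a == b:
                continue
            try:
                pair = build_active_comparator_cohorts(eligible, exposures, a, b)
            except ValueError:
                out.cells[(a, b)] = None
                continue
            X, labels, ids = build_design_matrices(
                pair, "one_hot" if method != "embedding_rf" else "embedding",
                persons, code_events, vocab, table=table,
            )
            h = outcomes_by_person.loc[ids].to_numpy(dtype=float)
            try:
                est = estimate_contrast(
                    X, labels, h,
                    method=method, spec=spec, B=B,
                    seed=seed + 97 * (16 * i + j), eps=eps,
                    contrast_name=pair.contrast_name,
                )
            except (ValueError, RuntimeError):
                est = _inestimable(pair.contrast_name, method, int(labels.sum()), int(len(labels) - labels.sum()))
            out.cells[(a, b)] = est
    return out
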