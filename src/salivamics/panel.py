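"""Greedy forward construction of small biomarker panels.

Panels (at most four markers) are scored by the AUC of leave-one-out
cross-validated logistic probabilities: for each sample, a logistic model
is fit on all other samples (features standardized with training-fold
statistics only, a tiny ridge keeping quasi-separated fits finite) and the
held-out predicted probability becomes that sample's score. Markers are
added greedily starting from the best single marker, each step adding the
candidate giving the biggest strict AUC improvement. Sensitivity at a
fixed specificity (default 0.95) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import OmicsMatrix
from .ranking import ROCResult, roc_auc, univariate_stats


def fit_ridge_logistic(
    x: np.ndarray, y: np.ndarray, ridge: float = 1e-6,
    max_iter: int = 200, tol: float = 1e-10,
) -> np.ndarray:
    """Newton/IRLS fit of a logistic model with an L2 penalty on the slopes.

    Returns [intercept, coefficients...]. The ridge guarantees a finite
    optimum under complete separation; the objective is checked each step
    with step-halving, and log-odds are clipped at +-35 before the sigmoid
    so saturated fits stay numerically stable.
    """
    n, p = x.shape
    xb = np.hstack([np.ones((n, 1)), x])
    w = np.zeros(p + 1)
    penalty_mask = np.r_[0.0, np.ones(p)]

    def objective(wv: np.ndarray) -> float:
        eta = np.clip(xb @ wv, -35, 35)
        return float(
            -np.sum(y * eta - np.logaddexp(0.0, eta))
            + 0.5 * ridge * np.sum(penalty_mask * wv**2)
        )

    obj = objective(w)
    for _ in range(max_iter):
        eta = np.clip(xb @ w, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = xb.T @ (y - mu) - ridge * penalty_mask * w
        wdiag = np.maximum(mu * (1.0 - mu), 1e-12)
        hess = (xb * wdiag[:, None]).T @ xb + ridge * np.diag(penalty_mask)
        step = np.linalg.solve(hess, grad)
        # step-halving line search on the penalized deviance
        t = 1.0
        for _ in range(30):
            new_obj = objective(w + t * step)
            if new_obj <= obj + 1e-12:
                break
            t /= 2.0
        w = w + t * step
        if abs(obj - new_obj) < tol * (1.0 + abs(obj)) and np.max(np.abs(t * step)) < 1e-6:
            obj = new_obj
            break
        obj = new_obj
    return w


def predict_proba(w: np.ndarray, x: np.ndarray) -> np.ndarray:
    eta = np.clip(w[0] + x @ w[1:], -35, 35)
    return 1.0 / (1.0 + np.exp(-eta))


def loocv_logistic_auc(
    x: np.ndarray, labels, ridge: float = 1e-6
) -> tuple[np.ndarray, ROCResult]:
    """Held-out logistic probabilities for every sample, and their AUC.

    ``x`` is samples x features. Each training fold standardizes features
    with its own mean/SD before fitting, so results are invariant to affine
    rescaling of the inputs.
    """
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels).astype(int)
    n = len(y)
    if n < 8:
        raise ValueError(f"need >= 8 samples for LOOCV, got {n}")
    if min(int(y.sum()), int(n - y.sum())) < 4:
        raise ValueError("both classes need >= 4 members")
    probs = np.empty(n)
    for i in range(n):
        tr = np.ones(n, bool)
        tr[i] = False
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a training fold lost a class")
        mu = x[tr].mean(axis=0)
        sd = x[tr].std(axis=0)
        sd[sd == 0] = 1.0
        w = fit_ridge_logistic((x[tr] - mu) / sd, y[tr], ridge=ridge)
        probs[i] = predict_proba(w, (x[i] - mu) / sd)
    return probs, roc_auc(probs, y)


@dataclass
class PanelModel:
    """Ordered marker panel with its LOOCV performance."""

    members: list
    probabilities: np.ndarray
    auc: float
    sensitivity_at_spec: float
    target_specificity: float
    trace: list = field(default_factory=list)  # (feature, auc) per addition
    pool_size: int = 0


def sens_at_spec(roc: ROCResult, target_specificity: float = 0.95) -> float:
    """Max sensitivity over thresholds with specificity >= target.

    Conservative convention: no interpolation between ROC points; if only
    the degenerate all-negative threshold reaches the target, the reported
    sensitivity is that point's (possibly zero) value.
    """
    if not 0 < target_specificity < 1:
        raise ValueError("target specificity must be in (0, 1)")
    ok = roc.specificity >= target_specificity
    if not ok.any():
        return 0.0
    return float(roc.sensitivity[ok].max())


def greedy_panel(
    matrix: OmicsMatrix,
    labels,
    candidates: list | None = None,
    max_size: int = 4,
    start_feature: str | None = None,
    target_specificity: float = 0.95,
    ridge: float = 1e-6,
) -> PanelModel:
    """Greedy forward panel search scored by LOOCV logistic AUC.

    Starting from ``start_feature`` (default: the candidate with the
    highest orientation-free univariate AUC), each step evaluates the
    LOOCV AUC of the current panel plus every remaining candidate and adds
    the arg-max — but only if it strictly improves the AUC. AUC ties are
    broken by the smaller sum of |panel coefficients|, then feature id.
    Stops at ``max_size`` (panels stay small by design: n < 5).
    """
    matrix.require_state("imputed")
    y = np.asarray(labels).astype(int)
    if candidates is None:
        candidates = list(matrix.feature_ids)
    if not candidates:
        raise ValueError("candidate list is empty")
    missing = set(candidates) - set(matrix.feature_ids)
    if missing:
        raise ValueError(f"candidates not in matrix: {sorted(missing)[:5]}")
    values = matrix.values

    if start_feature is None:
        uni = univariate_stats(matrix, y)
        uni = uni[uni["feature_id"].isin(candidates)]
        start_feature = uni.sort_values(
            ["auc_star", "feature_id"], ascending=[False, True]
        )["feature_id"].iloc[0]
    elif start_feature not in candidates:
        raise ValueError(f"start_feature {start_feature!r} not among candidates")

    members = [start_feature]
    probs, roc = loocv_logistic_auc(values.loc[members].to_numpy(float).T, y, ridge)
    trace = [(start_feature, roc.auc)]
    remaining = [c for c in candidates if c != start_feature]

    while len(members) < max_size and remaining:
        best = None  # (auc, coef_l1, feature, probs, roc)
        for cand in remaining:
            x = values.loc[members + [cand]].to_numpy(float).T
            cand_probs, cand_roc = loocv_logistic_auc(x, y, ridge)
            mu, sd = x.mean(axis=0), x.std(axis=0)
            sd[sd == 0] = 1.0
            coef_l1 = float(np.abs(fit_ridge_logistic((x - mu) / sd, y, ridge)[1:]).sum())
            key = (-cand_roc.auc, coef_l1, cand)
            if best is None or key < best[0]:
                best = (key, cand, cand_probs, cand_roc)
        _, cand, cand_probs, cand_roc = best
        if cand_roc.auc <= roc.auc:
            break
        members.append(cand)
        remaining.remove(cand)
        probs, roc = cand_probs, cand_roc
        trace.append((cand, roc.auc))

    aucs = [a for _, a in trace]
    assert all(b > a for a, b in zip(aucs, aucs[1:])), "AUC trace must strictly increase"
    return PanelModel(
        members=members,
        probabilities=probs,
        auc=roc.auc,
        sensitivity_at_spec=sens_at_spec(roc, target_specificity),
        target_specificity=target_specificity,
        trace=trace,
        pool_size=len(candidates),
    )
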