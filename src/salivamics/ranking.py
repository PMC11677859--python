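"""Univariate marker statistics and resampled ensemble importance ranking.

AUCs are computed by rank statistics (tie-aware Mann-Whitney probability).
The ensemble ranker repeats three importance methods — an L1-penalized
logistic model and two gradient-boosted tree variants — on random
subsamples of the cohort (5/6 subsamples for the first two, a 75% training
split for the third), counts how often each feature enters the per-run
top-k importance list, and sums the counts across methods and repeats into
one overall stability rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
import xgboost as xgb

from .datatypes import OmicsMatrix

logger = logging.getLogger(__name__)

RANKER_IDS = ("sparse_linear_l1", "boosted_trees_a", "boosted_trees_b")


@dataclass
class ROCResult:
    """AUC plus the full ROC curve (per-threshold sensitivity/specificity)."""

    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    positive_class: str = "case"


def roc_auc(scores, labels, positive_class: str = "case") -> ROCResult:
    """Tie-aware AUC: P(score_case > score_control) + 0.5 * P(tie).

    ``labels`` is boolean/0-1 with 1 marking the positive (case) class.
    One-vs-all comparisons (control vs MCI and AD combined) are handled by
    relabeling upstream.
    """
    scores = np.asarray(scores, float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thresholds = roc_curve(y.astype(int), scores)
    return ROCResult(
        auc=float(auc),
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        positive_class=positive_class,
    )


def univariate_stats(matrix: OmicsMatrix, labels) -> pd.DataFrame:
    """Per-feature log2FC, unpaired t-test p and AUC for a binary contrast.

    ``auc_star`` is the orientation-free max(AUC, 1-AUC) used for ranking;
    the raw AUC (cases as the positive class) is retained.
    """
    matrix.require_state("imputed")
    y = np.asarray(labels).astype(bool)
    values = matrix.values.to_numpy(float)
    x_ctrl, x_case = values[:, ~y], values[:, y]
    log2fc = x_case.mean(axis=1) - x_ctrl.mean(axis=1)
    _, p = stats.ttest_ind(x_case, x_ctrl, axis=1)
    aucs = np.array([roc_auc(row, y).auc for row in values])
    return pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "log2fc": log2fc,
        "p": p,
        "auc": aucs,
        "auc_star": np.maximum(aucs, 1.0 - aucs),
    })


@dataclass
class RankerConfig:
    n_repeats: int = 100
    subsample_fraction: float = 5.0 / 6.0  # sparse linear + first booster
    train_fraction: float = 0.75  # second booster
    top_k: int = 20
    rankers: tuple = RANKER_IDS
    l1_c_grid: tuple = (0.01, 0.05, 0.2, 1.0)
    n_estimators: int = 50
    max_depth: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.subsample_fraction < 1 or not 0 < self.train_fraction < 1:
            raise ValueError("subsample/train fractions must be in (0, 1)")
        if self.top_k < 1 or self.n_repeats < 1:
            raise ValueError("top_k and n_repeats must be >= 1")
        unknown = set(self.rankers) - set(RANKER_IDS)
        if unknown:
            raise ValueError(f"unknown ranker ids: {sorted(unknown)}")


def _l1_importance(x: np.ndarray, y: np.ndarray, config: RankerConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """|coefficients| of an L1 logistic fit, penalty picked by internal CV."""
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd
    best_c, best_acc = config.l1_c_grid[0], -np.inf
    seed = int(rng.integers(2**31))
    for c in config.l1_c_grid:
        accs = []
        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        for tr, te in cv.split(xs, y):
            model = LogisticRegression(C=c, solver="liblinear", l1_ratio=1.0,
                                       max_iter=200)
            model.fit(xs[tr], y[tr])
            accs.append(model.score(xs[te], y[te]))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best_acc, best_c = acc, c
    model = LogisticRegression(C=best_c, solver="liblinear", l1_ratio=1.0,
                               max_iter=500)
    model.fit(xs, y)
    return np.abs(model.coef_.ravel())


def _xgb_importance(x: np.ndarray, y: np.ndarray, config: RankerConfig,
                    rng: np.random.Generator) -> np.ndarray:
    model = xgb.XGBClassifier(
        n_estimators=config.n_estimators, max_depth=config.max_depth,
        tree_method="hist", n_jobs=1, verbosity=0,
        random_state=int(rng.integers(2**31)),
    )
    model.fit(x, y)
    return model.feature_importances_


def _gbm_importance(x: np.ndarray, y: np.ndarray, config: RankerConfig,
                    rng: np.random.Generator) -> np.ndarray:
    model = GradientBoostingClassifier(
        n_estimators=config.n_estimators, max_depth=config.max_depth,
        random_state=int(rng.integers(2**31)),
    )
    model.fit(x, y)
    return model.feature_importances_


_RANKER_FUNCS = {
    "sparse_linear_l1": _l1_importance,
    "boosted_trees_a": _xgb_importance,
    "boosted_trees_b": _gbm_importance,
}


def ensemble_rank(matrix: OmicsMatrix, labels, config: RankerConfig | None = None) -> pd.DataFrame:
    """Stability-selection style rank aggregation over three methods.

    For each repeat, each method is fit on its own random subsample (5/6 of
    samples for the sparse linear model and the first booster; a 75%
    training split for the second booster) and the ``top_k`` features by
    importance are recorded (features with exactly zero importance never
    qualify). Counts are accumulated over all methods and repeats; the
    overall rank is by descending total count, ties broken by mean
    within-run importance rank, then feature id. Fully seeded.

    Returns a DataFrame indexed by feature with per-method counts, the
    total, the mean selected rank and ``overall_rank`` (1 = best).
    """
    config = config or RankerConfig()
    config.validate()
    matrix.require_state("imputed")
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("ensemble_rank needs a binary contrast")
    x_full = matrix.values.to_numpy(float).T  # samples x features
    n_samples, n_features = x_full.shape
    if config.top_k > n_features:
        raise ValueError(f"top_k={config.top_k} exceeds n_features={n_features}")

    counts = {m: np.zeros(n_features, int) for m in config.rankers}
    rank_sums = np.zeros(n_features)
    rank_hits = np.zeros(n_features, int)
    successes = {m: 0 for m in config.rankers}
    master = np.random.default_rng(np.random.SeedSequence(config.seed))

    for _ in range(config.n_repeats):
        for method in config.rankers:
            rng = np.random.default_rng(master.integers(2**31))
            frac = (config.train_fraction if method == "boosted_trees_b"
                    else config.subsample_fraction)
            size = int(round(frac * n_samples))
            idx = rng.choice(n_samples, size=size, replace=False)
            y_sub = y[idx]
            if len(np.unique(y_sub)) < 2:
                logger.warning("%s: subsample lost a class; skipping run", method)
                continue
            try:
                importance = _RANKER_FUNCS[method](x_full[idx], y_sub, config, rng)
            except Exception as exc:  # a failed fit skips the (method, repeat)
                logger.warning("%s failed on a subsample: %s", method, exc)
                continue
            successes[method] += 1
            order = np.argsort(-importance, kind="mergesort")
            selected = [j for j in order[: config.top_k] if importance[j] > 0]
            counts[method][selected] += 1
            for pos, j in enumerate(selected, start=1):
                rank_sums[j] += pos
                rank_hits[j] += 1

    total = sum(counts.values())
    mean_rank = np.where(rank_hits > 0, rank_sums / np.maximum(rank_hits, 1), np.inf)
    table = pd.DataFrame({
        "feature_id": matrix.feature_ids,
        **{f"count_{m}": counts[m] for m in config.rankers},
        "total_count": total,
        "mean_selected_rank": mean_rank,
    })
    table = table.sort_values(
        ["total_count", "mean_selected_rank", "feature_id"],
        ascending=[False, True, True], kind="mergesort",
    ).reset_index(drop=True)
    table["overall_rank"] = np.arange(1, len(table) + 1)
    table.attrs["n_successful_runs"] = successes
    table.attrs["top_k"] = config.top_k
    return table
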