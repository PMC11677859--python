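"""Per-feature differential statistics between diagnostic groups.

Implements empirical-Bayes moderated t-tests (per-feature residual
variances shrunk towards a prior estimated across features by
method-of-moments on the log residual variances), Benjamini-Hochberg
FDR adjustment, and group-comparison tests computable from printed summary
statistics alone: one-way ANOVA from group means/SDs/sizes and the Pearson
chi-square test on count tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import OmicsMatrix

CONTRASTS = (("CN", "MCI"), ("CN", "AD"), ("MCI", "AD"), ("CN", "MCI+AD"))


def _group_members(labels: pd.Series, group: str) -> np.ndarray:
    """Boolean membership; 'MCI+AD' is the combined case group (one vs all)."""
    if "+" in group:
        return labels.isin(group.split("+")).to_numpy()
    return (labels == group).to_numpy()


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments prior (d0, s0^2) for residual variances.

    Treats each log residual variance as a scaled log chi-square variable
    with ``df`` degrees of freedom; excess dispersion of the log variances
    beyond trigamma(df/2) determines the prior degrees of freedom d0
    (infinite when there is no excess, i.e. complete pooling).
    """
    s2 = np.asarray(s2, float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def moderated_ttest(
    matrix: OmicsMatrix,
    labels: pd.Series,
    contrast: tuple[str, str],
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Moderated two-group t-tests for one contrast, over all features.

    ``contrast`` names (reference, comparison) groups; the comparison group
    may be a combination such as ``"MCI+AD"`` (one vs all). The sign
    convention is: positive log2FC / t means higher abundance in the
    second-named group.

    Per feature the pooled residual variance s^2 (df = n1+n2-2) is shrunk
    to the posterior (d0*s0^2 + df*s^2) / (d0 + df); the moderated t is
    referred to a t distribution with d0 + df degrees of freedom. When the
    prior df estimate is infinite the variances pool completely to s0^2 and
    a normal reference is used. ``d0_override`` forces the prior df (0
    recovers the ordinary pooled t-test).

    Returns a DataFrame with columns feature_id, contrast, log2fc, t_mod,
    p, fdr, df_total; the fitted prior is in ``result.attrs``.
    """
    matrix.require_state("imputed")
    labels = labels.reindex(matrix.sample_ids)
    g1, g2 = contrast
    m1 = _group_members(labels, g1)
    m2 = _group_members(labels, g2)
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"contrast {g1}-{g2} needs >= 2 samples per group (got {n1}, {n2})")
    df_resid = n1 + n2 - 2
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    values = matrix.values.to_numpy(float)
    x1, x2 = values[:, m1], values[:, m2]
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + ((x2 - mean2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if d0_override is not None:
        d0 = float(d0_override)
        _, s0sq = fit_variance_prior(s2, df_resid)
    else:
        d0, s0sq = fit_variance_prior(s2, df_resid)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    # zero-variance features borrow the prior variance instead of t = inf
    s2_post[s2_post == 0] = s0sq if s0sq > 0 else np.finfo(float).tiny

    delta = mean2 - mean1
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t_mod = delta / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    result = pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "contrast": f"{g1}-{g2}",
        "log2fc": delta,
        "t_mod": t_mod,
        "p": p,
        "fdr": bh_adjust(p),
        "df_total": df_total,
    })
    result.attrs["d0"] = d0
    result.attrs["s0sq"] = s0sq
    return result


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(pvalues, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


@dataclass
class GroupSummary:
    """Printed group summaries: labels with means, SDs and sizes."""

    labels: tuple
    means: tuple
    sds: tuple
    ns: tuple

    def validate(self) -> None:
        k = len(self.labels)
        if not (len(self.means) == len(self.sds) == len(self.ns) == k):
            raise ValueError("labels, means, sds, ns must have equal lengths")
        if k < 2:
            raise ValueError("need >= 2 groups")
        if any(n < 2 for n in self.ns):
            raise ValueError("every group needs n >= 2")
        if any(s < 0 for s in self.sds):
            raise ValueError("SDs must be non-negative")


def anova_from_summary(summary: GroupSummary) -> tuple[float, float]:
    """One-way ANOVA F and p computed from group means/SDs/sizes only.

    Between-group sum of squares uses the size-weighted grand mean;
    within-group sum of squares is sum((n_j - 1) * sd_j^2). Identical to a
    one-way ANOVA on any raw data realizing the same summaries.
    """
    summary.validate()
    m = np.asarray(summary.means, float)
    s = np.asarray(summary.sds, float)
    n = np.asarray(summary.ns, float)
    k, total = m.size, n.sum()
    grand = (n * m).sum() / total
    ssb = (n * (m - grand) ** 2).sum()
    ssw = ((n - 1) * s**2).sum()
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        return np.inf, 0.0  # degenerate: zero within-group variance
    f = (ssb / (k - 1)) / (ssw / (total - k))
    p = float(stats.f.sf(f, k - 1, total - k))
    return float(f), p


def chisq_from_counts(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on an r x c count table."""
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)) or np.any(table < 0):
            raise ValueError("counts must be non-negative integers")
        table = table.astype(int)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all row and column totals must be positive")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
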