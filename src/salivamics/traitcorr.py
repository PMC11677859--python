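"""Analyte-trait correlations with optional case/control stratification.

Every feature of an imputed layer is correlated (Spearman by default,
Pearson optionally) against a continuous plasma or phenotype trait such as
pTau181, age, homocysteine or vitamin B12. Records can be restricted to
controls only or cases only (MCI and AD combined), mirroring age analyses
stratified by disease status. P-values use the t approximation
t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom; FDR adjustment
is applied within each (layer x trait x stratum) family and records are
emitted in increasing order of p.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import OmicsMatrix
from .diffstats import bh_adjust

STRATA = ("all", "control_only", "case_only")


def _stratum_mask(labels: pd.Series, stratum: str) -> np.ndarray:
    if stratum == "all":
        return np.ones(len(labels), bool)
    if stratum == "control_only":
        return (labels == "CN").to_numpy()
    if stratum == "case_only":
        return labels.isin(["MCI", "AD"]).to_numpy()
    raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")


def correlation_pvalue(rho: float, n: int) -> float:
    """Two-sided p for a correlation via the t approximation, n-2 df."""
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def correlate_trait(
    matrix: OmicsMatrix,
    metadata: pd.DataFrame,
    trait: str,
    method: str = "spearman",
    stratum: str = "all",
) -> pd.DataFrame:
    """Correlate every feature with one trait over samples in a stratum.

    Samples with a missing trait value are dropped. Spearman uses average
    ranks for ties. Constant features (or a constant trait) yield an
    undefined correlation: such records are flagged ``undefined`` and
    excluded from the FDR family. The result is sorted by ascending p.
    """
    matrix.require_state("imputed")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    metadata = metadata.loc[matrix.sample_ids]
    keep = _stratum_mask(metadata["diagnosis"], stratum)
    trait_values = metadata[trait].to_numpy(float)
    keep &= ~np.isnan(trait_values)
    n = int(keep.sum())
    if n < 3:
        raise ValueError(f"trait {trait!r} has fewer than 3 usable samples in {stratum}")

    y = trait_values[keep]
    x = matrix.values.to_numpy(float)[:, keep]
    if method == "spearman":
        y = stats.rankdata(y)
        x = stats.rankdata(x, axis=1)

    y_c = y - y.mean()
    x_c = x - x.mean(axis=1, keepdims=True)
    y_ss = float((y_c**2).sum())
    x_ss = (x_c**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (x_c @ y_c) / np.sqrt(x_ss * y_ss)
    undefined = (x_ss == 0) | (y_ss == 0)
    rho[undefined] = np.nan
    rho = np.clip(rho, -1.0, 1.0, out=rho)

    p = np.array([
        np.nan if und else correlation_pvalue(r, n) for r, und in zip(rho, undefined)
    ])
    fdr = np.full_like(p, np.nan)
    defined = ~undefined
    if defined.any():
        fdr[defined] = bh_adjust(p[defined])

    out = pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "trait": trait,
        "method": method,
        "stratum": stratum,
        "rho": rho,
        "p": p,
        "fdr": fdr,
        "n_used": n,
        "undefined": undefined,
    })
    return out.sort_values(["p", "feature_id"], kind="mergesort").reset_index(drop=True)


def top_correlates(records: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Top-k defined records by correlation p-value (table-style report)."""
    defined = records[~records["undefined"]]
    return defined.nsmallest(k, "p")[["feature_id", "rho", "fdr"]].reset_index(drop=True)
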