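"""Preprocessing: log transform, median normalization, downshift imputation.

The pipeline order is fixed and enforced by the matrix state flag:
raw -> (log + median normalize) -> impute. Missing values are assumed to be
left-censored low-abundance measurements, so they are imputed by sampling
from a Gaussian shifted below each sample's observed distribution
(downshift 1.8 SD, width 0.3 SD by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class ImputationParams:
    """Parameters of left-censored Gaussian imputation.

    ``downshift`` and ``width`` are in multiples of the observed SD of the
    scope unit; ``scope`` selects whether moments are computed per sample
    column (the usual convention for expression matrices), per feature row,
    or globally.
    """

    downshift: float = 1.8
    width: float = 0.3
    scope: str = "per_sample"
    seed: int = 0

    def validate(self) -> None:
        if self.downshift < 0:
            raise ValueError(f"downshift must be >= 0, got {self.downshift}")
        if self.width <= 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        if self.scope not in ("per_sample", "per_feature", "global"):
            raise ValueError(f"unknown scope {self.scope!r}")


def _median_shift(values: np.ndarray) -> np.ndarray:
    """Shift each column so its observed median equals the grand median.

    The grand median is the median of the per-column medians, so the
    operation is idempotent: re-applying it leaves the matrix unchanged.
    """
    col_medians = np.nanmedian(values, axis=0)
    grand = np.median(col_medians)
    return values + (grand - col_medians)[None, :]


def log_median_normalize(
    matrix: OmicsMatrix, base: float = 2, on_empty_column: str = "error"
) -> OmicsMatrix:
    """Log-transform observed cells, then median-normalize sample columns.

    Each column is shifted so that its median of observed values equals the
    grand median of all pre-shift column medians. The missingness mask is
    unchanged. ``on_empty_column`` controls all-missing columns: ``error``
    raises, ``pass`` leaves them untouched (never silent NaN medians).
    """
    matrix.require_state("raw")
    if base not in (2, np.e, 10):
        raise ValueError(f"base must be 2, e or 10, got {base}")
    values = matrix.values.to_numpy(float).copy()
    bad = np.argwhere(np.nan_to_num(values, nan=1.0) <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive observed value at feature {matrix.feature_ids[i]!r}, "
            f"sample {matrix.sample_ids[j]!r}"
        )
    empty_cols = np.isnan(values).all(axis=0)
    if empty_cols.any():
        names = matrix.sample_ids[empty_cols].tolist()
        if on_empty_column == "error":
            raise ValueError(f"all-missing sample columns: {names}")
        logger.warning("leaving all-missing columns untouched: %s", names)
    logged = np.log(values) / np.log(base)
    keep = ~empty_cols
    logged[:, keep] = _median_shift(logged[:, keep])
    out = matrix.copy()
    out.values = pd.DataFrame(logged, index=matrix.feature_ids, columns=matrix.sample_ids)
    out.state = "normalized"
    out.params = {**matrix.params, "log_base": float(base), "normalized": "median"}
    return out


def impute_downshift(matrix: OmicsMatrix, params: ImputationParams | None = None) -> OmicsMatrix:
    """Impute missing cells from a downshifted Gaussian per scope unit.

    For each scope unit (default: sample column) with observed mean mu and
    SD sigma, missing cells are replaced by independent draws from
    Normal(mu - downshift*sigma, (width*sigma)^2). Draws are consumed in
    row-major feature x sample order of the missing cells so results are
    reproducible for a given seed. Features with zero observed values are
    dropped with a warning (their moments are undefined). Observed cells
    are untouched.
    """
    params = params or ImputationParams()
    params.validate()
    matrix.require_state("normalized")
    values = matrix.values.to_numpy(float).copy()

    all_missing = np.isnan(values).all(axis=1)
    if all_missing.any():
        dropped = matrix.feature_ids[all_missing].tolist()
        logger.warning("dropping %d features with zero observed values: %s",
                       len(dropped), dropped[:5])
        values = values[~all_missing]
    feature_ids = matrix.feature_ids[~all_missing]

    missing = np.isnan(values)
    if missing.any():
        if params.scope == "per_sample":
            axis, n_obs = 0, (~missing).sum(axis=0)
        elif params.scope == "per_feature":
            axis, n_obs = 1, (~missing).sum(axis=1)
        else:
            axis, n_obs = None, int((~missing).sum())
        if np.any(np.atleast_1d(n_obs) < 3):
            raise ValueError(
                f"every {params.scope} scope unit needs >= 3 observed values "
                "to estimate imputation moments"
            )
        mu = np.nanmean(values, axis=axis)
        sigma = np.nanstd(values, axis=axis, ddof=1)
        rng = np.random.default_rng(params.seed)
        rows, cols = np.nonzero(missing)  # row-major order
        z = rng.standard_normal(rows.size)
        if params.scope == "per_sample":
            loc, scale = mu[cols], sigma[cols]
        elif params.scope == "per_feature":
            loc, scale = mu[rows], sigma[rows]
        else:
            loc, scale = mu, sigma
        values[rows, cols] = (loc - params.downshift * scale) + params.width * scale * z

    out = OmicsMatrix(
        pd.DataFrame(values, index=feature_ids, columns=matrix.sample_ids),
        state="imputed",
        layer=matrix.layer,
        params={**matrix.params, "imputation": {
            "downshift": params.downshift, "width": params.width,
            "scope": params.scope, "seed": params.seed,
        }},
    )
    return out


def completeness_summary(matrix: OmicsMatrix, threshold: float = 0.5) -> tuple[pd.Series, float]:
    """Per-feature detection fractions and the share at/above ``threshold``.

    A feature observed in exactly ``threshold`` of the samples counts as
    meeting the threshold (>=, not >).
    """
    matrix.require_state("raw", "normalized")
    observed = (~matrix.mask).mean(axis=1)
    share = float((observed >= threshold).mean())
    return observed, share
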