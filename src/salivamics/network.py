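"""Weighted correlation network analysis for one omics layer.

A soft-thresholded correlation network is built over features
(adjacency = |cor|^beta, unsigned by default), the power beta chosen as the
smallest one whose connectivity distribution fits a scale-free topology
(signed R^2 >= 0.85 by default). Features are clustered by average-linkage
hierarchical clustering on the topological overlap dissimilarity; branches
below the minimum module size are left unassigned ("grey"), the rest are
named by size rank using the conventional color order. Each module is
summarized by its eigenfeature (first principal component of the
standardized member block), members are ranked by kME (correlation with
the eigenfeature, hubs on top), and eigenfeatures are correlated against
clinical traits, flagging modules whose MMSE correlation reaches p < 0.001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import OmicsMatrix, diagnosis_codes
from .traitcorr import correlation_pvalue

logger = logging.getLogger(__name__)

#: conventional module color order, largest module first
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
)
UNASSIGNED = "grey"


@dataclass
class NetworkParams:
    rsq_cutoff: float = 0.85
    min_module_size: int = 20
    power_grid: tuple = tuple(range(1, 21))
    network_type: str = "unsigned"
    cut_height_fraction: float = 0.99
    merge_cut: float | None = None

    def validate(self) -> None:
        if not 0 < self.rsq_cutoff <= 1:
            raise ValueError(f"rsq_cutoff must be in (0, 1], got {self.rsq_cutoff}")
        if self.min_module_size < 2:
            raise ValueError(f"min_module_size must be >= 2, got {self.min_module_size}")
        if any(int(p) != p or p < 1 for p in self.power_grid):
            raise ValueError("power_grid must contain positive integers")
        if self.network_type not in ("unsigned", "signed"):
            raise ValueError(f"unknown network_type {self.network_type!r}")


@dataclass
class ModuleSet:
    """Feature -> module color labels plus the clustering provenance."""

    labels: pd.Series
    linkage_matrix: np.ndarray | None = None
    power: int | None = None

    def members(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]

    def module_names(self) -> list[str]:
        return [c for c in self.labels.unique() if c != UNASSIGNED]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


def _feature_correlation(matrix: OmicsMatrix) -> tuple[np.ndarray, pd.Index]:
    """Feature-feature Pearson correlations, constant features dropped."""
    matrix.require_state("imputed")
    values = matrix.values.to_numpy(float)
    sds = values.std(axis=1)
    keep = sds > 0
    if not keep.all():
        logger.warning("removing %d constant features before correlation",
                       int((~keep).sum()))
    corr = np.corrcoef(values[keep])
    return np.atleast_2d(corr), matrix.feature_ids[keep]


def _adjacency(corr: np.ndarray, power: int, network_type: str) -> np.ndarray:
    if network_type == "signed":
        a = ((1.0 + corr) / 2.0) ** power
    else:
        a = np.abs(corr) ** power
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index for a connectivity vector.

    Connectivities are binned into ~``n_bins`` equal-occupancy bins;
    log10 frequency is regressed on log10 mean connectivity. Returns
    (signed R^2, slope) with signed R^2 = -sign(slope) * R^2, so a
    scale-free (negative-slope) fit scores positively.
    """
    k = np.asarray(connectivity, float)
    if k.size < n_bins:
        n_bins = max(2, k.size // 2)
    # equal-width bins over the connectivity range; empty bins dropped
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    mean_k = np.array([k[which == b].mean() if (which == b).any() else np.nan
                       for b in range(n_bins)])
    freq = np.array([(which == b).mean() for b in range(n_bins)])
    ok = np.isfinite(mean_k) & (mean_k > 0) & (freq > 0)
    if ok.sum() < 3:
        return 0.0, 0.0
    x, y = np.log10(mean_k[ok]), np.log10(freq[ok])
    slope, _, r, _, _ = stats.linregress(x, y)
    return float(-np.sign(slope) * r**2), float(slope)


def pick_soft_threshold(
    matrix: OmicsMatrix, params: NetworkParams | None = None
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power and return the full fit table.

    Picks the smallest power in the grid whose signed scale-free fit R^2
    reaches the cutoff; if none does, the power maximizing the fit is used
    with a warning.
    """
    params = params or NetworkParams()
    params.validate()
    corr, _ = _feature_correlation(matrix)
    if corr.shape[0] < 3:
        raise ValueError("need at least 3 non-constant features")
    rows = []
    for power in params.power_grid:
        a = _adjacency(corr, int(power), params.network_type)
        k = a.sum(axis=1)
        rsq, slope = scale_free_fit(k)
        rows.append({"power": int(power), "signed_rsq": rsq, "slope": slope,
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
    table = pd.DataFrame(rows)
    reaching = table[table["signed_rsq"] >= params.rsq_cutoff]
    if len(reaching):
        power = int(reaching["power"].iloc[0])
    else:
        power = int(table.loc[table["signed_rsq"].idxmax(), "power"])
        logger.warning(
            "no power reached signed R^2 >= %.2f; using power %d (R^2 = %.3f)",
            params.rsq_cutoff, power, table["signed_rsq"].max(),
        )
    return power, table


def adjacency_tom(
    matrix: OmicsMatrix, power: int, network_type: str = "unsigned"
) -> pd.DataFrame:
    """Topological overlap dissimilarity of the soft-thresholded network.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu * a_uj over u != i, j; the returned matrix is
    1 - TOM with a zero diagonal.
    """
    if power < 1:
        raise ValueError(f"power must be >= 1, got {power}")
    corr, feature_ids = _feature_correlation(matrix)
    if corr.shape[0] < 3:
        raise ValueError("TOM requires at least 3 features")
    a = _adjacency(corr, int(power), network_type)
    k = a.sum(axis=1)
    # zero diagonal of a makes (a @ a)_ij = sum_{u != i,j} a_iu * a_uj = l_ij
    l = a @ a  # noqa: E741 - conventional symbol
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0
    return pd.DataFrame(dissim, index=feature_ids, columns=feature_ids)


def detect_modules(
    dissimilarity: pd.DataFrame, params: NetworkParams | None = None, power: int | None = None
) -> ModuleSet:
    """Cluster features on TOM dissimilarity into color-labeled modules.

    Average-linkage hierarchical clustering; branches are obtained by a
    fixed-height cut at ``cut_height_fraction`` of the maximum merge
    height. Branches smaller than ``min_module_size`` are relabeled grey;
    the rest are named by decreasing size with the conventional colors.
    """
    params = params or NetworkParams()
    params.validate()
    d = dissimilarity.to_numpy(float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("dissimilarity must be square and symmetric")
    z = linkage(squareform(d, checks=False), method="average")
    min_height, max_height = z[:, 2].min(), z[:, 2].max()
    if max_height <= min_height:
        logger.warning("degenerate dissimilarity (all equal); single module")
        raw = np.ones(d.shape[0], int)
    else:
        # scale-invariant cut: fraction of the merge-height range, so branch
        # detection survives the dissimilarity compression of high powers
        cut = min_height + params.cut_height_fraction * (max_height - min_height)
        raw = fcluster(z, t=cut, criterion="distance")
    labels = pd.Series(raw, index=dissimilarity.index, name="module")
    counts = labels.value_counts()
    keep = counts[counts >= params.min_module_size].index
    named: dict[int, str] = {}
    ordered = counts.loc[keep].sort_values(ascending=False)
    for rank, cluster_id in enumerate(ordered.index):
        named[cluster_id] = (
            MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        )
    colors = labels.map(lambda c: named.get(c, UNASSIGNED))
    return ModuleSet(labels=colors, linkage_matrix=z, power=power)


@dataclass
class Eigenfeature:
    """Per-module summary profile (first PC of the standardized block)."""

    module: str
    scores: pd.Series  # per-sample, unit-norm weights
    variance_explained: float


def module_eigenfeatures(
    matrix: OmicsMatrix, modules: ModuleSet
) -> dict[str, Eigenfeature]:
    """First principal component per module, sign-oriented to its members.

    Member rows are standardized across samples; the eigenfeature is the
    first right singular vector of the member x sample block, with sign
    chosen so the mean member correlation (mean kME) is non-negative.
    """
    matrix.require_state("imputed")
    values = matrix.values
    out: dict[str, Eigenfeature] = {}
    for module in modules.module_names():
        members = modules.members(module)
        block = values.loc[members].to_numpy(float)
        sds = block.std(axis=1)
        if (sds == 0).any():
            logger.warning("module %s: excluding %d zero-variance members",
                           module, int((sds == 0).sum()))
            block = block[sds > 0]
            sds = sds[sds > 0]
        if block.shape[0] < 2:
            raise ValueError(f"module {module!r} has fewer than 2 usable members")
        std_block = (block - block.mean(axis=1, keepdims=True)) / sds[:, None]
        _, s, vt = np.linalg.svd(std_block, full_matrices=False)
        eig = vt[0]
        member_corr = std_block @ eig / np.linalg.norm(std_block, axis=1) / np.linalg.norm(eig)
        if member_corr.mean() < 0:
            eig = -eig
        out[module] = Eigenfeature(
            module=module,
            scores=pd.Series(eig, index=values.columns, name=module),
            variance_explained=float(s[0] ** 2 / (s**2).sum()),
        )
    return out


def kme(
    matrix: OmicsMatrix,
    eigenfeatures: dict[str, Eigenfeature],
    modules: ModuleSet,
    top_n: int = 5,
    all_features: bool = False,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """kME table (feature vs module eigenfeature correlation) + hub lists.

    By default each feature is correlated with its own module's
    eigenfeature; ``all_features=True`` correlates every feature with every
    eigenfeature. Hubs are the ``top_n`` members per module by descending
    kME, ties broken by feature id.
    """
    matrix.require_state("imputed")
    values = matrix.values
    rows = []
    for module, eig in eigenfeatures.items():
        feats = values.index if all_features else modules.members(module)
        block = values.loc[feats].to_numpy(float)
        e = eig.scores.to_numpy(float)
        e_c = e - e.mean()
        b_c = block - block.mean(axis=1, keepdims=True)
        denom = np.sqrt((b_c**2).sum(axis=1) * (e_c**2).sum())
        with np.errstate(invalid="ignore"):
            r = b_c @ e_c / denom
        for fid, val in zip(feats, r):
            rows.append({"feature_id": fid, "module": module, "kme": val})
    table = pd.DataFrame(rows, columns=["feature_id", "module", "kme"])
    hubs = {
        module: grp.sort_values(["kme", "feature_id"], ascending=[False, True])
        ["feature_id"].head(top_n).tolist()
        for module, grp in table.groupby("module")
    }
    return table, hubs


def module_trait_correlations(
    eigenfeatures: dict[str, Eigenfeature],
    metadata: pd.DataFrame,
    traits: list[str] | None = None,
    mmse_alpha: float = 0.001,
) -> pd.DataFrame:
    """Pearson correlations of eigenfeatures with clinical traits.

    Binary traits must be coded 0/1 beforehand; diagnosis is offered as an
    ordinal severity code (CN=0, MCI=1, AD=2) under the name ``severity``.
    Modules whose MMSE correlation p-value is below ``mmse_alpha`` are
    flagged. The ``label`` column holds "corr (p)" strings for heatmaps.
    """
    if traits is None:
        numeric = metadata.select_dtypes("number").columns.tolist()
        traits = numeric + ["severity"]
    rows = []
    for module, eig in eigenfeatures.items():
        samples = eig.scores.index
        meta = metadata.loc[samples]
        for trait in traits:
            if trait == "severity":
                y = diagnosis_codes(meta).to_numpy(float)
            elif trait == "sex":
                y = (meta["sex"] == "M").astype(float).to_numpy()
            else:
                y = meta[trait].to_numpy(float)
            x = eig.scores.to_numpy(float)
            ok = ~np.isnan(y)
            if y[ok].std() == 0 or x[ok].std() == 0:
                rows.append({"module": module, "trait": trait, "correlation": np.nan,
                             "p": np.nan, "significant_mmse": False,
                             "label": "undefined"})
                continue
            r = float(np.corrcoef(x[ok], y[ok])[0, 1])
            p = correlation_pvalue(r, int(ok.sum()))
            rows.append({
                "module": module, "trait": trait, "correlation": r, "p": p,
                "significant_mmse": bool(trait == "mmse" and p < mmse_alpha),
                "label": f"{r:.2f} ({p:.3g})",
            })
    return pd.DataFrame(rows)


def run_network_analysis(
    matrix: OmicsMatrix,
    metadata: pd.DataFrame,
    params: NetworkParams | None = None,
    traits: list[str] | None = None,
) -> dict:
    """Full per-layer network workflow; returns all intermediate products."""
    params = params or NetworkParams()
    power, fit_table = pick_soft_threshold(matrix, params)
    dissim = adjacency_tom(matrix, power, params.network_type)
    modules = detect_modules(dissim, params, power=power)
    eigs = module_eigenfeatures(matrix, modules)
    kme_table, hubs = kme(matrix, eigs, modules)
    trait_corr = module_trait_correlations(eigs, metadata, traits)
    return {
        "power": power,
        "fit_table": fit_table,
        "modules": modules,
        "eigenfeatures": eigs,
        "kme": kme_table,
        "hubs": hubs,
        "module_trait": trait_corr,
    }
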