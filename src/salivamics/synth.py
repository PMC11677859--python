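"""Seeded synthetic multi-omics cohorts with planted ground truth.

The generator emulates the statistical structure a saliva biomarker study
of cognitive decline presents to its analysis pipeline: three diagnostic
groups (40 cognitively normal, 20 MCI, 20 AD), three abundance layers
(751 proteins, 174 metabolites, 115 microbial species on a 51-sample
subset), plasma covariates including a pTau181-like trait, correlated
feature modules tied to disease severity, monotone single-marker effects,
and missing-not-at-random left-censoring tuned so that ~61% of protein
features are detected in at least half the samples.

Everything is generated on the log2 scale and exponentiated, so the
downstream log transform recovers Gaussian structure. All randomness flows
from one master seed through named child streams (cohort, one per layer,
one per layer's censoring), so layers can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DIAGNOSES, LAYERS, OmicsMatrix, write_matrix

# Group-conditional covariate marginals (CN, MCI, AD): mean/SD pairs for
# continuous traits, probabilities for binary ones. pTau181 and the clinical
# chemistry values are in the units noted. Values without a published
# marginal (homocysteine, cholesterol) are plausible elderly-cohort choices.
COVARIATE_DEFAULTS: dict[str, dict] = {
    "sex_male_p": {"CN": 0.525, "MCI": 0.45, "AD": 0.60},
    "apoe4_p": {"CN": 0.15, "MCI": 0.55, "AD": 0.50},
    "age": {"CN": (74.9, 7.2), "MCI": (77.8, 8.1), "AD": (78.0, 6.5)},
    "mmse": {"CN": (28.6, 1.6), "MCI": (26.6, 3.1), "AD": (21.1, 3.3)},
    "il6": {"CN": (19.1, 47.0), "MCI": (16.9, 41.1), "AD": (14.4, 22.7)},
    "tnf_alpha": {"CN": (1.6, 0.7), "MCI": (1.9, 1.2), "AD": (2.1, 2.2)},
    "vitamin_b12": {"CN": (303.1, 91.3), "MCI": (392.9, 186.0), "AD": (395.6, 120.5)},
    "holo_tc": {"CN": (61.8, 24.6), "MCI": (83.6, 18.5), "AD": (63.0, 6.9)},
    "homocysteine": {"CN": (10.5, 3.0), "MCI": (11.8, 3.5), "AD": (12.5, 4.0)},
    "cholesterol": {"CN": (5.2, 1.0), "MCI": (5.3, 1.1), "AD": (5.1, 1.1)},
}

_LAYER_PREFIX = {"protein": "PROT", "metabolite": "METB", "microbiome": "MICR"}


@dataclass
class SynthConfig:
    """Configuration of the synthetic cohort.

    ``effect_profile`` gives the per-group mean shift of planted single
    markers in SD units of the feature noise, ordered CN, MCI, AD; it must
    be monotone. ``module_loading`` is the loading of module members on
    their latent factor; ``disease_link`` / ``ptau_link`` tie the first two
    module factors to disease severity and the pTau proxy respectively.
    """

    n_control: int = 40
    n_mci: int = 20
    n_ad: int = 20
    n_proteins: int = 751
    n_metabolites: int = 174
    n_species: int = 115
    microbiome_subset: int = 51
    n_modules_per_layer: int = 3
    module_size_range: tuple[int, int] = (25, 60)
    # the latent links are calibrated so the *observed* module-trait and
    # analyte-pTau correlations after censoring + imputation land in the
    # 0.4-0.5 range a saliva cohort of this size reports
    module_loading: float = 0.8
    disease_link: float = 0.7
    ptau_link: float = 0.5
    n_planted_markers: int = 10
    effect_profile: tuple[float, float, float] = (0.0, 0.5, 1.0)
    marker_sign: str = "alternating"  # or "positive" / "negative"
    n_ptau_correlates: int = 10
    ptau_loading: float = 0.6
    ptau_group_means: tuple[float, float, float] = (3.2, 4.8, 6.6)
    ptau_group_sds: tuple[float, float, float] = (1.3, 2.2, 2.6)
    censor_quantile: float = 0.9
    target_protein_completeness: float = 0.61
    target_metabolite_completeness: float = 1.0
    target_species_completeness: float = 0.52
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_control", "n_mci", "n_ad", "n_proteins", "n_metabolites",
                     "n_species", "microbiome_subset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.microbiome_subset > self.n_control + self.n_mci + self.n_ad:
            raise ValueError("microbiome_subset exceeds cohort size")
        diffs = np.diff(self.effect_profile)
        if not ((diffs >= 0).all() or (diffs <= 0).all()):
            raise ValueError(
                f"effect_profile must be monotone across CN->MCI->AD, got {self.effect_profile}"
            )
        if not 0.0 <= self.censor_quantile <= 0.9:
            raise ValueError(f"censor_quantile must be in [0, 0.9], got {self.censor_quantile}")
        lo, hi = self.module_size_range
        if lo < 2 or hi < lo:
            raise ValueError(f"module_size_range invalid: {self.module_size_range}")
        if self.marker_sign not in ("alternating", "positive", "negative"):
            raise ValueError(f"marker_sign invalid: {self.marker_sign!r}")
        for name in ("target_protein_completeness", "target_metabolite_completeness",
                     "target_species_completeness"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_control + self.n_mci + self.n_ad

    def group_sizes(self) -> dict[str, int]:
        return {"CN": self.n_control, "MCI": self.n_mci, "AD": self.n_ad}

    def layer_sizes(self) -> dict[str, int]:
        return {
            "protein": self.n_proteins,
            "metabolite": self.n_metabolites,
            "microbiome": self.n_species,
        }

    def completeness_target(self, layer: str) -> float:
        return {
            "protein": self.target_protein_completeness,
            "metabolite": self.target_metabolite_completeness,
            "microbiome": self.target_species_completeness,
        }[layer]


@dataclass
class GroundTruth:
    """Manifest of everything the generator planted (the test oracle).

    Per layer: planted marker ids with signed effect sizes (SD units at the
    AD end of the profile), feature->module membership of planted blocks,
    pTau-proxy loadings of planted trait correlates, and the per-feature
    censoring thresholds applied by :func:`apply_missingness`.
    """

    planted_markers: dict[str, dict[str, float]] = field(default_factory=dict)
    module_membership: dict[str, dict[str, int]] = field(default_factory=dict)
    latent_trait_loadings: dict[str, dict[str, float]] = field(default_factory=dict)
    censoring_thresholds: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _child_rngs(config: SynthConfig) -> dict[str, np.random.Generator]:
    """Named child streams spawned from the master seed, in fixed order."""
    children = np.random.SeedSequence(config.seed).spawn(7)
    names = ["cohort", "protein", "metabolite", "microbiome",
             "censor_protein", "censor_metabolite", "censor_microbiome"]
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal(mean, sd) truncated at zero (abundance-like traits)."""
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(config: SynthConfig) -> pd.DataFrame:
    """Generate per-sample metadata (diagnosis, demographics, plasma traits).

    Group sizes are exact; pTau181 is drawn per group from normal
    distributions with the configured means/SDs truncated at zero; the
    remaining covariates follow group-conditional marginals. Reproducible
    given the seed.
    """
    config.validate()
    rng = _child_rngs(config)["cohort"]
    sizes = config.group_sizes()
    rows = []
    idx = 0
    for gi, group in enumerate(DIAGNOSES):
        n = sizes[group]
        sex = rng.random(n) < COVARIATE_DEFAULTS["sex_male_p"][group]
        apoe4 = rng.random(n) < COVARIATE_DEFAULTS["apoe4_p"][group]
        age = rng.normal(*COVARIATE_DEFAULTS["age"][group], size=n)
        mmse = np.clip(np.rint(rng.normal(*COVARIATE_DEFAULTS["mmse"][group], size=n)), 0, 30)
        ptau = _truncated_normal(
            rng, config.ptau_group_means[gi], config.ptau_group_sds[gi], n
        )
        extras = {
            name: _truncated_normal(rng, *COVARIATE_DEFAULTS[name][group], n)
            for name in ("il6", "tnf_alpha", "vitamin_b12", "holo_tc",
                         "homocysteine", "cholesterol")
        }
        for k in range(n):
            rows.append({
                "sample_id": f"S{idx:03d}",
                "diagnosis": group,
                "sex": "M" if sex[k] else "F",
                "age": age[k],
                "mmse": mmse[k],
                "apoe4": int(apoe4[k]),
                "ptau181": ptau[k],
                **{name: extras[name][k] for name in extras},
            })
            idx += 1
    return pd.DataFrame(rows).set_index("sample_id")


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _generate_layer(
    rng: np.random.Generator,
    layer: str,
    n_features: int,
    metadata: pd.DataFrame,
    config: SynthConfig,
    truth: GroundTruth,
) -> OmicsMatrix:
    samples = metadata.index
    n = len(samples)
    severity = _zscore(metadata["diagnosis"].map({d: i for i, d in enumerate(DIAGNOSES)}).to_numpy(float))
    ptau_z = _zscore(metadata["ptau181"].to_numpy(float))
    shift = np.array(config.effect_profile)[
        metadata["diagnosis"].map({d: i for i, d in enumerate(DIAGNOSES)}).to_numpy()
    ]

    prefix = _LAYER_PREFIX[layer]
    feature_ids = [f"{prefix}_{i:04d}" for i in range(n_features)]
    z = np.empty((n_features, n))

    # planted module blocks: features = loading * factor + noise, with the
    # first factor tied to disease severity and the second to the pTau proxy
    budget = n_features - config.n_planted_markers - config.n_ptau_correlates
    if config.n_modules_per_layer > 0:
        lo, hi = config.module_size_range
        # small layers cap module sizes so the planted structure always fits
        hi = min(hi, budget // config.n_modules_per_layer)
        if budget <= 0 or hi < lo:
            raise ValueError(
                f"layer {layer}: module sizes >= {lo} x {config.n_modules_per_layer} "
                f"modules exceed the layer size {n_features}"
            )
        module_sizes = rng.integers(lo, hi + 1, size=config.n_modules_per_layer)
    else:
        module_sizes = np.array([], dtype=int)

    membership: dict[str, int] = {}
    pos = 0
    for m, size in enumerate(module_sizes):
        if m == 0:
            link, driver = config.disease_link, -severity  # abundance falls with disease
        elif m == 1:
            link, driver = config.ptau_link, ptau_z
        else:
            link, driver = 0.0, np.zeros(n)
        factor = link * driver + np.sqrt(max(1.0 - link**2, 0.0)) * rng.standard_normal(n)
        lam = config.module_loading
        block = lam * factor + np.sqrt(1.0 - lam**2) * rng.standard_normal((size, n))
        z[pos:pos + size] = block
        for fid in feature_ids[pos:pos + size]:
            membership[fid] = m
        pos += size

    # planted single markers: noise is centered within each group so the
    # achieved group means equal the configured monotone shifts exactly
    group_idx = metadata["diagnosis"].map({d: i for i, d in enumerate(DIAGNOSES)}).to_numpy()
    markers: dict[str, float] = {}
    for k in range(config.n_planted_markers):
        if config.marker_sign == "alternating":
            sign = 1.0 if k % 2 == 0 else -1.0
        else:
            sign = 1.0 if config.marker_sign == "positive" else -1.0
        noise = rng.standard_normal(n)
        for g in range(len(DIAGNOSES)):
            sel = group_idx == g
            if sel.any():
                noise[sel] -= noise[sel].mean()
        z[pos] = sign * shift + noise
        markers[feature_ids[pos]] = sign * float(config.effect_profile[-1])
        pos += 1

    # pTau-proxy correlates: noise is residualized against the trait so the
    # achieved in-sample Pearson correlation equals the loading exactly
    loadings: dict[str, float] = {}
    lam = config.ptau_loading
    for _ in range(config.n_ptau_correlates):
        e = rng.standard_normal(n)
        e -= e.mean()
        e -= (e @ ptau_z) / (ptau_z @ ptau_z) * ptau_z
        e /= e.std()
        z[pos] = lam * ptau_z + np.sqrt(1.0 - lam**2) * e
        loadings[feature_ids[pos]] = lam
        pos += 1

    z[pos:] = rng.standard_normal((n_features - pos, n))

    baseline = rng.normal(20.0, 2.0, size=n_features)
    scale = rng.uniform(0.8, 1.6, size=n_features)
    log2_values = baseline[:, None] + scale[:, None] * z
    raw = np.exp2(log2_values)

    truth.planted_markers[layer] = markers
    truth.module_membership[layer] = membership
    truth.latent_trait_loadings[layer] = loadings
    values = pd.DataFrame(raw, index=pd.Index(feature_ids, name="feature_id"), columns=samples)
    return OmicsMatrix(values, state="raw", layer=layer)


def _microbiome_samples(metadata: pd.DataFrame, config: SynthConfig,
                        rng: np.random.Generator) -> pd.Index:
    """Pick the microbiome sub-cohort (22 CN / 13 MCI / 16 AD at defaults)."""
    wanted = {"CN": 22, "MCI": 13, "AD": 16}
    sizes = config.group_sizes()
    total_wanted = sum(wanted.values())
    if config.microbiome_subset != total_wanted or any(
        wanted[g] > sizes[g] for g in wanted
    ):
        # non-default subset size: allocate proportionally to group sizes
        n_total = config.n_samples
        wanted = {
            g: min(sizes[g], int(round(config.microbiome_subset * sizes[g] / n_total)))
            for g in DIAGNOSES
        }
        g = "CN"
        while sum(wanted.values()) < config.microbiome_subset:
            for g in DIAGNOSES:
                if wanted[g] < sizes[g] and sum(wanted.values()) < config.microbiome_subset:
                    wanted[g] += 1
        while sum(wanted.values()) > config.microbiome_subset:
            for g in DIAGNOSES:
                if wanted[g] > 0 and sum(wanted.values()) > config.microbiome_subset:
                    wanted[g] -= 1
    chosen: list[str] = []
    for group in DIAGNOSES:
        ids = metadata.index[metadata["diagnosis"] == group]
        chosen.extend(rng.choice(ids, size=wanted[group], replace=False))
    return pd.Index([s for s in metadata.index if s in set(chosen)])


def generate_omics(
    config: SynthConfig, metadata: pd.DataFrame
) -> tuple[dict[str, OmicsMatrix], GroundTruth]:
    """Generate all three abundance layers plus the ground-truth manifest.

    The microbiome layer is restricted to the configured sample subset.
    Matrices are raw-scale (strictly positive) with no missing cells;
    censoring is applied separately by :func:`apply_missingness`.
    """
    config.validate()
    rngs = _child_rngs(config)
    truth = GroundTruth()
    layers: dict[str, OmicsMatrix] = {}
    sizes = config.layer_sizes()
    for layer in LAYERS:
        meta = metadata
        if layer == "microbiome":
            subset = _microbiome_samples(metadata, config, rngs["microbiome"])
            meta = metadata.loc[subset]
        layers[layer] = _generate_layer(
            rngs[layer], layer, sizes[layer], meta, config, truth
        )
    return layers, truth


def apply_missingness(
    matrix: OmicsMatrix, truth: GroundTruth, config: SynthConfig
) -> OmicsMatrix:
    """Left-censor a raw matrix at per-feature detection thresholds (MNAR).

    Each feature draws a censoring quantile: with probability equal to the
    layer's completeness target it falls in [0, 0.5) (the feature stays
    detected in at least half the samples), otherwise in [0.5,
    ``censor_quantile``). Values strictly below the feature's empirical
    quantile at that level are masked. Thresholds are recorded in the
    ground truth; the input matrix is not modified.
    """
    config.validate()
    matrix.require_state("raw")
    if matrix.mask.any().any():
        raise ValueError("apply_missingness expects a matrix with no missing entries")
    out = matrix.copy()
    if config.censor_quantile == 0.0:
        truth.censoring_thresholds[matrix.layer] = {}
        return out
    rng = _child_rngs(config)[f"censor_{matrix.layer}"]
    target = config.completeness_target(matrix.layer)
    values = out.values.to_numpy(float)
    thresholds: dict[str, float] = {}
    for i, fid in enumerate(out.feature_ids):
        if rng.random() < target:
            q = rng.uniform(0.0, 0.5)
        else:
            q = rng.uniform(0.5, config.censor_quantile)
        thr = float(np.quantile(values[i], q))
        thresholds[fid] = thr
        values[i, values[i] < thr] = np.nan
    truth.censoring_thresholds[matrix.layer] = thresholds
    out.values = pd.DataFrame(values, index=out.feature_ids, columns=out.sample_ids)
    return out


def generate_study(config: SynthConfig) -> tuple[pd.DataFrame, dict[str, OmicsMatrix], GroundTruth]:
    """Full cohort: metadata plus censored raw layers and ground truth."""
    metadata = generate_cohort(config)
    layers, truth = generate_omics(config, metadata)
    censored = {
        layer: apply_missingness(mat, truth, config) for layer, mat in layers.items()
    }
    return metadata, censored, truth


def write_study(outdir: str | Path, config: SynthConfig) -> None:
    """Write metadata TSV, per-layer abundance TSVs and the truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metadata, layers, truth = generate_study(config)
    metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    for layer, mat in layers.items():
        write_matrix(mat, outdir / f"{layer}.tsv")
    truth.to_json(outdir / "ground_truth.json")
    (outdir / "synth_config.json").write_text(
        json.dumps(asdict(config), indent=2, default=list)
    )
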