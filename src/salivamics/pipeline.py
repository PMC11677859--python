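"""End-to-end orchestration of the biomarker-discovery workflow.

Each omics layer passes through a fixed stage order — median-normalized
log transform, downshift imputation, differential statistics per contrast,
trait correlations, correlation-network modules, ensemble marker ranking,
and (for configured layers) greedy panel construction — with a shared
sample-metadata table. All stage outputs are written as TSV/JSON and
declared in a manifest with content hashes, so identical configuration and
seed yield identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synth
from .datatypes import LAYERS, OmicsMatrix, read_matrix, validate_metadata
from .diffstats import CONTRASTS, moderated_ttest
from .network import NetworkParams, run_network_analysis
from .panel import greedy_panel
from .preprocess import ImputationParams, impute_downshift, log_median_normalize
from .ranking import RankerConfig, ensemble_rank
from .traitcorr import correlate_trait

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; loadable from a YAML file."""

    input_dir: str | None = None  # directory with metadata.tsv + <layer>.tsv
    synth_config: dict = field(default_factory=dict)  # used when input_dir is None
    output_dir: str = "pipeline_out"
    layers: tuple = LAYERS
    contrasts: tuple = CONTRASTS
    traits: tuple = ("ptau181", "age", "homocysteine", "vitamin_b12")
    correlation_methods: tuple = ("spearman", "pearson")
    imputation: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    ranking: dict = field(default_factory=dict)
    panel_layers: tuple = ("protein", "metabolite")
    panel_max_size: int = 4
    panel_pool: int = 37
    target_specificity: float = 0.95
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def validate_inputs(input_dir: str | Path) -> list[dict]:
    """Machine-readable issue list for a study directory (never raises)."""
    input_dir = Path(input_dir)
    issues: list[dict] = []
    meta_path = input_dir / "metadata.tsv"
    if not meta_path.exists():
        return [{"issue": "missing metadata.tsv", "path": str(meta_path)}]
    metadata = pd.read_csv(meta_path, sep="\t", index_col=0)
    dup = metadata.index[metadata.index.duplicated()].tolist()
    if dup:
        issues.append({"issue": "duplicate sample id", "ids": dup})
    if "diagnosis" not in metadata.columns:
        issues.append({"issue": "metadata lacks diagnosis column"})
    else:
        bad = sorted(set(metadata["diagnosis"]) - {"CN", "MCI", "AD"})
        if bad:
            issues.append({"issue": "unknown diagnosis labels", "labels": bad})
    for layer in LAYERS:
        path = input_dir / f"{layer}.tsv"
        if not path.exists():
            continue
        table = pd.read_csv(path, sep="\t", index_col=0)
        dup_rows = [
            {"feature_id": fid, "rows": list(np.where(table.index == fid)[0])}
            for fid in table.index[table.index.duplicated()].unique()
        ]
        if dup_rows:
            issues.append({"issue": "duplicated feature id", "layer": layer,
                           "details": dup_rows})
        unmatched = sorted(set(table.columns) - set(metadata.index.astype(str)))
        if unmatched:
            issues.append({"issue": "unmatched sample id", "layer": layer,
                           "ids": unmatched})
        non_numeric = table.apply(
            lambda col: pd.to_numeric(col, errors="coerce")
        ).isna() & table.notna()
        if non_numeric.any().any():
            issues.append({"issue": "non-numeric cells", "layer": layer,
                           "count": int(non_numeric.sum().sum())})
    return issues


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: PipelineConfig):
    if config.input_dir is not None:
        input_dir = Path(config.input_dir)
        metadata = pd.read_csv(input_dir / "metadata.tsv", sep="\t", index_col=0)
        layers = {
            layer: read_matrix(input_dir / f"{layer}.tsv")
            for layer in config.layers
            if (input_dir / f"{layer}.tsv").exists()
        }
    else:
        scfg = synth.SynthConfig(**{"seed": config.seed, **config.synth_config})
        metadata, layers, _ = synth.generate_study(scfg)
        layers = {k: v for k, v in layers.items() if k in config.layers}
    validate_metadata(metadata)
    return metadata, layers


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages for every layer and write the report bundle.

    Returns the manifest dict (also written to ``manifest.json``): config,
    seeds, per-stage row counts and a content hash for every output file.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    metadata, raw_layers = _load_inputs(config)
    metadata.to_csv(outdir / "metadata.tsv", sep="\t")

    outputs: list[Path] = [outdir / "metadata.tsv"]
    stage_counts: dict[str, dict] = {}
    results: dict = {"layers": {}}

    for layer, raw in raw_layers.items():
        stage = f"layer:{layer}"
        try:
            ldir = outdir / layer
            ldir.mkdir(exist_ok=True)
            meta = metadata.loc[raw.sample_ids]
            labels = meta["diagnosis"]
            case = labels.isin(["MCI", "AD"]).to_numpy()

            normalized = log_median_normalize(raw)
            imputed = impute_downshift(
                normalized,
                ImputationParams(**{"seed": config.seed, **config.imputation}),
            )

            de_tables = []
            for contrast in config.contrasts:
                de = moderated_ttest(imputed, labels, tuple(contrast))
                de_tables.append(de)
            de_all = pd.concat(de_tables, ignore_index=True)
            de_all.to_csv(ldir / "differential_stats.tsv", sep="\t", index=False)
            outputs.append(ldir / "differential_stats.tsv")

            corr_tables = []
            for trait in config.traits:
                if trait not in meta.columns:
                    continue
                for method in config.correlation_methods:
                    strata = ["all"]
                    if trait == "age":
                        strata = ["control_only", "case_only"]
                    for stratum in strata:
                        corr_tables.append(
                            correlate_trait(imputed, meta, trait, method, stratum)
                        )
            corr_all = pd.concat(corr_tables, ignore_index=True)
            corr_all.to_csv(ldir / "trait_correlations.tsv", sep="\t", index=False)
            outputs.append(ldir / "trait_correlations.tsv")

            net = run_network_analysis(
                imputed, meta, NetworkParams(**config.network)
            )
            net["fit_table"].to_csv(ldir / "soft_threshold_fit.tsv", sep="\t", index=False)
            assignment = net["modules"].labels.rename("module").to_frame()
            if len(net["kme"]):
                assignment = assignment.join(net["kme"].set_index("feature_id")["kme"])
            else:
                assignment["kme"] = np.nan
            assignment.to_csv(ldir / "module_assignment.tsv", sep="\t",
                              index_label="feature_id")
            eig_frame = pd.DataFrame(
                {m: e.scores for m, e in net["eigenfeatures"].items()}
            )
            eig_frame.to_csv(ldir / "eigenfeatures.tsv", sep="\t", index_label="sample_id")
            net["module_trait"].to_csv(ldir / "module_trait.tsv", sep="\t", index=False)
            outputs += [ldir / "soft_threshold_fit.tsv", ldir / "module_assignment.tsv",
                        ldir / "eigenfeatures.tsv", ldir / "module_trait.tsv"]

            rank_cfg = RankerConfig(**{"seed": config.seed, **config.ranking})
            ranking_table = ensemble_rank(imputed, case, rank_cfg)
            ranking_table.to_csv(ldir / "ranking.tsv", sep="\t", index=False)
            outputs.append(ldir / "ranking.tsv")

            layer_result = {"ranking": ranking_table, "network": net, "de": de_all,
                            "correlations": corr_all}

            if layer in config.panel_layers:
                pool = ranking_table["feature_id"].head(config.panel_pool).tolist()
                model = greedy_panel(
                    imputed, case, candidates=pool,
                    max_size=config.panel_max_size,
                    target_specificity=config.target_specificity,
                )
                panel_json = {
                    "members": model.members,
                    "auc": model.auc,
                    "sensitivity_at_spec": model.sensitivity_at_spec,
                    "target_specificity": model.target_specificity,
                    "trace": model.trace,
                    "pool_size": model.pool_size,
                }
                (ldir / "panel.json").write_text(json.dumps(panel_json, indent=2))
                pd.DataFrame({
                    "sample_id": imputed.sample_ids,
                    "loocv_probability": model.probabilities,
                }).to_csv(ldir / "panel_loocv_probabilities.tsv", sep="\t", index=False)
                outputs += [ldir / "panel.json", ldir / "panel_loocv_probabilities.tsv"]
                layer_result["panel"] = model

            stage_counts[layer] = {
                "features": raw.n_features,
                "samples": raw.n_samples,
                "de_rows": len(de_all),
                "correlation_rows": len(corr_all),
                "modules": len(net["modules"].module_names()),
                "ranking_rows": len(ranking_table),
            }
            results["layers"][layer] = layer_result
        except Exception as exc:
            (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
            raise RuntimeError(f"pipeline stage {stage} failed: {exc}") from exc

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "seed": config.seed,
        "stage_counts": stage_counts,
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(outputs))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
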