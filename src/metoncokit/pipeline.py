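"""End-to-end orchestration: features → labels → matrix → forest → reports.

A :class:`PipelineConfig` (loadable from YAML) names the model document and
the five omics tables, the labeling thresholds, forest hyperparameters,
validation scheme, and seeds.  :func:`run_pipeline` executes the stages in
order, writing every intermediate (distance profiles, knockout fluxes,
labels, feature matrix with sidecar, evaluation report, importance table)
into a run directory together with a manifest carrying the config hash and
seeds, so a rerun with the same config reproduces the outputs exactly.
Pan-cancer runs concatenate the per-cancer matrices into one pooled model;
cancer identity can optionally be added as a categorical feature.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (
    biochem_features,
    classifier_eval,
    feature_table,
    flux_analysis,
    network_model,
    target_labels,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "ConfigError",
    "run_pipeline",
    "config_hash",
    "concat_feature_matrices",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage (CLI exit code 3)."""


@dataclass
class CancerInputs:
    name: str
    model: str
    kcat: str
    expression: str
    survival: str
    cnv: str
    de: str


@dataclass
class PipelineConfig:
    cancers: list[CancerInputs]
    out_dir: str
    target: str = "de_label"  # de_label | cnv_label | survival_label
    thresholds: target_labels.LabelThresholds = field(
        default_factory=target_labels.LabelThresholds
    )
    forest: dict = field(default_factory=dict)
    scheme: str = "kfold"  # kfold | holdout | loco | lofso
    k: int = 10
    holdout_fraction: float = 0.3
    n_permutations: int = 0  # 0 disables the permutation null
    seed: int = 0
    paper_mode: bool = False
    absolute_flux_deltas: bool = False
    include_cancer_id: bool = False

    def validate(self) -> None:
        if not self.cancers:
            raise ConfigError("config names no cancer input set")
        if self.target not in ("de_label", "cnv_label", "survival_label"):
            raise ConfigError(f"unknown target {self.target!r}")
        if self.scheme not in ("kfold", "holdout", "loco", "lofso"):
            raise ConfigError(f"unknown validation scheme {self.scheme!r}")
        if not self.thresholds.hr_down < self.thresholds.hr_up:
            raise ConfigError("survival thresholds must satisfy down < up")
        for cancer in self.cancers:
            for fld in ("model", "kcat", "expression", "survival", "cnv", "de"):
                path = getattr(cancer, fld)
                if not Path(path).exists():
                    raise ConfigError(f"{cancer.name}: {fld} path not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        try:
            cancers = [CancerInputs(**c) for c in doc["cancers"]]
            thresholds = target_labels.LabelThresholds(**doc.get("thresholds", {}))
            kwargs = {
                k: doc[k]
                for k in (
                    "target", "forest", "scheme", "k", "holdout_fraction",
                    "n_permutations", "seed", "paper_mode",
                    "absolute_flux_deltas", "include_cancer_id",
                )
                if k in doc
            }
            return cls(
                cancers=cancers, out_dir=doc["out_dir"], thresholds=thresholds,
                **kwargs,
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed config: {exc}") from exc

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        return doc


def config_hash(config: PipelineConfig) -> str:
    """Stable hash over the full config, including thresholds and seeds."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def concat_feature_matrices(
    matrices: dict[str, feature_table.FeatureMatrix],
    include_cancer_id: bool = False,
) -> feature_table.FeatureMatrix:
    """Pool per-cancer matrices into one (pan-cancer) matrix.

    Cell-line index entries are prefixed with the cancer name so pooled
    rows stay unique; with *include_cancer_id* the cancer name is added as
    a categorical feature column.
    """
    frames, label_frames = [], []
    base_schema = next(iter(matrices.values())).schema
    for name, matrix in sorted(matrices.items()):
        data = matrix.data.copy()
        data.index = pd.MultiIndex.from_tuples(
            [(g, f"{name}/{cl}") for g, cl in data.index],
            names=["gene", "cell_line"],
        )
        if include_cancer_id:
            data["cancer"] = name
        frames.append(data)
        if matrix.labels is not None:
            labels = matrix.labels.copy()
            labels.index = data.index
            label_frames.append(labels)
    pooled = pd.concat(frames)
    schema = base_schema
    if include_cancer_id:
        schema = feature_table.FeatureSchema(
            tuple(list(base_schema.names) + ["cancer"]),
            {**dict(base_schema.category), "cancer": "topological"},
            {**dict(base_schema.kind), "cancer": "categorical"},
        )
    labels = pd.concat(label_frames) if label_frames else None
    return feature_table.FeatureMatrix(data=pooled, schema=schema, labels=labels)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except (ConfigError, PipelineError):
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("features")
def _build_cancer_matrix(
    cancer: CancerInputs, config: PipelineConfig, run_dir: Path
) -> feature_table.FeatureMatrix:
    model = network_model.parse_model(cancer.model)
    graph = network_model.build_metabolite_graph(model)
    profiles = network_model.compute_distance_profiles(model, graph)
    unreachable = len(model.metabolites) + 1
    dist_frame = network_model.distance_profiles_to_frame(profiles, unreachable)
    dist_frame.to_csv(run_dir / f"{cancer.name}.distances.tsv", sep="\t")

    ko_frame = flux_analysis.knockout_feature_frame(
        model, absolute=config.absolute_flux_deltas
    )
    ko_frame.to_csv(run_dir / f"{cancer.name}.knockout_flux.tsv", sep="\t")

    kcat = biochem_features.curate_kcat(
        biochem_features.read_kcat_tsv(cancer.kcat), model.genes
    )
    biochem_features.kcat_features_to_frame(kcat).to_csv(
        run_dir / f"{cancer.name}.kcat.tsv", sep="\t"
    )
    expression = biochem_features.read_expression_tsv(cancer.expression)

    matrix = feature_table.assemble_feature_matrix(
        model, dist_frame, ko_frame, kcat, expression
    )

    labels = target_labels.build_label_sets(
        pd.read_csv(cancer.survival, sep="\t"),
        pd.read_csv(cancer.cnv, sep="\t"),
        pd.read_csv(cancer.de, sep="\t"),
        config.thresholds,
    )
    label_frame = target_labels.label_sets_to_frame(labels)
    label_frame.to_csv(run_dir / f"{cancer.name}.labels.tsv", sep="\t")
    return feature_table.attach_labels(
        matrix, label_frame[["de_label", "cnv_label", "survival_label"]]
    )


@_stage("evaluate")
def _evaluate(matrix, config: PipelineConfig):
    common = {"seed": config.seed, "forest_params": config.forest or None}
    if config.scheme == "kfold":
        report = classifier_eval.k_fold_cv(
            matrix, config.target, k=config.k, paper_mode=config.paper_mode, **common
        )
        return {"kfold": report.to_dict()}
    if config.scheme == "holdout":
        report = classifier_eval.holdout_validation(
            matrix, config.target, fraction=config.holdout_fraction,
            paper_mode=config.paper_mode, **common,
        )
        return {"holdout": report.to_dict()}
    if config.scheme == "loco":
        reports = classifier_eval.leave_one_cell_line_out(
            matrix, config.target, **common
        )
        return {line: r.to_dict() for line, r in reports.items()}
    reports = classifier_eval.leave_one_feature_set_out(
        matrix, config.target, k=config.k, **common
    )
    return {cat: r.to_dict() for cat, r in reports.items()}


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the run directory.

    Outputs per cancer: distance, knockout-flux, kcat, and label tables;
    pooled: the encoded feature matrix (TSV + JSON sidecar), the
    evaluation report, the importance table, and ``manifest.json``.
    """
    config.validate()
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    matrices = {
        cancer.name: _build_cancer_matrix(cancer, config, run_dir)
        for cancer in config.cancers
    }
    if len(matrices) == 1:
        matrix = next(iter(matrices.values()))
    else:
        matrix = concat_feature_matrices(matrices, config.include_cancer_id)

    matrix = feature_table.encode_categoricals(matrix)
    matrix.to_tsv(run_dir / "feature_matrix.tsv")

    reports = _evaluate(matrix, config)
    if config.n_permutations > 0:
        reports["permutation"] = classifier_eval.permutation_significance(
            matrix, config.target, n_iter=config.n_permutations,
            seed=config.seed, forest_params=config.forest or None,
        )
    (run_dir / "evaluation.json").write_text(json.dumps(reports, indent=1, sort_keys=True))

    # Final model on all rows (scaled), for the importance ranking.
    scaled, scaling = feature_table.robust_scale(matrix.data)
    x_res, y_res = feature_table.random_oversample(
        scaled, matrix.labels[config.target], config.seed
    )
    model = classifier_eval.train_random_forest(
        x_res, y_res, config.forest or None, seed=config.seed, target=config.target
    )
    importance = classifier_eval.importance_report(
        model, scaled, matrix.labels[config.target]
    )
    importance.to_csv(run_dir / "importance.tsv", sep="\t")

    manifest = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_rows": int(len(matrix.data)),
        "n_features": int(len(matrix.schema.names)),
        "outputs": sorted(
            p.name for p in run_dir.iterdir() if p.name != "manifest.json"
        ),
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return run_dir
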