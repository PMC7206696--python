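"""Assembly of the gene × cell-line feature matrix.

Rows are (gene, cell line) pairs: features that are static for a gene —
network distances, epicenter scores, pathway membership, log2(kcat) — are
repeated across the gene's cell lines, while expression (and, when
cell-line-specific models are supplied, knockout-flux features) vary per
line.  Replicating genes across the lines of one cancer exposes the model
to within-cancer biological variation instead of a single point estimate.
Genes missing from any feature source are dropped and logged rather than
imputed.  Categorical columns are ordinally encoded with lexicographic
codes and a reversible map; numeric columns are robust-scaled
((x − median)/IQR); class imbalance is addressed by seeded random
oversampling of minority classes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .biochem_features import KcatFeature
from .network_model import MetabolicModel

__all__ = [
    "CATEGORIES",
    "FeatureSchema",
    "FeatureMatrix",
    "assemble_feature_matrix",
    "encode_categoricals",
    "apply_categorical_codes",
    "decode_categoricals",
    "robust_scale",
    "inverse_scale",
    "random_oversample",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("topological", "dynamic", "biochemical")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names with a category and a type per feature."""

    names: tuple[str, ...]
    category: Mapping[str, str]  # name -> topological | dynamic | biochemical
    kind: Mapping[str, str]  # name -> numeric | categorical

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names in schema")
        for name in self.names:
            if self.category.get(name) not in CATEGORIES:
                raise ValueError(f"feature {name!r} has no valid category")
            if self.kind.get(name) not in ("numeric", "categorical"):
                raise ValueError(f"feature {name!r} has no valid type")

    def of_category(self, category: str) -> list[str]:
        return [n for n in self.names if self.category[n] == category]

    @property
    def categorical_names(self) -> list[str]:
        return [n for n in self.names if self.kind[n] == "categorical"]

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "category": dict(self.category),
            "kind": dict(self.kind),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FeatureSchema":
        return cls(tuple(doc["names"]), doc["category"], doc["kind"])


@dataclass
class FeatureMatrix:
    """Feature values plus everything needed to interpret them.

    ``data`` is indexed by (gene, cell_line); ``labels`` (optional) holds
    one ternary class column per prediction target, aligned to ``data``.
    ``code_maps`` and ``scaling`` are populated by
    :func:`encode_categoricals` / :func:`robust_scale`.
    """

    data: pd.DataFrame
    schema: FeatureSchema
    labels: pd.DataFrame | None = None
    code_maps: dict[str, dict[str, int]] = field(default_factory=dict)
    scaling: pd.DataFrame | None = None  # columns: center, iqr

    def to_tsv(self, path: str | Path) -> None:
        """TSV of the matrix (and labels) plus a JSON sidecar with the schema,
        code maps, and scaling parameters."""
        path = Path(path)
        out = self.data
        if self.labels is not None:
            out = out.join(self.labels)
        out.to_csv(path, sep="\t")
        sidecar = {
            "schema": self.schema.to_dict(),
            "code_maps": self.code_maps,
            "scaling": None
            if self.scaling is None
            else self.scaling.to_dict(orient="index"),
            "label_columns": [] if self.labels is None else list(self.labels.columns),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True)
        )


def build_schema(
    distance_columns: list[str],
    subsystem_columns: list[str],
) -> FeatureSchema:
    """Schema for a model-derived matrix: distances + epicenters + pathway
    membership (topological), per-subsystem knockout flux (dynamic), and
    kcat + expression (biochemical)."""
    names: list[str] = []
    category: dict[str, str] = {}
    kind: dict[str, str] = {}
    for col in distance_columns:
        names.append(col)
        category[col] = "topological"
        kind[col] = "numeric"
    names.append("subsystem")
    category["subsystem"] = "topological"
    kind["subsystem"] = "categorical"
    for sub in subsystem_columns:
        col = f"ko_flux_{sub}"
        names.append(col)
        category[col] = "dynamic"
        kind[col] = "numeric"
    for col in ("log2_kcat", "expression"):
        names.append(col)
        category[col] = "biochemical"
        kind[col] = "numeric"
    return FeatureSchema(tuple(names), category, kind)


def assemble_feature_matrix(
    model: MetabolicModel,
    distance_frame: pd.DataFrame,
    knockout_frame: pd.DataFrame,
    kcat_features: Mapping[str, KcatFeature],
    expression: pd.Series,
    schema: FeatureSchema | None = None,
) -> FeatureMatrix:
    """One row per (gene, cell line) from the per-gene feature sources.

    *distance_frame* and *knockout_frame* are gene-indexed; *expression*
    is indexed by (gene, cell_line).  Genes absent from any source are
    dropped (logged at INFO); an empty intersection is an error.
    """
    cell_lines = sorted(expression.index.get_level_values("cell_line").unique())
    expr_genes = set(expression.index.get_level_values("gene"))
    gene_sets = {
        "distances": set(distance_frame.index),
        "knockout fluxes": set(knockout_frame.index),
        "kcat": set(kcat_features),
        "expression": expr_genes,
    }
    genes = sorted(set.intersection(*gene_sets.values()))
    dropped = sorted(set.union(*gene_sets.values()) - set(genes))
    for gene in dropped:
        missing_from = [k for k, v in gene_sets.items() if gene not in v]
        logger.info("dropping gene %s: missing from %s", gene, missing_from)
    if not genes:
        raise ValueError("no gene is present in every feature source")

    # Pathway membership: the subsystem of the gene's first reaction (id order).
    gene_subsystem = {
        g: (model.reactions_of_gene(g)[0].subsystem if g in model.genes else "")
        for g in genes
    }

    if schema is None:
        schema = build_schema(list(distance_frame.columns), list(knockout_frame.columns))

    index = pd.MultiIndex.from_product([genes, cell_lines], names=["gene", "cell_line"])
    rows = []
    for gene, line in index:
        row: dict[str, object] = {}
        for col in distance_frame.columns:
            row[col] = distance_frame.at[gene, col]
        row["subsystem"] = gene_subsystem[gene]
        for sub in knockout_frame.columns:
            row[f"ko_flux_{sub}"] = knockout_frame.at[gene, sub]
        row["log2_kcat"] = kcat_features[gene].log2_kcat
        if (gene, line) not in expression.index:
            raise ValueError(f"expression missing for ({gene}, {line})")
        row["expression"] = expression.loc[(gene, line)]
        rows.append(row)
    data = pd.DataFrame(rows, index=index, columns=list(schema.names))
    return FeatureMatrix(data=data, schema=schema)


def attach_labels(matrix: FeatureMatrix, label_frame: pd.DataFrame) -> FeatureMatrix:
    """Broadcast per-gene label columns to the matrix rows; genes without
    labels are dropped (the missing-value rule)."""
    genes = matrix.data.index.get_level_values("gene")
    keep = genes.isin(label_frame.index)
    n_drop = (~keep).sum()
    if n_drop:
        logger.info("dropping %d rows of genes without labels", n_drop)
    data = matrix.data[keep]
    labels = label_frame.reindex(data.index.get_level_values("gene"))
    labels.index = data.index
    return FeatureMatrix(
        data=data,
        schema=matrix.schema,
        labels=labels,
        code_maps=dict(matrix.code_maps),
        scaling=matrix.scaling,
    )


# ---------------------------------------------------------------------------
# Encoding / scaling / rebalancing
# ---------------------------------------------------------------------------


def encode_categoricals(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace categorical strings with stable lexicographic integer codes."""
    data = matrix.data.copy()
    code_maps: dict[str, dict[str, int]] = {}
    for col in matrix.schema.categorical_names:
        values = sorted({str(v) for v in data[col]})
        code_maps[col] = {v: i for i, v in enumerate(values)}
        data[col] = [code_maps[col][str(v)] for v in data[col]]
    data = data.astype(float)
    return FeatureMatrix(data, matrix.schema, matrix.labels, code_maps, matrix.scaling)


def apply_categorical_codes(
    frame: pd.DataFrame, code_maps: Mapping[str, Mapping[str, int]]
) -> pd.DataFrame:
    """Encode new rows with previously learned codes; unseen values are errors."""
    out = frame.copy()
    for col, mapping in code_maps.items():
        encoded = []
        for v in out[col]:
            key = str(v)
            if key not in mapping:
                raise KeyError(
                    f"unseen category {key!r} in column {col!r} at predict time"
                )
            encoded.append(mapping[key])
        out[col] = encoded
    return out.astype(float)


def decode_categoricals(matrix: FeatureMatrix) -> pd.DataFrame:
    """Map integer codes back to the original strings."""
    data = matrix.data.copy()
    for col, mapping in matrix.code_maps.items():
        inverse = {i: v for v, i in mapping.items()}
        data[col] = [inverse[int(v)] for v in data[col]]
    return data


def robust_scale(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale each column to (x − median)/IQR; zero-IQR columns divide by 1.

    Returns the scaled frame and a parameter frame (index = feature,
    columns = center, iqr) for exact inversion.
    """
    center = frame.median(axis=0)
    q1 = frame.quantile(0.25, interpolation="linear")
    q3 = frame.quantile(0.75, interpolation="linear")
    iqr = (q3 - q1).replace(0.0, 1.0)
    scaled = (frame - center) / iqr
    params = pd.DataFrame({"center": center, "iqr": iqr})
    return scaled, params


def inverse_scale(scaled: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    return scaled * params["iqr"] + params["center"]


def random_oversample(
    frame: pd.DataFrame, labels: pd.Series, seed: int
) -> tuple[pd.DataFrame, pd.Series]:
    """Resample minority classes with replacement up to the majority count.

    Every original row is retained; only the shortfall per class is drawn.
    Deterministic for a fixed seed.
    """
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("oversampling needs at least two classes")
    rng = np.random.default_rng(seed)
    majority = int(counts.max())
    take = [np.arange(len(frame))]
    positions = np.arange(len(frame))
    label_values = np.asarray(labels)
    for cls in sorted(counts.index):
        short = majority - int(counts[cls])
        if short > 0:
            pool = positions[label_values == cls]
            take.append(rng.choice(pool, size=short, replace=True))
    order = np.concatenate(take)
    return frame.iloc[order], labels.iloc[order]
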