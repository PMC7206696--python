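"""Enzyme turnover-number (kcat) curation and cell-line expression features.

Turnover numbers span many orders of magnitude, so the feature used
downstream is log2(kcat).  An enzyme measured against several substrates
gets the median of its per-substrate log2 values; an enzyme with no
measurement at all gets the median of the per-gene medians, flagged as
imputed.  Expression values are taken as provided (optionally log2
transformed) — one value per (gene, cell line).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "KcatRecord",
    "KcatFeature",
    "read_kcat_tsv",
    "read_expression_tsv",
    "curate_kcat",
    "kcat_features_to_frame",
]


@dataclass(frozen=True)
class KcatRecord:
    gene: str
    substrate: str
    kcat: float  # s^-1, > 0

    def __post_init__(self) -> None:
        if not self.kcat > 0:
            raise ValueError(
                f"kcat must be positive: {self.gene}/{self.substrate} = {self.kcat}"
            )


@dataclass(frozen=True)
class KcatFeature:
    gene: str
    log2_kcat: float
    imputed: bool


def read_kcat_tsv(path: str | Path) -> list[KcatRecord]:
    """Read a (gene, substrate, kcat_s^-1) table; non-positive kcat is rejected."""
    frame = pd.read_csv(path, sep="\t")
    return [
        KcatRecord(str(r.gene), str(r.substrate), float(r["kcat_s^-1"]))
        for _, r in frame.iterrows()
    ]


def read_expression_tsv(path: str | Path, log2: bool = False) -> pd.Series:
    """Read (gene, cell_line, value) rows into a Series indexed by (gene, cell_line)."""
    frame = pd.read_csv(path, sep="\t")
    dup = frame.duplicated(subset=["gene", "cell_line"])
    if dup.any():
        raise ValueError("duplicate (gene, cell_line) expression entries")
    series = frame.set_index(["gene", "cell_line"])["value"].astype(float)
    return np.log2(series) if log2 else series


def curate_kcat(
    records: Iterable[KcatRecord], gene_universe: set[str]
) -> dict[str, KcatFeature]:
    """Per-gene log2(kcat) features with median-of-medians imputation.

    A gene with records gets the median over its records of log2(kcat);
    a gene in *gene_universe* without records gets the median of the
    per-gene medians (computed over genes WITH records, so multi-substrate
    enzymes do not dominate the imputation value) with ``imputed=True``.
    """
    if not gene_universe:
        raise ValueError("gene universe is empty")
    per_gene: dict[str, list[float]] = {}
    for rec in records:
        per_gene.setdefault(rec.gene, []).append(np.log2(rec.kcat))
    if not per_gene:
        raise ValueError("no kcat records: imputation median is undefined")
    medians = {g: float(np.median(v)) for g, v in per_gene.items()}
    impute_value = float(np.median(list(medians.values())))

    features: dict[str, KcatFeature] = {}
    n_imputed = 0
    for gene in sorted(gene_universe):
        if gene in medians:
            features[gene] = KcatFeature(gene, medians[gene], imputed=False)
        else:
            features[gene] = KcatFeature(gene, impute_value, imputed=True)
            n_imputed += 1
    if n_imputed == len(gene_universe):
        warnings.warn("every gene in the universe lacked kcat records; all imputed")
    return features


def kcat_features_to_frame(features: Mapping[str, KcatFeature]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [(f.gene, f.log2_kcat, f.imputed) for f in features.values()],
        columns=["gene", "log2_kcat", "imputed"],
    )
    return frame.sort_values("gene").set_index("gene")
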