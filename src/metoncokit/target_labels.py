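"""Ternary tumor-fitness labels from survival, copy-number, and expression tables.

Each gene receives one of three classes — ``UP`` (increased activity favors
the tumor), ``NEUTRAL``, ``DOWN`` — for each of three prognostic targets:

* **survival** — from Cox proportional-hazards summaries (hazard ratio HR
  and p-value per cohort): UP if HR ≥ 1.33 and p ≤ 0.05, DOWN if HR ≤ 0.75
  and p ≤ 0.05, NEUTRAL otherwise; multiple cohort calls per gene are
  reconciled by plurality, ties → NEUTRAL.
* **cnv** — sample-level total copy number and average genome ploidy are
  classified GAIN/LOSS/NONE by the COSMIC v83 clauses; a gene is GAIN if its
  GAIN/LOSS count ratio exceeds 2.0, LOSS if below 0.5, NEUTRAL when the
  ratio is in [0.5, 2.0] or fewer than 5 measurements exist.
* **de** (differential expression) — median tumor-over-normal log2 fold
  change: UP at ≥ 2, DOWN at ≤ −2, NEUTRAL in between.

On output, UP/DOWN are rendered as UPREG/DOWNREG for survival and
differential expression and GAIN/LOSS for copy number.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UP",
    "NEUTRAL",
    "DOWN",
    "LabelThresholds",
    "LabelSet",
    "label_survival_record",
    "reconcile_labels",
    "classify_cnv_sample",
    "label_cnv_gene",
    "label_differential_expression",
    "build_label_sets",
    "label_sets_to_frame",
    "encode_label",
]

UP = "UP"
NEUTRAL = "NEUTRAL"
DOWN = "DOWN"

_ORDINAL = {
    DOWN: -1, NEUTRAL: 0, UP: 1,
    "DOWNREG": -1, "LOSS": -1, "UPREG": 1, "GAIN": 1,
}


def encode_label(label: str) -> int:
    """Ordinal encoding DOWN/LOSS → −1, NEUTRAL → 0, UP/GAIN → +1."""
    return _ORDINAL[label]


@dataclass(frozen=True)
class LabelThresholds:
    """All labeling cutoffs in one place.

    ``hr_up``/``hr_down`` may be swapped for the alternative pairs
    (0.90, 1.10) or (0.5, 2.0) used to probe threshold sensitivity.
    ``cnv_loss_ploidy_offset`` is the 2.7 subtracted from ploidy in the
    high-ploidy LOSS clause.
    """

    hr_up: float = 1.33
    hr_down: float = 0.75
    alpha: float = 0.05
    cnv_ploidy_cut: float = 2.7
    cnv_gain_cn_low_ploidy: int = 5
    cnv_gain_cn_high_ploidy: int = 9
    cnv_loss_ploidy_offset: float = 2.7
    cnv_ratio_low: float = 0.5
    cnv_ratio_high: float = 2.0
    cnv_min_measurements: int = 5
    de_up: float = 2.0
    de_down: float = -2.0


@dataclass
class LabelSet:
    gene: str
    de_label: str
    cnv_label: str
    survival_label: str
    provenance: dict[str, int]


def label_survival_record(
    hr: float,
    p: float,
    up_threshold: float = 1.33,
    down_threshold: float = 0.75,
    alpha: float = 0.05,
) -> str:
    """Classify one cohort's Cox summary; boundaries are inclusive."""
    if hr < 0 or math.isnan(hr):
        raise ValueError(f"hazard ratio must be non-negative, got {hr}")
    if not 0 <= p <= 1:
        raise ValueError(f"p-value out of [0, 1]: {p}")
    if p <= alpha:
        if hr >= up_threshold:
            return UP
        if hr <= down_threshold:
            return DOWN
    return NEUTRAL


def reconcile_labels(labels: Iterable[str]) -> str:
    """Plurality vote over per-cohort classes; any tie for the top → NEUTRAL."""
    counts = Counter(labels)
    if not counts:
        raise ValueError("cannot reconcile an empty label set")
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return NEUTRAL
    return ranked[0][0]


def classify_cnv_sample(
    total_copy_number: int,
    genome_ploidy: float,
    thresholds: LabelThresholds = LabelThresholds(),
) -> str:
    """COSMIC v83 sample-level call: GAIN, LOSS, or NONE.

    GAIN: ploidy ≤ 2.7 and CN ≥ 5, or ploidy > 2.7 and CN ≥ 9.
    LOSS: ploidy ≤ 2.7 and CN = 0, or ploidy > 2.7 and CN < (ploidy − 2.7).
    """
    t = thresholds
    if genome_ploidy <= 0:
        raise ValueError(f"genome ploidy must be positive, got {genome_ploidy}")
    if total_copy_number < 0:
        raise ValueError(f"total copy number must be non-negative, got {total_copy_number}")
    if genome_ploidy <= t.cnv_ploidy_cut:
        if total_copy_number >= t.cnv_gain_cn_low_ploidy:
            return "GAIN"
        if total_copy_number == 0:
            return "LOSS"
    else:
        if total_copy_number >= t.cnv_gain_cn_high_ploidy:
            return "GAIN"
        if total_copy_number < genome_ploidy - t.cnv_loss_ploidy_offset:
            return "LOSS"
    return "NONE"


def label_cnv_gene(
    samples: Sequence[tuple[int, float]],
    thresholds: LabelThresholds = LabelThresholds(),
) -> tuple[str, dict[str, int]]:
    """Gene-level CNV class from sample-level (copy number, ploidy) records.

    The gain/loss ratio is #GAIN / #LOSS over the gene's samples (ratio
    +inf when LOSS count is 0 but GAIN count positive).  Returns the class
    and the provenance counts.  NONE calls count toward the minimum-
    measurement requirement.
    """
    t = thresholds
    calls = Counter(classify_cnv_sample(cn, pl, t) for cn, pl in samples)
    counts = {
        "n_measurements": len(samples),
        "n_gain": calls.get("GAIN", 0),
        "n_loss": calls.get("LOSS", 0),
    }
    if len(samples) < t.cnv_min_measurements:
        return NEUTRAL, counts
    gain, loss = counts["n_gain"], counts["n_loss"]
    if loss == 0:
        ratio = math.inf if gain > 0 else 1.0  # no calls either way: balanced
    else:
        ratio = gain / loss
    if ratio > t.cnv_ratio_high:
        return UP, counts
    if ratio < t.cnv_ratio_low:
        return DOWN, counts
    return NEUTRAL, counts


def label_differential_expression(
    values: Sequence[float], up: float = 2.0, down: float = -2.0
) -> str:
    """Median log2 fold change, then the ±2 rule (boundaries inclusive)."""
    if len(values) == 0:
        raise ValueError("no differential-expression values for gene")
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite log2 fold change")
    med = float(np.median(arr))
    if med >= up:
        return UP
    if med <= down:
        return DOWN
    return NEUTRAL


# ---------------------------------------------------------------------------
# Table-level assembly
# ---------------------------------------------------------------------------


def build_label_sets(
    survival: pd.DataFrame,
    cnv: pd.DataFrame,
    de: pd.DataFrame,
    thresholds: LabelThresholds = LabelThresholds(),
) -> dict[str, LabelSet]:
    """Label every gene present in ALL three tables.

    Expected columns — survival: gene, cohort, hazard_ratio, p_value;
    cnv: gene, sample, total_copy_number, genome_ploidy;
    de: gene, log2_fold_change.  Genes missing from any table are dropped
    (the missing-value rule; they cannot be labeled on every target).
    """
    genes = (
        set(survival["gene"]) & set(cnv["gene"]) & set(de["gene"])
    )
    out: dict[str, LabelSet] = {}
    surv_by_gene = dict(tuple(survival.groupby("gene")))
    cnv_by_gene = dict(tuple(cnv.groupby("gene")))
    de_by_gene = dict(tuple(de.groupby("gene")))
    for gene in sorted(genes):
        srows = surv_by_gene[gene]
        per_cohort = [
            label_survival_record(
                float(r.hazard_ratio), float(r.p_value),
                thresholds.hr_up, thresholds.hr_down, thresholds.alpha,
            )
            for r in srows.itertuples()
        ]
        survival_label = reconcile_labels(per_cohort)
        crows = cnv_by_gene[gene]
        cnv_label, cnv_counts = label_cnv_gene(
            [(int(r.total_copy_number), float(r.genome_ploidy)) for r in crows.itertuples()],
            thresholds,
        )
        de_label = label_differential_expression(
            list(de_by_gene[gene]["log2_fold_change"]),
            thresholds.de_up,
            thresholds.de_down,
        )
        out[gene] = LabelSet(
            gene=gene,
            de_label=de_label,
            cnv_label=cnv_label,
            survival_label=survival_label,
            provenance={
                "n_survival_records": len(srows),
                "n_de_values": len(de_by_gene[gene]),
                **cnv_counts,
            },
        )
    return out


_RENDER = {
    "de": {UP: "UPREG", NEUTRAL: "NEUTRAL", DOWN: "DOWNREG"},
    "cnv": {UP: "GAIN", NEUTRAL: "NEUTRAL", DOWN: "LOSS"},
    "survival": {UP: "UPREG", NEUTRAL: "NEUTRAL", DOWN: "DOWNREG"},
}


def label_sets_to_frame(label_sets: dict[str, LabelSet]) -> pd.DataFrame:
    """One row per gene with field-standard class names and supporting counts."""
    rows = []
    for gene in sorted(label_sets):
        ls = label_sets[gene]
        rows.append(
            {
                "gene": gene,
                "de_label": _RENDER["de"][ls.de_label],
                "cnv_label": _RENDER["cnv"][ls.cnv_label],
                "survival_label": _RENDER["survival"][ls.survival_label],
                **ls.provenance,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def read_labels_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
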