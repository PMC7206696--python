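"""Synthetic toy models and omics tables with planted, recoverable signal.

Real runs of the pipeline consume a genome-scale reconstruction and large
tumor-omics extracts; nothing of that scale is needed to test the method.
This module generates

* small feasible metabolic models — media sources, a chain of internal
  conversions through every biomass precursor, random extra reactions,
  single-gene associations — so topology and flux features are computable
  and a positive wild-type biomass flux is guaranteed;
* omics tables (kcat, expression, survival, copy number, differential
  expression) whose records are constructed to reproduce a planted ternary
  label per gene under the labeling rules, with an optional label-noise
  flip applied last;
* a direct feature dataset with designated *signal features* shifted by a
  chosen effect size conditional on the class, for calibration and
  signal-recovery tests of the classifier stack.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .feature_table import CATEGORIES, FeatureMatrix, FeatureSchema
from .network_model import MetabolicModel, Metabolite, Reaction
from .target_labels import DOWN, NEUTRAL, UP, encode_label

__all__ = [
    "SUBSYSTEM_NAMES",
    "FixtureSpec",
    "generate_toy_model",
    "generate_omics_tables",
    "generate_feature_dataset",
]

SUBSYSTEM_NAMES = (
    "Glycolysis",
    "TCA cycle",
    "Amino acid metabolism",
    "Nucleotide synthesis",
    "Lipid metabolism",
    "Transport",
)

_CLASSES = (DOWN, NEUTRAL, UP)


@dataclass(frozen=True)
class FixtureSpec:
    """Sizes, planted-signal layout, and noise levels for all generators.

    ``effect_size`` is the per-class shift of each signal feature in units
    of the feature's unit-variance noise (classes at −1/0/+1 × effect);
    ``label_noise`` is the probability that an emitted label is flipped
    away from the planted one.
    """

    n_metabolites: int = 24
    n_reactions: int = 24
    n_genes: int = 15
    n_media: int = 3
    n_biomass: int = 3
    n_cell_lines: int = 5
    n_topological: int = 10
    n_dynamic: int = 10
    n_biochemical: int = 10
    signal_features: tuple[str, ...] = (
        "bio_feat_00",
        "bio_feat_01",
        "bio_feat_02",
        "bio_feat_03",
        "bio_feat_04",
    )
    effect_size: float = 2.0
    label_noise: float = 0.05
    compound_gprs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_metabolites", "n_reactions", "n_genes", "n_media",
            "n_biomass", "n_cell_lines",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.signal_features and self.effect_size <= 0:
            raise ValueError("signal features planted but effect_size <= 0")


# ---------------------------------------------------------------------------
# Toy metabolic models
# ---------------------------------------------------------------------------


def generate_toy_model(spec: FixtureSpec, max_retries: int = 5) -> MetabolicModel:
    """A random, connected, guaranteed-feasible toy model.

    Construction: one source exchange per media component; a linear chain
    of internal conversions from the media pool through intermediate
    metabolites to every biomass precursor; a biomass reaction consuming
    all precursors; remaining reaction budget spent on random internal
    conversions (some reversible).  Internal reactions carry a subsystem
    label and a gene association.  Feasibility (positive biomass flux) is
    certain by construction but still verified, regenerating with a bumped
    seed up to *max_retries* times.
    """
    for attempt in range(max_retries):
        model = _build_toy_model(replace(spec, seed=spec.seed + attempt))
        from .flux_analysis import wild_type_flux

        if wild_type_flux(model).objective_value > 1e-6:
            return model
    raise RuntimeError(f"no feasible toy model after {max_retries} attempts")


def _build_toy_model(spec: FixtureSpec) -> MetabolicModel:
    rng = np.random.default_rng(spec.seed)
    media = [f"M{i}_e" for i in range(spec.n_media)]
    biomass = [f"B{i}_c" for i in range(spec.n_biomass)]
    n_inter = max(2, spec.n_metabolites - spec.n_media - spec.n_biomass)
    inter = [f"X{i}_c" for i in range(n_inter)]

    metabolites = {
        **{m: Metabolite(m, compartment="e") for m in media},
        **{m: Metabolite(m, compartment="c") for m in inter + biomass},
    }

    genes = [f"g{i:02d}" for i in range(spec.n_genes)]
    # Reserve roughly a third of the genes for the random extra reactions so
    # the fixture has non-essential genes with non-trivial knockout profiles.
    n_core = max(1, (2 * spec.n_genes + 2) // 3)
    pools = {"core": genes[:n_core], "extra": genes[n_core:] or genes[:n_core]}
    reactions: dict[str, Reaction] = {}
    gene_idx = 0

    def _gpr(pool: str = "core") -> object:
        nonlocal gene_idx
        members = pools[pool]
        g = members[gene_idx % len(members)]
        gene_idx += 1
        if spec.compound_gprs and gene_idx % 3 == 0:
            g2 = members[gene_idx % len(members)]
            gene_idx += 1
            return ["or" if gene_idx % 2 else "and", g, g2]
        return g

    def _add(rid, reactants, products, lb=0.0, ub=1000.0, subsystem="", gpr=None):
        reactions[rid] = Reaction(
            id=rid, reactants=reactants, products=products,
            lower_bound=lb, upper_bound=ub, subsystem=subsystem,
            gene_association=gpr,
        )

    for m in media:
        _add(f"EX_{m}", {}, {m: 1.0}, ub=10.0, subsystem="Exchange")

    def _sub(r: np.random.Generator) -> str:
        return SUBSYSTEM_NAMES[int(r.integers(len(SUBSYSTEM_NAMES)))]

    # Backbone: every medium feeds the first intermediate; a chain runs
    # through all intermediates; the last intermediate makes every
    # biomass precursor.
    for m in media:
        _add(f"U_{m}", {m: 1.0}, {inter[0]: 1.0}, subsystem="Transport", gpr=_gpr())
    for a, b in zip(inter, inter[1:]):
        _add(f"C_{a}_{b}", {a: 1.0}, {b: 1.0}, subsystem=_sub(rng), gpr=_gpr())
    for b in biomass:
        _add(f"S_{b}", {inter[-1]: 1.0}, {b: 1.0}, subsystem=_sub(rng), gpr=_gpr())

    n_backbone = spec.n_media + (len(inter) - 1) + spec.n_biomass
    pool = inter + biomass
    for j in range(max(0, spec.n_reactions - n_backbone)):
        a, b = rng.choice(len(pool), size=2, replace=False)
        reversible = bool(rng.random() < 0.3)
        _add(
            f"R{j:02d}",
            {pool[a]: 1.0},
            {pool[b]: 1.0},
            lb=-1000.0 if reversible else 0.0,
            subsystem=_sub(rng),
            gpr=_gpr("extra"),
        )

    _add("BIOMASS", {b: 1.0 for b in biomass}, {}, subsystem="Biomass")
    used_genes: set[str] = set()
    for rxn in reactions.values():
        used_genes |= rxn.genes
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=used_genes,
        biomass_reaction_id="BIOMASS",
        biomass_components=list(biomass),
        media_components=list(media),
    )


# ---------------------------------------------------------------------------
# Omics tables
# ---------------------------------------------------------------------------


def _flip(label: str, rng: np.random.Generator, p: float) -> str:
    if rng.random() < p:
        others = [c for c in _CLASSES if c != label]
        return others[int(rng.integers(2))]
    return label


def generate_omics_tables(
    model: MetabolicModel, spec: FixtureSpec
) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Five omics tables engineered so labeling recovers a planted class.

    One planted ternary label is drawn per gene (balanced round-robin);
    each target's emitted records encode that label — flipped independently
    per target with probability ``label_noise`` — such that the survival,
    CNV-ratio, and fold-change rules reproduce it exactly.  Returns the
    tables keyed ``kcat, expression, survival, cnv, de`` and the planted
    per-gene labels.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = sorted(model.genes)
    planted = pd.Series(
        [_CLASSES[i % 3] for i in range(len(genes))], index=genes, name="planted"
    )
    # Shuffle which gene gets which class, deterministically.
    planted[:] = rng.permutation(planted.to_numpy())

    # HR centers per class are fixture constants chosen to sit safely inside
    # each labeling region (UP >= 1.33, DOWN <= 0.75 at significant p).
    surv_rows, cnv_rows, de_rows, kcat_rows, expr_rows = [], [], [], [], []
    for gene in genes:
        surv_label = _flip(planted[gene], rng, spec.label_noise)
        for cohort in range(3):
            if surv_label == UP:
                hr = max(1.34, float(rng.lognormal(math.log(1.8), 0.2)))
                p = float(rng.uniform(0.001, 0.05))
            elif surv_label == DOWN:
                hr = min(0.745, float(rng.lognormal(math.log(0.55), 0.2)))
                p = float(rng.uniform(0.001, 0.05))
            else:
                hr = float(rng.uniform(0.80, 1.25))
                p = float(rng.uniform(0.0, 1.0))
            surv_rows.append(
                {"gene": gene, "cohort": f"cohort{cohort}", "hazard_ratio": hr,
                 "p_value": p}
            )

        cnv_label = _flip(planted[gene], rng, spec.label_noise)
        if cnv_label == UP:
            counts = {"GAIN": 6, "LOSS": 1, "NONE": 3}  # ratio 6 > 2
        elif cnv_label == DOWN:
            counts = {"GAIN": 1, "LOSS": 6, "NONE": 3}  # ratio 1/6 < 0.5
        else:
            counts = {"GAIN": 2, "LOSS": 2, "NONE": 6}  # ratio 1
        sample_i = 0
        for call, n in counts.items():
            for _ in range(n):
                if call == "GAIN":
                    cn, ploidy = int(rng.integers(5, 9)), 2.0
                elif call == "LOSS":
                    cn, ploidy = 0, 2.0
                else:
                    cn, ploidy = int(rng.integers(1, 5)), 2.0
                cnv_rows.append(
                    {"gene": gene, "sample": f"s{sample_i}",
                     "total_copy_number": cn, "genome_ploidy": ploidy}
                )
                sample_i += 1

        de_label = _flip(planted[gene], rng, spec.label_noise)
        for _ in range(3):
            if de_label == UP:
                v = max(2.0, float(rng.normal(3.0, 0.4)))
            elif de_label == DOWN:
                v = min(-2.0, float(rng.normal(-3.0, 0.4)))
            else:
                v = float(np.clip(rng.normal(0.0, 0.5), -1.9, 1.9))
            de_rows.append({"gene": gene, "log2_fold_change": v})

        kcat_center = 5.0
        if "log2_kcat" in spec.signal_features:
            kcat_center += spec.effect_size * encode_label(planted[gene])
        for s in range(int(rng.integers(1, 4))):
            kcat_rows.append(
                {"gene": gene, "substrate": f"sub{s}",
                 "kcat_s^-1": float(2.0 ** rng.normal(kcat_center, 1.0))}
            )

        expr_center = 0.0
        if "expression" in spec.signal_features:
            expr_center = spec.effect_size * encode_label(planted[gene])
        for line in range(spec.n_cell_lines):
            expr_rows.append(
                {"gene": gene, "cell_line": f"CL{line}",
                 "value": float(rng.normal(expr_center, 1.0))}
            )

    tables = {
        "kcat": pd.DataFrame(kcat_rows),
        "expression": pd.DataFrame(expr_rows),
        "survival": pd.DataFrame(surv_rows),
        "cnv": pd.DataFrame(cnv_rows),
        "de": pd.DataFrame(de_rows),
    }
    return tables, planted


# ---------------------------------------------------------------------------
# Direct feature dataset with planted signal
# ---------------------------------------------------------------------------


def generate_feature_dataset(spec: FixtureSpec) -> FeatureMatrix:
    """A gene × cell-line feature matrix with class-conditional signal.

    Features are unit-variance Gaussian noise; each designated signal
    feature is additionally shifted by ``effect_size × class`` (class
    encoded −1/0/+1).  One balanced label per gene is broadcast to its
    cell lines, then flipped with probability ``label_noise`` (per gene).
    The emitted label column is named ``target``.  With
    ``effect_size = 0`` (allowed when ``signal_features`` is empty) the
    dataset is pure noise and any classifier should sit at chance.
    """
    rng = np.random.default_rng(spec.seed)
    names: list[str] = []
    category: dict[str, str] = {}
    kind: dict[str, str] = {}
    for cat, prefix, n in (
        ("topological", "topo_dist", spec.n_topological),
        ("dynamic", "dyn_flux", spec.n_dynamic),
        ("biochemical", "bio_feat", spec.n_biochemical),
    ):
        for i in range(n):
            name = f"{prefix}_{i:02d}"
            names.append(name)
            category[name] = cat
            kind[name] = "numeric"
    schema = FeatureSchema(tuple(names), category, kind)
    unknown = set(spec.signal_features) - set(names)
    if unknown:
        raise ValueError(f"signal features not in schema: {sorted(unknown)}")

    genes = [f"g{i:03d}" for i in range(spec.n_genes)]
    lines = [f"CL{i}" for i in range(spec.n_cell_lines)]
    true_labels = np.array([_CLASSES[i % 3] for i in range(len(genes))])
    rng.shuffle(true_labels)

    index = pd.MultiIndex.from_product([genes, lines], names=["gene", "cell_line"])
    data = pd.DataFrame(
        rng.normal(size=(len(index), len(names))), index=index, columns=names
    )
    shifts = np.array([encode_label(l) for l in true_labels], dtype=float)
    per_row_shift = np.repeat(shifts, len(lines))
    for feat in spec.signal_features:
        data[feat] += spec.effect_size * per_row_shift

    emitted = np.array(
        [_flip(l, rng, spec.label_noise) for l in true_labels], dtype=object
    )
    labels = pd.DataFrame(
        {"target": np.repeat(emitted, len(lines)),
         "planted": np.repeat(true_labels, len(lines))},
        index=index,
    )
    return FeatureMatrix(data=data, schema=schema, labels=labels)
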