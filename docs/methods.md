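# Methods notes

This note records the modelling choices, defaults, and numerical details
behind `metoncokit`, and what the synthetic fixtures do and do not probe.

## Network topology features

The metabolite graph is an unweighted simple digraph: each irreversible
reaction contributes an edge from every reactant to every product, each
reversible reaction contributes both directions, and parallel edges
collapse (hop counts are unaffected). Currency metabolites are **not**
excluded by default — an explicit exclusion list can be passed to
`build_metabolite_graph` when protons/water/ATP shortcuts are a concern.

A gene's position is anchored at the **products** of its reactions in both
directions: the media distance is the minimum hop count from a media
component to any product, the biomass distance the minimum from any product
to a biomass component. Product anchoring in the biomass direction is a
design choice (anchoring at reactants shifts every distance by one edge on
linear paths and is available by building the profile from a reversed
graph); it keeps the two directions symmetric around the same anchor set.
A gene in several reactions takes the minimum over all of them, and the
boolean structure of the gene–protein–reaction (GPR) rule is ignored for
topology — membership anywhere in the rule counts.

Unreachable components would make epicenter sums infinite; they instead
contribute a finite penalty of `n_metabolites + 1` (strictly larger than
any realizable hop count, so disconnection always ranks worse than any
connection). The penalty is a parameter of `epicenter_scores` /
`compute_distance_profiles`.

SBML input is read with libsbml (Level 3 `fbc` bounds and gene
associations); biomass components are taken as the biomass reaction's
reactants and media components as the metabolites importable through open
exchange reactions. The toy JSON dialect spells all of these explicitly.

## Flux analysis

Flux states come from a two-stage LP on scipy's HiGHS solver. Reversible
fluxes are split into non-negative forward/backward parts so the stage-2
objective Σ|v| stays linear. Numerical settings:

| quantity | value | why |
|---|---|---|
| solver feasibility/optimality tolerance | 1e-9 | solver-side precision |
| biomass fixing slack in stage 2 | 1e-9 | avoids knife-edge infeasibility |
| flux zero threshold | 1e-9 | sub-tolerance fluxes reported as exactly 0 |
| assertion-side tolerance (tests) | 1e-6 | what the solutions are held to |

Single-gene deletions clamp bounds to [0, 0] for every reaction whose GPR
evaluates inactive with that gene removed, then re-run **both** stages —
re-minimizing total flux after the knockout keeps the knockout state as
well-defined as the wild type. A deletion with no feasible steady state is
represented as the all-zero flux map, so its subsystem deltas equal −v_wt
(a lethal deletion carries no flux).

Per-subsystem dynamic features are the **signed** mean of (v_ko − v_wt)
over the subsystem's reactions; signed differences preserve the direction
of the rewiring, and an absolute-value mode is available behind the
`absolute` flag (and the `absolute_flux_deltas` config key). Subsystems
with no member reactions get 0.

## Biochemical features

Turnover numbers span orders of magnitude, so the feature is log2(kcat).
Per gene: median of the per-substrate log2 values (even counts: mean of the
central pair). Genes without any record receive the median of the
**per-gene medians** — not of the raw records — so enzymes measured against
many substrates cannot drag the imputation value; imputed features carry a
flag. Expression values are used as provided, with an optional log2
transform on read.

## Labeling rules

All boundaries are inclusive where the rule says "or less" / "or above":
p ≤ 0.05, HR ≥ 1.33 / ≤ 0.75, log2FC ≥ 2 / ≤ −2, and the CNV ratio band
[0.5, 2.0] is NEUTRAL-inclusive on both ends (GAIN and LOSS are the strict
outer regions). The high-ploidy COSMIC LOSS clause is read as
CN < (ploidy − 2.7) — the only numerically usable reading of the published
clause — and the offset is configurable. NONE-class samples count toward
the 5-measurement minimum (it is a minimum on *measurements*, not calls),
and a gene with gains but zero losses has ratio +∞ → GAIN. Alternative HR
pairs (0.90/1.10, 0.5/2.0) used for threshold-sensitivity checks are plain
parameters of `LabelThresholds`.

## Feature matrix and preprocessing

Rows are (gene, cell line) pairs: static features repeat across a gene's
lines, expression varies per line. Genes missing from any source are
dropped and logged, never imputed — filling missing genes with NEUTRAL
would inflate both class imbalance and apparent accuracy. A gene's pathway
feature is the subsystem of its first reaction in id order (deterministic;
multi-pathway genes are rare in the fixtures and a single label matches the
one-column pathway feature).

Categoricals are ordinally encoded with lexicographic codes and a stored
reverse map (unseen categories at predict time raise an error naming the
column). Scaling is (x − median)/IQR with linear-interpolation quartiles;
zero-IQR features divide by 1. Oversampling draws minority rows with
replacement up to the majority count, keeping every original row.

**Fold placement.** Scaling and oversampling are fit inside training folds
only, by default. Resampling before the split duplicates rows across the
train/evaluation boundary and inflates accuracy; `paper_mode=True`
reproduces that variant (resample + scale the full matrix, then split) for
comparison, and the regression test on pure noise pins the leakage-safe
default to chance-level accuracy.

## Classifier and validation

Forest defaults: 500 trees, unlimited depth, √(n_features) per split,
seeded; an optional grid search (3-fold, accuracy) records the best
parameters. Evaluation schemes: stratified k-fold (k = 10 default; k equal
to the row count degenerates to unstratified leave-one-out), stratified
70/30 holdout, leave-one-cell-line-out, and leave-one-feature-set-out over
the three feature categories.

Metrics are computed from the pooled out-of-fold confusion matrix:
per-class one-vs-rest precision/recall/specificity/F1 (macro-averaged,
zero when undefined), multiclass MCC in the covariance form (0 when the
denominator vanishes), and one-vs-rest macro AUROC from class
probabilities. The permutation null re-runs the evaluator on shuffled
labels and reports both the normal-fit upper-tail p (which can understate
significance when the null is skewed) and the empirical
(1 + #{null ≥ obs})/(n + 1). Correlation directions encode the class
−1/0/+1; this ordinal encoding is the package's choice. Per-gene summaries
take the plurality label across cell lines, resolving ties through the
median of the ordinal encodings, with numeric features summarized by their
median.

Pan-cancer runs concatenate per-cancer matrices (cell lines prefixed with
the cancer name); cancer identity is excluded as a feature by default and
available behind `include_cancer_id`.

## Synthetic fixtures: what they emulate, what they don't

`generate_toy_model` builds a feasible model by construction: per-medium
source exchanges (capacity 10), a conversion chain through every biomass
precursor, a biomass sink, and a random-reaction budget on top; roughly a
third of the genes are reserved for the random extra reactions so the
fixture contains both essential and dispensable genes. Defaults (24
metabolites, 24 reactions, 15 genes, 3 media, 3 biomass components, 5 cell
lines — five lines matching a typical per-cancer cell-line panel) keep
every stage exercised in milliseconds.

`generate_omics_tables` draws one balanced ternary label per gene and emits
records that reproduce it exactly under the labeling rules (HR centered
log-normally at 1.8 / 0.55 / uniform near 1 — fixture constants chosen to
sit safely inside each labeling region; CNV sample blocks with gain/loss
ratios 6, 1, and 1/6; fold changes at ±3 or near 0), flipping the emitted
label per target with probability `label_noise` first.

`generate_feature_dataset` skips the model entirely: unit-Gaussian features
in three named categories, with designated signal features shifted by
`effect_size × class`. Defaults plant 5 biochemical features at effect size
2.0 with 5% label noise over 60 genes × 5 lines (300 rows) — enough
separation that a calibrated pipeline should exceed 85% CV accuracy while
noise keeps it from being trivially perfect.

Passing tests on these fixtures show that the machinery is correct and
calibrated — the graph distances, LP optima, label rules, fold hygiene, and
importance ranking behave as specified. They do **not** show that real
tumor data is this predictable: the fixtures have no correlated feature
structure, no realistic metabolic topology, no missing-data pattern, and a
signal planted in exactly the features the labels were drawn from.

## Problem sizes in the acceptance checks

The acceptance script and suite run: 200 random models (≤ ~46 metabolites)
for the BFS-oracle comparison; 50 models of ≤ 15 reactions, wild type plus
every single-gene deletion, against the cobra pFBA oracle; null
calibration and permutation at n = 300 rows with a 200-iteration null over
a 100-tree holdout evaluator; signal recovery over 10 seeds with 200-tree
forests. These sizes give stable statistics in about ninety seconds on one
CPU; the forest size used in evaluation (200 trees) is an
evaluation-economy choice, with the 500-tree default unchanged for
analysis runs.

## Known limitations

- Per-cell-line metabolic models are accepted conceptually but the
  assembler shares one model's flux features across a cancer's cell lines
  (cell-line variation enters through expression); wiring per-line models
  in requires one `knockout_feature_frame` per line.
- No thermodynamic (loop-law) constraints: the two-stage LP can in
  principle leave flux in internal cycles, though Σ|v| minimization
  removes any cycle not required by the optimum.
- The SBML reader covers Level 3 + `fbc`; legacy "notes"-encoded bounds or
  GPRs are not parsed.
- AUROC is reported as NaN when a class is absent from an evaluation split.
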