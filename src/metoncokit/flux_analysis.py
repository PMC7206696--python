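"""Flux balance analysis with flux-sum minimization and gene deletions.

The flux state of a model is obtained by a two-stage linear program
(parsimonious FBA): stage 1 maximizes biomass flux subject to steady-state
mass balance ``S·v = 0`` and the flux bounds; stage 2 fixes biomass at its
optimum (minus a small numerical slack) and minimizes the total flux
``Σ|v|``, yielding a unique, parsimonious flux distribution.  Reversible
fluxes are split into non-negative forward and backward parts so both
stages stay linear.  Single-gene deletions clamp to zero the bounds of
every reaction whose gene–protein–reaction rule evaluates inactive without
the gene, then re-run the two-stage program.  The per-gene *dynamic*
features are, for each metabolic subsystem, the mean signed flux change
(knockout − wild type) over the subsystem's reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

from .network_model import Gpr, MetabolicModel

__all__ = [
    "SOLVER_TOLERANCE",
    "FLUX_ZERO_TOLERANCE",
    "BIOMASS_SLACK",
    "FluxSolution",
    "KnockoutFluxFeatures",
    "evaluate_gpr",
    "wild_type_flux",
    "knockout_flux",
    "subsystem_flux_deltas",
    "knockout_feature_frame",
]

# Solver-side feasibility/optimality tolerance.
SOLVER_TOLERANCE = 1e-9
# Fluxes with magnitude below this are reported as exactly 0.
FLUX_ZERO_TOLERANCE = 1e-9
# Stage-2 slack on the fixed biomass optimum, avoids numerical infeasibility.
BIOMASS_SLACK = 1e-9


@dataclass
class FluxSolution:
    reaction_flux: dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class KnockoutFluxFeatures:
    gene: str
    subsystem_delta: dict[str, float] = field(default_factory=dict)
    feasible: bool = True


def evaluate_gpr(expression: Gpr, deleted: set[str]) -> bool:
    """Evaluate a GPR tree: is the reaction still catalyzed after *deleted*?

    AND nodes require all children active (enzyme complex); OR nodes any
    child (isozymes); a leaf is active iff its gene is not deleted; an
    empty association (``None``) is always active (spontaneous reaction).
    """
    if expression is None:
        return True
    if isinstance(expression, str):
        return expression not in deleted
    if isinstance(expression, (list, tuple)) and len(expression) >= 2:
        op, children = expression[0], expression[1:]
        if op == "and":
            return all(evaluate_gpr(c, deleted) for c in children)
        if op == "or":
            return any(evaluate_gpr(c, deleted) for c in children)
    raise ValueError(f"malformed GPR expression: {expression!r}")


def _two_stage_lp(
    model: MetabolicModel, bound_overrides: dict[str, tuple[float, float]]
) -> FluxSolution:
    """Maximize biomass, then minimize Σ|v| at the biomass optimum."""
    rxn_ids = list(model.reactions)
    met_ids = list(model.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    n_rxn = len(rxn_ids)

    bounds_net = []
    for rid in rxn_ids:
        rxn = model.reactions[rid]
        lb, ub = bound_overrides.get(rid, (rxn.lower_bound, rxn.upper_bound))
        bounds_net.append((lb, ub))

    # Variable layout: forward part per reaction, then one backward part per
    # reaction with a negative lower bound.  Net flux v = f - b.
    back_of: dict[int, int] = {}
    var_bounds: list[tuple[float, float]] = []
    for j, (lb, ub) in enumerate(bounds_net):
        var_bounds.append((max(lb, 0.0), max(ub, 0.0)))
    for j, (lb, ub) in enumerate(bounds_net):
        if lb < 0:
            back_of[j] = len(var_bounds)
            var_bounds.append((max(-ub, 0.0), -lb))
    n_var = len(var_bounds)

    s = lil_matrix((len(met_ids), n_var))
    for j, rid in enumerate(rxn_ids):
        rxn = model.reactions[rid]
        for met, coef in rxn.reactants.items():
            s[met_index[met], j] -= coef
            if j in back_of:
                s[met_index[met], back_of[j]] += coef
        for met, coef in rxn.products.items():
            s[met_index[met], j] += coef
            if j in back_of:
                s[met_index[met], back_of[j]] -= coef
    s = s.tocsr()
    b_eq = np.zeros(len(met_ids))

    bio_j = rxn_ids.index(model.biomass_reaction_id)
    c1 = np.zeros(n_var)
    c1[bio_j] = -1.0
    if bio_j in back_of:
        c1[back_of[bio_j]] = 1.0

    opts = {"primal_feasibility_tolerance": SOLVER_TOLERANCE,
            "dual_feasibility_tolerance": SOLVER_TOLERANCE}
    res1 = linprog(c1, A_eq=s, b_eq=b_eq, bounds=var_bounds, method="highs",
                   options=opts)
    if not res1.success:
        return FluxSolution({}, float("nan"), "infeasible")
    biomass_opt = -res1.fun

    # Stage 2: min Σ(f + b) subject to biomass ≥ optimum − slack.
    c2 = np.ones(n_var)
    a_ub = np.zeros((1, n_var))
    a_ub[0, bio_j] = -1.0
    if bio_j in back_of:
        a_ub[0, back_of[bio_j]] = 1.0
    b_ub = np.array([-(biomass_opt - BIOMASS_SLACK)])
    res2 = linprog(c2, A_ub=a_ub, b_ub=b_ub, A_eq=s, b_eq=b_eq,
                   bounds=var_bounds, method="highs", options=opts)
    if not res2.success:  # pragma: no cover - stage 1 succeeded, slack guards this
        return FluxSolution({}, float("nan"), "infeasible")

    flux: dict[str, float] = {}
    for j, rid in enumerate(rxn_ids):
        v = res2.x[j] - (res2.x[back_of[j]] if j in back_of else 0.0)
        flux[rid] = 0.0 if abs(v) < FLUX_ZERO_TOLERANCE else float(v)
    return FluxSolution(flux, flux[model.biomass_reaction_id], "optimal")


def wild_type_flux(model: MetabolicModel) -> FluxSolution:
    """Parsimonious wild-type flux distribution (two-stage LP, see module doc)."""
    return _two_stage_lp(model, {})


def knockout_flux(model: MetabolicModel, gene: str) -> FluxSolution:
    """Flux distribution after deleting one gene.

    Reactions whose GPR evaluates inactive without *gene* get both bounds
    clamped to zero; the two-stage program is re-run.  A deletion that
    leaves no feasible steady state (never the case when zero flux is
    admissible) returns an all-zero flux map with status ``infeasible``.
    """
    if gene not in model.genes:
        raise KeyError(f"unknown gene {gene!r}")
    overrides = {
        rxn.id: (0.0, 0.0)
        for rxn in model.reactions.values()
        if rxn.gene_association is not None
        and not evaluate_gpr(rxn.gene_association, {gene})
    }
    sol = _two_stage_lp(model, overrides)
    if not sol.optimal:
        return FluxSolution({rid: 0.0 for rid in model.reactions}, 0.0, "infeasible")
    return sol


def subsystem_flux_deltas(
    model: MetabolicModel,
    wild: FluxSolution,
    ko: FluxSolution,
    gene: str = "",
    absolute: bool = False,
) -> KnockoutFluxFeatures:
    """Mean flux change per subsystem between a knockout and the wild type.

    For each subsystem the delta is the mean over its member reactions of
    ``v_ko − v_wt`` (signed by default; ``absolute=True`` averages
    magnitudes instead).  Subsystems without member reactions get 0.
    """
    if set(wild.reaction_flux) != set(ko.reaction_flux):
        raise ValueError("wild-type and knockout solutions cover different reactions")
    deltas: dict[str, list[float]] = {s: [] for s in model.subsystem_list}
    for rid, rxn in model.reactions.items():
        if rxn.subsystem in deltas:
            d = ko.reaction_flux[rid] - wild.reaction_flux[rid]
            deltas[rxn.subsystem].append(abs(d) if absolute else d)
    return KnockoutFluxFeatures(
        gene=gene,
        subsystem_delta={
            s: float(np.mean(v)) if v else 0.0 for s, v in deltas.items()
        },
        feasible=ko.optimal,
    )


def knockout_feature_frame(model: MetabolicModel, absolute: bool = False):
    """Single-gene deletion screen: gene × subsystem mean-flux-change table."""
    import pandas as pd

    wild = wild_type_flux(model)
    if not wild.optimal:
        raise ValueError("wild-type model is infeasible")
    rows = {}
    for gene in sorted(model.genes):
        ko = knockout_flux(model, gene)
        feats = subsystem_flux_deltas(model, wild, ko, gene=gene, absolute=absolute)
        rows[gene] = feats.subsystem_delta
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame = frame.reindex(columns=model.subsystem_list).fillna(0.0)
    frame.index.name = "gene"
    return frame
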