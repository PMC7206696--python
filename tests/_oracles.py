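"""Independent oracles used to cross-check the package's computations.

Deliberately avoid the code paths under test: shortest paths are a
hand-rolled breadth-first search (not networkx); flux solutions come from
cobra's solver stack (glpk via optlang, not scipy/HiGHS); metric formulas
come from scikit-learn's metric functions applied to label vectors (not
our confusion-matrix arithmetic).
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_distance(adjacency: dict[str, set[str]], source: str, target: str) -> float:
    """Hop count by plain breadth-first search; inf when unreachable."""
    if source not in adjacency:
        return float("inf")
    seen = {source}
    queue = deque([(source, 0)])
    while queue:
        node, d = queue.popleft()
        if node == target:
            return d
        for nxt in adjacency.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                queue.append((nxt, d + 1))
    return float("inf")


def model_adjacency(model) -> dict[str, set[str]]:
    """Directed metabolite adjacency rebuilt straight from the reactions."""
    adj: dict[str, set[str]] = {m: set() for m in model.metabolites}
    for rxn in model.reactions.values():
        for a in rxn.reactants:
            for b in rxn.products:
                adj[a].add(b)
                if rxn.lower_bound < 0:
                    adj[b].add(a)
    return adj


def oracle_gene_component_distance(model, gene, component, direction) -> float:
    adj = model_adjacency(model)
    best = float("inf")
    for rxn in model.reactions.values():
        if gene not in rxn.genes:
            continue
        for prod in rxn.products:
            if direction == "to_gene_products":
                d = bfs_distance(adj, component, prod)
            else:
                d = bfs_distance(adj, prod, component)
            best = min(best, d)
    return best


# ---------------------------------------------------------------------------
# Flux oracle via cobra
# ---------------------------------------------------------------------------


def _gpr_to_rule(gpr) -> str:
    if gpr is None:
        return ""
    if isinstance(gpr, str):
        return gpr
    op, children = gpr[0], gpr[1:]
    joined = f" {op} ".join(f"({_gpr_to_rule(c)})" for c in children)
    return joined


def to_cobra_model(model):
    import cobra

    cm = cobra.Model(getattr(model, "id", "oracle"))
    mets = {
        m.id: cobra.Metabolite(m.id, compartment=m.compartment)
        for m in model.metabolites.values()
    }
    rxns = []
    for rxn in model.reactions.values():
        cr = cobra.Reaction(rxn.id)
        cr.add_metabolites(
            {
                **{mets[m]: -c for m, c in rxn.reactants.items()},
                **{mets[m]: c for m, c in rxn.products.items()},
            }
        )
        cr.bounds = (rxn.lower_bound, rxn.upper_bound)
        rule = _gpr_to_rule(rxn.gene_association)
        if rule:
            cr.gene_reaction_rule = rule
        rxns.append(cr)
    cm.add_reactions(rxns)
    cm.objective = model.biomass_reaction_id
    return cm


def cobra_pfba_fluxes(model, knockout_gene: str | None = None):
    """Two-stage oracle: cobra FBA then parsimonious FBA; returns
    (biomass flux, {reaction: flux}).  Lethal knockouts return (0, zeros)."""
    from cobra.flux_analysis import pfba

    cm = to_cobra_model(model)
    with cm:
        if knockout_gene is not None and knockout_gene in {g.id for g in cm.genes}:
            cm.genes.get_by_id(knockout_gene).knock_out()
        sol = cm.slim_optimize(error_value=None)
        if sol is None or sol <= 1e-9:
            # no growth: the parsimonious solution is the zero flux state
            return 0.0, {r.id: 0.0 for r in cm.reactions}
        psol = pfba(cm)
        return float(psol.fluxes[model.biomass_reaction_id]), dict(psol.fluxes)


def steady_state_residual(model, flux: dict[str, float]) -> float:
    """max_m |Σ_r S[m, r]·v_r| recomputed from the stoichiometry."""
    balance = {m: 0.0 for m in model.metabolites}
    for rid, rxn in model.reactions.items():
        v = flux[rid]
        for m, c in rxn.reactants.items():
            balance[m] -= c * v
        for m, c in rxn.products.items():
            balance[m] += c * v
    return max(abs(v) for v in balance.values()) if balance else 0.0


# ---------------------------------------------------------------------------
# Metric oracle via scikit-learn
# ---------------------------------------------------------------------------


def sklearn_metric_bundle(y_true, y_pred, classes):
    from sklearn.metrics import (
        accuracy_score,
        f1_score,
        matthews_corrcoef,
        precision_score,
        recall_score,
    )

    return {
        "accuracy": accuracy_score(y_true, y_pred),
        "precision": precision_score(
            y_true, y_pred, labels=list(classes), average="macro", zero_division=0
        ),
        "recall": recall_score(
            y_true, y_pred, labels=list(classes), average="macro", zero_division=0
        ),
        "f1": f1_score(
            y_true, y_pred, labels=list(classes), average="macro", zero_division=0
        ),
        "mcc": matthews_corrcoef(y_true, y_pred),
    }
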