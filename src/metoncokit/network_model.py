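"""Constraint-based metabolic models and network-topology features.

A metabolic model is read either from SBML (Level 3 with the ``fbc``
flux-bounds and gene-association extensions) or from a small JSON dialect
used for toy models and fixtures.  The model's reactions induce an
unweighted directed graph over metabolites: every irreversible reaction
contributes one edge per (reactant, product) pair, every reversible
reaction contributes both directions.  On that graph we compute, per gene,
shortest-path hop distances between the products of the gene's reactions
and two declared component sets — exogenous media components (nutrients)
and biomass precursors — and summarize them as three *epicenter scores*:
the sum of media distances, the sum of biomass distances, and their total.
Genes near many nutrients or biomass precursors get low scores; genes in
the network periphery get high ones.

Gene–protein–reaction (GPR) associations are boolean trees encoded as
``None`` (no association), a gene-id string (leaf), or a list
``["and"|"or", child, child, ...]``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "UNREACHABLE",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "DistanceProfile",
    "ModelParseError",
    "ModelConfigurationError",
    "gpr_genes",
    "parse_model",
    "write_model_json",
    "build_metabolite_graph",
    "gene_component_distance",
    "epicenter_scores",
    "compute_distance_profiles",
    "distance_profiles_to_frame",
]


class ModelParseError(ValueError):
    """A model document is structurally invalid."""


class ModelConfigurationError(ValueError):
    """A model is missing required configuration (e.g. biomass reaction)."""


#: Sentinel returned when no directed path connects a gene to a component.
UNREACHABLE = math.inf

# GPR tree: None | gene-id string | ["and"|"or", child, ...]
Gpr = None | str | list


def gpr_genes(gpr: Gpr) -> set[str]:
    """All gene ids appearing anywhere in a GPR tree (boolean structure ignored)."""
    if gpr is None:
        return set()
    if isinstance(gpr, str):
        return {gpr}
    if isinstance(gpr, (list, tuple)):
        if len(gpr) < 2 or gpr[0] not in ("and", "or"):
            raise ModelParseError(f"malformed GPR node: {gpr!r}")
        out: set[str] = set()
        for child in gpr[1:]:
            out |= gpr_genes(child)
        return out
    raise ModelParseError(f"malformed GPR node: {gpr!r}")


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self) -> None:
        if not self.compartment:
            raise ModelParseError(f"metabolite {self.id!r}: empty compartment")


@dataclass
class Reaction:
    """A (possibly reversible) stoichiometric conversion with flux bounds.

    ``reactants`` and ``products`` map metabolite ids to positive
    stoichiometric coefficients.  Reversibility is synonymous with a
    negative lower flux bound.  Bounds are in mmol·gDW⁻¹·h⁻¹.
    """

    id: str
    reactants: dict[str, float] = field(default_factory=dict)
    products: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    subsystem: str = ""
    gene_association: Gpr = None

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelParseError(
                f"reaction {self.id!r}: lower_bound > upper_bound"
            )
        for side in (self.reactants, self.products):
            for met, coef in side.items():
                if coef <= 0:
                    raise ModelParseError(
                        f"reaction {self.id!r}: non-positive coefficient for {met!r}"
                    )
        gpr_genes(self.gene_association)  # validates the tree

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def genes(self) -> set[str]:
        return gpr_genes(self.gene_association)


@dataclass
class MetabolicModel:
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    genes: set[str]
    biomass_reaction_id: str
    biomass_components: list[str]
    media_components: list[str]
    subsystem_list: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for met in list(rxn.reactants) + list(rxn.products):
                if met not in self.metabolites:
                    raise ModelParseError(
                        f"reaction {rxn.id!r} references unknown metabolite {met!r}"
                    )
        if self.biomass_reaction_id not in self.reactions:
            raise ModelConfigurationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        for comp in list(self.biomass_components) + list(self.media_components):
            if comp not in self.metabolites:
                raise ModelConfigurationError(
                    f"declared component {comp!r} is not a model metabolite"
                )
        assoc_genes: set[str] = set()
        for rxn in self.reactions.values():
            assoc_genes |= rxn.genes
        missing = assoc_genes - self.genes
        if missing:
            raise ModelParseError(
                f"genes in associations but not declared: {sorted(missing)}"
            )
        if not self.subsystem_list:
            self.subsystem_list = sorted(
                {r.subsystem for r in self.reactions.values() if r.subsystem}
            )

    def reactions_of_gene(self, gene: str) -> list[Reaction]:
        """Reactions whose GPR mentions *gene*, in id order."""
        if gene not in self.genes:
            raise KeyError(f"unknown gene {gene!r}")
        return sorted(
            (r for r in self.reactions.values() if gene in r.genes),
            key=lambda r: r.id,
        )


@dataclass
class DistanceProfile:
    """Per-gene shortest-path distances to every declared component.

    ``media_distance`` holds, per media component, the minimum hop count
    from that component to any product of the gene's reactions;
    ``biomass_distance`` the minimum hop count from any product to the
    biomass component.  The three epicenter scores are the sums, with
    unreachable components substituted by a finite penalty value.
    """

    gene: str
    media_distance: dict[str, float]
    biomass_distance: dict[str, float]
    media_epicenter: float
    biomass_epicenter: float
    total_epicenter: float


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_JSON_KEYS = {"metabolites", "reactions", "biomass_reaction"}


def parse_model(source: str | Path | Mapping) -> MetabolicModel:
    """Parse a model from SBML, a toy-JSON file, or an already-loaded mapping.

    The toy JSON dialect is::

        {"metabolites": [{"id", "name", "compartment"}, ...],
         "reactions": [{"id", "reactants": {met: coef}, "products": {...},
                        "lower_bound", "upper_bound", "subsystem",
                        "gene_association"}, ...],
         "biomass_reaction": "...",
         "biomass_components": [...], "media_components": [...]}
    """
    if isinstance(source, Mapping):
        return _model_from_dict(source)
    path = Path(source)
    text = path.read_text()
    if text.lstrip().startswith("<"):
        return _model_from_sbml(str(path))
    return _model_from_dict(json.loads(text))


def _model_from_dict(doc: Mapping) -> MetabolicModel:
    missing = _JSON_KEYS - set(doc)
    if missing:
        raise ModelParseError(f"model document missing keys: {sorted(missing)}")
    metabolites = {
        m["id"]: Metabolite(
            id=m["id"], name=m.get("name", ""), compartment=m.get("compartment", "c")
        )
        for m in doc["metabolites"]
    }
    reactions: dict[str, Reaction] = {}
    for r in doc["reactions"]:
        rxn = Reaction(
            id=r["id"],
            reactants=dict(r.get("reactants", {})),
            products=dict(r.get("products", {})),
            lower_bound=float(r.get("lower_bound", 0.0)),
            upper_bound=float(r.get("upper_bound", 1000.0)),
            subsystem=r.get("subsystem", ""),
            gene_association=r.get("gene_association"),
        )
        reactions[rxn.id] = rxn
    genes = set(doc.get("genes", ()))
    for rxn in reactions.values():
        genes |= rxn.genes
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        biomass_reaction_id=doc["biomass_reaction"],
        biomass_components=list(doc.get("biomass_components", ())),
        media_components=list(doc.get("media_components", ())),
    )


def _model_from_sbml(path: str) -> MetabolicModel:
    import libsbml

    sdoc = libsbml.readSBMLFromString(Path(path).read_text())
    if sdoc.getNumErrors() > 0 and sdoc.getError(0).getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
        raise ModelParseError(f"SBML read error: {sdoc.getError(0).getMessage()}")
    smodel = sdoc.getModel()
    if smodel is None:
        raise ModelParseError("SBML document contains no model")

    metabolites = {
        sp.getId(): Metabolite(
            id=sp.getId(),
            name=sp.getName() or "",
            compartment=sp.getCompartment() or "c",
        )
        for sp in (smodel.getSpecies(i) for i in range(smodel.getNumSpecies()))
    }

    def _param(pid: str, default: float) -> float:
        p = smodel.getParameter(pid) if pid else None
        return p.getValue() if p is not None else default

    reactions: dict[str, Reaction] = {}
    for i in range(smodel.getNumReactions()):
        sr = smodel.getReaction(i)
        fbc_r = sr.getPlugin("fbc")
        if fbc_r is not None and fbc_r.isSetLowerFluxBound():
            lb = _param(fbc_r.getLowerFluxBound(), 0.0)
            ub = _param(fbc_r.getUpperFluxBound(), 1000.0)
        else:
            lb = -1000.0 if sr.getReversible() else 0.0
            ub = 1000.0
        gpr = None
        if fbc_r is not None and fbc_r.isSetGeneProductAssociation():
            gpr = _gpr_from_fbc(fbc_r.getGeneProductAssociation().getAssociation(), smodel)
        reactions[sr.getId()] = Reaction(
            id=sr.getId(),
            reactants={
                sr.getReactant(j).getSpecies(): sr.getReactant(j).getStoichiometry()
                for j in range(sr.getNumReactants())
            },
            products={
                sr.getProduct(j).getSpecies(): sr.getProduct(j).getStoichiometry()
                for j in range(sr.getNumProducts())
            },
            lower_bound=lb,
            upper_bound=ub,
            subsystem="",
            gene_association=gpr,
        )

    fbc_m = smodel.getPlugin("fbc")
    biomass_id = None
    if fbc_m is not None and fbc_m.getNumObjectives() > 0:
        obj = fbc_m.getActiveObjective() or fbc_m.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            biomass_id = obj.getFluxObjective(0).getReaction()
    if biomass_id is None:
        cands = [rid for rid in reactions if "biomass" in rid.lower()]
        if not cands:
            raise ModelConfigurationError("no biomass reaction declared in SBML")
        biomass_id = cands[0]

    biomass_components = sorted(reactions[biomass_id].reactants)
    # Media: metabolites importable through exchange reactions, i.e. boundary
    # reactions with a single participant and an open uptake direction.
    media = set()
    for rxn in reactions.values():
        if rxn.id == biomass_id:
            continue
        if len(rxn.reactants) + len(rxn.products) == 1:
            if rxn.reactants and rxn.lower_bound < 0:
                media |= set(rxn.reactants)
            elif rxn.products and rxn.upper_bound > 0 and not rxn.reactants:
                media |= set(rxn.products)
    genes = set()
    for rxn in reactions.values():
        genes |= rxn.genes
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        biomass_reaction_id=biomass_id,
        biomass_components=biomass_components,
        media_components=sorted(media),
    )


def _gpr_from_fbc(assoc, smodel) -> Gpr:
    import libsbml

    if assoc is None:
        return None
    if isinstance(assoc, libsbml.GeneProductRef):
        gp = smodel.getPlugin("fbc").getGeneProduct(assoc.getGeneProduct())
        return gp.getLabel() or gp.getId() if gp is not None else assoc.getGeneProduct()
    op = "and" if isinstance(assoc, libsbml.FbcAnd) else "or"
    children = [
        _gpr_from_fbc(assoc.getAssociation(i), smodel)
        for i in range(assoc.getNumAssociations())
    ]
    return [op, *children]


def write_model_json(model: MetabolicModel, path: str | Path) -> None:
    """Serialize a model to the toy JSON dialect (round-trips via parse_model)."""
    doc = {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "reactants": r.reactants,
                "products": r.products,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "gene_association": r.gene_association,
            }
            for r in model.reactions.values()
        ],
        "genes": sorted(model.genes),
        "biomass_reaction": model.biomass_reaction_id,
        "biomass_components": model.biomass_components,
        "media_components": model.media_components,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------


def build_metabolite_graph(
    model: MetabolicModel, exclude: Iterable[str] = ()
) -> nx.DiGraph:
    """Unweighted directed metabolite graph of reactant→product conversions.

    Reversible reactions contribute edges in both directions.  Parallel
    edges collapse (simple digraph); hop counts are unaffected.  Metabolite
    ids in *exclude* (e.g. currency metabolites) contribute no edges.
    """
    excluded = set(exclude)
    g = nx.DiGraph()
    g.add_nodes_from(m for m in model.metabolites if m not in excluded)
    for rxn in model.reactions.values():
        for a in rxn.reactants:
            if a in excluded:
                continue
            for b in rxn.products:
                if b in excluded:
                    continue
                g.add_edge(a, b)
                if rxn.reversible:
                    g.add_edge(b, a)
    return g


def gene_component_distance(
    model: MetabolicModel,
    graph: nx.DiGraph,
    gene: str,
    component: str,
    direction: str,
) -> float:
    """Shortest hop distance between a gene's reaction products and a component.

    ``direction="to_gene_products"`` (media): minimum over the gene's
    reactions and their products of the path length component → product.
    ``direction="from_gene_products"`` (biomass): minimum of product →
    component.  A product identical to the component has distance 0.
    Returns :data:`UNREACHABLE` when no path exists.
    """
    if direction not in ("to_gene_products", "from_gene_products"):
        raise ValueError(f"unknown direction {direction!r}")
    best = UNREACHABLE
    for rxn in model.reactions_of_gene(gene):
        for prod in rxn.products:
            if prod not in graph or component not in graph:
                continue
            try:
                if direction == "to_gene_products":
                    d = nx.shortest_path_length(graph, component, prod)
                else:
                    d = nx.shortest_path_length(graph, prod, component)
            except nx.NetworkXNoPath:
                continue
            best = min(best, d)
    return best


def epicenter_scores(
    model: MetabolicModel,
    graph: nx.DiGraph,
    gene: str,
    unreachable_value: float | None = None,
) -> DistanceProfile:
    """Distance profile and epicenter sums for one gene.

    Unreachable components enter the sums as *unreachable_value*
    (default: number of metabolites + 1), keeping the scores finite and
    ordinal while penalizing disconnection.
    """
    if unreachable_value is None:
        unreachable_value = len(model.metabolites) + 1
    media = {
        c: gene_component_distance(model, graph, gene, c, "to_gene_products")
        for c in model.media_components
    }
    biomass = {
        c: gene_component_distance(model, graph, gene, c, "from_gene_products")
        for c in model.biomass_components
    }

    def _sum(dists: dict[str, float]) -> float:
        return float(
            sum(unreachable_value if d == UNREACHABLE else d for d in dists.values())
        )

    m_sum, b_sum = _sum(media), _sum(biomass)
    return DistanceProfile(
        gene=gene,
        media_distance=media,
        biomass_distance=biomass,
        media_epicenter=m_sum,
        biomass_epicenter=b_sum,
        total_epicenter=m_sum + b_sum,
    )


def compute_distance_profiles(
    model: MetabolicModel,
    graph: nx.DiGraph | None = None,
    unreachable_value: float | None = None,
) -> dict[str, DistanceProfile]:
    """Distance profiles for every gene, sharing one BFS per component.

    Equivalent to calling :func:`epicenter_scores` per gene but computes a
    single single-source BFS per media component (forward) and per biomass
    component (on the reversed graph) instead of one path query per
    (gene, component) pair.
    """
    if graph is None:
        graph = build_metabolite_graph(model)
    if unreachable_value is None:
        unreachable_value = len(model.metabolites) + 1

    media_maps = {
        c: nx.single_source_shortest_path_length(graph, c) if c in graph else {}
        for c in model.media_components
    }
    rgraph = graph.reverse(copy=False)
    biomass_maps = {
        c: nx.single_source_shortest_path_length(rgraph, c) if c in rgraph else {}
        for c in model.biomass_components
    }

    gene_products: dict[str, set[str]] = {g: set() for g in model.genes}
    for rxn in model.reactions.values():
        for g in rxn.genes:
            gene_products[g] |= set(rxn.products)

    profiles: dict[str, DistanceProfile] = {}
    for gene in sorted(model.genes):
        prods = gene_products[gene]
        media = {
            c: min((m[p] for p in prods if p in m), default=UNREACHABLE)
            for c, m in media_maps.items()
        }
        biomass = {
            c: min((m[p] for p in prods if p in m), default=UNREACHABLE)
            for c, m in biomass_maps.items()
        }
        m_sum = float(
            sum(unreachable_value if d == UNREACHABLE else d for d in media.values())
        )
        b_sum = float(
            sum(unreachable_value if d == UNREACHABLE else d for d in biomass.values())
        )
        profiles[gene] = DistanceProfile(
            gene, media, biomass, m_sum, b_sum, m_sum + b_sum
        )
    return profiles


def distance_profiles_to_frame(
    profiles: Mapping[str, DistanceProfile],
    unreachable_value: float,
) -> pd.DataFrame:
    """Tabulate profiles: one row per gene, one column per component distance
    plus the three epicenter columns.  Unreachable distances are written as
    the substitution value so the table is fully numeric."""
    rows = []
    for gene in sorted(profiles):
        p = profiles[gene]
        row: dict[str, float] = {"gene": gene}
        for c, d in p.media_distance.items():
            row[f"media_dist_{c}"] = unreachable_value if d == UNREACHABLE else d
        for c, d in p.biomass_distance.items():
            row[f"biomass_dist_{c}"] = unreachable_value if d == UNREACHABLE else d
        row["media_epicenter"] = p.media_epicenter
        row["biomass_epicenter"] = p.biomass_epicenter
        row["total_epicenter"] = p.total_epicenter
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
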