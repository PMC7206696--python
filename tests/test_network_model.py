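"""Model parsing, metabolite-graph construction, and epicenter scores."""

import math

import networkx as nx
import pytest

import _oracles
from metoncokit.network_model import (
    UNREACHABLE,
    MetabolicModel,
    Metabolite,
    ModelConfigurationError,
    ModelParseError,
    Reaction,
    build_metabolite_graph,
    compute_distance_profiles,
    epicenter_scores,
    gene_component_distance,
    parse_model,
    write_model_json,
)
from metoncokit.synthetic_fixtures import FixtureSpec, generate_toy_model


class TestParsing:
    def test_toy_json_round_trip(self, tmp_path, toy_model):
        path = tmp_path / "model.json"
        write_model_json(toy_model, path)
        reparsed = parse_model(path)
        assert set(reparsed.metabolites) == set(toy_model.metabolites)
        assert set(reparsed.reactions) == set(toy_model.reactions)
        assert reparsed.genes == toy_model.genes
        assert reparsed.biomass_components == toy_model.biomass_components
        assert reparsed.media_components == toy_model.media_components
        for rid, rxn in toy_model.reactions.items():
            other = reparsed.reactions[rid]
            assert rxn.reactants == other.reactants
            assert rxn.products == other.products
            assert rxn.lower_bound == other.lower_bound
            assert rxn.gene_association == other.gene_association

    def test_chain_document_parses(self, chain_model, tmp_path):
        write_model_json(chain_model, tmp_path / "chain.json")
        model = parse_model(tmp_path / "chain.json")
        assert len(model.reactions) == 5
        assert model.biomass_components == ["D"]
        assert model.subsystem_list == sorted({"Exchange", "core", "Biomass"})

    def test_unknown_metabolite_is_parse_error(self):
        doc = {
            "metabolites": [{"id": "A"}],
            "reactions": [
                {"id": "BAD", "reactants": {"A": 1}, "products": {"GHOST": 1}},
                {"id": "BIO", "reactants": {"A": 1}, "products": {}},
            ],
            "biomass_reaction": "BIO",
        }
        with pytest.raises(ModelParseError, match="BAD"):
            parse_model(doc)

    def test_missing_biomass_is_configuration_error(self):
        doc = {
            "metabolites": [{"id": "A"}],
            "reactions": [{"id": "R", "reactants": {"A": 1}, "products": {}}],
            "biomass_reaction": "NOPE",
        }
        with pytest.raises(ModelConfigurationError):
            parse_model(doc)

    def test_invariant_violations_rejected(self):
        with pytest.raises(ModelParseError):
            Reaction("R", {"A": 1.0}, {}, lower_bound=5, upper_bound=1)
        with pytest.raises(ModelParseError):
            Reaction("R", {"A": -1.0}, {})
        with pytest.raises(ModelParseError):
            Metabolite("m", compartment="")


class TestGraph:
    def test_irreversible_edges_reactant_to_product_only(self):
        mets = {m: Metabolite(m) for m in "ABC"}
        rxns = {
            "R": Reaction("R", {"A": 1.0, "B": 1.0}, {"C": 1.0}),
            "BIO": Reaction("BIO", {"C": 1.0}, {}),
        }
        model = MetabolicModel(mets, rxns, set(), "BIO", [], [])
        g = build_metabolite_graph(model)
        assert set(g.edges) == {("A", "C"), ("B", "C")}

    def test_reversible_edges_both_directions(self):
        mets = {m: Metabolite(m) for m in "AB"}
        rxns = {
            "R": Reaction("R", {"A": 1.0}, {"B": 1.0}, lower_bound=-10),
            "BIO": Reaction("BIO", {"B": 1.0}, {}),
        }
        model = MetabolicModel(mets, rxns, set(), "BIO", [], [])
        g = build_metabolite_graph(model)
        assert set(g.edges) == {("A", "B"), ("B", "A")}

    def test_empty_model_empty_graph(self):
        mets = {"A": Metabolite("A")}
        model = MetabolicModel(
            mets, {"BIO": Reaction("BIO", {"A": 1.0}, {})}, set(), "BIO", [], []
        )
        g = build_metabolite_graph(model)
        assert g.number_of_edges() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_edge_count_bound(self, seed):
        model = generate_toy_model(FixtureSpec(seed=seed, signal_features=()))
        g = build_metabolite_graph(model)
        expected = sum(
            len(r.reactants) * len(r.products) * (2 if r.reversible else 1)
            for r in model.reactions.values()
        )
        assert g.number_of_edges() <= expected
        for rxn in model.reactions.values():
            for a in rxn.reactants:
                for b in rxn.products:
                    assert g.has_edge(a, b)
                    if rxn.reversible:
                        assert g.has_edge(b, a)

    def test_currency_exclusion_removes_edges(self, chain_model):
        g = build_metabolite_graph(chain_model, exclude=["B"])
        assert "B" not in g
        assert not nx.has_path(g, "A", "D")


class TestDistances:
    def test_single_edge_media_distance(self, chain_model):
        g = build_metabolite_graph(chain_model)
        # g1 catalyzes A->B; distance from medium A to product B is one hop
        assert gene_component_distance(chain_model, g, "g1", "A", "to_gene_products") == 1

    def test_chain_biomass_distance(self, chain_model):
        g = build_metabolite_graph(chain_model)
        # g1's product is B; B -> C -> D is two hops to the biomass precursor
        assert gene_component_distance(chain_model, g, "g1", "D", "from_gene_products") == 2

    def test_unknown_gene_is_lookup_error(self, chain_model):
        g = build_metabolite_graph(chain_model)
        with pytest.raises(KeyError):
            gene_component_distance(chain_model, g, "nope", "A", "to_gene_products")

    def test_unknown_direction_rejected(self, chain_model):
        g = build_metabolite_graph(chain_model)
        with pytest.raises(ValueError):
            gene_component_distance(chain_model, g, "g1", "A", "sideways")

    @pytest.mark.parametrize("seed", range(20))
    def test_distances_match_bfs_oracle(self, seed):
        model = generate_toy_model(
            FixtureSpec(seed=100 + seed, n_metabolites=30, n_reactions=30,
                        signal_features=())
        )
        g = build_metabolite_graph(model)
        for gene in sorted(model.genes):
            for comp in model.media_components:
                mine = gene_component_distance(model, g, gene, comp, "to_gene_products")
                assert mine == _oracles.oracle_gene_component_distance(
                    model, gene, comp, "to_gene_products"
                )
            for comp in model.biomass_components:
                mine = gene_component_distance(model, g, gene, comp, "from_gene_products")
                assert mine == _oracles.oracle_gene_component_distance(
                    model, gene, comp, "from_gene_products"
                )

    def test_reversible_copy_never_increases_distances(self):
        model = generate_toy_model(FixtureSpec(seed=11, signal_features=()))
        g = build_metabolite_graph(model)
        before = {
            (gene, comp): gene_component_distance(model, g, gene, comp, "to_gene_products")
            for gene in model.genes
            for comp in model.media_components
        }
        # add a reversible duplicate of every irreversible internal reaction
        for rid in list(model.reactions):
            rxn = model.reactions[rid]
            if not rxn.reversible and rxn.reactants and rxn.products:
                model.reactions[f"{rid}__rev"] = Reaction(
                    f"{rid}__rev", dict(rxn.reactants), dict(rxn.products),
                    lower_bound=-10, upper_bound=10,
                    gene_association=rxn.gene_association,
                )
        g2 = build_metabolite_graph(model)
        for (gene, comp), old in before.items():
            new = gene_component_distance(model, g2, gene, comp, "to_gene_products")
            assert new <= old


class TestEpicenterScores:
    def test_sums_recompute_from_component_maps(self, toy_model):
        g = build_metabolite_graph(toy_model)
        sentinel = len(toy_model.metabolites) + 1
        for gene in sorted(toy_model.genes):
            prof = epicenter_scores(toy_model, g, gene)
            media_sum = sum(
                sentinel if d == UNREACHABLE else d
                for d in prof.media_distance.values()
            )
            biomass_sum = sum(
                sentinel if d == UNREACHABLE else d
                for d in prof.biomass_distance.values()
            )
            assert prof.media_epicenter == media_sum
            assert prof.biomass_epicenter == biomass_sum
            assert prof.total_epicenter == prof.media_epicenter + prof.biomass_epicenter

    def test_known_chain_sums(self, chain_model):
        g = build_metabolite_graph(chain_model)
        prof = epicenter_scores(chain_model, g, "g1")
        assert prof.media_epicenter == 1  # A -> B
        assert prof.biomass_epicenter == 2  # B -> C -> D
        assert prof.total_epicenter == 3

    def test_all_unreachable_uses_sentinel(self):
        mets = {m: Metabolite(m) for m in "ABZ"}
        rxns = {
            "R": Reaction("R", {"A": 1.0}, {"B": 1.0}, gene_association="g1"),
            "BIO": Reaction("BIO", {"Z": 1.0}, {}),
        }
        model = MetabolicModel(mets, rxns, {"g1"}, "BIO", ["Z"], ["Z"])
        g = build_metabolite_graph(model)
        prof = epicenter_scores(model, g, "g1")
        sentinel = len(model.metabolites) + 1
        assert prof.media_distance["Z"] == UNREACHABLE
        assert prof.media_epicenter == sentinel
        assert prof.total_epicenter == 2 * sentinel

    def test_custom_unreachable_value(self, chain_model):
        mets = dict(chain_model.metabolites)
        mets["Z"] = Metabolite("Z")
        model = MetabolicModel(
            mets, dict(chain_model.reactions), set(chain_model.genes),
            "BIOMASS", ["D"], ["A", "Z"],
        )
        g = build_metabolite_graph(model)
        prof = epicenter_scores(model, g, "g1", unreachable_value=99)
        assert prof.media_epicenter == 1 + 99

    @pytest.mark.parametrize("seed", range(5))
    def test_bulk_profiles_match_per_gene_scores(self, seed):
        model = generate_toy_model(FixtureSpec(seed=200 + seed, signal_features=()))
        g = build_metabolite_graph(model)
        bulk = compute_distance_profiles(model, g)
        for gene in model.genes:
            single = epicenter_scores(model, g, gene)
            assert bulk[gene].media_distance == single.media_distance
            assert bulk[gene].biomass_distance == single.biomass_distance
            assert bulk[gene].total_epicenter == single.total_epicenter
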