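import numpy as np
import pytest

from topomod import FixtureSpec, fixture_currency_table, generate_network
from topomod.clustering import (
    adjacency_matrix,
    build_reaction_graph,
    cluster_modules,
    detect_antiporters,
    module_subnetwork,
    strip_currency,
)
from topomod.model import CurrencyTable, from_reaction_table

from conftest import open_exchanges, run_pipeline


class TestStripCurrency:
    def test_carrier_removed_exception_kept(self):
        model = from_reaction_table(
            [
                ("kinase", {"A[c]": -1, "atp[c]": -1, "B[c]": 1, "adp[c]": 1}, -10, 10),
                ("atp_synth", {"adp[c]": -1, "atp[c]": 1}, 0, 10),
            ]
        )
        ct = CurrencyTable(
            metabolites={"atp[c]", "adp[c]"},
            exceptions={("atp_synth", "atp[c]"), ("atp_synth", "adp[c]")},
        )
        out = strip_currency(model, ct)
        assert "atp[c]" not in out.stoichiometry(out.rxn_index()["kinase"])
        assert "atp[c]" in out.stoichiometry(out.rxn_index()["atp_synth"])

    def test_keep_all_reaction_untouched(self):
        model = from_reaction_table(
            [("cotransport", {"cl[e]": -1, "k[e]": -1, "cl[c]": 1, "k[c]": 1}, -10, 10)]
        )
        ct = CurrencyTable(metabolites={"k[c]"}, keep_all={"cotransport"})
        out = strip_currency(model, ct)
        assert "k[c]" in out.stoichiometry(0)

    def test_empty_table_identity(self, diamond):
        out = strip_currency(diamond, CurrencyTable())
        assert (out.S != diamond.S).nnz == 0


class TestAntiporters:
    def test_structural_detection(self):
        model = from_reaction_table(
            [
                ("anti", {"ala[c]": -1, "leu[e]": -1, "ala[e]": 1, "leu[c]": 1}, -10, 10),
                ("uni", {"glc[e]": -1, "glc[c]": 1}, -10, 10),
            ]
        )
        anti, keep = detect_antiporters(model)
        assert anti == {"anti"}

    def test_keep_list_preserves_transportability(self):
        # three antiporters over two species plus one uniporter; dropping
        # all antiporters would leave leu untransportable
        model = from_reaction_table(
            [
                ("a1", {"ala[c]": -1, "leu[e]": -1, "ala[e]": 1, "leu[c]": 1}, -10, 10),
                ("a2", {"ala[e]": -1, "leu[c]": -1, "ala[c]": 1, "leu[e]": 1}, -10, 10),
                ("a3", {"ala[c]": -1, "gly[e]": -1, "ala[e]": 1, "gly[c]": 1}, -10, 10),
                ("uni", {"ala[e]": -1, "ala[c]": 1}, -10, 10),
            ]
        )
        anti, keep = detect_antiporters(model)
        assert anti == {"a1", "a2", "a3"}
        removed = anti - keep
        # every movement of a removed antiporter stays possible
        kept_model_rxns = set(model.reaction_ids) - removed
        assert any(r in kept_model_rxns for r in ("a1", "a2"))  # leu transport
        assert "a3" in keep or any(r in kept_model_rxns for r in ("a1", "a3"))

    def test_irreversible_not_detected(self):
        model = from_reaction_table(
            [("anti", {"ala[c]": -1, "leu[e]": -1, "ala[e]": 1, "leu[c]": 1}, 0, 10)]
        )
        anti, _ = detect_antiporters(model)
        assert anti == set()


class TestReactionGraph:
    def test_currency_only_link_gives_no_edge(self):
        model = from_reaction_table(
            [
                ("r1", {"A[c]": -1, "atp[c]": -1, "B[c]": 1, "adp[c]": 1}, -10, 10),
                ("r2", {"C[c]": -1, "atp[c]": -1, "D[c]": 1, "adp[c]": 1}, -10, 10),
            ]
        )
        ct = CurrencyTable(metabolites={"atp[c]", "adp[c]"})
        g = build_reaction_graph(strip_currency(model, ct))
        assert not g.has_edge("r1", "r2")
        g_full = build_reaction_graph(model)
        assert g_full.has_edge("r1", "r2")

    def test_chain_edge_label(self):
        model = from_reaction_table(
            [
                ("r1", {"A[c]": -1, "B[c]": 1}, -10, 10),
                ("r2", {"B[c]": -1, "C[c]": 1}, -10, 10),
            ]
        )
        g = build_reaction_graph(model)
        assert g[r"r1"]["r2"]["metabolites"] == {"B[c]"}

    def test_edge_count_matches_pairwise_intersection_oracle(self):
        model, _ = generate_network(FixtureSpec(seed=5, n_modules=4))
        stripped, graph, _ = run_pipeline(model)
        mets = {
            rid: {
                m
                for m in stripped.stoichiometry(j)
                if m not in stripped.boundary_metabolites
            }
            for j, rid in enumerate(stripped.reaction_ids)
        }
        expected = sum(
            1
            for i, a in enumerate(stripped.reaction_ids)
            for b in stripped.reaction_ids[i + 1 :]
            if mets[a] & mets[b]
        )
        assert graph.number_of_edges() == expected


class TestClusterModules:
    def test_planted_partition_recovered(self):
        for seed in range(5):
            model, planted = generate_network(FixtureSpec(seed=seed))
            _, _, part = run_pipeline(model)
            assert part.reversible_sets() == planted.reversible_sets()

    def test_adjacency_is_block_diagonal(self):
        model, _ = generate_network(FixtureSpec(seed=9))
        _, graph, part = run_pipeline(model)
        A, order = adjacency_matrix(graph.subgraph([r for m in part.modules.values() for r in m]), part)
        member = part.module_of()
        mids = [member[r] for r in order]
        off_block = [
            A[i, j]
            for i in range(len(order))
            for j in range(len(order))
            if mids[i] != mids[j]
        ]
        assert not any(off_block)

    def test_internal_external_classification(self):
        # internal: all metabolites inside the module; external: borders it
        model = from_reaction_table(
            [
                ("rev1", {"A[c]": -1, "B[c]": 1}, -10, 10),
                ("irr_int", {"A[c]": -1, "B[c]": 1}, 0, 10),
                ("irr_ext", {"B[c]": -1, "Z[c]": 1}, 0, 10),
                ("rev2", {"Z[c]": -1, "W[c]": 1}, -10, 10),
            ]
            + open_exchanges("A[c]", "a")
            + open_exchanges("W[c]", "w")
        )
        g = build_reaction_graph(model)
        part = cluster_modules(g)
        sets = part.reversible_sets()
        assert frozenset({"rev1"}) in sets and frozenset({"rev2"}) in sets
        by_member = {next(iter(v)): k for k, v in part.modules.items()}
        m1 = by_member["rev1"]
        assert "irr_int" in part.internal_irreversible[m1]
        assert "irr_ext" in part.external_irreversible[m1]

    def test_no_shared_metabolite_across_modules(self):
        model, _ = generate_network(FixtureSpec(seed=13))
        stripped, graph, part = run_pipeline(model)
        mets_of = {
            mid: set().union(
                *(graph.nodes[r]["metabolites"] for r in members)
            )
            for mid, members in part.modules.items()
        }
        mids = sorted(mets_of)
        for i, a in enumerate(mids):
            for b in mids[i + 1 :]:
                assert not (mets_of[a] & mets_of[b])


class TestModuleSubnetwork:
    def test_restores_currency_stoichiometry(self):
        model, _ = generate_network(
            FixtureSpec(seed=1, n_modules=3, single_fraction=0.0, archetypes=("mixed_pair",))
        )
        _, _, part = run_pipeline(model)
        big = max(part.modules, key=lambda m: len(part.modules[m]))
        sub = module_subnetwork(model, part, big)
        # the connectors of the mixed pair carry their currency metabolites
        touched = set().union(
            *(sub.stoichiometry(j) for j in range(sub.n_reactions))
        )
        assert touched & {"atp[c]", "adp[c]", "nadh[c]", "nad[c]"}
        # currency is boundary inside the subnetwork (supplied from outside)
        assert {"atp[c]", "adp[c]"} & sub.boundary_metabolites or {
            "nadh[c]",
            "nad[c]",
        } & sub.boundary_metabolites

    def test_unknown_module(self, single_module):
        _, _, part = run_pipeline(single_module)
        with pytest.raises(KeyError):
            module_subnetwork(single_module, part, 999)

    def test_single_reaction_module_includes_neighbours(self, single_module):
        _, _, part = run_pipeline(single_module)
        sub = module_subnetwork(single_module, part, 1)
        assert set(sub.reaction_ids) == set(single_module.reaction_ids)
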