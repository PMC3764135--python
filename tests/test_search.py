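import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dmbn import (
    AcyclicityGuard,
    DirectedNetwork,
    PerturbationMatrix,
    SearchConfig,
    SimulationConfig,
    complete_template,
    local_score,
    network_score,
    simulate_planted_model,
    tabu_search,
)
from dmbn.errors import StructureError
from dmbn.search import _Scorer

from conftest import random_matrix


def all_dags(nodes):
    """Every labeled DAG over the node tuple (3 nodes -> 25 DAGs)."""
    pairs = list(itertools.combinations(nodes, 2))
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = set()
        for (a, b), s in zip(pairs, states):
            if s == 1:
                edges.add((a, b))
            elif s == 2:
                edges.add((b, a))
        g = nx.DiGraph(edges)
        g.add_nodes_from(nodes)
        if nx.is_directed_acyclic_graph(g):
            yield DirectedNetwork(tuple(nodes), edges)


class TestLocalScore:
    def test_empty_parent_set_scores_zero(self, rng):
        m = random_matrix(rng, n_genes=40, n_mutants=3)
        assert local_score("m0", set(), m, SearchConfig()) == 0.0

    def test_child_in_parents_rejected(self, rng):
        m = random_matrix(rng, n_genes=10, n_mutants=2)
        with pytest.raises(ValueError):
            local_score("m0", {"m0"}, m, SearchConfig())

    def test_omega_penalty_closed_form(self, rng):
        # each parent carries a 2x2 feature cross-block: 4 parameters, so
        # score(omega=3) - score(omega=1) = -2 * 2 * |Pa| * log N
        m = random_matrix(rng, n_genes=60, n_mutants=4)
        parents = {"m1", "m2"}
        s3 = local_score("m0", parents, m, SearchConfig(omega=3))
        s1 = local_score("m0", parents, m, SearchConfig(omega=1))
        expected = -(3 - 1) * (4 * len(parents) / 2) * math.log(60)
        assert s3 - s1 == pytest.approx(expected, abs=1e-10)

    def test_duplicate_parent_beats_independent(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            child = rng.integers(-1, 2, size=300)
            noise = rng.integers(-1, 2, size=300)
            df = pd.DataFrame(
                {"c": child, "dup": child, "ind": noise},
                index=[f"g{i}" for i in range(300)],
            )
            m = PerturbationMatrix(df)
            cfg = SearchConfig(omega=1.0)
            dup = local_score("c", {"dup"}, m, cfg)
            ind = local_score("c", {"ind"}, m, cfg)
            wins += dup > ind
        assert wins == 20


class TestNetworkScore:
    def test_empty_graph_zero(self, rng):
        m = random_matrix(rng, n_genes=30, n_mutants=3)
        g = DirectedNetwork(tuple(m.mutant_ids), set())
        assert network_score(g, m, SearchConfig()) == 0.0

    def test_single_edge_decomposability(self, rng):
        m = random_matrix(rng, n_genes=30, n_mutants=3)
        cfg = SearchConfig()
        g = DirectedNetwork(tuple(m.mutant_ids), {("m0", "m1")})
        assert network_score(g, m, cfg) == pytest.approx(
            local_score("m1", {"m0"}, m, cfg), abs=1e-10
        )

    def test_cache_matches_recomputation(self, rng):
        m = random_matrix(rng, n_genes=40, n_mutants=4)
        cfg = SearchConfig()
        g = DirectedNetwork(
            tuple(m.mutant_ids), {("m0", "m2"), ("m1", "m2"), ("m2", "m3")}
        )
        cached = network_score(g, m, cfg, _scorer=_Scorer(m, cfg))
        fresh = sum(
            local_score(n, g.parents(n), m, cfg) for n in g.node_ids
        )
        assert cached == pytest.approx(fresh, abs=1e-10)

    def test_cyclic_input_rejected(self, rng):
        m = random_matrix(rng, n_genes=10, n_mutants=2)
        with pytest.raises(StructureError):
            DirectedNetwork(("m0", "m1"), {("m0", "m1"), ("m1", "m0")})


class TestAcyclicityGuard:
    def test_two_cycle_detected(self):
        g = DirectedNetwork(("A", "B"), {("A", "B")})
        guard = AcyclicityGuard(g)
        assert guard.would_create_cycle(("add", "B", "A"))

    def test_transitive_edge_safe(self):
        g = DirectedNetwork(("A", "B", "C"), {("A", "B"), ("B", "C")})
        guard = AcyclicityGuard(g)
        assert not guard.would_create_cycle(("add", "A", "C"))
        assert guard.would_create_cycle(("add", "C", "A"))

    def test_reverse_with_alternative_path(self):
        g = DirectedNetwork(
            ("A", "B", "C"), {("A", "B"), ("A", "C"), ("C", "B")}
        )
        guard = AcyclicityGuard(g)
        # reversing A->B is unsafe: A -> C -> B survives
        assert guard.would_create_cycle(("reverse", "A", "B"))
        assert not guard.would_create_cycle(("reverse", "C", "B"))

    def test_missing_edge_queries_rejected(self):
        guard = AcyclicityGuard(DirectedNetwork(("A", "B"), set()))
        with pytest.raises(ValueError):
            guard.would_create_cycle(("delete", "A", "B"))
        with pytest.raises(ValueError):
            guard.would_create_cycle(("reverse", "A", "B"))

    def test_matches_dfs_oracle_over_random_moves(self):
        rng = np.random.default_rng(5)
        nodes = tuple(f"n{i}" for i in range(20))
        edges: set = set()
        guard = AcyclicityGuard(DirectedNetwork(nodes, edges))
        for _ in range(1000):
            a, b = rng.choice(20, size=2, replace=False)
            a, b = nodes[a], nodes[b]
            if (a, b) in edges:
                kind = rng.choice(["delete", "reverse"])
            else:
                kind = "add"
            move = (kind, a, b)
            # fresh DFS oracle
            g = nx.DiGraph(edges)
            g.add_nodes_from(nodes)
            if kind == "add":
                g.add_edge(a, b)
            elif kind == "delete":
                g.remove_edge(a, b)
            else:
                g.remove_edge(a, b)
                g.add_edge(b, a)
            expected = not nx.is_directed_acyclic_graph(g)
            assert guard.would_create_cycle(move) == expected
            if not expected:
                guard.apply(move)
                if kind == "add":
                    edges.add((a, b))
                elif kind == "delete":
                    edges.discard((a, b))
                else:
                    edges.discard((a, b))
                    edges.add((b, a))


class TestTabuSearch:
    def test_independent_columns_give_empty_graph(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "a": rng.integers(-1, 2, size=200),
                "b": rng.integers(-1, 2, size=200),
            },
            index=[f"g{i}" for i in range(200)],
        )
        m = PerturbationMatrix(df)
        g = tabu_search(m, complete_template(["a", "b"]), SearchConfig(omega=5))
        assert g.edges == set()

    @pytest.mark.parametrize("seed", range(5))
    def test_three_node_exhaustive_optimality(self, seed):
        rng = np.random.default_rng(seed)
        # C jointly determined by A and B, plus noise
        a = rng.integers(-1, 2, size=250)
        b = rng.integers(-1, 2, size=250)
        c = np.where(rng.random(250) < 0.85, np.sign(a + b), rng.integers(-1, 2, size=250))
        m = PerturbationMatrix(
            pd.DataFrame({"A": a, "B": b, "C": c}, index=[f"g{i}" for i in range(250)])
        )
        cfg = SearchConfig(omega=1.0)
        template = complete_template(["A", "B", "C"])
        best = tabu_search(m, template, cfg)
        scores = [network_score(g, m, cfg) for g in all_dags(("A", "B", "C"))]
        assert network_score(best, m, cfg) == pytest.approx(max(scores), abs=1e-8)

    def test_planted_chain_recovered(self):
        cfg = SimulationConfig(seed=11, n_regulators=6, n_genes=600, noise_flip=0.02)
        truth, matrix = simulate_planted_model(
            cfg, planted_edges={(i, i + 1) for i in range(5)}
        )
        from dmbn import build_template, extract_target_lists

        template = build_template(extract_target_lists(matrix), matrix.mutant_ids)
        learned = tabu_search(matrix, template, SearchConfig(omega=2.0))
        assert {tuple(sorted(e)) for e in learned.edges} == {
            tuple(sorted(e)) for e in truth.edges
        }

    def test_template_consistency_of_result(self, rng):
        m = random_matrix(rng, n_genes=100, n_mutants=5, density=0.3)
        from dmbn import build_template, extract_target_lists

        template = build_template(extract_target_lists(m), m.mutant_ids)
        g = tabu_search(m, template, SearchConfig(omega=1.0))
        for a, b in g.edges:
            assert template.allows(a, b)

    def test_omega_sparsity_monotone(self):
        cfg = SimulationConfig(seed=4, n_regulators=8, n_genes=800)
        truth, matrix = simulate_planted_model(cfg)
        from dmbn import build_template, extract_target_lists

        template = build_template(extract_target_lists(matrix), matrix.mutant_ids)
        counts = []
        for omega in (0.5, 1.0, 2.0, 4.0):
            g = tabu_search(matrix, template, SearchConfig(omega=omega))
            counts.append(len(g.edges))
        assert counts == sorted(counts, reverse=True)

    def test_zero_variance_nodes_isolated(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {
                "a": rng.integers(-1, 2, size=150),
                "b": rng.integers(-1, 2, size=150),
                "silent": np.zeros(150, dtype=int),
            },
            index=[f"g{i}" for i in range(150)],
        )
        m = PerturbationMatrix(df)
        g = tabu_search(m, complete_template(["a", "b", "silent"]), SearchConfig(omega=0.5))
        assert not any("silent" in e for e in g.edges)

    def test_deterministic_for_fixed_config(self):
        cfg = SimulationConfig(seed=2, n_regulators=6, n_genes=400)
        truth, matrix = simulate_planted_model(cfg)
        from dmbn import build_template, extract_target_lists

        template = build_template(extract_target_lists(matrix), matrix.mutant_ids)
        g1 = tabu_search(matrix, template, SearchConfig(omega=2.0, seed=1))
        g2 = tabu_search(matrix, template, SearchConfig(omega=2.0, seed=1))
        assert g1.edges == g2.edges

    def test_template_node_mismatch_rejected(self, rng):
        m = random_matrix(rng, n_genes=20, n_mutants=3)
        with pytest.raises(ValueError):
            tabu_search(m, complete_template(["x", "y"]), SearchConfig())
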