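"""Bayesian networks: scoring, search, parameters, inference, sampling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tbiroc import bn as bnmod
from tbiroc.bn import DAG, EdgeConstraints, ParameterizedBN


def all_three_node_dags(nodes=("A", "B", "C")):
    """All 25 DAGs on three labelled nodes."""
    pairs = list(itertools.combinations(nodes, 2))
    dags = []
    for choice in itertools.product((None, 0, 1), repeat=3):
        edges = set()
        for (u, v), c in zip(pairs, choice):
            if c == 0:
                edges.add((u, v))
            elif c == 1:
                edges.add((v, u))
        try:
            dags.append(DAG(tuple(nodes), frozenset(edges)))
        except ValueError:
            continue
    assert len(dags) == 25
    return dags


def chain_bn(strength=0.8):
    states = {v: (f"{v.lower()}0", f"{v.lower()}1") for v in "ABC"}
    s = strength
    cpts = {
        "A": np.array([0.35, 0.65]),
        "B": np.array([[s, 1 - s], [1 - s, s]]),
        "C": np.array([[s, 1 - s], [1 - s, s]]),
    }
    dag = DAG(("A", "B", "C"), frozenset({("A", "B"), ("B", "C")}))
    return ParameterizedBN(dag, states, cpts)


def enumerate_conditional(bn, target, evidence):
    """Brute-force joint enumeration oracle for query()."""
    nodes = bn.dag.nodes
    parents = {v: bn.dag.parents(v) for v in nodes}
    dist = np.zeros(bn.card(target))
    for combo in itertools.product(*(range(bn.card(v)) for v in nodes)):
        idx = dict(zip(nodes, combo))
        if any(idx[v] != bn.states[v].index(val) for v, val in evidence.items()):
            continue
        p = 1.0
        for v in nodes:
            key = tuple(idx[u] for u in parents[v]) + (idx[v],)
            p *= float(bn.cpts[v][key])
        dist[idx[target]] += p
    return dist / dist.sum()


@pytest.fixture(scope="module")
def five_node_bn():
    rng = np.random.default_rng(4)
    nodes = ("A", "B", "C", "D", "E")
    edges = frozenset({("A", "B"), ("A", "C"), ("B", "D"), ("C", "D"), ("D", "E")})
    dag = DAG(nodes, edges)
    cards = {"A": 2, "B": 3, "C": 2, "D": 2, "E": 3}
    states = {v: tuple(f"{v.lower()}{i}" for i in range(cards[v])) for v in nodes}
    cpts = {}
    for v in nodes:
        shape = tuple(cards[p] for p in dag.parents(v)) + (cards[v],)
        raw = rng.random(shape) + 0.1
        cpts[v] = raw / raw.sum(axis=-1, keepdims=True)
    return ParameterizedBN(dag, states, cpts)


class TestDAG:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            DAG(("A", "B"), frozenset({("A", "B"), ("B", "A")}))

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            DAG(("A",), frozenset({("A", "A")}))

    def test_equivalence_signature_ignores_covered_orientation(self):
        a = DAG(("A", "B"), frozenset({("A", "B")}))
        b = DAG(("A", "B"), frozenset({("B", "A")}))
        assert a.cpdag_signature() == b.cpdag_signature()


class TestBICScore:
    def test_empty_graph_best_on_independent_data(self, rng):
        n = 3000
        data = pd.DataFrame({v: rng.integers(0, 2, n).astype(str) for v in "ABC"})
        scores = {dag.edges: bnmod.bic_score(dag, data)
                  for dag in all_three_node_dags()}
        assert max(scores, key=scores.get) == frozenset()

    def test_score_equivalence_of_covered_edge_flip(self, rng):
        n = 500
        a = rng.integers(0, 2, n)
        b = (a ^ (rng.random(n) < 0.3)).astype(int)
        data = pd.DataFrame({"A": a.astype(str), "B": b.astype(str)})
        s_ab = bnmod.bic_score(DAG(("A", "B"), frozenset({("A", "B")})), data)
        s_ba = bnmod.bic_score(DAG(("A", "B"), frozenset({("B", "A")})), data)
        assert s_ab == pytest.approx(s_ba, abs=1e-9)

    def test_true_edge_raises_score_on_dependent_data(self):
        df = bnmod.sample_bn(chain_bn(), 4000, seed=8)
        empty = bnmod.bic_score(DAG(("A", "B", "C")), df)
        withedge = bnmod.bic_score(DAG(("A", "B", "C"), frozenset({("A", "B")})), df)
        assert withedge > empty


class TestHillClimb:
    def test_recovers_chain_equivalence_class(self):
        truth = chain_bn()
        df = bnmod.sample_bn(truth, 10000, seed=5)
        learned = bnmod.hill_climb(df, restarts=3, seed=1)
        assert learned.cpdag_signature() == truth.dag.cpdag_signature()
        # exhaustive oracle: learned score equals the global maximum
        best = max(bnmod.bic_score(d, df) for d in all_three_node_dags())
        assert bnmod.bic_score(learned, df) == pytest.approx(best, abs=1e-9)

    def test_whitelist_edge_always_present(self):
        df = bnmod.sample_bn(chain_bn(), 2000, seed=6)
        cons = EdgeConstraints(whitelist=frozenset({("C", "A")}))
        learned = bnmod.hill_climb(df, cons, restarts=2, seed=2)
        assert ("C", "A") in learned.edges

    def test_blacklist_respected(self):
        df = bnmod.sample_bn(chain_bn(), 5000, seed=7)
        cons = EdgeConstraints(blacklist=frozenset({("A", "B"), ("B", "A")}))
        learned = bnmod.hill_climb(df, cons, restarts=2, seed=2)
        assert not {("A", "B"), ("B", "A")} & learned.edges

    def test_independent_data_yields_empty_graph(self, rng):
        data = pd.DataFrame({v: rng.integers(0, 3, 4000).astype(str) for v in "ABCD"})
        learned = bnmod.hill_climb(data, restarts=3, seed=3)
        assert learned.edges == frozenset()

    def test_inconsistent_constraints_rejected(self):
        with pytest.raises(ValueError):
            EdgeConstraints(whitelist=frozenset({("A", "B")}),
                            blacklist=frozenset({("A", "B")}))

    def test_deterministic_given_seed(self):
        df = bnmod.sample_bn(chain_bn(), 3000, seed=9)
        a = bnmod.hill_climb(df, restarts=4, seed=11)
        b = bnmod.hill_climb(df, restarts=4, seed=11)
        assert a.edges == b.edges


class TestFitCPTs:
    def test_single_node_frequencies(self):
        df = pd.DataFrame({"X": ["a"] * 2 + ["b"] * 3 + ["c"] * 5})
        bn = bnmod.fit_cpts(DAG(("X",)), df, states={"X": ("a", "b", "c")})
        np.testing.assert_allclose(bn.cpts["X"], [0.2, 0.3, 0.5])

    def test_unseen_config_uniform_and_flagged(self):
        df = pd.DataFrame({"P": ["p0"] * 10, "X": ["x0"] * 5 + ["x1"] * 5})
        dag = DAG(("P", "X"), frozenset({("P", "X")}))
        bn = bnmod.fit_cpts(dag, df, states={"P": ("p0", "p1"),
                                             "X": ("x0", "x1", "x2", "x3")},
                            smoothing=0.0)
        np.testing.assert_allclose(bn.cpts["X"][1], [0.25] * 4)
        assert bn.flagged_configs["X"] == [(1,)]

    def test_parameter_recovery(self):
        truth = chain_bn(0.75)
        df = bnmod.sample_bn(truth, 50000, seed=12)
        bn = bnmod.fit_cpts(truth.dag, df, states=truth.states)
        for v in truth.dag.nodes:
            assert np.max(np.abs(bn.cpts[v] - truth.cpts[v])) < 0.02


class TestQuery:
    def test_root_without_evidence_returns_cpt(self, five_node_bn):
        out = bnmod.query(five_node_bn, "A")
        np.testing.assert_allclose(out.to_numpy(), five_node_bn.cpts["A"],
                                   atol=1e-12)

    def test_chain_evidence_returns_cpt_row(self):
        bn = chain_bn()
        out = bnmod.query(bn, "B", {"A": "a1"})
        np.testing.assert_allclose(out.to_numpy(), bn.cpts["B"][1], atol=1e-12)

    @pytest.mark.parametrize("target, evidence", [
        ("A", {}), ("A", {"E": "e2"}), ("A", {"B": "b1", "E": "e0"}),
        ("D", {}), ("D", {"A": "a0"}), ("D", {"E": "e2"}),
        ("D", {"B": "b1", "E": "e0"}), ("D", {"A": "a1", "C": "c0", "E": "e1"}),
    ])
    def test_matches_brute_force_enumeration(self, five_node_bn, target, evidence):
        got = bnmod.query(five_node_bn, target, evidence).to_numpy()
        want = enumerate_conditional(five_node_bn, target, evidence)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_impossible_evidence_rejected(self):
        bn = chain_bn(1.0)  # deterministic links
        with pytest.raises(ValueError, match="zero probability"):
            bnmod.query(bn, "C", {"A": "a0", "B": "b1"})


class TestSampling:
    def test_marginals_match_query(self, five_node_bn):
        n = 100000
        df = bnmod.sample_bn(five_node_bn, n, seed=13)
        for v in five_node_bn.dag.nodes:
            exact = bnmod.query(five_node_bn, v).to_numpy()
            emp = (df[v].value_counts(normalize=True)
                   .reindex(five_node_bn.states[v]).fillna(0).to_numpy())
            se = np.sqrt(exact * (1 - exact) / n)
            assert np.all(np.abs(emp - exact) <= 3 * np.maximum(se, 1e-4))

    def test_deterministic(self, five_node_bn):
        a = bnmod.sample_bn(five_node_bn, 300, seed=14)
        b = bnmod.sample_bn(five_node_bn, 300, seed=14)
        pd.testing.assert_frame_equal(a, b)

    def test_n_zero_rejected(self, five_node_bn):
        with pytest.raises(ValueError):
            bnmod.sample_bn(five_node_bn, 0, seed=1)
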