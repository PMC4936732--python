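"""Discrete Bayesian networks: constrained structure learning and inference.

Structure search is greedy hill-climbing over single-edge moves (add,
delete, reverse) scored by BIC, with whitelist/blacklist constraints —
the association analysis pre-fixes edges between outcome and the key
predictors and lets the search arrange everything else.  Inference is
exact variable elimination; parameters are conditional frequency tables
with optional uniform pseudo-counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DAG",
    "EdgeConstraints",
    "ParameterizedBN",
    "bic_score",
    "hill_climb",
    "fit_cpts",
    "query",
    "sample_bn",
]

Edge = tuple[str, str]


@dataclass(frozen=True)
class DAG:
    """Directed acyclic graph over named variables."""

    nodes: tuple[str, ...]
    edges: frozenset[Edge] = frozenset()

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("graph contains a cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in self.edges if v == node))

    def topological_order(self) -> list[str]:
        # deterministic: lexicographic among ready nodes
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    def cpdag_signature(self) -> tuple[frozenset, frozenset]:
        """Markov-equivalence class signature: (skeleton, v-structures)."""
        skel = frozenset(frozenset(e) for e in self.edges)
        parents = {n: set() for n in self.nodes}
        for u, v in self.edges:
            parents[v].add(u)
        vstructs = set()
        for v, ps in parents.items():
            for a, b in itertools.combinations(sorted(ps), 2):
                if frozenset((a, b)) not in skel:
                    vstructs.add((a, v, b))
        return skel, frozenset(vstructs)


@dataclass(frozen=True)
class EdgeConstraints:
    """Whitelist edges must appear in every candidate; blacklist never may."""

    whitelist: frozenset[Edge] = frozenset()
    blacklist: frozenset[Edge] = frozenset()

    def __post_init__(self) -> None:
        overlap = self.whitelist & self.blacklist
        if overlap:
            raise ValueError(f"edges both whitelisted and blacklisted: {overlap}")

    def validate(self, nodes: tuple[str, ...]) -> None:
        DAG(nodes, frozenset(self.whitelist))  # raises if whitelist is cyclic


@dataclass
class ParameterizedBN:
    """DAG plus one CPT per node.

    ``cpts[v]`` has shape ``(*parent cardinalities, card(v))`` with parent
    axes in ``dag.parents(v)`` order; every row sums to one.
    """

    dag: DAG
    states: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray]
    n_fit: int = 0
    flagged_configs: dict[str, list[tuple]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.dag.nodes:
            cpt = self.cpts[v]
            expected = tuple(len(self.states[p]) for p in self.dag.parents(v))
            expected += (len(self.states[v]),)
            if cpt.shape != expected:
                raise ValueError(f"CPT shape mismatch for {v!r}: {cpt.shape} vs {expected}")
            if not np.allclose(cpt.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows for {v!r} do not sum to 1")

    def card(self, v: str) -> int:
        return len(self.states[v])


# ---------------------------------------------------------------------------
# scoring


def _encode(data: pd.DataFrame, states: dict[str, tuple[str, ...]]) -> dict[str, np.ndarray]:
    codes = {}
    for v, labels in states.items():
        cat = pd.Categorical(data[v], categories=list(labels))
        arr = cat.codes.astype(np.int64)
        if (arr < 0).any():
            bad = data[v][cat.codes < 0].iloc[0]
            raise ValueError(f"value {bad!r} of {v!r} not in declared states")
        codes[v] = arr
    return codes


def _local_counts(codes: dict[str, np.ndarray], states, node: str,
                  parents: tuple[str, ...]) -> np.ndarray:
    """Joint count array of shape (n_parent_configs, card(node))."""
    card = len(states[node])
    cfg_card = 1
    cfg = np.zeros_like(codes[node])
    for p in parents:
        cfg = cfg * len(states[p]) + codes[p]
        cfg_card *= len(states[p])
    flat = cfg * card + codes[node]
    return np.bincount(flat, minlength=cfg_card * card).reshape(cfg_card, card)


def _local_bic(codes, states, node: str, parents: tuple[str, ...], n: int) -> float:
    counts = _local_counts(codes, states, node, parents)
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(counts / row), 0.0).sum()
    free = counts.shape[0] * (counts.shape[1] - 1)
    return float(ll - 0.5 * free * np.log(n))


def _states_of(data, states):
    if states is None:
        states = {c: tuple(sorted(data[c].unique())) for c in data.columns}
    return states


def bic_score(dag: DAG, data: pd.DataFrame,
              states: dict[str, tuple[str, ...]] | None = None) -> float:
    """Decomposable BIC network score (larger is better)."""
    states = _states_of(data[list(dag.nodes)], states)
    codes = _encode(data, states)
    n = len(data)
    return sum(_local_bic(codes, states, v, dag.parents(v), n) for v in dag.nodes)


# ---------------------------------------------------------------------------
# structure search


def _creates_cycle(g: nx.DiGraph, u: str, v: str) -> bool:
    return g.has_node(v) and g.has_node(u) and nx.has_path(g, v, u)


def hill_climb(data: pd.DataFrame,
               constraints: EdgeConstraints | None = None,
               states: dict[str, tuple[str, ...]] | None = None,
               restarts: int = 5,
               seed: int = 0,
               tol: float = 1e-9) -> DAG:
    """Greedy BIC hill-climbing with random restarts.

    Each step applies the single add/delete/reverse move with the largest
    strictly positive score gain among those respecting the constraints
    and acyclicity; a local optimum ends the climb.  Restart 0 begins
    from the whitelist-only graph, later restarts from random
    whitelist-consistent graphs; the best-scoring local optimum wins.
    """
    constraints = constraints or EdgeConstraints()
    nodes = tuple(data.columns)
    constraints.validate(nodes)
    states = _states_of(data, states)
    codes = _encode(data, states)
    n = len(data)

    cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def local(node: str, parents: tuple[str, ...]) -> float:
        key = (node, parents)
        if key not in cache:
            cache[key] = _local_bic(codes, states, node, parents, n)
        return cache[key]

    def parents_of(g: nx.DiGraph, v: str) -> tuple[str, ...]:
        return tuple(sorted(g.predecessors(v)))

    rng = np.random.default_rng(seed)
    candidate_edges = [(u, v) for u in nodes for v in nodes
                       if u != v and (u, v) not in constraints.blacklist]

    best_graph: nx.DiGraph | None = None
    best_score = -np.inf

    for r in range(max(1, restarts)):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(constraints.whitelist)
        if r > 0:
            order = list(candidate_edges)
            rng.shuffle(order)
            for u, v in order:
                if g.has_edge(u, v) or g.has_edge(v, u):
                    continue
                if rng.random() < 0.15 and not _creates_cycle(g, u, v):
                    g.add_edge(u, v)

        score = sum(local(v, parents_of(g, v)) for v in nodes)
        while True:
            best_delta, best_move = tol, None
            for u, v in candidate_edges:
                if not g.has_edge(u, v):
                    if g.has_edge(v, u) or _creates_cycle(g, u, v):
                        continue
                    old = local(v, parents_of(g, v))
                    new = local(v, tuple(sorted(set(parents_of(g, v)) | {u})))
                    delta = new - old
                    if delta > best_delta:
                        best_delta, best_move = delta, ("add", u, v)
                else:
                    if (u, v) not in constraints.whitelist:
                        old = local(v, parents_of(g, v))
                        new = local(v, tuple(sorted(set(parents_of(g, v)) - {u})))
                        delta = new - old
                        if delta > best_delta:
                            best_delta, best_move = delta, ("del", u, v)
                        # reverse u->v to v->u
                        if (v, u) not in constraints.blacklist:
                            g.remove_edge(u, v)
                            ok = not _creates_cycle(g, v, u)
                            g.add_edge(u, v)
                            if ok:
                                d = (new - old
                                     + local(u, tuple(sorted(set(parents_of(g, u)) | {v})))
                                     - local(u, parents_of(g, u)))
                                if d > best_delta:
                                    best_delta, best_move = d, ("rev", u, v)
            if best_move is None:
                break
            op, u, v = best_move
            if op == "add":
                g.add_edge(u, v)
            elif op == "del":
                g.remove_edge(u, v)
            else:
                g.remove_edge(u, v)
                g.add_edge(v, u)
            score += best_delta
        if score > best_score:
            best_score, best_graph = score, g.copy()

    return DAG(nodes, frozenset(best_graph.edges()))


# ---------------------------------------------------------------------------
# parameters, inference, sampling


def fit_cpts(dag: DAG, data: pd.DataFrame,
             states: dict[str, tuple[str, ...]] | None = None,
             smoothing: float = 0.0) -> ParameterizedBN:
    """Conditional frequency tables with a uniform pseudo-count.

    Parent configurations never observed (and unsmoothed) get the uniform
    distribution and are recorded in ``flagged_configs``.
    """
    states = _states_of(data[list(dag.nodes)], states)
    codes = _encode(data, states)
    cpts: dict[str, np.ndarray] = {}
    flagged: dict[str, list[tuple]] = {}
    for v in dag.nodes:
        parents = dag.parents(v)
        counts = _local_counts(codes, states, v, parents).astype(float) + smoothing
        row = counts.sum(axis=1, keepdims=True)
        empty = row[:, 0] == 0
        counts[empty] = 1.0
        row = counts.sum(axis=1, keepdims=True)
        cpt = counts / row
        shape = tuple(len(states[p]) for p in parents) + (len(states[v]),)
        cpts[v] = cpt.reshape(shape)
        if empty.any():
            cards = [len(states[p]) for p in parents]
            flagged[v] = [tuple(np.unravel_index(i, cards)) for i in np.flatnonzero(empty)]
    return ParameterizedBN(dag, states, cpts, n_fit=len(data), flagged_configs=flagged)


def _factor_product(f1, f2):
    (vars1, a1), (vars2, a2) = f1, f2
    union = list(vars1) + [v for v in vars2 if v not in vars1]
    sl1 = tuple(slice(None) if v in vars1 else None for v in union)
    sl2 = tuple(slice(None) if v in vars2 else None for v in union)
    a1e = a1.reshape([a1.shape[vars1.index(v)] if v in vars1 else 1 for v in union])
    perm2 = [vars2.index(v) for v in union if v in vars2]
    a2t = np.transpose(a2, perm2)
    a2e = a2t.reshape([a2t.shape[[v for v in union if v in vars2].index(v)]
                       if v in vars2 else 1 for v in union])
    return tuple(union), a1e * a2e


def _sum_out(factor, var):
    variables, arr = factor
    idx = variables.index(var)
    new_vars = tuple(v for v in variables if v != var)
    return new_vars, arr.sum(axis=idx)


def query(bn: ParameterizedBN, target: str,
          evidence: dict[str, str] | None = None) -> pd.Series:
    """Exact conditional distribution of ``target`` via variable elimination."""
    evidence = evidence or {}
    if target not in bn.dag.nodes:
        raise ValueError(f"unknown target {target!r}")
    for v, val in evidence.items():
        if v not in bn.dag.nodes:
            raise ValueError(f"unknown evidence variable {v!r}")
        if val not in bn.states[v]:
            raise ValueError(f"invalid value {val!r} for evidence variable {v!r}")

    factors = []
    for v in bn.dag.nodes:
        variables = bn.dag.parents(v) + (v,)
        arr = bn.cpts[v]
        # reduce by evidence
        keep_vars, slicer = [], []
        for fv in variables:
            if fv in evidence:
                slicer.append(bn.states[fv].index(evidence[fv]))
            else:
                slicer.append(slice(None))
                keep_vars.append(fv)
        arr = arr[tuple(slicer)]
        factors.append((tuple(keep_vars), np.asarray(arr)))

    to_eliminate = [v for v in bn.dag.nodes if v != target and v not in evidence]
    # greedy min-fill-ish: eliminate the variable whose combined factor is smallest
    while to_eliminate:
        best_v, best_size = None, None
        for v in to_eliminate:
            size = 1
            involved_vars = set()
            for variables, arr in factors:
                if v in variables:
                    involved_vars |= set(variables)
            size = int(np.prod([len(bn.states[u]) for u in involved_vars])) if involved_vars else 1
            if best_size is None or size < best_size:
                best_v, best_size = v, size
        v = best_v
        to_eliminate.remove(v)
        involved = [f for f in factors if v in f[0]]
        factors = [f for f in factors if v not in f[0]]
        if not involved:
            continue
        prod = involved[0]
        for f in involved[1:]:
            prod = _factor_product(prod, f)
        factors.append(_sum_out(prod, v))

    result = ((), np.array(1.0))
    for f in factors:
        result = _factor_product(result, f)
    variables, arr = result
    if variables and variables != (target,):
        perm = [variables.index(target)]
        arr = np.transpose(arr, perm)
    total = arr.sum()
    if total <= 0:
        raise ValueError(f"evidence has zero probability under the network: {evidence}")
    dist = arr / total
    if not np.isclose(dist.sum(), 1.0, atol=1e-9):  # pragma: no cover
        raise AssertionError("query distribution failed to normalize")
    return pd.Series(dist, index=list(bn.states[target]), name=target)


def sample_bn(bn: ParameterizedBN, n: int, seed: int) -> pd.DataFrame:
    """Ancestral sampling in topological order; deterministic given seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    order = bn.dag.topological_order()
    out: dict[str, np.ndarray] = {}
    for v in order:
        parents = bn.dag.parents(v)
        card = bn.card(v)
        cpt = bn.cpts[v].reshape(-1, card)
        cfg = np.zeros(n, dtype=np.int64)
        for p in parents:
            cfg = cfg * bn.card(p) + out[p]
        cum = np.cumsum(cpt[cfg], axis=1)
        u = rng.random(n)
        out[v] = np.minimum((u[:, None] > cum).sum(axis=1), card - 1)
    return pd.DataFrame({v: pd.Categorical.from_codes(out[v], list(bn.states[v]))
                         .astype(str) for v in bn.dag.nodes})


def exact_marginal(bn: ParameterizedBN, target: str) -> np.ndarray:
    """Marginal distribution of one node, by variable elimination."""
    return query(bn, target).to_numpy()


def dag_to_dot(dag: DAG, highlight: set[str] | None = None) -> str:
    """DOT serialization for visualisation; highlighted nodes drawn filled."""
    highlight = highlight or set()
    lines = ["digraph G {"]
    for v in dag.nodes:
        style = ' [style=filled, fillcolor=salmon]' if v in highlight else ""
        lines.append(f'  "{v}"{style};')
    for u, v in sorted(dag.edges):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines)
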