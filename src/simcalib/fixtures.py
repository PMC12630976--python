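"""Synthetic ground-truth networks.

A :class:`FixtureSpec` draws a random DAG (edges only from earlier to later
nodes in a random permutation, so acyclicity holds by construction) and
fills in CPTs with symmetric-Dirichlet rows. A small catalogue of
hand-specified toy networks with documented exact marginals backs the
oracle tests; ``hub5`` doubles as the desk-scale benchmarking fixture.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .bn import BayesianNetwork, CPT, DAGStructure, Variable, markov_boundary

__all__ = ["FixtureSpec", "random_dag", "random_cpts", "random_network", "toy_network", "auto_target"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a random ground-truth network."""

    n_nodes: int
    edge_probability: float = 0.3
    max_parents: int = 4
    min_levels: int = 2
    max_levels: int = 3
    alpha: float = 0.5  # Dirichlet concentration of CPT rows
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not 0.0 <= self.edge_probability <= 1.0:
            raise ValueError("edge_probability must be in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.min_levels < 2 or self.max_levels < self.min_levels:
            raise ValueError("need 2 <= min_levels <= max_levels")


def random_dag(spec: FixtureSpec) -> DAGStructure:
    """Random DAG: Bernoulli(p) edges along a random topological permutation.

    In-degree is capped at ``max_parents`` by keeping a random subset of the
    proposed parents. Node names are V0..V{n-1}; seed-deterministic.
    """
    rng = np.random.default_rng(spec.seed)
    nodes = tuple(f"V{i}" for i in range(spec.n_nodes))
    perm = rng.permutation(spec.n_nodes)
    order = [nodes[i] for i in perm]
    edges: set[tuple[str, str]] = set()
    for j in range(1, spec.n_nodes):
        child = order[j]
        mask = rng.random(j) < spec.edge_probability
        parents = [order[i] for i in range(j) if mask[i]]
        if len(parents) > spec.max_parents:
            keep = rng.choice(len(parents), size=spec.max_parents, replace=False)
            parents = [parents[i] for i in sorted(keep)]
        edges.update((p, child) for p in parents)
    return DAGStructure(nodes, frozenset(edges))


def random_cpts(
    dag: DAGStructure,
    alpha: float = 0.5,
    seed: int = 0,
    min_levels: int = 2,
    max_levels: int = 3,
) -> BayesianNetwork:
    """Fill ``dag`` with symmetric-Dirichlet(alpha) CPT rows.

    Small alpha gives near-degenerate (strong) CPTs, large alpha near-uniform
    ones; seed-deterministic.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    rng = np.random.default_rng(seed)
    cards = {
        n: int(rng.integers(min_levels, max_levels + 1)) for n in dag.nodes
    }
    variables = tuple(
        Variable(n, tuple(f"l{i}" for i in range(cards[n]))) for n in dag.nodes
    )
    cpts: dict[str, CPT] = {}
    for n in dag.nodes:
        parents = dag.parents(n)
        q = int(np.prod([cards[p] for p in parents])) if parents else 1
        rows = rng.dirichlet([alpha] * cards[n], size=q)
        shape = tuple(cards[p] for p in parents) + (cards[n],)
        cpts[n] = CPT(n, parents, rows.reshape(shape))
    return BayesianNetwork(variables, dag, cpts)


def random_network(spec: FixtureSpec) -> BayesianNetwork:
    """Random DAG plus random CPTs under one spec (seed split internally)."""
    dag = random_dag(spec)
    return random_cpts(
        dag, alpha=spec.alpha, seed=spec.seed + 1,
        min_levels=spec.min_levels, max_levels=spec.max_levels,
    )


def _binary(name: str) -> Variable:
    return Variable(name, ("0", "1"))


def _bn(variables, edges, tables) -> BayesianNetwork:
    structure = DAGStructure(tuple(v.name for v in variables), frozenset(edges))
    cpts = {
        v.name: CPT(v.name, structure.parents(v.name), np.asarray(tables[v.name]))
        for v in variables
    }
    return BayesianNetwork(tuple(variables), structure, cpts)


def toy_network(name: str) -> BayesianNetwork:
    """Hand-specified toy networks with documented exact marginals.

    * ``chain3``    — A -> B -> C, binary. P(A=1)=0.6, P(B=1|A=0,1)=(0.2,0.9),
      P(C=1|B=0,1)=(0.1,0.8). Exact: P(B=1)=0.62, P(C=1)=0.534.
    * ``collider3`` — A -> C <- B, binary, A and B fair coins; C is a noisy OR
      (P(C=1)=0.9 if A or B, else 0.1).
    * ``sprinkler4``— cloudy -> sprinkler, cloudy -> rain, sprinkler -> wet,
      rain -> wet: 4 nodes, 4 edges, binary.
    * ``hub5``      — hub H with four children of varying signal strength;
      H's Markov boundary is all four children, making it the natural
      prediction target for desk-scale benchmarks.
    """
    if name == "chain3":
        A, B, C = _binary("A"), _binary("B"), _binary("C")
        return _bn(
            [A, B, C],
            {("A", "B"), ("B", "C")},
            {
                "A": [0.4, 0.6],
                "B": [[0.8, 0.2], [0.1, 0.9]],
                "C": [[0.9, 0.1], [0.2, 0.8]],
            },
        )
    if name == "collider3":
        A, B, C = _binary("A"), _binary("B"), _binary("C")
        return _bn(
            [A, B, C],
            {("A", "C"), ("B", "C")},
            {
                "A": [0.5, 0.5],
                "B": [0.5, 0.5],
                "C": [
                    [[0.9, 0.1], [0.1, 0.9]],
                    [[0.1, 0.9], [0.1, 0.9]],
                ],
            },
        )
    if name == "sprinkler4":
        cloudy, sprinkler, rain, wet = map(
            _binary, ("cloudy", "sprinkler", "rain", "wet")
        )
        return _bn(
            [cloudy, sprinkler, rain, wet],
            {
                ("cloudy", "sprinkler"),
                ("cloudy", "rain"),
                ("sprinkler", "wet"),
                ("rain", "wet"),
            },
            {
                "cloudy": [0.5, 0.5],
                "sprinkler": [[0.5, 0.5], [0.9, 0.1]],
                "rain": [[0.8, 0.2], [0.2, 0.8]],
                "wet": [
                    [[1.0, 0.0], [0.1, 0.9]],
                    [[0.1, 0.9], [0.01, 0.99]],
                ],
            },
        )
    if name == "hub5":
        H = _binary("H")
        xs = [_binary(f"X{i}") for i in range(1, 5)]
        # children of varying signal strength: X1 strong ... X4 weak
        tables = {
            "H": [0.5, 0.5],
            "X1": [[0.9, 0.1], [0.15, 0.85]],
            "X2": [[0.8, 0.2], [0.25, 0.75]],
            "X3": [[0.7, 0.3], [0.35, 0.65]],
            "X4": [[0.6, 0.4], [0.45, 0.55]],
        }
        return _bn(
            [H, *xs],
            {("H", f"X{i}") for i in range(1, 5)},
            tables,
        )
    raise KeyError(
        f"unknown toy network {name!r}; catalogue: chain3, collider3, sprinkler4, hub5"
    )


def auto_target(bn: BayesianNetwork) -> str:
    """Node with the largest Markov boundary (ties by name) — the candidate
    most likely to spread variance across ML methods."""
    best = None
    best_size = -1
    for n in sorted(bn.structure.nodes):
        mb = markov_boundary(bn.structure, n)
        size = sum(len(v) for v in mb.values())
        if size > best_size:
            best, best_size = n, size
    return best
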