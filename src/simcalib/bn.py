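"""Discrete Bayesian networks: representation, sampling, fitting, exact inference.

A :class:`BayesianNetwork` is a DAG over categorical variables plus one
conditional probability table (CPT) per node. It plays the role of the
data-generating process (DGP): datasets are drawn from it by ancestral
(forward) sampling, and structure-learner output is turned back into a
sampling DGP by maximum-likelihood CPT fitting on data.

Level order is semantic: it is fixed at declaration (BIF file order, or the
order supplied when fitting) and preserved everywhere, so that CPT arrays,
one-hot encodings and marginal vectors are comparable across the package.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Variable",
    "DAGStructure",
    "CPT",
    "BayesianNetwork",
    "TabularDataset",
    "topological_order",
    "forward_sample",
    "fit_cpts",
    "exact_marginals",
]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class Variable:
    """A categorical variable: a name and an ordered tuple of level labels."""

    name: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 1:
            raise ValueError(f"variable {self.name!r} needs at least one level")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"variable {self.name!r} has duplicate levels")

    @property
    def cardinality(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class DAGStructure:
    """Directed acyclic graph: node names plus (parent, child) edges."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        node_set = set(self.nodes)
        for p, c in self.edges:
            if p == c:
                raise ValueError(f"self-loop on {p!r}")
            if p not in node_set or c not in node_set:
                raise ValueError(f"edge ({p!r}, {c!r}) references unknown node")
        # acyclicity; raises with one offending cycle named
        topological_order(self)

    @staticmethod
    def from_edges(
        nodes: "list[str] | tuple[str, ...]",
        edges: "list[tuple[str, str]] | set[tuple[str, str]] | frozenset[tuple[str, str]]",
    ) -> "DAGStructure":
        return DAGStructure(tuple(nodes), frozenset(edges))

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(p for p, c in self.edges if c == node))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(c for p, c in self.edges if p == node))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def topological_order(dag: DAGStructure) -> list[str]:
    """Parent-before-child node order, deterministic (ties by node name).

    Raises ``ValueError`` naming one cycle if the graph is cyclic.
    """
    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    g.add_edges_from(dag.edges)
    try:
        return list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        path = " -> ".join(e[0] for e in cycle) + " -> " + cycle[-1][1]
        raise ValueError(f"graph contains a cycle: {path}") from None


@dataclass(frozen=True)
class CPT:
    """Conditional probability table for one node.

    ``probs`` has one axis per parent (in ``parents`` order, sized by that
    parent's cardinality) plus a trailing axis over the child's levels; every
    slice along the trailing axis is a probability vector.
    """

    child: str
    parents: tuple[str, ...]
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != len(self.parents) + 1:
            raise ValueError(
                f"CPT for {self.child!r}: expected {len(self.parents) + 1} axes, got {p.ndim}"
            )
        if np.any(p < -_PROB_TOL) or np.any(p > 1 + _PROB_TOL):
            raise ValueError(f"CPT for {self.child!r}: entries outside [0, 1]")
        sums = p.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            worst = float(np.abs(sums - 1.0).max())
            raise ValueError(
                f"CPT for {self.child!r}: rows do not sum to 1 (max deviation {worst:.2e})"
            )

    @property
    def flat(self) -> np.ndarray:
        """View with parent configurations flattened: shape (n_configs, card)."""
        return self.probs.reshape(-1, self.probs.shape[-1])


@dataclass(frozen=True)
class BayesianNetwork:
    """A DAG plus one CPT per node — a complete discrete DGP."""

    variables: tuple[Variable, ...]
    structure: DAGStructure
    cpts: dict[str, CPT] = field(repr=False)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if set(names) != set(self.structure.nodes):
            raise ValueError("variables and structure nodes disagree")
        card = {v.name: v.cardinality for v in self.variables}
        for name in names:
            if name not in self.cpts:
                raise ValueError(f"missing CPT for {name!r}")
            cpt = self.cpts[name]
            if cpt.child != name:
                raise ValueError(f"CPT stored under {name!r} is for {cpt.child!r}")
            if tuple(sorted(cpt.parents)) != tuple(sorted(self.structure.parents(name))):
                raise ValueError(f"CPT parents for {name!r} do not match structure")
            expected = tuple(card[p] for p in cpt.parents) + (card[name],)
            if cpt.probs.shape != expected:
                raise ValueError(
                    f"CPT for {name!r}: shape {cpt.probs.shape} != expected {expected}"
                )

    @property
    def variable_map(self) -> dict[str, Variable]:
        return {v.name: v for v in self.variables}

    @property
    def domains(self) -> dict[str, tuple[str, ...]]:
        return {v.name: v.levels for v in self.variables}

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)


@dataclass
class TabularDataset:
    """Categorical rows with declared level domains and a train/test split.

    ``data`` stores level *labels* (strings); encoding for ML happens in the
    benchmark engine. The first ``n_train`` rows are the training split, the
    next ``n_test`` rows the test split; an unsplit dataset has
    ``n_train = len(data)`` and ``n_test = 0``.
    """

    data: pd.DataFrame
    domains: dict[str, tuple[str, ...]]
    target: str | None = None
    n_train: int | None = None
    n_test: int = 0

    def __post_init__(self) -> None:
        if self.n_train is None:
            self.n_train = len(self.data)
        if self.n_train + self.n_test > len(self.data):
            raise ValueError("train + test exceeds number of rows")
        if self.target is not None and self.target not in self.data.columns:
            raise ValueError(f"target {self.target!r} not a column")
        for col in self.data.columns:
            if col not in self.domains:
                raise ValueError(f"no declared domain for column {col!r}")
            levels = set(self.domains[col])
            bad = set(self.data[col].unique()) - levels
            if bad:
                raise ValueError(f"column {col!r} contains undeclared levels {sorted(bad)}")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def train(self) -> pd.DataFrame:
        return self.data.iloc[: self.n_train]

    @property
    def test(self) -> pd.DataFrame:
        return self.data.iloc[self.n_train : self.n_train + self.n_test]

    def with_split(self, n_train: int, n_test: int, target: str) -> "TabularDataset":
        return TabularDataset(self.data, self.domains, target, n_train, n_test)

    def codes(self, columns: "list[str] | None" = None) -> np.ndarray:
        """Integer-coded matrix (rows x columns) under the declared domains."""
        cols = columns if columns is not None else self.columns
        out = np.empty((len(self.data), len(cols)), dtype=np.int64)
        for j, col in enumerate(cols):
            mapping = {lev: i for i, lev in enumerate(self.domains[col])}
            out[:, j] = self.data[col].map(mapping).to_numpy()
        return out

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _parent_config_index(codes: np.ndarray, cards: "list[int]") -> np.ndarray:
    """Mixed-radix index of each row's parent configuration (row-major)."""
    idx = np.zeros(codes.shape[0], dtype=np.int64)
    for j, card in enumerate(cards):
        idx = idx * card + codes[:, j]
    return idx


def forward_sample(
    bn: BayesianNetwork, n: int, seed: "int | np.random.Generator"
) -> TabularDataset:
    """Draw ``n`` rows from ``bn`` by ancestral sampling.

    Each node is sampled in topological order conditioned on its parents'
    sampled values. Same (bn, n, seed) gives a bit-identical table.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = topological_order(bn.structure)
    var = bn.variable_map
    samples: dict[str, np.ndarray] = {}  # node -> integer codes
    for node in order:
        cpt = bn.cpts[node]
        if cpt.parents:
            pcodes = np.column_stack([samples[p] for p in cpt.parents])
            cards = [var[p].cardinality for p in cpt.parents]
            cfg = _parent_config_index(pcodes, cards)
            dist = cpt.flat[cfg]  # (n, card)
        else:
            dist = np.broadcast_to(cpt.probs, (n, cpt.probs.shape[-1]))
        u = rng.random(n)
        cum = np.cumsum(dist, axis=1)
        cum[:, -1] = 1.0  # guard against round-off at the top
        samples[node] = (u[:, None] >= cum).sum(axis=1)
    cols = {
        v.name: pd.Series(np.asarray(v.levels, dtype=object)[samples[v.name]])
        for v in bn.variables
    }
    frame = pd.DataFrame(cols, columns=[v.name for v in bn.variables])
    return TabularDataset(frame, bn.domains)


def fit_cpts(
    structure: DAGStructure,
    data: TabularDataset,
    pseudo_count: float = 0.0,
    domains: "dict[str, tuple[str, ...]] | None" = None,
) -> BayesianNetwork:
    """Maximum-likelihood CPTs (optionally Dirichlet-smoothed) on ``structure``.

    Each CPT entry is ``(count + pseudo_count) / (config_total + pseudo_count * card)``.
    A parent configuration never observed (with ``pseudo_count`` 0) falls back
    to a uniform vector. Level domains default to the dataset's declarations;
    in meta-simulation mode the caller passes the ground-truth network's
    domains so unobserved rare levels keep their place in the state space.
    """
    if pseudo_count < 0:
        raise ValueError("pseudo_count must be non-negative")
    doms = domains if domains is not None else data.domains
    for node in structure.nodes:
        if node not in data.columns:
            raise ValueError(f"data has no column for node {node!r}")
        if node not in doms:
            raise ValueError(f"no level domain for node {node!r}")
    variables = tuple(Variable(n, tuple(doms[n])) for n in structure.nodes)
    card = {v.name: v.cardinality for v in variables}
    use = TabularDataset(data.data, {c: tuple(doms[c]) for c in data.columns})
    codes = use.codes(list(structure.nodes))
    col_of = {n: j for j, n in enumerate(structure.nodes)}
    cpts: dict[str, CPT] = {}
    for node in structure.nodes:
        parents = structure.parents(node)
        k = card[node]
        pcards = [card[p] for p in parents]
        q = int(np.prod(pcards)) if parents else 1
        counts = np.zeros((q, k), dtype=float)
        child = codes[:, col_of[node]]
        if parents:
            cfg = _parent_config_index(codes[:, [col_of[p] for p in parents]], pcards)
        else:
            cfg = np.zeros(len(child), dtype=np.int64)
        np.add.at(counts, (cfg, child), 1.0)
        totals = counts.sum(axis=1, keepdims=True)
        probs = np.empty_like(counts)
        denom = totals + pseudo_count * k
        seen = denom[:, 0] > 0
        probs[seen] = (counts[seen] + pseudo_count) / denom[seen]
        probs[~seen] = 1.0 / k
        cpts[node] = CPT(node, parents, probs.reshape(tuple(pcards) + (k,)))
    return BayesianNetwork(variables, structure, cpts)


def exact_marginals(
    bn: BayesianNetwork, max_states: int = 10**6
) -> dict[str, np.ndarray]:
    """Marginal distribution of every variable by summing the exact joint.

    Intended as a test oracle for small networks: refuses when the joint
    state space exceeds ``max_states`` configurations.
    """
    order = topological_order(bn.structure)
    var = bn.variable_map
    cards = [var[n].cardinality for n in order]
    n_states = int(np.prod(cards))
    if n_states > max_states:
        raise ValueError(
            f"joint state space has {n_states} configurations (> {max_states})"
        )
    axis = {n: i for i, n in enumerate(order)}
    joint = np.ones([1] * len(order))
    for node in order:
        cpt = bn.cpts[node]
        # reshape the CPT onto the global axis layout and broadcast-multiply
        shape = [1] * len(order)
        src_axes = [axis[p] for p in cpt.parents] + [axis[node]]
        for a, size in zip(src_axes, cpt.probs.shape):
            shape[a] = size
        t = np.ones(shape)
        perm = np.argsort(src_axes)
        moved = np.transpose(cpt.probs, perm)
        t[...] = moved.reshape(shape)
        joint = joint * t
    out: dict[str, np.ndarray] = {}
    for node in order:
        axes = tuple(i for i in range(len(order)) if i != axis[node])
        m = joint.sum(axis=axes)
        out[node] = m / m.sum()
    return out


def markov_boundary(structure: DAGStructure, node: str) -> dict[str, tuple[str, ...]]:
    """Parents, children and spouses (co-parents of children) of ``node``."""
    if node not in structure.nodes:
        raise KeyError(f"unknown node {node!r}")
    parents = set(structure.parents(node))
    children = set(structure.children(node))
    spouses = set()
    for c in children:
        spouses.update(structure.parents(c))
    spouses -= {node}
    spouses -= parents | children
    return {
        "parents": tuple(sorted(parents)),
        "children": tuple(sorted(children)),
        "spouses": tuple(sorted(spouses)),
    }


def all_parent_configs(
    bn: BayesianNetwork, node: str
) -> list[tuple[str, ...]]:
    """Every full parent-level configuration of ``node``, in CPT row order."""
    var = bn.variable_map
    parents = bn.cpts[node].parents
    return list(itertools.product(*(var[p].levels for p in parents)))
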