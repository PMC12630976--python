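"""Structure learning for discrete Bayesian networks.

Implements one representative per algorithm family, from first principles:

* score-based — greedy hill climbing and tabu search over add/delete/reverse
  single-edge moves, maximising the decomposable BIC score;
* constraint-based — PC-stable (order-independent skeleton, v-structure
  orientation, Meek rules) driven by the G-squared conditional-independence
  test;
* hybrid — MMHC: the MMPC parents-and-children heuristic restricts the edge
  space, then hill climbing searches inside it.

All learners are deterministic for a fixed input: score ties are broken by
the lexicographically smallest (operation, parent, child) move, and
undirected leftovers are oriented by node-name order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .bn import DAGStructure, TabularDataset

__all__ = [
    "PartiallyDirectedGraph",
    "CITestResult",
    "CodedData",
    "family_score_bic",
    "total_score_bic",
    "hill_climb",
    "tabu_search",
    "ci_test_g2",
    "pc_stable",
    "mmpc",
    "mmhc",
    "pdag_to_dag",
    "cpdag_of",
    "LEARNERS",
    "learn_structure",
]


# ---------------------------------------------------------------------------
# coded data

class CodedData:
    """Integer-coded view of a categorical dataset, shared by all learners."""

    def __init__(self, dataset: TabularDataset, columns: "list[str] | None" = None):
        self.columns = columns if columns is not None else dataset.columns
        self.codes = dataset.codes(self.columns)
        self.cards = np.array(
            [len(dataset.domains[c]) for c in self.columns], dtype=np.int64
        )
        self.n = self.codes.shape[0]
        self.index = {c: j for j, c in enumerate(self.columns)}

    def col(self, name: str) -> np.ndarray:
        return self.codes[:, self.index[name]]

    def card(self, name: str) -> int:
        return int(self.cards[self.index[name]])

    def config_index(self, names: "tuple[str, ...] | list[str]") -> tuple[np.ndarray, int]:
        """Mixed-radix configuration index over ``names`` plus its radix size."""
        idx = np.zeros(self.n, dtype=np.int64)
        size = 1
        for name in names:
            c = self.card(name)
            idx = idx * c + self.col(name)
            size *= c
        return idx, size


def _as_coded(data: "TabularDataset | CodedData") -> CodedData:
    return data if isinstance(data, CodedData) else CodedData(data)


# ---------------------------------------------------------------------------
# scores

def family_score_bic(
    child: str, parents: "set[str] | tuple[str, ...] | list[str]",
    data: "TabularDataset | CodedData",
) -> float:
    """BIC contribution of one family (child given its parents).

    Maximised log-likelihood of the child's conditional distribution minus
    the ``(r - 1) * q * ln(n) / 2`` dimension penalty, where r is the child's
    cardinality and q the number of parent configurations. Decomposable:
    the total score of a DAG is the sum of its family scores.
    """
    coded = _as_coded(data)
    parents = tuple(sorted(parents))
    if child in parents:
        raise ValueError(f"child {child!r} cannot be its own parent")
    r = coded.card(child)
    cfg, q = coded.config_index(parents)
    counts = np.zeros((q, r), dtype=float)
    np.add.at(counts, (cfg, coded.col(child)), 1.0)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = counts * (np.log(counts) - np.log(totals))
    ll = float(np.nansum(ll))
    penalty = (r - 1) * q * np.log(coded.n) / 2.0
    return ll - penalty


def total_score_bic(dag: DAGStructure, data: "TabularDataset | CodedData") -> float:
    coded = _as_coded(data)
    return sum(family_score_bic(n, dag.parents(n), coded) for n in dag.nodes)


# ---------------------------------------------------------------------------
# greedy search (hill climbing / tabu)

_OPS = ("add", "delete", "reverse")


class _SearchState:
    """Mutable DAG as parent sets, with a family-score cache."""

    def __init__(self, coded: CodedData, score_fn):
        self.coded = coded
        self.score_fn = score_fn
        self.nodes = list(coded.columns)
        self.parents: dict[str, set[str]] = {n: set() for n in self.nodes}
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def family(self, child: str, parents: "set[str]") -> float:
        key = (child, tuple(sorted(parents)))
        if key not in self._cache:
            self._cache[key] = self.score_fn(child, parents, self.coded)
        return self._cache[key]

    def total(self) -> float:
        return sum(self.family(n, self.parents[n]) for n in self.nodes)

    def has_edge(self, p: str, c: str) -> bool:
        return p in self.parents[c]

    def creates_cycle(self, p: str, c: str, *, ignore: "tuple[str, str] | None" = None) -> bool:
        """Would adding p -> c create a cycle (optionally ignoring one edge)?"""
        # cycle iff c already reaches p
        stack = [c]
        seen = {c}
        while stack:
            u = stack.pop()
            if u == p:
                return True
            for child, ps in self.parents.items():
                if u in ps and child not in seen:
                    if ignore is not None and (u, child) == ignore:
                        continue
                    seen.add(child)
                    stack.append(child)
        return False

    def move_delta(self, op: str, p: str, c: str) -> float:
        cur = self.family(c, self.parents[c])
        if op == "add":
            return self.family(c, self.parents[c] | {p}) - cur
        if op == "delete":
            return self.family(c, self.parents[c] - {p}) - cur
        # reverse p -> c into c -> p
        cur_p = self.family(p, self.parents[p])
        return (
            self.family(c, self.parents[c] - {p})
            + self.family(p, self.parents[p] | {c})
            - cur
            - cur_p
        )

    def apply(self, op: str, p: str, c: str) -> None:
        if op == "add":
            self.parents[c].add(p)
        elif op == "delete":
            self.parents[c].discard(p)
        else:
            self.parents[c].discard(p)
            self.parents[p].add(c)

    def legal_moves(self, max_parents: int, allowed: "set[frozenset[str]] | None"):
        """Yield (op, parent, child) moves preserving acyclicity and caps."""
        for p, c in itertools.permutations(self.nodes, 2):
            pair_ok = allowed is None or frozenset((p, c)) in allowed
            if self.has_edge(p, c):
                yield ("delete", p, c)
                if (
                    pair_ok
                    and len(self.parents[p]) < max_parents
                    and not self.creates_cycle(c, p, ignore=(p, c))
                ):
                    yield ("reverse", p, c)
            elif (
                pair_ok
                and not self.has_edge(c, p)
                and len(self.parents[c]) < max_parents
                and not self.creates_cycle(p, c)
            ):
                yield ("add", p, c)

    def to_dag(self) -> DAGStructure:
        edges = {(p, c) for c, ps in self.parents.items() for p in ps}
        return DAGStructure(tuple(self.nodes), frozenset(edges))

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset((p, c) for c, ps in self.parents.items() for p in ps)


def _best_move(state: _SearchState, max_parents, allowed, forbidden) -> "tuple[tuple[str, str, str], float] | None":
    """Highest-delta legal move; ties broken by smallest (op, parent, child)."""
    best = None
    best_delta = None
    for move in state.legal_moves(max_parents, allowed):
        if move in forbidden:
            continue
        delta = state.move_delta(*move)
        if (
            best_delta is None
            or delta > best_delta + 1e-12
            or (abs(delta - best_delta) <= 1e-12 and move < best)
        ):
            best, best_delta = move, delta
    if best is None:
        return None
    return best, best_delta


def _greedy_climb(state: _SearchState, max_parents: int, allowed) -> None:
    """Ascend to a local optimum of the score (in place)."""
    while True:
        found = _best_move(state, max_parents, allowed, frozenset())
        if found is None:
            return
        move, delta = found
        if delta <= 1e-9:
            return
        state.apply(*move)


def hill_climb(
    data: "TabularDataset | CodedData",
    score=family_score_bic,
    max_parents: int = 8,
    restarts: int = 0,
    seed: int = 0,
    allowed_pairs: "set[frozenset[str]] | None" = None,
) -> DAGStructure:
    """Greedy hill climbing from the empty graph over single-edge moves.

    The result is a verified local optimum: no score-improving add, delete
    or reverse move remains. Optional random restarts perturb the local
    optimum with random edge flips and re-climb, keeping the best DAG found.
    """
    coded = _as_coded(data)
    if len(coded.columns) < 2:
        raise ValueError("need at least two columns to learn a structure")
    state = _SearchState(coded, score)
    _greedy_climb(state, max_parents, allowed_pairs)
    best_edges = state.edge_set()
    best_score = state.total()
    if restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            # perturb: random legal additions/deletions, then climb again
            for _ in range(max(2, len(coded.columns) // 2)):
                moves = sorted(state.legal_moves(max_parents, allowed_pairs))
                if not moves:
                    break
                state.apply(*moves[rng.integers(len(moves))])
            _greedy_climb(state, max_parents, allowed_pairs)
            total = state.total()
            if total > best_score + 1e-12:
                best_score, best_edges = total, state.edge_set()
    return DAGStructure(tuple(coded.columns), best_edges)


def _inverse_move(op: str, p: str, c: str) -> tuple[str, str, str]:
    if op == "add":
        return ("delete", p, c)
    if op == "delete":
        return ("add", p, c)
    return ("reverse", c, p)


def tabu_search(
    data: "TabularDataset | CodedData",
    score=family_score_bic,
    tabu_length: int = 10,
    max_worsening_moves: int = 10,
    seed: int = 0,
    max_parents: int = 8,
    allowed_pairs: "set[frozenset[str]] | None" = None,
) -> DAGStructure:
    """Tabu-list greedy search; returns the best DAG visited.

    Behaves like :func:`hill_climb` until the local optimum, then may take up
    to ``max_worsening_moves`` non-improving moves while the tabu list blocks
    the immediate undo of recent moves. With ``tabu_length = 0`` and
    ``max_worsening_moves = 0`` it reduces exactly to hill climbing.
    """
    coded = _as_coded(data)
    if len(coded.columns) < 2:
        raise ValueError("need at least two columns to learn a structure")
    state = _SearchState(coded, score)
    current = state.total()
    best_edges = state.edge_set()
    best_score = current
    tabu: list[tuple[str, str, str]] = []
    worsening_left = max_worsening_moves
    while True:
        found = _best_move(state, max_parents, allowed_pairs, frozenset(tabu))
        if found is None:
            break
        move, delta = found
        if delta <= 1e-9:
            if worsening_left <= 0:
                break
            worsening_left -= 1
        state.apply(*move)
        current += delta
        if tabu_length > 0:
            tabu.append(_inverse_move(*move))
            if len(tabu) > tabu_length:
                tabu.pop(0)
        if current > best_score + 1e-9:
            best_score = current
            best_edges = state.edge_set()
            worsening_left = max_worsening_moves
    return DAGStructure(tuple(coded.columns), best_edges)


# ---------------------------------------------------------------------------
# conditional-independence testing

@dataclass(frozen=True)
class CITestResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float
    independent: bool


def ci_test_g2(
    x: str,
    y: str,
    Z: "tuple[str, ...] | list[str] | set[str]",
    data: "TabularDataset | CodedData",
    alpha: float = 0.05,
) -> CITestResult:
    """G-squared (likelihood-ratio) test of X independent of Y given Z.

    ``G2 = 2 * sum O * ln(O / E)`` with expectations from the conditional
    independence model within each Z stratum. Degrees of freedom follow the
    sparse-table correction: within each stratum, rows/columns with zero
    margin are dropped, so empty cells make the test conservative rather
    than anti-conservative.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    Z = tuple(sorted(Z))
    if x in Z or y in Z:
        raise ValueError("conditioning set must not contain x or y")
    if x == y:
        raise ValueError("x and y must differ")
    coded = _as_coded(data)
    rx, ry = coded.card(x), coded.card(y)
    zidx, nz = coded.config_index(Z)
    flat = (zidx * rx + coded.col(x)) * ry + coded.col(y)
    counts = np.bincount(flat, minlength=nz * rx * ry).reshape(nz, rx, ry).astype(float)
    row = counts.sum(axis=2, keepdims=True)
    col = counts.sum(axis=1, keepdims=True)
    tot = counts.sum(axis=(1, 2), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row * col / tot
        terms = counts * np.log(counts / expected)
    g2 = 2.0 * float(np.nansum(terms))
    nz_rows = (row[:, :, 0] > 0).sum(axis=1)
    nz_cols = (col[:, 0, :] > 0).sum(axis=1)
    df = int(np.sum(np.maximum(nz_rows - 1, 0) * np.maximum(nz_cols - 1, 0)))
    if df <= 0:
        p = 1.0
    else:
        p = float(chi2.sf(g2, df))
    return CITestResult(g2, df, p, p > alpha)


# ---------------------------------------------------------------------------
# partially directed graphs

@dataclass(frozen=True)
class PartiallyDirectedGraph:
    """Skeleton with a mix of directed and undirected edge marks."""

    nodes: tuple[str, ...]
    directed: frozenset[tuple[str, str]]
    undirected: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        for a, b in self.directed:
            if a == b:
                raise ValueError("self-loop")
            if frozenset((a, b)) in self.undirected:
                raise ValueError(f"edge {a!r}-{b!r} both directed and undirected")

    def adjacent(self, a: str, b: str) -> bool:
        return (
            (a, b) in self.directed
            or (b, a) in self.directed
            or frozenset((a, b)) in self.undirected
        )

    def neighbours(self, a: str) -> set[str]:
        out = {c for p, c in self.directed if p == a}
        out |= {p for p, c in self.directed if c == a}
        for e in self.undirected:
            if a in e:
                out |= e - {a}
        return out

    def skeleton(self) -> frozenset[frozenset[str]]:
        return frozenset(
            {frozenset(e) for e in self.directed} | set(self.undirected)
        )


def _directed_reaches(directed: "set[tuple[str, str]]", src: str, dst: str) -> bool:
    stack, seen = [src], {src}
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for a, b in directed:
            if a == u and b not in seen:
                seen.add(b)
                stack.append(b)
    return False


def _apply_meek_rules(
    nodes: "tuple[str, ...]",
    directed: "set[tuple[str, str]]",
    undirected: "set[frozenset[str]]",
) -> None:
    """Orient undirected edges by Meek rules 1-4 until closure (in place)."""

    def adjacent(a, b):
        return (a, b) in directed or (b, a) in directed or frozenset((a, b)) in undirected

    changed = True
    while changed:
        changed = False
        for e in sorted(undirected, key=sorted):
            a, b = sorted(e)
            for x, y in ((a, b), (b, a)):
                orient = False
                # R1: z -> x, z not adjacent y  =>  x -> y
                for z, w in list(directed):
                    if w == x and z != y and not adjacent(z, y):
                        orient = True
                        break
                # R2: directed path x -> ... -> y of length 2 => x -> y
                if not orient:
                    for z in nodes:
                        if (x, z) in directed and (z, y) in directed:
                            orient = True
                            break
                # R3: x - z1 -> y, x - z2 -> y, z1 not adjacent z2 => x -> y
                if not orient:
                    zs = [
                        z
                        for z in nodes
                        if frozenset((x, z)) in undirected and (z, y) in directed
                    ]
                    for z1, z2 in itertools.combinations(zs, 2):
                        if not adjacent(z1, z2):
                            orient = True
                            break
                # R4: x - z, z -> w, w -> y, z not adjacent y, x adjacent w
                if not orient:
                    for z in nodes:
                        if frozenset((x, z)) not in undirected:
                            continue
                        for w in nodes:
                            if (
                                (z, w) in directed
                                and (w, y) in directed
                                and not adjacent(z, y)
                                and adjacent(x, w)
                            ):
                                orient = True
                                break
                        if orient:
                            break
                if orient:
                    undirected.discard(e)
                    directed.add((x, y))
                    changed = True
                    break
            if changed:
                break


def pc_stable(
    data: "TabularDataset | CodedData",
    alpha: float = 0.05,
    max_cond_set: int = 3,
    ci_test=ci_test_g2,
) -> PartiallyDirectedGraph:
    """PC-stable: order-independent skeleton, v-structures, Meek rules.

    At each conditioning-set size the adjacency sets are frozen and edge
    removals are applied only after the whole level completes, so the
    skeleton does not depend on the order of columns or tests.
    """
    coded = _as_coded(data)
    nodes = tuple(coded.columns)
    adj: dict[str, set[str]] = {a: set(nodes) - {a} for a in nodes}
    sepset: dict[frozenset[str], tuple[str, ...]] = {}
    for level in range(max_cond_set + 1):
        frozen = {a: set(adj[a]) for a in nodes}
        to_remove: set[frozenset[str]] = set()
        for a, b in itertools.combinations(nodes, 2):
            if b not in adj[a] or frozenset((a, b)) in to_remove:
                continue
            found = False
            for x, y in ((a, b), (b, a)):
                pool = sorted(frozen[x] - {y})
                if len(pool) < level:
                    continue
                for S in itertools.combinations(pool, level):
                    res = ci_test(x, y, S, coded, alpha)
                    if res.independent:
                        to_remove.add(frozenset((a, b)))
                        sepset[frozenset((a, b))] = S
                        found = True
                        break
                if found:
                    break
        for e in to_remove:
            a, b = tuple(e)
            adj[a].discard(b)
            adj[b].discard(a)
        if all(len(adj[a]) <= level for a in nodes):
            break
    undirected: set[frozenset[str]] = {
        frozenset((a, b)) for a in nodes for b in adj[a] if a < b
    }
    directed: set[tuple[str, str]] = set()
    # v-structures: a - c - b with a, b non-adjacent and c outside sepset(a, b)
    for a, b in itertools.combinations(nodes, 2):
        if b in adj[a]:
            continue
        for c in sorted(adj[a] & adj[b]):
            if c not in sepset.get(frozenset((a, b)), ()):
                for parent in (a, b):
                    e = frozenset((parent, c))
                    if e in undirected:
                        undirected.discard(e)
                        directed.add((parent, c))
                    elif (c, parent) in directed:
                        # conflicting collider claims: leave earlier one
                        pass
    _apply_meek_rules(nodes, directed, undirected)
    return PartiallyDirectedGraph(nodes, frozenset(directed), frozenset(undirected))


# ---------------------------------------------------------------------------
# MMPC / MMHC

def _max_p_over_subsets(
    x: str, t: str, cpc: "set[str]", coded: CodedData, max_cond_set: int, ci_test, alpha
) -> float:
    """Worst-case (largest) p-value of assoc(x, t | Z) over Z subsets of cpc."""
    worst = 0.0
    pool = sorted(cpc)
    for size in range(min(len(pool), max_cond_set) + 1):
        for S in itertools.combinations(pool, size):
            p = ci_test(x, t, S, coded, alpha).p_value
            if p > worst:
                worst = p
                if worst > alpha:
                    return worst  # already non-significant; no need to go on
    return worst


def mmpc(
    target: str,
    data: "TabularDataset | CodedData",
    alpha: float = 0.05,
    max_cond_set: int = 3,
    ci_test=ci_test_g2,
) -> set[str]:
    """Max-min parents-and-children heuristic for one node.

    Forward phase: repeatedly add the candidate whose *minimum* association
    with the target over conditioning subsets of the current set is largest
    (equivalently, whose maximum p-value is smallest), while it stays
    significant. Backward phase: drop members separated from the target by
    some subset of the rest. Symmetry correction happens in :func:`mmhc`.
    """
    coded = _as_coded(data)
    cpc: set[str] = set()
    candidates = set(coded.columns) - {target}
    while True:
        best: str | None = None
        best_p = None
        for x in sorted(candidates - cpc):
            p = _max_p_over_subsets(x, target, cpc, coded, max_cond_set, ci_test, alpha)
            if p <= alpha and (best_p is None or p < best_p - 1e-15):
                best, best_p = x, p
        if best is None:
            break
        cpc.add(best)
    # backward: remove false positives
    for x in sorted(cpc):
        others = cpc - {x}
        pool = sorted(others)
        separated = False
        for size in range(min(len(pool), max_cond_set) + 1):
            for S in itertools.combinations(pool, size):
                if ci_test(x, target, S, coded, alpha).independent:
                    separated = True
                    break
            if separated:
                break
        if separated:
            cpc.discard(x)
    return cpc


def mmhc(
    data: "TabularDataset | CodedData",
    alpha: float = 0.05,
    score=family_score_bic,
    seed: int = 0,
    max_cond_set: int = 3,
    max_parents: int = 8,
) -> DAGStructure:
    """Max-min hill climbing: MMPC-restricted edge space, then hill climb.

    The symmetry-corrected MMPC graph (x adjacent to y only if each is in the
    other's parents-and-children set) defines the allowed pairs; the returned
    DAG's edges are always a subset of those pairs.
    """
    coded = _as_coded(data)
    pc = {n: mmpc(n, coded, alpha, max_cond_set) for n in coded.columns}
    allowed = {
        frozenset((a, b))
        for a in coded.columns
        for b in pc[a]
        if a in pc[b]
    }
    if not allowed:
        return DAGStructure(tuple(coded.columns), frozenset())
    return hill_climb(
        coded, score, max_parents=max_parents, restarts=0, seed=seed,
        allowed_pairs=allowed,
    )


# ---------------------------------------------------------------------------
# PDAG <-> DAG

def pdag_to_dag(g: PartiallyDirectedGraph) -> DAGStructure:
    """Extend a PDAG to a DAG (Dor-Tarsi), with a deterministic fallback.

    When a consistent extension exists the Dor-Tarsi procedure finds it; if
    at some step no node qualifies, the remaining undirected edge with the
    smallest node names is oriented low -> high (flipped if that would close
    a cycle) and the procedure continues.
    """
    directed: set[tuple[str, str]] = set(g.directed)
    undirected: set[frozenset[str]] = set(g.undirected)
    live = set(g.nodes)
    removed: set[str] = set()

    def adj_live(a):
        out = set()
        for p, c in directed:
            if p == a and c in live:
                out.add(c)
            if c == a and p in live:
                out.add(p)
        for e in undirected:
            if a in e:
                b = next(iter(e - {a}))
                if b in live:
                    out.add(b)
        return out

    while live:
        progressed = False
        # largest-name sink first, so symmetric ties orient low -> high
        for x in sorted(live, reverse=True):
            # no outgoing directed edges into live nodes
            if any(p == x and c in live for p, c in directed):
                continue
            und_nb = {
                y
                for e in undirected
                if x in e
                for y in e - {x}
                if y in live
            }
            ax = adj_live(x)
            if all(
                g.adjacent(y, z) or frozenset((y, z)) in undirected
                or (y, z) in directed or (z, y) in directed
                for y in und_nb
                for z in ax - {y}
            ):
                for y in und_nb:
                    undirected.discard(frozenset((x, y)))
                    directed.add((y, x))
                live.discard(x)
                removed.add(x)
                progressed = True
                break
        if not progressed:
            if undirected:
                e = min(undirected, key=sorted)
                a, b = sorted(e)
                undirected.discard(e)
                if _directed_reaches(directed, b, a):
                    directed.add((b, a))
                else:
                    directed.add((a, b))
            else:
                # inconsistent orientations left a directed cycle among the
                # remaining nodes; drop the smallest edge lying on a cycle
                live_edges = sorted(
                    (p, c) for p, c in directed if p in live and c in live
                )
                for p, c in live_edges:
                    if _directed_reaches(directed - {(p, c)}, c, p):
                        directed.discard((p, c))
                        break
                else:  # no cycle at all: every live node must be removable
                    live.discard(min(live))
    return DAGStructure(tuple(g.nodes), frozenset(directed))


def cpdag_of(dag: DAGStructure) -> PartiallyDirectedGraph:
    """CPDAG of ``dag``: compelled edges directed, reversible edges undirected.

    Starts from the skeleton with only v-structure edges directed, then runs
    the Meek rules to closure — the standard characterisation of the
    Markov-equivalence class.
    """
    nodes = dag.nodes
    directed: set[tuple[str, str]] = set()
    undirected: set[frozenset[str]] = {frozenset(e) for e in dag.edges}
    for c in nodes:
        ps = dag.parents(c)
        for a, b in itertools.combinations(ps, 2):
            if (a, b) not in dag.edges and (b, a) not in dag.edges:
                for parent in (a, b):
                    e = frozenset((parent, c))
                    if e in undirected:
                        undirected.discard(e)
                        directed.add((parent, c))
    _apply_meek_rules(nodes, directed, undirected)
    return PartiallyDirectedGraph(nodes, frozenset(directed), frozenset(undirected))


# ---------------------------------------------------------------------------
# learner registry

def _learn_hc(data, config) -> DAGStructure:
    return hill_climb(
        data,
        max_parents=config.get("max_parents", 8),
        restarts=config.get("restarts", 0),
        seed=config.get("seed", 0),
    )


def _learn_tabu(data, config) -> DAGStructure:
    return tabu_search(
        data,
        tabu_length=config.get("tabu_length", 10),
        max_worsening_moves=config.get("max_worsening_moves", 10),
        seed=config.get("seed", 0),
        max_parents=config.get("max_parents", 8),
    )


def _learn_pc_stable(data, config) -> DAGStructure:
    pdag = pc_stable(
        data,
        alpha=config.get("alpha", 0.05),
        max_cond_set=config.get("max_cond_set", 3),
    )
    return pdag_to_dag(pdag)


def _learn_mmhc(data, config) -> DAGStructure:
    return mmhc(
        data,
        alpha=config.get("alpha", 0.05),
        seed=config.get("seed", 0),
        max_cond_set=config.get("max_cond_set", 3),
        max_parents=config.get("max_parents", 8),
    )


#: Registry keyed by the bnlearn-style learner names. Each entry is a
#: callable ``learn(data, config) -> DAGStructure``; constraint-based output
#: is auto-extended to a DAG. New learners plug in by adding an entry.
LEARNERS: dict[str, object] = {
    "hc": _learn_hc,
    "tabu": _learn_tabu,
    "pc.stable": _learn_pc_stable,
    "mmhc": _learn_mmhc,
}


def learn_structure(
    name: str, data: "TabularDataset | CodedData", config: "dict | None" = None
) -> DAGStructure:
    """Run the registered learner ``name`` on ``data``."""
    if name not in LEARNERS:
        raise KeyError(f"unknown learner {name!r}; available: {sorted(LEARNERS)}")
    return LEARNERS[name](data, dict(config or {}))
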