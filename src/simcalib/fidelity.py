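"""Structural and distributional fidelity of learned DGPs.

Structural fidelity is the Structural Hamming Distance (SHD) between the
learned and true adjacency structures; distributional fidelity is the
Jensen-Shannon divergence between real and synthetic data, averaged over
per-variable marginals (base-2 logs, so values live in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .bn import BayesianNetwork, DAGStructure, TabularDataset
from .structure import PartiallyDirectedGraph, cpdag_of

__all__ = ["shd", "marginal_js", "FidelitySummary", "fidelity_report"]


def shd(g1: DAGStructure, g2: DAGStructure, *, equivalence_class: bool = False) -> int:
    """Structural Hamming Distance between two DAGs over the same nodes.

    Counts the edge edits (insertion, deletion, reversal — reversal costs 1)
    needed to turn ``g1`` into ``g2``, comparing adjacency pair by pair.
    With ``equivalence_class=True`` the comparison is between the CPDAGs of
    the two DAGs (bnlearn-style): a directed-vs-undirected mark mismatch on
    the same skeleton edge also counts 1.
    """
    if set(g1.nodes) != set(g2.nodes):
        raise ValueError("graphs must share the same node set")
    if equivalence_class:
        return _shd_pdag(cpdag_of(g1), cpdag_of(g2))
    dist = 0
    seen: set[frozenset[str]] = set()
    for a, b in set(g1.edges) | set(g2.edges):
        pair = frozenset((a, b))
        if pair in seen:
            continue
        seen.add(pair)
        s1 = _pair_state(g1.edges, a, b)
        s2 = _pair_state(g2.edges, a, b)
        if s1 != s2:
            dist += 1
    return dist


def _pair_state(edges: frozenset, a: str, b: str) -> str:
    if (a, b) in edges:
        return f"{a}>{b}"
    if (b, a) in edges:
        return f"{b}>{a}"
    return "none"


def _shd_pdag(p1: PartiallyDirectedGraph, p2: PartiallyDirectedGraph) -> int:
    dist = 0
    pairs = {frozenset(e) for e in p1.directed} | set(p1.undirected)
    pairs |= {frozenset(e) for e in p2.directed} | set(p2.undirected)
    for pair in pairs:
        a, b = sorted(pair)
        s1 = _pdag_state(p1, a, b)
        s2 = _pdag_state(p2, a, b)
        if s1 != s2:
            dist += 1
    return dist


def _pdag_state(p: PartiallyDirectedGraph, a: str, b: str) -> str:
    if (a, b) in p.directed:
        return f"{a}>{b}"
    if (b, a) in p.directed:
        return f"{b}>{a}"
    if frozenset((a, b)) in p.undirected:
        return "und"
    return "none"


def marginal_js(data1: TabularDataset, data2: TabularDataset) -> float:
    """Mean per-variable Jensen-Shannon divergence (base 2) between datasets.

    For each shared column the empirical marginal over the declared level
    domain is compared; the result is the average across columns and lies in
    [0, 1], with 0 iff every pair of marginals coincides.
    """
    if list(data1.columns) != list(data2.columns):
        raise ValueError("datasets must have identical column sets and order")
    vals = []
    for col in data1.columns:
        if tuple(data1.domains[col]) != tuple(data2.domains[col]):
            raise ValueError(f"level domains for {col!r} differ")
        levels = data1.domains[col]
        p = _marginal(data1.data[col], levels)
        q = _marginal(data2.data[col], levels)
        # scipy returns the JS *distance* (sqrt of the divergence)
        vals.append(jensenshannon(p, q, base=2) ** 2)
    return float(np.mean(vals))


def _marginal(series: pd.Series, levels: tuple[str, ...]) -> np.ndarray:
    counts = series.value_counts()
    vec = np.array([counts.get(lev, 0) for lev in levels], dtype=float)
    return vec / vec.sum()


@dataclass
class FidelitySummary:
    """Per-learner fidelity: SHD per repetition and JS moments."""

    learner: str
    shd_values: list[int]
    js_values: list[float]

    @property
    def shd_median(self) -> float:
        return float(np.median(self.shd_values)) if self.shd_values else float("nan")

    @property
    def js_mean(self) -> float:
        return float(np.mean(self.js_values)) if self.js_values else float("nan")

    @property
    def js_variance(self) -> float:
        if len(self.js_values) < 2:
            return 0.0
        return float(np.var(self.js_values, ddof=1))


def fidelity_report(
    true_bn: BayesianNetwork,
    learned: "dict[str, list[DAGStructure]]",
    real_data: "TabularDataset | None" = None,
    synthetic_data: "dict[str, list[TabularDataset]] | None" = None,
    *,
    equivalence_class: bool = False,
) -> list[FidelitySummary]:
    """Summarise structural and distributional fidelity per learner.

    ``learned`` maps learner id to the structures inferred across
    practitioner repetitions; ``synthetic_data`` (optional) maps learner id
    to synthetic datasets to compare against ``real_data``.
    """
    out = []
    for learner in sorted(learned):
        structures = learned[learner]
        if not structures:
            raise ValueError(f"no learned structures for {learner!r}")
        shds = [
            shd(true_bn.structure, g, equivalence_class=equivalence_class)
            for g in structures
        ]
        js_vals: list[float] = []
        if real_data is not None and synthetic_data is not None:
            for synth in synthetic_data.get(learner, []):
                js_vals.append(marginal_js(real_data, synth))
        out.append(FidelitySummary(learner, shds, js_vals))
    return out
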