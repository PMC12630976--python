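"""BIF (Bayesian Interchange Format 0.15) read/write.

Accepts the dialect used by the public bnlearn network repository:
``network``/``variable``/``probability`` blocks, ``property`` lines ignored,
and both ``table`` rows and per-parent-configuration ``( levels ) p1, p2;``
rows. Variable and level declaration order is preserved exactly.
"""

from __future__ import annotations

import itertools
import re
from pathlib import Path

import numpy as np

from .bn import BayesianNetwork, CPT, DAGStructure, Variable

__all__ = ["read_bif", "write_bif", "BIFParseError"]

_ROW_SUM_TOL = 1e-4


class BIFParseError(ValueError):
    """Malformed BIF input; message names the offending line."""


_TOKEN_RE = re.compile(
    r"""
    (?P<comment>//[^\n]*|\#[^\n]*) |
    (?P<word>[A-Za-z0-9_.\-+=%/:<>?!&@']+) |
    (?P<punct>[{}()\[\]|,;])       |
    (?P<string>"[^"]*")            |
    (?P<ws>\s+)
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    line = 1
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise BIFParseError(f"line {line}: unexpected character {text[pos]!r}")
        kind = m.lastgroup
        value = m.group()
        if kind == "word" or kind == "punct":
            tokens.append((value, line))
        elif kind == "string":
            tokens.append((value.strip('"'), line))
        line += value.count("\n")
        pos = m.end()
    return tokens


class _Cursor:
    def __init__(self, tokens: list[tuple[str, int]]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    @property
    def line(self) -> int:
        i = min(self.i, len(self.tokens) - 1)
        return self.tokens[i][1] if self.tokens else 0

    def next(self) -> str:
        if self.i >= len(self.tokens):
            raise BIFParseError("unexpected end of file")
        tok = self.tokens[self.i][0]
        self.i += 1
        return tok

    def expect(self, value: str) -> None:
        tok = self.next()
        if tok != value:
            raise BIFParseError(f"line {self.line}: expected {value!r}, got {tok!r}")

    def skip_block(self) -> None:
        """Skip a balanced { ... } block (used for property payloads)."""
        self.expect("{")
        depth = 1
        while depth:
            tok = self.next()
            if tok == "{":
                depth += 1
            elif tok == "}":
                depth -= 1


def _skip_property(cur: _Cursor) -> None:
    # property lines end at ';'
    while True:
        tok = cur.next()
        if tok == ";":
            return


def _parse_variable(cur: _Cursor) -> Variable:
    name = cur.next()
    cur.expect("{")
    levels: list[str] | None = None
    while True:
        tok = cur.next()
        if tok == "}":
            break
        if tok == "property":
            _skip_property(cur)
            continue
        if tok != "type":
            raise BIFParseError(f"line {cur.line}: unexpected {tok!r} in variable block")
        cur.expect("discrete")
        # accept "type discrete [ n ] { a, b };"; the [ n ] part is optional
        declared = None
        tok = cur.next()
        if tok == "[":
            declared = int(cur.next())
            cur.expect("]")
            tok = cur.next()
        if tok != "{":
            raise BIFParseError(f"line {cur.line}: expected '{{' in type declaration")
        levels = []
        while True:
            tok = cur.next()
            if tok == "}":
                break
            if tok == ",":
                continue
            levels.append(tok)
        cur.expect(";")
        if declared is not None and declared != len(levels):
            raise BIFParseError(
                f"line {cur.line}: variable {name!r} declares {declared} levels, lists {len(levels)}"
            )
    if levels is None:
        raise BIFParseError(f"variable {name!r} has no type declaration")
    return Variable(name, tuple(levels))


def _parse_floats_until_semicolon(cur: _Cursor) -> list[float]:
    vals: list[float] = []
    while True:
        tok = cur.next()
        if tok == ";":
            return vals
        if tok == ",":
            continue
        try:
            vals.append(float(tok))
        except ValueError:
            raise BIFParseError(f"line {cur.line}: expected a number, got {tok!r}") from None


def _parse_probability(
    cur: _Cursor, variables: dict[str, Variable]
) -> tuple[str, tuple[str, ...], np.ndarray]:
    cur.expect("(")
    child = cur.next()
    parents: list[str] = []
    tok = cur.next()
    if tok == "|":
        while True:
            tok = cur.next()
            if tok == ")":
                break
            if tok == ",":
                continue
            parents.append(tok)
    elif tok != ")":
        raise BIFParseError(f"line {cur.line}: malformed probability header")
    for v in [child, *parents]:
        if v not in variables:
            raise BIFParseError(f"line {cur.line}: probability block references unknown variable {v!r}")
    card = variables[child].cardinality
    pcards = [variables[p].cardinality for p in parents]
    n_cfg = int(np.prod(pcards)) if parents else 1
    level_index = {
        p: {lev: i for i, lev in enumerate(variables[p].levels)} for p in parents
    }
    table = np.full((n_cfg, card), np.nan)
    cur.expect("{")
    while True:
        tok = cur.next()
        if tok == "}":
            break
        if tok == "property":
            _skip_property(cur)
        elif tok == "table":
            vals = _parse_floats_until_semicolon(cur)
            if len(vals) != n_cfg * card:
                raise BIFParseError(
                    f"line {cur.line}: table for {child!r} has {len(vals)} entries, expected {n_cfg * card}"
                )
            table[:] = np.asarray(vals).reshape(n_cfg, card)
        elif tok == "(":
            cfg_levels: list[str] = []
            while True:
                tok = cur.next()
                if tok == ")":
                    break
                if tok == ",":
                    continue
                cfg_levels.append(tok)
            if len(cfg_levels) != len(parents):
                raise BIFParseError(
                    f"line {cur.line}: configuration for {child!r} names {len(cfg_levels)} levels, expected {len(parents)}"
                )
            idx = 0
            for p, lev in zip(parents, cfg_levels):
                if lev not in level_index[p]:
                    raise BIFParseError(
                        f"line {cur.line}: unknown level {lev!r} for parent {p!r}"
                    )
                idx = idx * variables[p].cardinality + level_index[p][lev]
            vals = _parse_floats_until_semicolon(cur)
            if len(vals) != card:
                raise BIFParseError(
                    f"line {cur.line}: row for {child!r} has {len(vals)} entries, expected {card}"
                )
            table[idx] = vals
        else:
            raise BIFParseError(f"line {cur.line}: unexpected {tok!r} in probability block")
    if np.isnan(table).any():
        raise BIFParseError(
            f"line {cur.line}: probability block for {child!r} does not cover all parent configurations"
        )
    sums = table.sum(axis=1)
    if np.abs(sums - 1.0).max() > _ROW_SUM_TOL:
        worst = float(np.abs(sums - 1.0).max())
        raise BIFParseError(
            f"line {cur.line}: CPT row for {child!r} sums off by {worst:.2e} (> {_ROW_SUM_TOL})"
        )
    table = table / sums[:, None]  # exact renormalisation within tolerance
    shape = tuple(pcards) + (card,)
    return child, tuple(parents), table.reshape(shape)


def read_bif(path: "str | Path") -> BayesianNetwork:
    """Parse a BIF file into a validated :class:`BayesianNetwork`."""
    text = Path(path).read_text()
    cur = _Cursor(_tokenize(text))
    variables: dict[str, Variable] = {}
    cpts: dict[str, CPT] = {}
    edges: set[tuple[str, str]] = set()
    while cur.peek() is not None:
        tok = cur.next()
        if tok == "network":
            cur.next()  # network name
            cur.skip_block()
        elif tok == "variable":
            v = _parse_variable(cur)
            if v.name in variables:
                raise BIFParseError(f"duplicate variable {v.name!r}")
            variables[v.name] = v
        elif tok == "probability":
            child, parents, table = _parse_probability(cur, variables)
            if child in cpts:
                raise BIFParseError(f"duplicate probability block for {child!r}")
            cpts[child] = CPT(child, parents, table)
            edges.update((p, child) for p in parents)
        else:
            raise BIFParseError(f"line {cur.line}: unexpected top-level token {tok!r}")
    missing = set(variables) - set(cpts)
    if missing:
        raise BIFParseError(f"no probability block for {sorted(missing)}")
    structure = DAGStructure(tuple(variables), frozenset(edges))
    # CPT parent order may differ from DAGStructure's sorted convention;
    # reorder axes so downstream code sees a single canonical order.
    canon: dict[str, CPT] = {}
    for name, cpt in cpts.items():
        want = structure.parents(name)
        if cpt.parents == want:
            canon[name] = cpt
        else:
            perm = [cpt.parents.index(p) for p in want] + [len(cpt.parents)]
            canon[name] = CPT(name, want, np.transpose(cpt.probs, perm))
    return BayesianNetwork(tuple(variables.values()), structure, canon)


def write_bif(bn: BayesianNetwork, path: "str | Path") -> None:
    """Write ``bn`` so that :func:`read_bif` recovers an identical network."""
    lines: list[str] = ["network unknown {", "}"]
    for v in bn.variables:
        lines.append(f"variable {v.name} {{")
        lines.append(
            f"  type discrete [ {v.cardinality} ] {{ {', '.join(v.levels)} }};"
        )
        lines.append("}")
    var = bn.variable_map
    for v in bn.variables:
        cpt = bn.cpts[v.name]
        if not cpt.parents:
            header = f"probability ( {v.name} ) {{"
            lines.append(header)
            row = ", ".join(f"{x:.10g}" for x in cpt.probs)
            lines.append(f"  table {row};")
        else:
            header = f"probability ( {v.name} | {', '.join(cpt.parents)} ) {{"
            lines.append(header)
            flat = cpt.flat
            configs = itertools.product(*(var[p].levels for p in cpt.parents))
            for i, cfg in enumerate(configs):
                row = ", ".join(f"{x:.10g}" for x in flat[i])
                lines.append(f"  ( {', '.join(cfg)} ) {row};")
        lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
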