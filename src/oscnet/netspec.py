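"""Regulatory network specification: signed digraphs with input algebra.

A network is written one line per target as ``Target : expr`` where
``expr`` multiplies parenthesized groups and sums sources within a group;
``~`` marks repression.  Example::

    A : F
    C : (A + E)(~D)

Node C's production is (input from A  +  input from E) x (input from D),
with the D term a decreasing function of D.  Each node has one output
threshold per out-edge, so a node with k out-edges has k+1 qualitative
levels in the switching-system semantics (see :mod:`oscnet.regions`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import networkx as nx

from .core import ACTIVATION, REPRESSION, EdgeHypothesis


class NetworkParseError(ValueError):
    """Raised for malformed network text."""


# (source, is_activation) term inside a group
Term = tuple[str, bool]


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Signed digraph with per-target sum-of-products input algebra.

    ``nodes`` fixes the variable order; ``inputs[v]`` is a tuple of groups,
    each group a tuple of ``(source, is_activation)`` terms (summed within
    a group, multiplied across groups).
    """

    nodes: tuple[str, ...]
    inputs: tuple[tuple[tuple[Term, ...], ...], ...]  # aligned with nodes

    def __post_init__(self) -> None:
        known = set(self.nodes)
        if len(known) != len(self.nodes):
            raise NetworkParseError("duplicate node names")
        for v, groups in zip(self.nodes, self.inputs):
            seen = set()
            for grp in groups:
                if not grp:
                    raise NetworkParseError(f"empty input group for node {v}")
                for src, _ in grp:
                    if src not in known:
                        raise NetworkParseError(f"unknown source {src!r} for node {v}")
                    if src in seen:
                        raise NetworkParseError(f"repeated source {src!r} for node {v}")
                    seen.add(src)

    # -- structure ---------------------------------------------------------

    def in_groups(self, node: str) -> tuple[tuple[Term, ...], ...]:
        return self.inputs[self.nodes.index(node)]

    def in_edges(self, node: str) -> list[Term]:
        return [t for grp in self.in_groups(node) for t in grp]

    def out_targets(self, node: str) -> list[str]:
        """Targets of ``node``, in canonical (node-order) sequence."""
        out = []
        for v, groups in zip(self.nodes, self.inputs):
            if any(src == node for grp in groups for src, _ in grp):
                out.append(v)
        return out

    def out_degree(self, node: str) -> int:
        return len(self.out_targets(node))

    def levels(self, node: str) -> int:
        """Number of qualitative levels: out-degree + 1."""
        return self.out_degree(node) + 1

    @property
    def edges(self) -> list[EdgeHypothesis]:
        out = []
        for v, groups in zip(self.nodes, self.inputs):
            for grp in groups:
                for src, act in grp:
                    out.append(EdgeHypothesis(v, src, ACTIVATION if act else REPRESSION))
        return sorted(out)

    def has_self_repression(self) -> bool:
        return any(e.is_self_repression for e in self.edges)

    def is_strongly_connected(self) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.source, e.target) for e in self.edges)
        return nx.is_strongly_connected(g)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(cls, edges: list[EdgeHypothesis],
                   nodes: list[str] | None = None) -> "RegulatoryNetwork":
        """Build a network with all-product algebra (one group per in-edge)."""
        if nodes is None:
            nodes = sorted({e.source for e in edges} | {e.target for e in edges})
        by_target: dict[str, list[Term]] = {v: [] for v in nodes}
        for e in sorted(set(edges)):
            by_target[e.target].append((e.source, e.sign == ACTIVATION))
        inputs = tuple(tuple((t,) for t in sorted(by_target[v])) for v in nodes)
        return cls(tuple(nodes), inputs)

    # -- serialization -----------------------------------------------------

    def serialize(self) -> str:
        lines = []
        for v, groups in zip(self.nodes, self.inputs):
            if not groups:
                expr = ""
            elif len(groups) == 1 and len(groups[0]) == 1:
                expr = _term_str(groups[0][0])
            else:
                expr = "".join(
                    "(" + " + ".join(_term_str(t) for t in grp) + ")" for grp in groups)
            lines.append(f"{v} : {expr}")
        return "\n".join(lines) + "\n"

    def canonical(self) -> str:
        """Order-independent serialization used for network deduplication."""
        parts = []
        for v in sorted(self.nodes):
            groups = self.in_groups(v)
            gs = sorted(tuple(sorted(grp)) for grp in groups)
            parts.append((v, tuple(gs)))
        return repr(parts)

    def __eq__(self, other) -> bool:
        return isinstance(other, RegulatoryNetwork) and self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())


def _term_str(term: Term) -> str:
    src, act = term
    return src if act else f"~{src}"


_NAME = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")


def parse_network(text: str) -> RegulatoryNetwork:
    """Parse the one-line-per-target network text format."""
    node_lines: list[tuple[str, str]] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise NetworkParseError(f"missing ':' in line {raw!r}")
        name, _, expr = line.partition(":")
        name = name.strip()
        if not _NAME.fullmatch(name):
            raise NetworkParseError(f"bad node name {name!r}")
        node_lines.append((name, expr.strip()))
    nodes = tuple(n for n, _ in node_lines)
    inputs = []
    for name, expr in node_lines:
        inputs.append(_parse_expr(name, expr))
    return RegulatoryNetwork(nodes, tuple(inputs))


def _parse_expr(node: str, expr: str) -> tuple[tuple[Term, ...], ...]:
    if not expr:
        raise NetworkParseError(f"empty expression for node {node}")
    if "(" in expr or ")" in expr:
        groups = []
        depth, buf = 0, ""
        for ch in expr:
            if ch == "(":
                if depth:
                    raise NetworkParseError(f"nested parentheses for node {node}")
                depth, buf = 1, ""
            elif ch == ")":
                if not depth:
                    raise NetworkParseError(f"unbalanced ')' for node {node}")
                depth = 0
                groups.append(_parse_group(node, buf))
            elif depth:
                buf += ch
            elif not ch.isspace() and ch != "*":
                raise NetworkParseError(
                    f"unexpected {ch!r} outside parentheses for node {node}")
        if depth:
            raise NetworkParseError(f"unbalanced '(' for node {node}")
        return tuple(groups)
    # no parentheses: a single group (sum of terms)
    return (_parse_group(node, expr),)


def _parse_group(node: str, text: str) -> tuple[Term, ...]:
    terms = []
    for piece in text.split("+"):
        piece = piece.strip()
        if not piece:
            raise NetworkParseError(f"empty term for node {node}")
        act = True
        if piece.startswith("~"):
            act = False
            piece = piece[1:].strip()
        if not _NAME.fullmatch(piece):
            raise NetworkParseError(f"bad source name {piece!r} for node {node}")
        terms.append((piece, act))
    return tuple(terms)
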