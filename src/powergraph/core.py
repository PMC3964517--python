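"""Graph and power-graph component data types.

A *power node* is a set of ordinary nodes treated as a unit; a *poweredge*
between power nodes A and B asserts that every node in A is connected to
every node in B (a complete biclique in the underlying graph).  A pair
(A, B) whose poweredge encoding is shorter than listing its edges is a
*compressible component*.  This module holds the graph container, the
component type, completeness checking, and the lossless decomposition of a
graph into selected components plus an overlap matrix V and a remainder R.

Supported graph modes:

``directed``
    Ordered edges u -> v.  Self-loops are permitted only when present in
    the input (or explicitly enabled).
``undirected_self`` / ``undirected_noself``
    Unordered edges, with / without self-loops.
``bipartite``
    Edges cross a fixed two-part node partition; stored left -> right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

__all__ = [
    "MODES",
    "UNDIRECTED_MODES",
    "PowerGraphError",
    "InputError",
    "ContractError",
    "NetworkGraph",
    "PowerComponent",
    "ComponentDecomposition",
    "validate_graph",
    "component_edges",
    "check_completeness",
    "decompose",
    "reconstruct",
]

Node = Hashable
Edge = tuple  # (u, v) in the graph's canonical orientation

MODES = ("directed", "undirected_self", "undirected_noself", "bipartite")
UNDIRECTED_MODES = frozenset({"undirected_self", "undirected_noself"})


class PowerGraphError(Exception):
    """Base class for powergraph errors."""


class InputError(PowerGraphError, ValueError):
    """Malformed or inconsistent user input."""


class ContractError(PowerGraphError, ValueError):
    """An internal contract was violated (e.g. an incomplete component)."""


def _sort_key(label: Node):
    # Deterministic order over arbitrary hashable labels.
    return (str(type(label).__name__), str(label))


class NetworkGraph:
    """A validated simple graph with a stable node iteration order.

    The node order (input order) defines the iteration sequence used by
    candidate enumeration, so it is part of the graph's identity.
    """

    __slots__ = ("nodes", "index", "edges", "mode", "parts", "allow_self", "_nbrs")

    def __init__(
        self,
        nodes: tuple,
        edges: frozenset,
        mode: str,
        parts: Mapping[Node, int] | None = None,
        allow_self: bool = False,
    ):
        self.nodes = nodes
        self.index = {n: i for i, n in enumerate(nodes)}
        self.edges = edges
        self.mode = mode
        self.parts = dict(parts) if parts is not None else None
        self.allow_self = allow_self
        self._nbrs: dict | None = None

    # -- basic accessors -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def density(self) -> float:
        """Fraction of possible node pairs that carry an edge."""
        n = self.n_nodes
        if self.mode == "directed":
            pairs = n * n if self.allow_self else n * (n - 1)
        elif self.mode == "bipartite":
            n_left = sum(1 for p in self.parts.values() if p == 0)
            pairs = n_left * (n - n_left)
        else:
            pairs = n * (n + 1) // 2 if self.allow_self else n * (n - 1) // 2
        return self.n_edges / pairs if pairs else 0.0

    @property
    def mean_degree(self) -> float:
        if self.n_nodes == 0:
            return 0.0
        return 2.0 * self.n_edges / self.n_nodes

    def canonical_edge(self, u: Node, v: Node) -> Edge:
        """Return (u, v) in this graph's canonical storage orientation."""
        if self.mode in UNDIRECTED_MODES:
            return (u, v) if self.index[u] <= self.index[v] else (v, u)
        if self.mode == "bipartite":
            return (u, v) if self.parts[u] == 0 else (v, u)
        return (u, v)

    # -- adjacency -------------------------------------------------------

    def _build_neighbors(self) -> dict:
        out: dict[Node, set] = {n: set() for n in self.nodes}
        inc: dict[Node, set] = {n: set() for n in self.nodes}
        for u, v in self.edges:
            out[u].add(v)
            inc[v].add(u)
            if self.mode in UNDIRECTED_MODES:
                out[v].add(u)
                inc[u].add(v)
            elif self.mode == "bipartite":
                # neighbor lookup is symmetric across the partition
                out[v].add(u)
                inc[u].add(v)
        if self.mode in UNDIRECTED_MODES:
            for u, v in self.edges:
                if u == v:  # a self-loop makes a node its own neighbor
                    out[u].add(u)
                    inc[u].add(u)
        return {"out": out, "in": inc}

    def neighbors(self, node: Node, direction: str = "out") -> frozenset:
        """Neighbors of ``node``: ``out``/``in`` for directed graphs;
        either works for undirected and bipartite graphs."""
        if self._nbrs is None:
            self._nbrs = self._build_neighbors()
        return frozenset(self._nbrs[direction][node])

    def degree(self, node: Node, direction: str = "out") -> int:
        return len(self.neighbors(node, direction))

    # -- equality / repr -------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, NetworkGraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.mode == other.mode
            and self.parts == other.parts
            and self.allow_self == other.allow_self
        )

    def __hash__(self):
        return hash((self.nodes, self.edges, self.mode, self.allow_self))

    def __repr__(self) -> str:
        return (
            f"NetworkGraph(N={self.n_nodes}, edges={self.n_edges}, "
            f"mode={self.mode!r})"
        )


def validate_graph(
    raw_nodes: Sequence[Node],
    raw_edges: Iterable[tuple],
    mode: str,
    parts: Mapping[Node, int] | None = None,
    allow_self: bool | None = None,
) -> NetworkGraph:
    """Validate raw input and build a :class:`NetworkGraph`.

    Duplicate nodes and edges are collapsed (first occurrence wins for
    ordering); undirected edges are stored with the earlier node first.

    Parameters
    ----------
    raw_nodes:
        Node labels; their order defines the iteration sequence.
    raw_edges:
        Pairs of node labels.
    mode:
        One of ``directed``, ``undirected_self``, ``undirected_noself``,
        ``bipartite``.
    parts:
        Bipartite mode only: mapping node -> 0 (left) or 1 (right).
    allow_self:
        Directed mode only: whether self-loops are legal.  Defaults to
        ``True`` iff the input contains one.
    """
    if mode not in MODES:
        raise InputError(f"unknown mode {mode!r}; expected one of {MODES}")

    nodes: list[Node] = []
    seen = set()
    for n in raw_nodes:
        if n not in seen:
            seen.add(n)
            nodes.append(n)
    node_tuple = tuple(nodes)
    known = seen
    index = {n: i for i, n in enumerate(node_tuple)}

    raw_edges = list(raw_edges)
    for u, v in raw_edges:
        if u not in known or v not in known:
            missing = u if u not in known else v
            raise InputError(f"edge ({u!r}, {v!r}) references unknown node {missing!r}")

    if mode == "bipartite":
        if parts is None:
            raise InputError("bipartite mode requires a part assignment")
        parts = dict(parts)
        bad = [n for n in node_tuple if parts.get(n) not in (0, 1)]
        if bad:
            raise InputError(f"nodes without a valid part assignment: {bad[:5]}")
        for u, v in raw_edges:
            if parts[u] == parts[v]:
                raise InputError(
                    f"edge ({u!r}, {v!r}) does not cross the bipartition"
                )
    else:
        parts = None

    if mode == "directed":
        has_self = any(u == v for u, v in raw_edges)
        if allow_self is None:
            allow_self = has_self
        elif not allow_self and has_self:
            raise InputError("self-loop present but allow_self=False")
    elif mode == "undirected_self":
        allow_self = True
    else:
        allow_self = False
        if mode == "undirected_noself":
            for u, v in raw_edges:
                if u == v:
                    raise InputError(f"self-loop ({u!r}, {u!r}) not allowed in mode undirected_noself")

    edges = set()
    for u, v in raw_edges:
        if mode in UNDIRECTED_MODES:
            e = (u, v) if index[u] <= index[v] else (v, u)
        elif mode == "bipartite":
            e = (u, v) if parts[u] == 0 else (v, u)
        else:
            e = (u, v)
        edges.add(e)

    return NetworkGraph(node_tuple, frozenset(edges), mode, parts, allow_self)


@dataclass(frozen=True)
class PowerComponent:
    """An ordered pair of power nodes (A, B) with its compression gain.

    In directed mode A is the source side and B the target side; in
    bipartite mode A lies in the left part; in undirected modes the pair is
    stored with the lexicographically smaller set first.  ``delta_i`` is
    the gain in bits of encoding the A-B biclique as one poweredge instead
    of listing its edges; it may be ``None`` before evaluation.
    """

    a_nodes: frozenset
    b_nodes: frozenset
    delta_i: float | None = field(default=None, compare=False)

    def __post_init__(self):
        if not self.a_nodes or not self.b_nodes:
            raise ContractError("power nodes must be non-empty")
        object.__setattr__(self, "a_nodes", frozenset(self.a_nodes))
        object.__setattr__(self, "b_nodes", frozenset(self.b_nodes))

    @property
    def n_a(self) -> int:
        return len(self.a_nodes)

    @property
    def n_b(self) -> int:
        return len(self.b_nodes)

    @property
    def n_ab(self) -> int:
        return len(self.a_nodes & self.b_nodes)

    def sort_key(self):
        return (
            tuple(sorted(self.a_nodes, key=_sort_key)),
            tuple(sorted(self.b_nodes, key=_sort_key)),
        )

    def canonical(self, mode: str) -> "PowerComponent":
        """Canonical orientation: in undirected modes the lexicographically
        smaller set becomes A; other modes are inherently ordered."""
        if mode in UNDIRECTED_MODES:
            ka = tuple(sorted(self.a_nodes, key=_sort_key))
            kb = tuple(sorted(self.b_nodes, key=_sort_key))
            if kb < ka:
                return PowerComponent(self.b_nodes, self.a_nodes, self.delta_i)
        return self

    def __repr__(self) -> str:
        di = f", delta_i={self.delta_i:.3f}" if self.delta_i is not None else ""
        return (
            f"PowerComponent(A={sorted(self.a_nodes, key=_sort_key)!r}, "
            f"B={sorted(self.b_nodes, key=_sort_key)!r}{di})"
        )


def component_edges(graph: NetworkGraph, component: PowerComponent) -> frozenset:
    """The set of canonical edges a component's poweredge asserts.

    Directed: all a -> b pairs (the diagonal a==a only when self-loops are
    enabled).  Undirected: all unordered {a, b} pairs with a != b, plus
    self-loops on A∩B nodes when the mode permits them — pairs inside the
    overlap are counted once.  Bipartite: all left-right pairs.
    """
    a, b = component.a_nodes, component.b_nodes
    mode = graph.mode
    out = set()
    if mode == "directed":
        for u in a:
            for v in b:
                if u == v and not graph.allow_self:
                    continue
                out.add((u, v))
    elif mode == "bipartite":
        pa = {graph.parts[n] for n in a}
        pb = {graph.parts[n] for n in b}
        if len(pa) > 1 or len(pb) > 1 or (pa and pb and pa == pb):
            raise ContractError(
                "bipartite component sides must lie in opposite parts"
            )
        for u in a:
            for v in b:
                out.add(graph.canonical_edge(u, v))
    else:
        for u in a:
            for v in b:
                if u == v:
                    if graph.allow_self:
                        out.add((u, u))
                    continue
                out.add(graph.canonical_edge(u, v))
    return frozenset(out)


def check_completeness(graph: NetworkGraph, component: PowerComponent) -> frozenset:
    """Verify the component is a complete biclique in ``graph``.

    Returns the component's edge set; raises :class:`ContractError` if any
    required edge is missing (compression must stay lossless).
    """
    unknown = (component.a_nodes | component.b_nodes) - set(graph.index)
    if unknown:
        raise ContractError(f"component references unknown nodes {sorted(unknown, key=_sort_key)[:5]}")
    edges = component_edges(graph, component)
    missing = edges - graph.edges
    if missing:
        raise ContractError(
            f"component is not complete: {len(missing)} required edge(s) absent, "
            f"e.g. {sorted(missing, key=lambda e: tuple(map(_sort_key, e)))[:3]}"
        )
    return edges


@dataclass(frozen=True)
class ComponentDecomposition:
    """A graph decomposed into selected components, overlap V, remainder R.

    The decomposition satisfies, per node pair, ``m = c + r - v`` where
    ``m`` is the adjacency indicator, ``c`` the number of selected
    components covering the pair, ``v = max(c - 1, 0)`` the overlap count
    and ``r`` the remainder indicator (edges covered by no component).
    Reconstruction is therefore lossless by construction.
    """

    graph: NetworkGraph
    selected: tuple  # ordered PowerComponents (set S)
    overlap: Mapping[Edge, int]  # V: only strictly positive entries
    remainder: frozenset  # R: edges not covered by any component
    delta_i_total: float
    gains: tuple = ()  # delta_i_total after each successive selection

    @property
    def n_components(self) -> int:
        return len(self.selected)

    @property
    def total_overlap(self) -> int:
        return sum(self.overlap.values())


def decompose(graph: NetworkGraph, selected: Iterable[PowerComponent]) -> ComponentDecomposition:
    """Decompose ``graph`` over an ordered component selection.

    Every component must be complete on the graph.  The same component may
    appear more than once; repeats only inflate the overlap matrix.
    """
    from .compression import total_compression_parts

    selected = tuple(c.canonical(graph.mode) for c in selected)
    cover: dict[Edge, int] = {}
    for comp in selected:
        for e in check_completeness(graph, comp):
            cover[e] = cover.get(e, 0) + 1
    overlap = {e: c - 1 for e, c in cover.items() if c > 1}
    remainder = frozenset(graph.edges - cover.keys())
    delta = total_compression_parts(graph, selected, remainder)
    return ComponentDecomposition(graph, selected, overlap, remainder, delta)


def reconstruct(decomposition: ComponentDecomposition, graph: NetworkGraph | None = None) -> frozenset:
    """Rebuild the original edge set from a decomposition (lossless check).

    The result is the union of all component-covered pairs and the
    remainder R; for a valid decomposition it equals the input edge set.
    """
    g = graph if graph is not None else decomposition.graph
    edges = set(decomposition.remainder)
    for comp in decomposition.selected:
        edges |= component_edges(g, comp)
    return frozenset(edges)
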