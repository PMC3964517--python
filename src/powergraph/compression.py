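"""Information-cost arithmetic for power graph compression.

Every identifier (a node or a power node) costs log2(N) bits, where N is
the number of nodes in the graph being compressed; with at most N power
nodes this bounds the true per-power-node cost.  A raw edge costs two
identifiers; a poweredge costs one identifier per member node plus two for
the power nodes themselves.  All costs below are an integer coefficient
times log2(N), and the coefficient is computed in exact integer
arithmetic, so identities between cost expressions hold to the last bit of
the float.

The per-component gain of encoding the complete biclique (A, B) as one
poweredge is

    delta_i = [2 e(A, B) - n_A - n_B - 2] * log2(N)

where e(A, B) is the number of distinct edges the poweredge asserts:
n_A*n_B in directed/bipartite graphs, minus n_AB in directed graphs
without self-loops, and n_A*n_B - n_AB*(n_AB -/+ 1)/2 in undirected
graphs with/without self-loops (the correction removes double-counted
unordered pairs, and self-pairs when those are disallowed).
"""

from __future__ import annotations

import math
from typing import Iterable

from .core import (
    ContractError,
    InputError,
    ComponentDecomposition,
    NetworkGraph,
    PowerComponent,
    UNDIRECTED_MODES,
)

__all__ = [
    "pair_count",
    "power_cost",
    "edge_cost",
    "delta_i",
    "delta_i_coefficient",
    "total_compression",
    "edge_removal_repair_cost",
]

#: Minimum improvement (bits) for a greedy step to count as an increase.
IMPROVEMENT_TOLERANCE = 1e-9


def _check_sizes(n_a: int, n_b: int, n_ab: int, N: int) -> None:
    if N < 2:
        raise InputError(f"N must be >= 2 for log2 identifier costs, got {N}")
    if not (1 <= n_a <= N and 1 <= n_b <= N):
        raise InputError(f"power node sizes out of range: n_a={n_a}, n_b={n_b}, N={N}")
    if not (0 <= n_ab <= min(n_a, n_b)):
        raise InputError(f"inconsistent overlap n_ab={n_ab} for n_a={n_a}, n_b={n_b}")


def pair_count(n_a: int, n_b: int, n_ab: int, mode: str, allow_self: bool = True) -> int:
    """Number of distinct edges asserted by a poweredge between sides of
    sizes ``n_a`` and ``n_b`` overlapping in ``n_ab`` nodes."""
    if mode == "directed":
        return n_a * n_b - (0 if allow_self else n_ab)
    if mode == "bipartite":
        if n_ab:
            raise InputError("bipartite power nodes cannot overlap across parts")
        return n_a * n_b
    if mode == "undirected_self":
        return n_a * n_b - n_ab * (n_ab - 1) // 2
    if mode == "undirected_noself":
        return n_a * n_b - n_ab * (n_ab + 1) // 2
    raise InputError(f"unknown mode {mode!r}")


def power_cost(n_a: int, n_b: int, N: int) -> float:
    """Bits to describe a poweredge: one log2(N) identifier per member node
    plus two for the power nodes themselves."""
    _check_sizes(n_a, n_b, 0, N)
    return (n_a + n_b + 2) * math.log2(N)


def edge_cost(
    n_a: int, n_b: int, n_ab: int, N: int, mode: str, allow_self: bool = True
) -> float:
    """Bits to list every edge of the (A, B) biclique individually
    (two identifiers per edge)."""
    _check_sizes(n_a, n_b, n_ab, N)
    return 2 * pair_count(n_a, n_b, n_ab, mode, allow_self) * math.log2(N)


def delta_i_coefficient(
    n_a: int, n_b: int, n_ab: int, mode: str, allow_self: bool = True
) -> int:
    """Integer coefficient c such that delta_i = c * log2(N)."""
    return 2 * pair_count(n_a, n_b, n_ab, mode, allow_self) - n_a - n_b - 2


def delta_i(
    component: PowerComponent,
    N: int,
    mode: str,
    allow_self: bool = True,
    graph: NetworkGraph | None = None,
) -> float:
    """Compression gain (bits, signed) of one component.

    If ``graph`` is given, completeness is verified first; gains are
    meaningful only for complete bicliques.
    """
    if graph is not None:
        from .core import check_completeness

        check_completeness(graph, component)
    _check_sizes(component.n_a, component.n_b, component.n_ab, N)
    coeff = delta_i_coefficient(component.n_a, component.n_b, component.n_ab, mode, allow_self)
    return coeff * math.log2(N)


def total_compression_parts(
    graph: NetworkGraph, selected: Iterable[PowerComponent], remainder: frozenset
) -> float:
    """First-principles total gain: raw edge-list cost minus the cost of
    the compressed description (poweredges plus remainder edge list).

    raw        = 2 |E| log2(N)
    compressed = sum_k (n_A + n_B + 2) log2(N)  +  2 |R| log2(N)
    """
    N = graph.n_nodes
    if N < 2:
        return 0.0
    coeff = 2 * graph.n_edges - 2 * len(remainder)
    for comp in selected:
        coeff -= comp.n_a + comp.n_b + 2
    return coeff * math.log2(N)


def total_compression(decomposition: ComponentDecomposition, graph: NetworkGraph | None = None) -> float:
    """Total compression gain of a decomposition, in bits.

    Computed from first principles (description-length difference), never
    via the per-component-sum-minus-overlap-penalty shortcut; the shortcut
    ``sum_k delta_i_k - 2 log2(N) sum_ij v_ij`` is an identity of this
    quantity and is exercised in the test suite.
    """
    g = graph if graph is not None else decomposition.graph
    for comp in decomposition.selected:
        from .core import check_completeness

        check_completeness(g, comp)
    return total_compression_parts(g, decomposition.selected, decomposition.remainder)


def edge_removal_repair_cost(n_a: int, n_b: int, N: int) -> float:
    """Approximate drop in a component's gain if one of its edges is
    removed: the cheapest repair evicts one node from the smaller side and
    re-encodes its min(n_A, n_B) - 1 surviving edges individually, costing
    about ``2 log2(N) (min(n_A, n_B) - 1)`` bits.  Small when the sides are
    very unequal, which is why component rankings are robust to single-edge
    perturbations."""
    if N < 2:
        raise InputError(f"N must be >= 2, got {N}")
    if n_a < 1 or n_b < 1:
        raise InputError("power node sizes must be >= 1")
    return 2 * math.log2(N) * (min(n_a, n_b) - 1)
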