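"""Candidate enumeration and greedy selection of compressible components.

Enumeration grows A-sets along the graph's stable node order: every node
pair sharing at least two neighbors is stored, each stored set is extended
with single nodes further on in the iteration sequence while the common
neighborhood keeps at least two members, and each stored set A is emitted
as the candidate (A, B) with B its full common neighborhood.  Because the
common neighborhood of a subset contains that of its superset, this
apriori-style growth enumerates exactly the A-sets whose common
neighborhood has >= 2 members.  In directed graphs both orientations are
enumerated (common out-neighbors give A -> B, common in-neighbors B -> A).

Pair-seeded growth can never emit a component whose A side is a single
node, yet a hub with >= 4 leaves is itself compressible (a star (1, k) has
gain (k - 3) log2 N).  ``include_stars`` therefore additionally seeds
single-node candidates from every node of degree >= 4; it is on by
default and switchable off to obtain the strict pair-seeded enumeration.

Selection is greedy on the total gain: the first pick maximises the
per-component gain, every later pick maximises the joint total, and the
procedure stops when no candidate improves the total.  The marginal gain
of a candidate given the already-covered edge set C is exact:

    marginal = [2 |edges(c) \\ C| - n_A - n_B - 2] * log2(N)

since only newly covered edges leave the remainder.  Coefficients are
integers, so ties are exact and the tie rule (more new edges first, then
lexicographically smallest (A, B)) is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .compression import (
    IMPROVEMENT_TOLERANCE,
    delta_i_coefficient,
    total_compression_parts,
)
from .core import (
    ComponentDecomposition,
    NetworkGraph,
    PowerComponent,
    component_edges,
)
import math

__all__ = [
    "CandidateList",
    "common_neighborhood",
    "enumerate_candidates",
    "greedy_select",
    "compress",
]

logger = logging.getLogger(__name__)

#: Default cap on the number of stored candidates.
DEFAULT_CANDIDATE_CAP = 10**6


@dataclass(frozen=True)
class CandidateList:
    """Candidates in discovery order; ``len(candidates)`` is the count M
    of enumerated compressible components."""

    candidates: tuple
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)


def common_neighborhood(graph: NetworkGraph, node_set: Iterable, direction: str = "out") -> frozenset:
    """Intersection of the neighborhoods of all nodes in ``node_set``.

    ``direction`` is ``out`` or ``in`` for directed graphs and ignored
    otherwise; in bipartite graphs the result lies in the opposite part.
    """
    nodes = list(node_set)
    if not nodes:
        raise ValueError("node_set must be non-empty")
    common = graph.neighbors(nodes[0], direction)
    for n in nodes[1:]:
        if not common:
            break
        common = common & graph.neighbors(n, direction)
    return common


def _directions(graph: NetworkGraph) -> tuple:
    return ("out", "in") if graph.mode == "directed" else ("out",)


def _oriented(a: frozenset, b: frozenset, direction: str) -> tuple:
    # 'in'-direction growth finds B -> A components: the common
    # in-neighborhood is the source side.
    return (b, a) if direction == "in" else (a, b)


def enumerate_candidates(
    graph: NetworkGraph,
    max_a_size: int | None = None,
    include_stars: bool = True,
    min_common: int = 2,
    max_candidates: int = DEFAULT_CANDIDATE_CAP,
) -> CandidateList:
    """Enumerate candidate compressible components of ``graph``.

    Parameters
    ----------
    max_a_size:
        Optional cap on the size of grown A-sets (None = unbounded).
    include_stars:
        Also emit ({v}, neighbors(v)) for every node of degree >= 4.
    min_common:
        Minimum common-neighborhood size for a grown set to be stored.
    max_candidates:
        Hard cap on stored candidates; exceeding it logs a warning and
        truncates the enumeration.
    """
    N = graph.n_nodes
    if N < 2:
        return CandidateList(())
    log2N = math.log2(N)
    order = graph.nodes
    n = len(order)
    seen_keys: set = set()
    out: list[PowerComponent] = []
    truncated = False

    def emit(a: frozenset, b: frozenset, direction: str) -> bool:
        """Store the candidate; returns False when the cap is hit."""
        src, dst = _oriented(a, b, direction)
        comp = PowerComponent(src, dst).canonical(graph.mode)
        key = (comp.a_nodes, comp.b_nodes)
        if key in seen_keys:
            return True
        seen_keys.add(key)
        coeff = delta_i_coefficient(
            comp.n_a, comp.n_b, comp.n_ab, graph.mode, graph.allow_self
        )
        out.append(PowerComponent(comp.a_nodes, comp.b_nodes, coeff * log2N))
        return len(out) < max_candidates

    for direction in _directions(graph):
        if truncated:
            break
        if include_stars:
            for v in order:
                nbrs = graph.neighbors(v, direction) - {v} if not graph.allow_self else graph.neighbors(v, direction)
                if len(nbrs) >= 4:
                    if not emit(frozenset({v}), nbrs, direction):
                        truncated = True
                        break
        if truncated:
            break
        # Seed: node pairs (in stable order) sharing >= min_common neighbors.
        frontier: list[tuple] = []  # (a_indices sorted tuple, common set)
        for i in range(n):
            ni = graph.neighbors(order[i], direction)
            if len(ni) < min_common:
                continue
            for j in range(i + 1, n):
                common = ni & graph.neighbors(order[j], direction)
                if len(common) >= min_common:
                    frontier.append(((i, j), common))
                    if not emit(frozenset((order[i], order[j])), common, direction):
                        truncated = True
                        break
            if truncated:
                break
        # Growth: extend each stored set with nodes further on in the
        # iteration sequence while the common neighborhood stays large.
        while frontier and not truncated:
            if max_a_size is not None and len(frontier[0][0]) >= max_a_size:
                break
            nxt: list[tuple] = []
            for idxs, common in frontier:
                for t in range(idxs[-1] + 1, n):
                    new_common = common & graph.neighbors(order[t], direction)
                    if len(new_common) >= min_common:
                        new_idxs = idxs + (t,)
                        nxt.append((new_idxs, new_common))
                        if not emit(frozenset(order[i] for i in new_idxs), new_common, direction):
                            truncated = True
                            break
                if truncated:
                    break
            frontier = nxt

    if truncated:
        logger.warning(
            "candidate enumeration truncated at %d candidates; "
            "consider max_a_size or a larger max_candidates", max_candidates,
        )
    logger.info("enumerated %d candidate components (M)", len(out))
    return CandidateList(tuple(out), truncated)


def greedy_select(
    candidates: CandidateList | Sequence[PowerComponent],
    graph: NetworkGraph,
    tolerance: float = IMPROVEMENT_TOLERANCE,
    max_components: int | None = None,
) -> ComponentDecomposition:
    """Greedily select components to maximise the total compression.

    Each round picks the candidate with the largest exact marginal gain;
    the first round therefore picks the largest per-component gain.  Stops
    when the best marginal improvement does not exceed ``tolerance`` bits
    (or after ``max_components`` picks).  Ties prefer the candidate
    covering more not-yet-covered edges, then the lexicographically
    smallest (A, B).
    """
    N = graph.n_nodes
    log2N = math.log2(N) if N >= 2 else 0.0
    pool = [c.canonical(graph.mode) for c in candidates]
    edge_sets = [component_edges(graph, c) for c in pool]
    for c, es in zip(pool, edge_sets):
        missing = es - graph.edges
        if missing:
            raise ValueError(f"candidate {c!r} is not complete on the graph")

    covered: set = set()
    selected: list[PowerComponent] = []
    gains: list[float] = []
    total_coeff = 0
    active = list(range(len(pool)))
    while active and (max_components is None or len(selected) < max_components):
        best_key = None
        tied: list[int] = []
        for i in active:
            c = pool[i]
            new_edges = len(edge_sets[i] - covered)
            key = (2 * new_edges - c.n_a - c.n_b - 2, new_edges)
            if best_key is None or key > best_key:
                best_key = key
                tied = [i]
            elif key == best_key:
                tied.append(i)
        coeff = best_key[0]
        if coeff * log2N <= tolerance:
            break
        i = min(tied, key=lambda j: pool[j].sort_key())
        comp = pool[i]
        selected.append(comp)
        covered |= edge_sets[i]
        total_coeff += coeff
        gains.append(total_coeff * log2N)
        active.remove(i)

    remainder = frozenset(graph.edges - covered)
    cover_count: dict = {}
    for comp in selected:
        for e in component_edges(graph, comp):
            cover_count[e] = cover_count.get(e, 0) + 1
    overlap = {e: c - 1 for e, c in cover_count.items() if c > 1}
    delta_total = total_compression_parts(graph, selected, remainder)
    logger.info(
        "greedy selected %d components, delta_i_total = %.3f bits",
        len(selected), delta_total,
    )
    return ComponentDecomposition(
        graph, tuple(selected), overlap, remainder, delta_total, tuple(gains)
    )


def compress(
    graph: NetworkGraph,
    max_a_size: int | None = None,
    include_stars: bool = True,
    tolerance: float = IMPROVEMENT_TOLERANCE,
    max_candidates: int = DEFAULT_CANDIDATE_CAP,
    max_components: int | None = None,
) -> ComponentDecomposition:
    """Enumerate candidates and greedily compress ``graph`` in one call."""
    cands = enumerate_candidates(
        graph,
        max_a_size=max_a_size,
        include_stars=include_stars,
        max_candidates=max_candidates,
    )
    return greedy_select(cands, graph, tolerance=tolerance, max_components=max_components)
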