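"""Shared fixtures: random graph/component generators and an independent
description-length oracle used to cross-check the compression arithmetic."""

from __future__ import annotations

import math
import random

import pytest
from hypothesis import settings

from powergraph import (
    AttributeTable,
    NetworkGraph,
    PowerComponent,
    common_neighborhood,
    karate_fixture,
    validate_graph,
)

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def karate() -> tuple[NetworkGraph, AttributeTable]:
    return karate_fixture()


# ---------------------------------------------------------------------------
# Random instance generators (plain seeded random, used by property loops)
# ---------------------------------------------------------------------------

ALL_MODES = ("directed", "undirected_self", "undirected_noself", "bipartite")


def random_graph(rng: random.Random, max_n: int = 12, mode: str | None = None) -> NetworkGraph:
    """A random validated graph of 2..max_n nodes in a random mode."""
    mode = mode or rng.choice(ALL_MODES)
    n = rng.randint(2, max_n)
    nodes = [f"v{i}" for i in range(n)]
    p = rng.uniform(0.1, 0.6)
    edges = []
    parts = None
    if mode == "bipartite":
        cut = rng.randint(1, n - 1)
        parts = {v: (0 if i < cut else 1) for i, v in enumerate(nodes)}
        for u in nodes[:cut]:
            for v in nodes[cut:]:
                if rng.random() < p:
                    edges.append((u, v))
    elif mode == "directed":
        allow_self = rng.random() < 0.3
        for u in nodes:
            for v in nodes:
                if u == v and not allow_self:
                    continue
                if rng.random() < p:
                    edges.append((u, v))
    else:
        for i, u in enumerate(nodes):
            lo = i if mode == "undirected_self" else i + 1
            for v in nodes[lo:]:
                if rng.random() < p:
                    edges.append((u, v))
    return validate_graph(nodes, edges, mode, parts=parts)


def random_valid_components(
    rng: random.Random, graph: NetworkGraph, max_k: int = 4
) -> list[PowerComponent]:
    """Random complete components: A sampled, B a non-empty subset of A's
    common neighborhood (always complete by construction).  May contain
    repeats, exercising the overlap matrix."""
    comps: list[PowerComponent] = []
    if graph.n_edges == 0:
        return comps
    nodes = list(graph.nodes)
    if graph.mode == "bipartite":
        sides = [
            [n for n in nodes if graph.parts[n] == 0],
            [n for n in nodes if graph.parts[n] == 1],
        ]
    for _ in range(rng.randint(0, max_k)):
        direction = rng.choice(("out", "in")) if graph.mode == "directed" else "out"
        if graph.mode == "bipartite":
            side = sides[rng.randrange(2)]
            if not side:
                continue
            pool = side
        else:
            pool = nodes
        a = frozenset(rng.sample(pool, rng.randint(1, min(3, len(pool)))))
        b_full = common_neighborhood(graph, a, direction)
        if not b_full:
            continue
        b = frozenset(rng.sample(sorted(b_full), rng.randint(1, len(b_full))))
        comp = (
            PowerComponent(b, a) if direction == "in" else PowerComponent(a, b)
        ).canonical(graph.mode)
        comps.append(comp)
        if comps and rng.random() < 0.2:  # duplicate to exercise V
            comps.append(comps[rng.randrange(len(comps))])
    return comps


# ---------------------------------------------------------------------------
# Independent description-length oracle
# ---------------------------------------------------------------------------


def oracle_required_pairs(graph: NetworkGraph, comp: PowerComponent) -> set:
    """Edges a poweredge asserts, derived directly from the mode's rules
    (independent of powergraph.core.component_edges)."""
    req = set()
    for a in comp.a_nodes:
        for b in comp.b_nodes:
            if graph.mode == "directed":
                if a == b and not graph.allow_self:
                    continue
                req.add((a, b))
            elif graph.mode == "bipartite":
                req.add((a, b) if graph.parts[a] == 0 else (b, a))
            else:
                if a == b:
                    if graph.mode == "undirected_self":
                        req.add((a, a))
                    continue
                u, v = (a, b) if graph.index[a] <= graph.index[b] else (b, a)
                req.add((u, v))
    return req


def oracle_total_compression_coeff(graph: NetworkGraph, comps) -> int:
    """Brute-force bit accounting, as a multiple of log2(N): literally
    count the identifiers of the raw edge list versus the power-graph
    description (poweredge memberships plus the uncovered edge list)."""
    covered: set = set()
    power_ids = 0
    for comp in comps:
        power_ids += len(comp.a_nodes) + len(comp.b_nodes) + 2
        covered |= oracle_required_pairs(graph, comp)
    uncovered = len(set(graph.edges) - covered)
    raw_ids = 2 * len(graph.edges)
    return raw_ids - (power_ids + 2 * uncovered)


def oracle_total_compression_bits(graph: NetworkGraph, comps) -> float:
    return oracle_total_compression_coeff(graph, comps) * math.log2(graph.n_nodes)
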