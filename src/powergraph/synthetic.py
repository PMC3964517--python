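"""Synthetic graphs with known ground truth, and the packaged karate club.

The planted-power-graph generator embeds known complete bicliques (with
optional node sharing between consecutive components, so power nodes can
overlap arbitrarily) in a background of Bernoulli noise edges; noise is
additive only and never lands on a planted pair, so the planted components
remain exactly recoverable.  The bipartite block generator emulates a
recipe-ingredient-like network in which left nodes carry block labels as
classification terms.  The Zachary karate club (34 members, 78 ties, two
post-split factions) is vendored as a plain-text fixture.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

from .core import InputError, NetworkGraph, PowerComponent, validate_graph
from .enrichment import AttributeTable

__all__ = [
    "PlantedComponentSpec",
    "PlantedSpec",
    "generate_planted_power_graph",
    "generate_bipartite_blocks",
    "karate_fixture",
]


@dataclass(frozen=True)
class PlantedComponentSpec:
    """One planted complete biclique.

    ``a_overlap_prev`` / ``b_overlap_prev`` request that many nodes of
    this component's A / B side be reused from the previous component's
    node pool (its A ∪ B), producing overlapping power nodes.
    """

    a_size: int
    b_size: int
    a_overlap_prev: int = 0
    b_overlap_prev: int = 0


@dataclass(frozen=True)
class PlantedSpec:
    """Recipe for a planted power graph."""

    n_nodes: int
    components: tuple  # of PlantedComponentSpec
    noise_p: float = 0.0
    mode: str = "undirected_noself"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.noise_p < 1.0):
            raise InputError(f"noise_p must be in [0, 1), got {self.noise_p}")
        comps = tuple(
            c if isinstance(c, PlantedComponentSpec) else PlantedComponentSpec(*c)
            for c in self.components
        )
        object.__setattr__(self, "components", comps)


def generate_planted_power_graph(spec: PlantedSpec) -> tuple[NetworkGraph, tuple]:
    """Generate a graph with planted complete bicliques plus noise.

    Returns the graph and the ground-truth components (canonical form,
    without gain values).  Noise edges are Bernoulli(noise_p) on node
    pairs not asserted by any planted component.
    """
    rng = random.Random(spec.seed)
    nodes = [f"n{i}" for i in range(spec.n_nodes)]
    used = 0
    prev_pool: list = []
    truth: list[PowerComponent] = []
    planted_edges: set = set()

    def fresh(count: int) -> list:
        nonlocal used
        if used + count > spec.n_nodes:
            raise InputError(
                f"planted components need more than n_nodes={spec.n_nodes} nodes"
            )
        out = nodes[used : used + count]
        used += count
        return out

    for cs in spec.components:
        if cs.a_overlap_prev + cs.b_overlap_prev > len(prev_pool):
            raise InputError(
                "overlap request exceeds the previous component's node pool"
            )
        reused = prev_pool[: cs.a_overlap_prev + cs.b_overlap_prev]
        a = reused[: cs.a_overlap_prev] + fresh(cs.a_size - cs.a_overlap_prev)
        b = reused[cs.a_overlap_prev :] + fresh(cs.b_size - cs.b_overlap_prev)
        if set(a) & set(b):
            raise InputError("planted A and B sides must be disjoint")
        truth.append(PowerComponent(frozenset(a), frozenset(b)))
        for u in a:
            for v in b:
                planted_edges.add((u, v))
        prev_pool = a + b

    graph_tmp = validate_graph(nodes, planted_edges, spec.mode)
    planted_canonical = set(graph_tmp.edges)

    edges = set(planted_edges)
    idx = {n: i for i, n in enumerate(nodes)}
    n = spec.n_nodes
    if spec.noise_p > 0:
        for i in range(n):
            js = range(n) if spec.mode == "directed" else range(i + 1, n)
            for j in js:
                if i == j:
                    continue
                e = (nodes[i], nodes[j])
                if e in planted_canonical or (nodes[j], nodes[i]) in planted_canonical:
                    continue
                if spec.mode == "directed" and e in edges:
                    continue
                if rng.random() < spec.noise_p:
                    edges.add(e)

    graph = validate_graph(nodes, edges, spec.mode)
    truth = tuple(c.canonical(spec.mode) for c in truth)
    return graph, truth


def generate_bipartite_blocks(
    n_left: int,
    n_right: int,
    n_blocks: int,
    within_p: float,
    between_p: float,
    seed: int = 0,
) -> tuple[NetworkGraph, AttributeTable]:
    """Bipartite block benchmark (recipe-ingredient-like).

    Left nodes ("recipes") and right nodes ("ingredients") are assigned to
    ``n_blocks`` blocks round-robin; a left-right edge appears with
    probability ``within_p`` inside a block and ``between_p`` across
    blocks.  Left nodes carry their block label as a classification term.
    """
    if not (0 <= within_p <= 1 and 0 <= between_p <= 1):
        raise InputError("probabilities must lie in [0, 1]")
    if n_blocks < 1 or n_left < 1 or n_right < 1:
        raise InputError("sizes must be >= 1")
    rng = random.Random(seed)
    left = [f"L{i}" for i in range(n_left)]
    right = [f"R{i}" for i in range(n_right)]
    block_of = {n: i % n_blocks for i, n in enumerate(left)}
    block_of.update({n: i % n_blocks for i, n in enumerate(right)})
    edges = set()
    for u in left:
        for v in right:
            p = within_p if block_of[u] == block_of[v] else between_p
            if rng.random() < p:
                edges.add((u, v))
    parts = {n: 0 for n in left}
    parts.update({n: 1 for n in right})
    graph = validate_graph(left + right, edges, "bipartite", parts=parts)
    table = AttributeTable.from_pairs((n, f"block{block_of[n]}") for n in left)
    return graph, table


def _data_lines(name: str):
    text = resources.files("powergraph.data").joinpath(name).read_text()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            yield line.split("\t")


def karate_fixture() -> tuple[NetworkGraph, AttributeTable]:
    """The Zachary karate club network and its two-faction labels.

    34 members, 78 undirected friendship ties, no self-loops.  Node labels
    are the strings "1".."34"; node 1 is the club instructor and node 34
    the president, the leaders of the two factions the club split into.
    """
    edges = [(u, v) for u, v in _data_lines("karate_edges.tsv")]
    order: list = []
    seen = set()
    for u, v in edges:
        for n in (u, v):
            if n not in seen:
                seen.add(n)
                order.append(n)
    graph = validate_graph(order, edges, "undirected_noself")
    table = AttributeTable.from_pairs(
        (node, term) for node, term in _data_lines("karate_factions.tsv")
    )
    return graph, table
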