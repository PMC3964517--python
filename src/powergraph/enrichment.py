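"""Term enrichment of power nodes (hypergeometric over-representation).

Given a table assigning classification terms to nodes, a power node (a
set of s nodes) is labelled with the terms that occur in it more often
than expected by chance.  A term carried by n_i of the N nodes appears k
times in a random s-set with hypergeometric probability

    P(k) = C(n_i, k) C(N - n_i, s - k) / C(N, s).

The p-value of an observed count k* sums P(k) over every k that is as
likely or less likely than k* — a two-sided, tie-sensitive definition, so
all probability comparisons are done in exact integer arithmetic (the
binomial numerators share the denominator C(N, s)).  Testing T distinct
terms multiplies each p-value by T (Bonferroni), capped at 1.  When term
assignments are correlated across terms, an alternative correction
randomizes the node-term membership network preserving both node and term
degrees and reports an empirical tail probability.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Hashable, Iterable, Mapping

from .core import InputError

__all__ = [
    "AttributeTable",
    "EnrichmentResult",
    "hypergeom_pmf",
    "enrichment_pvalue",
    "bonferroni_correct",
    "enrich_power_node",
    "randomized_corrected_pvalue",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AttributeTable:
    """Node -> set-of-terms assignments with global term counts."""

    assignments: Mapping[Hashable, frozenset]
    term_counts: Mapping[Hashable, int]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "AttributeTable":
        """Build from (node, term) rows; multiple rows per node allowed."""
        assignments: dict = {}
        for node, term in pairs:
            assignments.setdefault(node, set()).add(term)
        counts: dict = {}
        for terms in assignments.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        if not counts:
            raise InputError("attribute table is empty")
        return cls(
            {n: frozenset(t) for n, t in assignments.items()},
            dict(counts),
        )

    @property
    def n_terms(self) -> int:
        """T, the number of distinct terms (hypotheses tested)."""
        return len(self.term_counts)

    def terms_of(self, node: Hashable) -> frozenset:
        return self.assignments.get(node, frozenset())


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of one term in one power node of size s."""

    power_node: frozenset
    term: Hashable
    k_star: int  # observed count of the term in the power node
    n_i: int  # global count of the term
    s: int  # power node size
    p_raw: float
    p_bonferroni: float


def _check_args(k: int, n_i: int, s: int, N: int) -> None:
    if N < 1 or not (0 <= n_i <= N) or not (0 <= s <= N) or not (0 <= k <= s):
        raise InputError(
            f"invalid hypergeometric arguments k={k}, n_i={n_i}, s={s}, N={N}"
        )


def _numerators(n_i: int, s: int, N: int) -> list[int]:
    # Numerator of P(k) over the common denominator C(N, s); impossible k
    # give comb() == 0.
    return [comb(n_i, k) * comb(N - n_i, s - k) for k in range(s + 1)]


def hypergeom_pmf(k: int, n_i: int, s: int, N: int) -> float:
    """Exact hypergeometric probability of drawing k term-carriers in an
    s-set, computed in integer arithmetic and converted to float last."""
    _check_args(k, n_i, s, N)
    return float(Fraction(comb(n_i, k) * comb(N - n_i, s - k), comb(N, s)))


def enrichment_pvalue_exact(k_star: int, n_i: int, s: int, N: int) -> Fraction:
    """Exact rational p-value: total probability of all counts k that are
    as likely or less likely than k*."""
    _check_args(k_star, n_i, s, N)
    nums = _numerators(n_i, s, N)
    threshold = nums[k_star]
    if threshold == 0:
        # k* itself is impossible; every possible k is "more likely".
        return Fraction(0) if any(nums) else Fraction(1)
    total = sum(x for x in nums if 0 < x <= threshold)
    return Fraction(total, comb(N, s))


def enrichment_pvalue(k_star: int, n_i: int, s: int, N: int) -> float:
    """Two-sided hypergeometric p-value ("as likely or less likely" than
    the observed count), with exact-integer tie handling."""
    p = enrichment_pvalue_exact(k_star, n_i, s, N)
    return float(p) if p > 0 else 0.0


def bonferroni_correct(p_raw: float, T: int) -> float:
    """Multiply by the number of hypotheses T, capped at 1."""
    if T < 1:
        raise InputError(f"T must be >= 1, got {T}")
    return min(1.0, T * p_raw)


def enrich_power_node(
    node_set: Iterable, table: AttributeTable, N: int
) -> list[EnrichmentResult]:
    """Enrichment of every term observed in ``node_set`` (k* >= 1),
    sorted by corrected p-value; T is the table's distinct-term count."""
    nodes = frozenset(node_set)
    s = len(nodes)
    if s > N:
        raise InputError(f"power node of size {s} exceeds N={N}")
    T = table.n_terms
    counts: dict = {}
    for n in nodes:
        for t in table.terms_of(n):
            counts[t] = counts.get(t, 0) + 1
    results = []
    for term, k in counts.items():
        n_i = table.term_counts[term]
        p = enrichment_pvalue(k, n_i, s, N)
        results.append(
            EnrichmentResult(nodes, term, k, n_i, s, p, bonferroni_correct(p, T))
        )
    # the two-sided p-value ties over- and under-representation of a
    # balanced term; rank over-represented terms (k* above expectation)
    # first so the top hit labels what the power node is made of
    results.sort(
        key=lambda r: (r.p_bonferroni, r.p_raw, r.k_star * N <= r.n_i * r.s, str(r.term))
    )
    return results


def _membership_edges(table: AttributeTable) -> list[tuple]:
    return [(n, t) for n, terms in sorted(table.assignments.items(), key=lambda kv: str(kv[0])) for t in sorted(terms, key=str)]


def randomized_corrected_pvalue(
    node_set: Iterable,
    table: AttributeTable,
    term: Hashable,
    n_replicates: int = 1000,
    seed: int = 0,
    swap_factor: int = 10,
    max_retry_factor: int = 100,
) -> float:
    """Empirical corrected p-value from degree-preserving randomization of
    the node-term membership network.

    Each replicate rewires the bipartite node-term graph by double-edge
    swaps that preserve every node's term count and every term's node
    count, then records whether the term's count in ``node_set`` reaches
    the observed k*.  Returns (1 + #exceedances) / (1 + n_replicates).
    """
    if n_replicates < 100:
        raise InputError("n_replicates must be >= 100 for a stable estimate")
    if term not in table.term_counts:
        raise InputError(f"unknown term {term!r}")
    nodes = frozenset(node_set)
    k_star = sum(1 for n in nodes if term in table.terms_of(n))
    edges = _membership_edges(table)
    m = len(edges)
    # A complete membership network (every node carries every term) admits
    # no swaps but is also invariant under the null: replicates equal the
    # original and the empirical p-value is 1.
    complete = m == len(table.assignments) * table.n_terms
    rng = random.Random(seed)
    n_swaps = max(1, swap_factor * m)
    exceed = 0
    for _ in range(n_replicates):
        cur = list(edges)
        present = set(cur)
        done = 0
        attempts = 0
        budget = max_retry_factor * n_swaps
        while done < n_swaps and attempts < budget:
            attempts += 1
            i, j = rng.randrange(m), rng.randrange(m)
            if i == j:
                continue
            (n1, t1), (n2, t2) = cur[i], cur[j]
            if t1 == t2 or n1 == n2:
                continue
            e1, e2 = (n1, t2), (n2, t1)
            if e1 in present or e2 in present:
                continue
            present.discard(cur[i])
            present.discard(cur[j])
            present.add(e1)
            present.add(e2)
            cur[i], cur[j] = e1, e2
            done += 1
        if done == 0 and m > 1 and not complete:
            raise InputError(
                "membership network admits no degree-preserving swaps "
                f"(retry budget {budget} exhausted)"
            )
        k = sum(1 for n, t in present if t == term and n in nodes)
        if k >= k_star:
            exceed += 1
    return (1 + exceed) / (1 + n_replicates)
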