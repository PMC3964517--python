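# powergraph

Lossless compression of networks into **power graphs with arbitrarily
overlapping power nodes**, for finding the dominant relationship patterns
in undirected, directed and bipartite networks — with hypergeometric term
enrichment to label the discovered node sets and degree-preserving null
models to show the structure is real.

A *power node* is a set of nodes; a *poweredge* between power nodes A and
B asserts that every node in A links to every node in B (a complete
biclique).  Encoding that biclique as one poweredge instead of listing
its n_A·n_B edges saves

```
ΔI_AB = (2 n_A n_B − n_A − n_B − 2) · log₂N   bits
```

(per-identifier cost log₂N; undirected and overlapping variants subtract
the double-counted pairs n_AB(n_AB ± 1)/2).  Pairs of node sets with
ΔI > 0 are *compressible components*.  The package enumerates candidates
by common-neighborhood growth, greedily selects components to maximise
the total saving ΔI_total (an edge covered twice is only banked once),
and keeps the decomposition lossless: selected poweredges plus the
remainder edge list reconstruct the input exactly.

Unlike modularity-style community detection, components are defined by
*shared relationships to other sets*, not internal density — sets of
predators unified by common prey in a food web, ingredient combinations
shared by a cuisine's recipes, or a faction leader connected to their
followers in a social network.

## Worked example

The packaged benchmark is Zachary's karate club (34 members, 78
friendship ties, split into two factions led by the instructor, node 1,
and the president, node 34):

```python
from powergraph import compress, enrich_power_node, karate_fixture

graph, factions = karate_fixture()
dec = compress(graph)
print(f"{dec.n_components} components, {dec.delta_i_total:.2f} bits saved")
for comp in dec.selected[:2]:
    print(sorted(comp.a_nodes, key=int), "<->", sorted(comp.b_nodes, key=int))
    large = max((comp.a_nodes, comp.b_nodes), key=len)
    top = enrich_power_node(large, factions, graph.n_nodes)[0]
    print(f"  enriched: {top.term} (k={top.k_star}/{top.s}, "
          f"p_bonferroni={top.p_bonferroni:.3g})")
```

prints

```
6 components, 330.69 bits saved
['9', '15', '16', '19', '21', '23', '24', '30', '31', '32'] <-> ['33', '34']
  enriched: President (k=9/10, p_bonferroni=0.0132)
['1', '2'] <-> ['3', '4', '8', '14', '18', '20', '22']
  enriched: Instructor (k=7/7, p_bonferroni=0.0145)
```

The two strongest components are node-disjoint and recover the club's
split — each pairs a faction leader (plus one lieutenant) with members of
their faction, and the faction labels are significantly enriched
(Bonferroni-corrected p < 0.05) in both large power nodes.

The same workflow from the shell:

```
powergraph simulate karate --out karate.tsv
powergraph compress --edges karate.tsv --mode undirected_noself --out karate.json
powergraph enrich --powergraph karate.json --attributes karate.tsv.factions.tsv --out enrichment.tsv
powergraph nullcompare --edges karate.tsv --replicates 100 --seed 1 --out null.tsv
```

`nullcompare` shows the club network saves far more bits than any of its
degree-preserving randomizations — the compressible structure is not a
degree-sequence artifact.

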