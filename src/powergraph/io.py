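"""Reading edge lists and attribute tables; power-graph JSON output.

Edge lists are two-column TSV (``#`` comments allowed); node IDs are
opaque strings and node order is first-appearance order.  Bipartite input
needs either a part-assignment file (node TAB part, with part in {0, 1} or
{left, right}) or ``left:`` / ``right:`` prefixes on the node IDs.  The
power-graph output is a versioned JSON schema: existing power-graph
dialects assume disjoint or nested power nodes, which this method
deliberately generalises, so a dedicated schema is used.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

from .core import (
    ComponentDecomposition,
    InputError,
    NetworkGraph,
    PowerComponent,
    validate_graph,
)
from .enrichment import AttributeTable

__all__ = [
    "read_edge_list",
    "read_part_file",
    "read_attribute_table",
    "write_power_graph",
    "read_power_graph",
    "write_null_comparison",
    "write_enrichment_table",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


def _tsv_rows(path, min_cols: int):
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise InputError(
                    f"{path}:{lineno}: expected >= {min_cols} tab-separated "
                    f"columns, got {len(fields)}: {line!r}"
                )
            rows.append((lineno, fields))
    if not rows:
        raise InputError(f"{path}: no data rows")
    return rows


def read_part_file(path) -> dict:
    """Read a bipartite part assignment: node TAB part per line."""
    names = {"0": 0, "1": 1, "left": 0, "right": 1}
    parts = {}
    for lineno, fields in _tsv_rows(path, 2):
        node, raw = fields[0], fields[1].strip().lower()
        if raw not in names:
            raise InputError(
                f"{path}:{lineno}: part must be 0/1/left/right, got {raw!r}"
            )
        parts[node] = names[raw]
    return parts


def read_edge_list(
    path,
    mode: str,
    parts: Mapping[str, int] | None = None,
    part_file=None,
) -> NetworkGraph:
    """Read a two-column TSV edge list into a validated graph.

    Node order is first-appearance order (this fixes the enumeration's
    iteration sequence).  Duplicate edges are collapsed with a warning.
    In bipartite mode, if neither ``parts`` nor ``part_file`` is given,
    every node ID must carry a ``left:`` or ``right:`` prefix (stripped
    after assignment).
    """
    rows = _tsv_rows(path, 2)
    raw_edges = [(f[0], f[1]) for _, f in rows]

    strip_prefix = False
    if mode == "bipartite" and parts is None:
        if part_file is not None:
            parts = read_part_file(part_file)
        else:
            parts = {}
            for lineno, (u, v) in zip((r[0] for r in rows), raw_edges):
                for n in (u, v):
                    if n.startswith("left:"):
                        parts[n] = 0
                    elif n.startswith("right:"):
                        parts[n] = 1
                    else:
                        raise InputError(
                            f"{path}:{lineno}: bipartite node {n!r} needs a "
                            "left:/right: prefix or a part file"
                        )
            strip_prefix = True
    if strip_prefix:
        raw_edges = [
            (u.split(":", 1)[1], v.split(":", 1)[1]) for u, v in raw_edges
        ]
        parts = {n.split(":", 1)[1]: p for n, p in parts.items()}

    order: list = []
    seen = set()
    for u, v in raw_edges:
        for n in (u, v):
            if n not in seen:
                seen.add(n)
                order.append(n)
    n_dup = len(raw_edges) - len(set(raw_edges))
    if n_dup:
        logger.warning("%s: %d duplicate edge line(s) collapsed", path, n_dup)
    return validate_graph(order, raw_edges, mode, parts=parts)


def read_attribute_table(path, header: bool = False) -> AttributeTable:
    """Read a node-term TSV (two columns, multiple rows per node)."""
    rows = _tsv_rows(path, 2)
    if header:
        rows = rows[1:]
        if not rows:
            raise InputError(f"{path}: no data rows below the header")
    return AttributeTable.from_pairs((f[0], f[1]) for _, f in rows)


def write_power_graph(
    decomposition: ComponentDecomposition,
    path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> None:
    """Serialize a decomposition (with its graph) as versioned JSON."""
    g = decomposition.graph
    doc = {
        "schema_version": SCHEMA_VERSION,
        "mode": g.mode,
        "allow_self": g.allow_self,
        "n_nodes": g.n_nodes,
        "nodes": list(g.nodes),
        "parts": g.parts,
        "edges": sorted(map(list, g.edges)),
        "components": [
            {
                "selection_rank": i + 1,
                "a_nodes": sorted(c.a_nodes, key=str),
                "b_nodes": sorted(c.b_nodes, key=str),
                "delta_i_bits": c.delta_i,
            }
            for i, c in enumerate(decomposition.selected)
        ],
        "remainder_edges": sorted(map(list, decomposition.remainder)),
        "overlap_edges": sorted(
            [list(e) + [v] for e, v in decomposition.overlap.items()]
        ),
        "delta_i_total_bits": decomposition.delta_i_total,
        "gains_bits": list(decomposition.gains),
        "config": dict(config) if config else {},
        "seed": seed,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_power_graph(path) -> ComponentDecomposition:
    """Read power-graph JSON back into a validated decomposition.

    The decomposition is rebuilt (coverage recounted, total recomputed),
    so a successful read re-validates completeness and losslessness."""
    from .core import decompose

    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise InputError(f"unsupported power-graph schema version {version!r}")
    graph = validate_graph(
        doc["nodes"],
        [tuple(e) for e in doc["edges"]],
        doc["mode"],
        parts=doc.get("parts"),
        allow_self=doc.get("allow_self"),
    )
    comps = []
    for c in doc["components"]:
        comps.append(
            PowerComponent(
                frozenset(c["a_nodes"]), frozenset(c["b_nodes"]), c.get("delta_i_bits")
            )
        )
    dec = decompose(graph, comps)
    return ComponentDecomposition(
        graph,
        dec.selected,
        dec.overlap,
        dec.remainder,
        dec.delta_i_total,
        tuple(doc.get("gains_bits", ())),
    )


def write_null_comparison(comparison, tsv_path, json_path=None) -> None:
    """Write the null-comparison summary TSV (and optionally the full
    replicate curves as JSON)."""
    lines = ["component_count\treal\tnull_mean\tnull_sd\tz"]
    for k, real, mean, sd, z in comparison.summary:
        lines.append(f"{k}\t{real:.6f}\t{mean:.6f}\t{sd:.6f}\t{z:.6f}")
    Path(tsv_path).write_text("\n".join(lines) + "\n")
    if json_path is not None:
        doc = {
            "seed": comparison.seed,
            "real": {
                "points": list(map(list, comparison.real.points)),
                "density": comparison.real.density,
                "mean_degree": comparison.real.mean_degree,
            },
            "replicates": [
                {
                    "provenance": c.provenance,
                    "seed": c.seed,
                    "points": list(map(list, c.points)),
                }
                for c in comparison.replicates
            ],
        }
        Path(json_path).write_text(json.dumps(doc, indent=1) + "\n")


def write_enrichment_table(rows, path) -> None:
    """Write enrichment results: one row per (power node, side, term)."""
    lines = ["power_node_id\tside\tterm\tk\ts\tn_i\tp_raw\tp_bonferroni"]
    for rank, side, res in rows:
        lines.append(
            f"{rank}\t{side}\t{res.term}\t{res.k_star}\t{res.s}\t{res.n_i}"
            f"\t{res.p_raw:.6g}\t{res.p_bonferroni:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
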