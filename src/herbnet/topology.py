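"""Node-centrality measures on a protein-interaction graph.

Five measures are computed per node of a simple undirected graph, the panel
commonly used to rank proteins in interaction networks:

DC   degree: number of incident edges.
BC   shortest-path betweenness (Brandes accumulation), unnormalised, each
     unordered pair counted once, endpoints excluded.
CC   closeness with the reachable-set size correction: for a node v that can
     reach r other nodes with total distance S,
     ``cc(v) = (r / S) * (r / (N - 1))``, and 0 for isolated nodes. The
     correction keeps nodes in tiny components from being inflated, which
     matters because the hub screen compares every node against one global
     median.
NC   edge-clustering-coefficient sum: over edges (u, v),
     ``ECC(u, v) = z / min(deg(u) - 1, deg(v) - 1)`` with z the number of
     triangles containing the edge (ECC = 0 when the denominator is <= 0);
     ``nc(v)`` is the sum of ECC over v's edges, so 0 <= nc(v) <= dc(v).
LAC  local average connectivity: the mean degree of v's neighbours inside
     the subgraph induced by those neighbours (0 for isolated nodes).

Degree, betweenness and closeness are delegated to networkx (whose closeness
with ``wf_improved`` is exactly the corrected formula above); NC and LAC are
implemented here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import EmptyGraphError, ParseError

MEASURES = ("dc", "bc", "cc", "nc", "lac")


@dataclass
class CentralityTable:
    """Per-node values of the five measures plus their five medians."""

    values: pd.DataFrame  # index: node symbol; columns: dc, bc, cc, nc, lac
    medians: dict[str, float]  # keyed by measure name

    def __len__(self) -> int:
        return len(self.values)


def load_graph(path: str | Path) -> nx.Graph:
    """Load an undirected simple graph from a TSV edge list or a SIF file.

    TSV rows are ``source<TAB>target`` (extra columns ignored; a header row
    starting with 'source'/'node1' is skipped). SIF rows are
    ``node relation target [target ...]``; a single-field SIF row declares an
    isolated node. Self-loops are dropped, duplicate edges collapsed.
    """
    path = Path(path)
    is_sif = path.suffix.lower() == ".sif"
    g = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            fields = [f.strip() for f in fields if f.strip()]
            if is_sif:
                if len(fields) == 1:
                    g.add_node(fields[0])
                    continue
                if len(fields) == 2:
                    raise ParseError("SIF row with a relation but no target", lineno)
                src, targets = fields[0], fields[2:]
            else:
                if lineno == 1 and fields[0].lower() in {"source", "node1", "from"}:
                    continue
                if len(fields) < 2:
                    raise ParseError("edge row needs at least two columns", lineno)
                src, targets = fields[0], [fields[1]]
            for t in targets:
                if t == src:
                    n_loops += 1
                    g.add_node(src)
                else:
                    g.add_edge(src, t)
    g.graph["n_self_loops_dropped"] = n_loops
    return g


def write_graph(g: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    """Write a graph as SIF (``a pp b`` rows, isolated nodes as bare rows)."""
    lines = []
    for a, b in sorted((min(u, v), max(u, v)) for u, v in g.edges()):
        lines.append(f"{a}\t{relation}\t{b}")
    for v in sorted(g.nodes()):
        if g.degree(v) == 0:
            lines.append(str(v))
    Path(path).write_text("".join(ln + "\n" for ln in lines))


def degree_centrality(g: nx.Graph) -> dict:
    return dict(g.degree())


def betweenness_centrality(g: nx.Graph) -> dict:
    """Unnormalised shortest-path betweenness, each unordered pair once."""
    return nx.betweenness_centrality(g, normalized=False)


def closeness_centrality(g: nx.Graph) -> dict:
    """Reachable-set closeness with the component-size correction (see module docs)."""
    return nx.closeness_centrality(g, wf_improved=True)


def _adjacency(g: nx.Graph) -> dict:
    return {v: set(g[v]) for v in g}


def nc_centrality(g: nx.Graph) -> dict:
    """Sum of edge clustering coefficients over each node's incident edges."""
    adj = _adjacency(g)
    nc = {}
    for v in g:
        nbrs = adj[v]
        total = 0.0
        dv = len(nbrs)
        for u in nbrs:
            den = min(len(adj[u]) - 1, dv - 1)
            if den > 0:
                total += len(adj[u] & nbrs) / den
        nc[v] = total
    return nc


def lac_centrality(g: nx.Graph) -> dict:
    """Average degree of each node's neighbours within the induced neighbour subgraph."""
    adj = _adjacency(g)
    lac = {}
    for v in g:
        nbrs = adj[v]
        if not nbrs:
            lac[v] = 0.0
            continue
        # deg of u inside G[N(v)] is |N(u) ∩ N(v)|
        lac[v] = sum(len(adj[u] & nbrs) for u in nbrs) / len(nbrs)
    return lac


def _median(values) -> float:
    """Even count -> mean of the middle two."""
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return float(s[mid]) if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def centrality_table(g: nx.Graph) -> CentralityTable:
    """All five measures per node plus the five medians over all nodes."""
    if g.number_of_nodes() == 0:
        raise EmptyGraphError("centrality analysis requires a non-empty graph")
    per = {
        "dc": degree_centrality(g),
        "bc": betweenness_centrality(g),
        "cc": closeness_centrality(g),
        "nc": nc_centrality(g),
        "lac": lac_centrality(g),
    }
    nodes = sorted(g.nodes(), key=str)
    df = pd.DataFrame({m: [float(per[m][v]) for v in nodes] for m in MEASURES}, index=nodes)
    df.index.name = "node"
    medians = {m: _median(df[m].tolist()) for m in MEASURES}
    return CentralityTable(values=df, medians=medians)


def write_centrality(ct: CentralityTable, table_path: str | Path, medians_path: str | Path | None = None) -> None:
    ct.values.to_csv(table_path, sep="\t", float_format="%.10g")
    if medians_path is not None:
        Path(medians_path).write_text(json.dumps(ct.medians, sort_keys=True) + "\n")


def read_centrality(path: str | Path) -> CentralityTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [m for m in MEASURES if m not in df.columns]
    if missing:
        raise ParseError(f"centrality table missing columns {missing}")
    medians = {m: _median(df[m].tolist()) for m in MEASURES}
    return CentralityTable(values=df[list(MEASURES)], medians=medians)


def write_graphml(g: nx.Graph, ct: CentralityTable, path: str | Path) -> None:
    """GraphML export with the five centralities attached as node attributes."""
    h = g.copy()
    for m in MEASURES:
        nx.set_node_attributes(h, {v: float(ct.values.at[v, m]) for v in h}, name=m)
    nx.write_graphml(h, path)
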