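"""Median-threshold hub screening.

A node is nominated as a hub when its degree strictly exceeds twice the
median degree of all nodes AND each of the four remaining measures
(betweenness, closeness, edge-clustering NC, local average connectivity)
strictly exceeds its own median over all nodes. Medians are computed over
every node of the analysed graph, including zero-centrality nodes; nodes
exactly at a cutoff fail. The degree multiplier (default 2.0) is exposed as
a knob.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import EmptyInputError, ValidationError
from .topology import MEASURES, CentralityTable


@dataclass
class HubResult:
    hubs: list[str]  # descending degree, ties broken by symbol
    thresholds: dict[str, float]  # cutoff actually applied per measure
    flags: pd.DataFrame  # per-node boolean pass/fail per criterion


def screen_hubs(ct: CentralityTable, degree_factor: float = 2.0) -> HubResult:
    """Apply the five strict median cutoffs to a centrality table.

    An empty hub list is a legal outcome (e.g. on vertex-transitive graphs,
    where no degree can exceed twice the median).
    """
    if len(ct) == 0:
        raise EmptyInputError("cannot screen an empty centrality table")
    thresholds = {m: (degree_factor * ct.medians[m] if m == "dc" else ct.medians[m]) for m in MEASURES}
    flags = pd.DataFrame(
        {m: ct.values[m] > thresholds[m] for m in MEASURES}, index=ct.values.index
    )
    passed = flags.all(axis=1)
    hubs = sorted(
        (str(v) for v in ct.values.index[passed]),
        key=lambda v: (-ct.values.at[v, "dc"], v),
    )
    return HubResult(hubs=hubs, thresholds=thresholds, flags=flags)


def hub_subnetwork(g: nx.Graph, hubs) -> nx.Graph:
    """Subgraph induced by the hub set; unknown symbols are an error."""
    unknown = sorted(set(hubs) - set(g.nodes()))
    if unknown:
        raise ValidationError(f"hub symbols not in graph: {unknown}")
    return g.subgraph(hubs).copy()


def write_screening_report(
    g: nx.Graph, result: HubResult, subnet: nx.Graph, path: str | Path
) -> None:
    report = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "thresholds": {k: float(v) for k, v in sorted(result.thresholds.items())},
        "n_hubs": len(result.hubs),
        "n_hub_edges": subnet.number_of_edges(),
    }
    Path(path).write_text(json.dumps(report, sort_keys=True) + "\n")
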