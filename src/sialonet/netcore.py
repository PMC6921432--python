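"""Interactome projection and network topology of a DEG set.

Projects a differentially-expressed gene list onto an undirected
protein-protein interactome, reports the induced subgraph (connected vs
isolated query genes), extracts the largest connected component, computes
degree / harmonic closeness / Brandes betweenness centralities, and
selects hub molecules as the genes shared across the top decile of all
three centrality rankings.  Harmonic closeness is used because the induced
DEG network is typically disconnected, where classical closeness is
undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import rankdata

from sialonet.errors import ValidationError


@dataclass
class ProjectionResult:
    """DEG-induced subgraph and its summary counts."""

    subgraph: nx.Graph
    connected_genes: list[str]  # query genes with >= 1 induced edge
    isolated_genes: list[str]  # query genes with none (incl. absent from graph)
    n_edges: int


def project_onto_interactome(genes, graph: nx.Graph) -> ProjectionResult:
    """Induced subgraph of the interactome over the query genes."""
    query = list(dict.fromkeys(genes))
    present = [g for g in query if g in graph]
    sub = graph.subgraph(present).copy()
    connected = sorted(n for n in sub.nodes if sub.degree(n) > 0)
    isolated = sorted(set(query) - set(connected))
    return ProjectionResult(
        subgraph=sub,
        connected_genes=connected,
        isolated_genes=isolated,
        n_edges=sub.number_of_edges(),
    )


def largest_connected_component(graph: nx.Graph) -> set[str]:
    """Maximum-cardinality component; ties broken by smallest member id."""
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph has no connected component")
    components = [set(c) for c in nx.connected_components(graph)]
    best_size = max(len(c) for c in components)
    ties = [c for c in components if len(c) == best_size]
    return min(ties, key=lambda c: min(c))


def centralities(graph: nx.Graph) -> pd.DataFrame:
    """Degree, harmonic closeness and betweenness with average-rank columns.

    Betweenness is unnormalized Brandes shortest-path betweenness (each
    unordered pair counted once); closeness is the harmonic variant, so
    unreachable pairs contribute zero rather than breaking the measure.
    """
    if any(graph.has_edge(n, n) for n in graph):
        raise ValidationError("graph has self-loops; expected a simple graph")
    nodes = sorted(graph.nodes)
    degree = {n: graph.degree(n) for n in nodes}
    closeness = nx.harmonic_centrality(graph)
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    table = pd.DataFrame(
        {
            "degree": [degree[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )
    for measure in ("degree", "closeness", "betweenness"):
        # rank 1 = highest centrality; ties share their average rank
        table[f"{measure}_rank"] = rankdata(-table[measure].to_numpy(),
                                            method="average")
    return table


def select_hubs(table: pd.DataFrame, fraction: float = 0.10) -> set[str]:
    """Genes in the shared top-``fraction`` of all three centrality ranks.

    The cutoff is ceil(fraction * n) positions per measure; a tie of
    average ranks straddling the cutoff admits every tied gene.
    """
    if table.empty:
        raise ValidationError("empty centrality table")
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    n = len(table)
    k = math.ceil(fraction * n)
    hubs: set[str] | None = None
    for measure in ("degree", "closeness", "betweenness"):
        ranks = table[f"{measure}_rank"]
        cutoff = ranks.sort_values(kind="mergesort").iloc[k - 1]
        top = set(table.index[ranks <= cutoff])
        hubs = top if hubs is None else hubs & top
    return hubs if hubs is not None else set()
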