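"""Key driver analysis on a directed gene network.

Given a target gene set G (e.g. the largest connected component of the
DEG-induced interactome) and a directed gene network N (ideally a DAG, as
produced by Bayesian-network projection), KDA asks which network nodes sit
upstream of G: for every candidate node g in the subnetwork NG around G,
the h-layer downstream neighborhood HLN(g, h) is tested for enrichment in
G by a one-sided Fisher's exact test for each h = 1..H; the enrichment
statistic ES(h, g) = -log10 p is maximized over layers (ES_h*, with the
smallest h kept on ties).  Nodes significant after Bonferroni correction
over all tested candidates are key drivers — "global" if they are roots
(no parents), "local" otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from sialonet.errors import ValidationError

logger = logging.getLogger(__name__)

# floor for p-values before -log10 (exact zeros from underflow)
_P_FLOOR = 1e-300


def h_layer_neighborhood(
    network: nx.DiGraph, gene: str, h: int, direction: str = "downstream"
) -> set[str]:
    """Nodes within h directed layers of ``gene`` (excluding the gene).

    ``direction="downstream"`` follows child edges only (a driver's
    regulated cascade); ``"undirected"`` ignores edge orientation.
    """
    if gene not in network:
        raise ValidationError(f"gene {gene!r} is not in the network")
    if h < 1:
        raise ValidationError(f"layer depth must be >= 1, got {h}")
    if direction == "downstream":
        search_graph = network
    elif direction == "undirected":
        search_graph = network.to_undirected(as_view=True)
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    lengths = nx.single_source_shortest_path_length(search_graph, gene, cutoff=h)
    return set(lengths) - {gene}


def build_subnetwork_ng(network: nx.DiGraph, targets, h_max: int) -> set[str]:
    """Candidate pool: target genes plus everything within H layers of them.

    The search runs in both edge orientations so upstream regulators of the
    target set are included as candidates.
    """
    if h_max < 1:
        raise ValidationError(f"layer depth must be >= 1, got {h_max}")
    present = set(targets) & set(network.nodes)
    if not present:
        raise ValidationError("no target gene is present in the network")
    undirected = network.to_undirected(as_view=True)
    ng = set(present)
    for t in present:
        ng |= set(
            nx.single_source_shortest_path_length(undirected, t, cutoff=h_max)
        )
    return ng


@dataclass
class KDACandidate:
    """One tested node with its optimal-layer enrichment."""

    gene: str
    h_star: int
    es: float  # -log10 raw p at h*
    p_raw: float
    p_bonferroni: float
    scope: str  # "global" (root) or "local"
    neighborhood_size: int
    overlap: int
    is_key_driver: bool


def key_driver_analysis(
    network: nx.DiGraph,
    targets,
    h_max: int = 3,
    alpha: float = 0.01,
    direction: str = "downstream",
    return_all: bool = False,
) -> list[KDACandidate]:
    """Run KDA; returns key drivers (or every tested candidate).

    For each candidate the Fisher background is every network node except
    the candidate itself, which is likewise excluded from its own
    neighborhood and from the target set for its own test.  Bonferroni
    correction uses m = number of tested candidates (|NG|).  Results are
    sorted by corrected p, ties broken by gene id.
    """
    if not 0 < alpha <= 1:
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    if network.number_of_nodes() == 0:
        raise ValidationError("empty network")
    if not nx.is_directed_acyclic_graph(network):
        logger.warning(
            "network contains cycles; global/local labels follow in-degree anyway"
        )
    target_set = set(targets) & set(network.nodes)
    if not target_set:
        raise ValidationError("no target gene is present in the network")
    ng = build_subnetwork_ng(network, target_set, h_max)
    m = len(ng)
    n_background_total = network.number_of_nodes() - 1

    candidates: list[KDACandidate] = []
    for gene in sorted(ng):
        own_targets = target_set - {gene}
        k_targets = len(own_targets)
        best = None  # (es, h, p, size, overlap)
        for h in range(1, h_max + 1):
            hln = h_layer_neighborhood(network, gene, h, direction=direction)
            size = len(hln)
            overlap = len(hln & own_targets)
            if size == 0:
                p = 1.0
            else:
                p = float(
                    stats.hypergeom.sf(
                        overlap - 1, n_background_total, k_targets, size
                    )
                )
            es = -math.log10(max(p, _P_FLOOR))
            if best is None or es > best[0] + 1e-12:
                best = (es, h, p, size, overlap)
        es, h_star, p_raw, size, overlap = best
        p_bonf = min(1.0, p_raw * m)
        scope = "global" if network.in_degree(gene) == 0 else "local"
        candidates.append(
            KDACandidate(
                gene=gene,
                h_star=h_star,
                es=es,
                p_raw=p_raw,
                p_bonferroni=p_bonf,
                scope=scope,
                neighborhood_size=size,
                overlap=overlap,
                is_key_driver=p_bonf < alpha,
            )
        )
    candidates.sort(key=lambda c: (c.p_bonferroni, c.gene))
    if return_all:
        return candidates
    return [c for c in candidates if c.is_key_driver]


def correlate_kdg_scores(
    expression, pathway_scores
) -> dict[str, tuple[float, float]]:
    """Pearson r (and p) of each candidate gene's expression vs a pathway score.

    ``expression`` is genes x samples, ``pathway_scores`` a sample-indexed
    vector; samples are aligned by id.
    """
    from sialonet.cluster_subgroup import pearson_test

    scores = pathway_scores.loc[expression.columns]
    out: dict[str, tuple[float, float]] = {}
    for gene in expression.index:
        out[gene] = pearson_test(
            expression.loc[gene].to_numpy(dtype=float),
            scores.to_numpy(dtype=float),
        )
    return out


def candidates_to_frame(candidates: list[KDACandidate]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "h_star": c.h_star,
                "es": c.es,
                "p_raw": c.p_raw,
                "p_bonferroni": c.p_bonferroni,
                "scope": c.scope,
                "neighborhood_size": c.neighborhood_size,
                "overlap": c.overlap,
                "is_key_driver": c.is_key_driver,
            }
            for c in candidates
        ],
        columns=[
            "gene", "h_star", "es", "p_raw", "p_bonferroni",
            "scope", "neighborhood_size", "overlap", "is_key_driver",
        ],
    )
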