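"""Gene-set enrichment: ORA, GSEA, single-sample GSEA, enrichment map.

Four complementary views of gene-set signal:

* :func:`fisher_ora` — hypergeometric over-representation of a query gene
  list in a target set against a universe;
* :func:`gsea_es` — the weighted Kolmogorov-Smirnov-like running-sum
  enrichment statistic over a ranked gene list, with leading-edge
  extraction, and :func:`gsea_permutation_p` for its gene-set-permutation
  significance;
* :func:`ssgsea_score` — a per-sample enrichment score from the summed
  difference between the weighted in-set and uniform out-of-set empirical
  CDFs over that sample's expression ranking;
* :func:`enrichment_map` — the gene-set similarity graph with edges where
  Jaccard overlap exceeds 0.25 (strictly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from sialonet.errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways or cell-type signatures)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def names(self) -> list[str]:
        return sorted(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe) -> "GeneSetCollection":
        """Drop genes outside the universe and sets left empty (warned)."""
        universe = set(universe)
        kept: dict[str, set[str]] = {}
        for name in self.names():
            inter = self.sets[name] & universe
            if inter:
                kept[name] = inter
            else:
                logger.warning("dropping gene set %r: no genes in matrix", name)
        return GeneSetCollection(sets=kept, descriptions=dict(self.descriptions))


# ---------------------------------------------------------------------------
# over-representation analysis


def fisher_ora(query, target, universe) -> tuple[float, float]:
    """One-sided (enrichment) Fisher's exact test of query vs target overlap.

    Returns (odds ratio, one-sided greater p).  The odds ratio uses the
    Haldane 0.5 correction when any table cell is zero.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    query = set(query) & universe
    target = set(target) & universe
    n = len(universe)
    a = len(query & target)
    b = len(query - target)
    c = len(target - query)
    d = n - a - b - c
    # hypergeometric tail: P(overlap >= a)
    p = float(stats.hypergeom.sf(a - 1, n, len(target), len(query)))
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), min(p, 1.0)


def ora_table(query, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """ORA of one query list against every set in a collection (BH-adjusted)."""
    from sialonet.dge import bh_adjust

    rows = []
    for name in collection.names():
        odds, p = fisher_ora(query, collection.sets[name], universe)
        overlap = len(set(query) & collection.sets[name] & set(universe))
        rows.append((name, overlap, len(collection.sets[name]), odds, p))
    table = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "odds_ratio", "p"]
    )
    table["adj_p"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table


# ---------------------------------------------------------------------------
# GSEA


@dataclass
class GseaResult:
    """Running-sum enrichment of one gene set in one ranked list."""

    set_name: str
    es: float
    peak_index: int  # 0-based position of the extreme deviation
    n: int
    n_hits: int
    n_r: float  # sum of |r|^p over hits
    p_hit: np.ndarray
    p_miss: np.ndarray
    leading_edge: list[str]
    p_value: float | None = None


def _ranked_arrays(ranked_genes, scores) -> tuple[list[str], np.ndarray]:
    genes = list(ranked_genes)
    if len(set(genes)) != len(genes):
        raise ValidationError("ranked gene list contains duplicates")
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(genes):
        raise ValidationError("genes and scores differ in length")
    return genes, scores


def gsea_es(
    ranked_genes, scores, gene_set, exponent: float = 1.0,
    set_name: str = "set",
) -> GseaResult:
    """Weighted running-sum enrichment statistic with leading edge.

    ``ranked_genes`` must already be ordered by decreasing score.  The hit
    increment at position i is |r_i|^exponent normalized by the total hit
    weight; the miss increment is uniform.  ES is the signed maximum
    deviation; the leading edge contains the set members at or before the
    peak for positive ES (at or after it for negative ES).
    """
    genes, scores = _ranked_arrays(ranked_genes, scores)
    members = set(gene_set)
    hit = np.array([g in members for g in genes])
    n = len(genes)
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValidationError("gene set has no genes in the ranked list")
    if n_hits == n:
        raise ValidationError("gene set covers the entire ranked list")
    weights = np.abs(scores) ** exponent
    n_r = float(weights[hit].sum())
    if n_r == 0:
        # all hit scores are zero: fall back to uniform hit increments
        p_hit = np.cumsum(hit) / n_hits
    else:
        p_hit = np.cumsum(np.where(hit, weights, 0.0)) / n_r
    p_miss = np.cumsum(~hit) / (n - n_hits)
    deviation = p_hit - p_miss
    peak = int(np.argmax(np.abs(deviation)))
    es = float(deviation[peak])
    if es >= 0:
        leading = [g for i, g in enumerate(genes[: peak + 1]) if hit[i]]
    else:
        leading = [g for i, g in enumerate(genes) if i >= peak and hit[i]]
    return GseaResult(
        set_name=set_name,
        es=es,
        peak_index=peak,
        n=n,
        n_hits=n_hits,
        n_r=n_r,
        p_hit=p_hit,
        p_miss=p_miss,
        leading_edge=leading,
    )


def gsea_permutation_p(
    ranked_genes,
    scores,
    gene_set,
    exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Gene-set permutation p-value for |ES| (random same-size sets)."""
    if n_perm < 100:
        raise ValidationError(f"need n_perm >= 100, got {n_perm}")
    genes, scores = _ranked_arrays(ranked_genes, scores)
    observed = gsea_es(genes, scores, gene_set, exponent=exponent)
    n = len(genes)
    k = observed.n_hits
    weights = np.abs(np.asarray(scores, dtype=float)) ** exponent
    rng = np.random.default_rng(seed)
    n_extreme = 0
    inv_miss = 1.0 / (n - k)
    for _ in range(n_perm):
        pos = rng.choice(n, size=k, replace=False)
        hit = np.zeros(n, dtype=bool)
        hit[pos] = True
        n_r = weights[pos].sum()
        if n_r == 0:
            p_hit = np.cumsum(hit) / k
        else:
            p_hit = np.cumsum(np.where(hit, weights, 0.0)) / n_r
        deviation = p_hit - np.cumsum(~hit) * inv_miss
        es_null = deviation[np.argmax(np.abs(deviation))]
        if abs(es_null) >= abs(observed.es):
            n_extreme += 1
    return (1 + n_extreme) / (n_perm + 1)


def gsea_table(
    ranked_genes,
    scores,
    collection: GeneSetCollection,
    exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """GSEA of every set in a collection against one ranked list."""
    from sialonet.dge import bh_adjust

    rows = []
    for name in collection.names():
        members = collection.sets[name] & set(ranked_genes)
        if not members or len(members) == len(list(ranked_genes)):
            logger.warning("skipping set %r (no usable overlap)", name)
            continue
        res = gsea_es(ranked_genes, scores, members, exponent=exponent,
                      set_name=name)
        res.p_value = gsea_permutation_p(
            ranked_genes, scores, members, exponent=exponent,
            n_perm=n_perm, seed=seed,
        )
        rows.append(
            (name, res.es, res.n_hits, res.p_value, "|".join(res.leading_edge))
        )
    table = pd.DataFrame(rows, columns=["set", "es", "n_hits", "p", "leading_edge"])
    table["adj_p"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table


# ---------------------------------------------------------------------------
# single-sample GSEA


def _rank_order(expr: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Descending expression order (ties by gene id) and average-rank weights."""
    genes = expr.index.to_numpy(dtype=str)
    values = expr.to_numpy(dtype=float)
    order_idx = np.lexsort((genes, -values))
    # average ranks from the bottom: highest expression -> largest value
    asc_ranks = stats.rankdata(values, method="average")
    return genes[order_idx], asc_ranks[order_idx]


def _ssgsea_from_order(
    ordered_genes: np.ndarray,
    rank_values: np.ndarray,
    members: set[str],
    alpha: float,
) -> float:
    n = len(ordered_genes)
    hit = np.isin(ordered_genes, list(members))
    n_hits = int(hit.sum())
    weights = np.abs(rank_values) ** alpha
    p_w = np.cumsum(np.where(hit, weights, 0.0))
    p_w /= p_w[-1]
    p_nw = np.cumsum(~hit) / (n - n_hits)
    return float(np.sum(p_w - p_nw))


def ssgsea_score(expr: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """Single-sample enrichment score of one gene set in one sample.

    Genes are ranked by decreasing expression (ties broken by gene id
    after average-rank normalization); the score is the sum over all list
    positions of the difference between the weighted in-set ECDF
    (weights = rank-normalized value ^ alpha) and the uniform out-of-set
    ECDF.  alpha = 0 makes the score depend on ranks only.
    """
    if expr.index.duplicated().any():
        raise ValidationError("expression vector has duplicated gene ids")
    members = set(gene_set) & set(expr.index)
    n = len(expr)
    if not members:
        raise ValidationError("gene set has no genes in the expression vector")
    if len(members) == n:
        raise ValidationError("gene set covers all genes; out-of-set ECDF undefined")
    ordered_genes, rank_values = _rank_order(expr)
    return _ssgsea_from_order(ordered_genes, rank_values, members, alpha)


def ssgsea_matrix(
    matrix: pd.DataFrame,
    collection: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Pathway x sample matrix of single-sample enrichment scores.

    Sets without any gene in the matrix are dropped with a warning.  With
    ``normalize=True`` scores are min-max rescaled over the whole matrix
    (a variant used in the field; raw sums are the default).
    """
    usable = collection.restrict(matrix.index)
    if len(usable) == 0:
        raise ValidationError("no gene set overlaps the expression matrix")
    scores = np.empty((len(usable), matrix.shape[1]))
    names = usable.names()
    n_genes = matrix.shape[0]
    for j, sample in enumerate(matrix.columns):
        ordered_genes, rank_values = _rank_order(matrix[sample])
        for i, name in enumerate(names):
            members = usable.sets[name]
            if len(members) == n_genes:
                raise ValidationError(
                    f"gene set {name!r} covers all genes; score undefined"
                )
            scores[i, j] = _ssgsea_from_order(
                ordered_genes, rank_values, members, alpha
            )
    out = pd.DataFrame(scores, index=pd.Index(names, name="pathway"),
                       columns=matrix.columns)
    if normalize:
        lo, hi = out.to_numpy().min(), out.to_numpy().max()
        if hi > lo:
            out = (out - lo) / (hi - lo)
    return out


# ---------------------------------------------------------------------------
# enrichment map


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def enrichment_map(
    collection: GeneSetCollection,
    node_scores: dict[str, float] | None = None,
    threshold: float = 0.25,
) -> nx.Graph:
    """Gene-set similarity graph: edge iff Jaccard overlap > threshold.

    The inequality is strict — an overlap of exactly the threshold does not
    connect two sets.  Nodes carry set size and an optional score.
    """
    graph = nx.Graph()
    names = collection.names()
    for name in names:
        graph.add_node(
            name,
            size=len(collection.sets[name]),
            score=(node_scores or {}).get(name),
        )
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            j = jaccard(collection.sets[a], collection.sets[b])
            if j > threshold:
                graph.add_edge(a, b, weight=j)
    return graph
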