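"""Pathway-score-driven unsupervised subgrouping and group statistics.

Patients are clustered on their pathway enrichment profiles (samples x
pathways, features z-scored) with agglomerative hierarchical clustering
(Euclidean distance, average linkage by default, Ward optional).  The
number of clusters is chosen over k = 2..5 by the gap statistic
(uniform reference sets in the PCA-aligned bounding box) with mean
silhouette reported alongside.  Between-group statistics mirror the usual
clinical toolbox: unpaired t / Mann-Whitney U per pathway, paired t across
timepoints, chi-squared / Fisher association, Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score as _sk_silhouette

from sialonet.errors import ValidationError


def zscore_features(data: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (feature); constant features map to zero."""
    sd = data.std(axis=0, ddof=1).replace(0.0, 1.0)
    return (data - data.mean(axis=0)) / sd


# ---------------------------------------------------------------------------
# hierarchical clustering


def hier_cluster(
    data: pd.DataFrame, k: int, method: str = "average"
) -> pd.Series:
    """Cut an agglomerative (Euclidean) dendrogram into k clusters.

    ``data`` is samples x features.  Returns integer labels (1..k) indexed
    by sample, renumbered in order of first appearance for determinism.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if k > data.shape[0]:
        raise ValidationError(f"k = {k} exceeds the number of samples ({data.shape[0]})")
    values = data.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("clustering input contains non-finite values")
    merges = linkage(values, method=method, metric="euclidean")
    raw = fcluster(merges, t=k, criterion="maxclust")
    # renumber so cluster ids follow first appearance in sample order
    seen: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in seen:
            seen[lab] = len(seen) + 1
        labels.append(seen[lab])
    return pd.Series(labels, index=data.index, name="cluster")


def silhouette(data: pd.DataFrame, labels: pd.Series) -> float:
    """Mean silhouette (b - a) / max(a, b); singletons contribute zero."""
    labs = np.asarray(labels.loc[data.index])
    if len(set(labs)) < 2:
        raise ValidationError("silhouette needs >= 2 clusters")
    return float(_sk_silhouette(data.to_numpy(dtype=float), labs,
                                metric="euclidean"))


# ---------------------------------------------------------------------------
# gap statistic


@dataclass
class GapResult:
    """Per-k gap statistic diagnostics and the chosen cluster count."""

    k_values: list[int]
    gap: list[float]
    s_k: list[float]
    log_w: list[float]
    chosen_k: int
    mean_silhouette: dict[int, float] = field(default_factory=dict)


def _within_dispersion(values: np.ndarray, labels: np.ndarray) -> float:
    """W_k = sum over clusters of (pairwise squared distances) / (2 n_r)."""
    total = 0.0
    for lab in np.unique(labels):
        pts = values[labels == lab]
        if len(pts) < 2:
            continue
        sq = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        total += sq.sum() / (2.0 * len(pts))
    return total


def gap_statistic(
    data: pd.DataFrame,
    k_range=range(2, 6),
    n_reference: int = 50,
    seed: int = 0,
    method: str = "average",
) -> GapResult:
    """Gap statistic over a k range with PCA-aligned uniform references.

    Gap(k) = mean_b log W*_kb - log W_k over ``n_reference`` uniform
    reference draws in the PCA-aligned bounding box of the data;
    s_k = sd_b(log W*) * sqrt(1 + 1/B).  The chosen k is the smallest k
    with Gap(k) >= Gap(k+1) - s_{k+1} (the last k if never satisfied).
    """
    if n_reference < 10:
        raise ValidationError(f"need >= 10 reference sets, got {n_reference}")
    k_values = sorted(set(int(k) for k in k_range))
    if not k_values:
        raise ValidationError("empty k range")
    values = data.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    center = values.mean(axis=0)
    xc = values - center
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    rotated = xc @ vt.T
    lo, hi = rotated.min(axis=0), rotated.max(axis=0)

    log_w, gaps, s_ks, sils = [], [], [], {}
    for k in k_values:
        labels = hier_cluster(data, k, method=method).to_numpy()
        w = _within_dispersion(values, labels)
        lw = float(np.log(max(w, 1e-300)))
        log_w.append(lw)
        if k >= 2 and len(set(labels)) >= 2:
            sils[k] = float(
                _sk_silhouette(values, labels, metric="euclidean")
            )
        ref_logs = np.empty(n_reference)
        for b in range(n_reference):
            z = rng.uniform(lo, hi, size=rotated.shape) @ vt + center
            ref_df = pd.DataFrame(z, index=data.index)
            ref_labels = hier_cluster(ref_df, k, method=method).to_numpy()
            ref_logs[b] = np.log(max(_within_dispersion(z, ref_labels), 1e-300))
        gaps.append(float(ref_logs.mean() - lw))
        s_ks.append(float(ref_logs.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_reference)))

    chosen = k_values[-1]
    for i, k in enumerate(k_values[:-1]):
        if gaps[i] >= gaps[i + 1] - s_ks[i + 1]:
            chosen = k
            break
    return GapResult(
        k_values=k_values,
        gap=gaps,
        s_k=s_ks,
        log_w=log_w,
        chosen_k=chosen,
        mean_silhouette=sils,
    )


# ---------------------------------------------------------------------------
# between-group statistics


def between_cluster_tests(
    scores: pd.DataFrame, labels: pd.Series, method: str = "t"
) -> pd.DataFrame:
    """Two-sided per-pathway tests between exactly two clusters.

    ``scores`` is pathways x samples; ``labels`` maps samples to two
    cluster ids.  Returns per-pathway statistic, p and BH-adjusted p.
    """
    labels = labels.loc[scores.columns]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValidationError(f"expected exactly 2 clusters, got {len(groups)}")
    cols_a = labels.index[labels == groups[0]]
    cols_b = labels.index[labels == groups[1]]
    if method == "t" and (len(cols_a) < 2 or len(cols_b) < 2):
        raise ValidationError("t test needs >= 2 samples per cluster")
    rows = []
    for pathway in scores.index:
        a = scores.loc[pathway, cols_a].to_numpy(dtype=float)
        b = scores.loc[pathway, cols_b].to_numpy(dtype=float)
        if method == "t":
            stat, p = stats.ttest_ind(a, b)
        elif method == "mannwhitney":
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        else:
            raise ValidationError(f"unknown method {method!r}")
        rows.append((pathway, float(stat), float(p)))
    from sialonet.dge import bh_adjust

    table = pd.DataFrame(rows, columns=["pathway", "statistic", "p"])
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    return table


def paired_change_tests(
    scores_before: pd.DataFrame,
    scores_after: pd.DataFrame,
    pairing: dict[str, str],
) -> pd.DataFrame:
    """Per-pathway paired t between two timepoints.

    ``pairing`` maps a "before" sample id to its "after" sample id; every
    pair must be complete in both matrices.
    """
    before_ids = list(pairing)
    after_ids = [pairing[s] for s in before_ids]
    missing = [s for s in before_ids if s not in scores_before.columns] + [
        s for s in after_ids if s not in scores_after.columns
    ]
    if missing:
        raise ValidationError(f"unpaired/missing samples: {missing[:5]}")
    if not set(scores_before.index) == set(scores_after.index):
        raise ValidationError("timepoint matrices have different pathways")
    rows = []
    for pathway in scores_before.index:
        x = scores_before.loc[pathway, before_ids].to_numpy(dtype=float)
        y = scores_after.loc[pathway, after_ids].to_numpy(dtype=float)
        stat, p = stats.ttest_rel(y, x)
        if np.isnan(stat):  # identical pre/post: t = 0 boundary
            stat, p = 0.0, 1.0
        rows.append((pathway, float(stat), float(p)))
    return pd.DataFrame(rows, columns=["pathway", "t", "p"])


def association_test(a, b) -> tuple[str, float]:
    """Chi-squared (falling back to Fisher) association of two categoricals.

    Returns (test name, p).  Fisher's exact is used for 2x2 tables with any
    expected count < 5.
    """
    table = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("association test needs >= 2 levels per factor")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any() and table.shape == (2, 2):
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return "fisher", float(p)
    return "chi2", float(p)


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson r with its t-based two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("vectors differ in length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("Pearson correlation undefined for constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def tsne_embed(
    data: pd.DataFrame, perplexity: float = 5.0, seed: int = 0
) -> pd.DataFrame:
    """2-D t-SNE embedding of samples x features (visual confirmation only)."""
    from sklearn.manifold import TSNE

    perplexity = min(perplexity, max(1.0, (data.shape[0] - 1) / 3.0))
    emb = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(data.to_numpy(dtype=float))
    return pd.DataFrame(emb, index=data.index, columns=["tsne1", "tsne2"])
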