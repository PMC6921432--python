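"""Normalization and batch correction for merged log2 expression matrices.

Three stages, mirroring how multi-study microarray compendia are merged:

* :func:`quantile_normalize` forces identical marginal distributions across
  samples (rank-wise substitution of the mean sorted profile, with tied
  values sharing the mean reference value over their rank span);
* :func:`combat_adjust` removes additive/multiplicative batch effects by
  parametric empirical-Bayes location-scale adjustment, with the biological
  group factor protected in the standardization design so case/control
  signal is not absorbed into the batch terms;
* :func:`pca_qc` quantifies how much of each principal component is
  explained by batch versus group, before and after correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sialonet.errors import ValidationError
from sialonet.io import align_annotation

logger = logging.getLogger(__name__)

#: variance floor for degenerate (near-constant) genes
EPS_VAR = 1e-8


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Equalize all sample distributions to the mean sorted profile.

    After the call every column holds the same multiset of values: the
    row-wise mean of the column-sorted matrix.  Ties within a column
    receive the mean of the reference values over their rank span, which
    makes the transform idempotent.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("matrix contains non-finite values")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        # tied observations share the mean reference value over their span
        sorted_col = col[order]
        start = 0
        for end in range(1, n + 1):
            if end == n or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    assigned[order[start:end]] = reference[start:end].mean()
                start = end
        out[:, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# ComBat-style batch adjustment


@dataclass
class BatchModel:
    """Fitted empirical-Bayes batch model (location-scale or mean-only)."""

    batches: list[str]
    gamma_hat: np.ndarray  # (n_batch, n_gene) raw per-batch locations
    delta_sq_hat: np.ndarray  # (n_batch, n_gene) raw per-batch scales
    gamma_star: np.ndarray  # EB-shrunk locations
    delta_sq_star: np.ndarray  # EB-shrunk scales (all 1 in mean-only mode)
    gamma_bar: np.ndarray  # (n_batch,) prior means for gamma
    tau_sq_bar: np.ndarray  # (n_batch,) prior variances for gamma
    grand_mean: np.ndarray  # (n_gene,)
    var_pooled: np.ndarray  # (n_gene,)
    mode: str


def _aprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return float((2 * s2 + m**2) / s2)


def _bprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return float((m * s2 + m**3) / s2)


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(s_data_b, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4):
    """Iterative joint EB solution for one batch (parametric ComBat)."""
    n = s_data_b.shape[1]
    g_old = g_hat.copy()
    d_old = d_hat.copy()
    for _ in range(500):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((s_data_b - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            (np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)).max(),
            (np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_adjust(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    mode: str = "location-scale",
) -> tuple[pd.DataFrame, BatchModel]:
    """Parametric empirical-Bayes batch correction of a genes x samples matrix.

    Per gene the data are standardized against a design holding full batch
    indicators plus the (protected) group factor; per-batch location and
    scale estimates are shrunk toward batch-level prior moments (normal
    prior on location, inverse-gamma on scale, method of moments) and the
    adjusted data transformed back.  ``mode="mean-only"`` fixes all scale
    factors at 1 and removes the raw (unshrunk) per-batch locations, which
    equalizes per-gene batch means exactly.
    """
    if mode not in ("location-scale", "mean-only"):
        raise ValidationError(f"unknown ComBat mode {mode!r}")
    annotation = align_annotation(annotation, matrix)
    batch = annotation["batch"].astype(str).to_numpy()
    group = annotation["group"].astype(str).to_numpy()
    batches = sorted(set(batch))

    if len(batches) == 1:
        logger.warning("single batch: nothing to correct, returning input")
        n_genes = matrix.shape[0]
        model = BatchModel(
            batches=batches,
            gamma_hat=np.zeros((1, n_genes)),
            delta_sq_hat=np.ones((1, n_genes)),
            gamma_star=np.zeros((1, n_genes)),
            delta_sq_star=np.ones((1, n_genes)),
            gamma_bar=np.zeros(1),
            tau_sq_bar=np.ones(1),
            grand_mean=matrix.mean(axis=1).to_numpy(),
            var_pooled=matrix.var(axis=1, ddof=0).to_numpy(),
            mode=mode,
        )
        return matrix.copy(), model

    counts = {b: int((batch == b).sum()) for b in batches}
    for b, c in counts.items():
        if c < 2:
            raise ValidationError(f"batch {b!r} has {c} sample(s); need >= 2")

    dat = matrix.to_numpy(dtype=float)  # genes x samples
    n_array = dat.shape[1]

    batch_design = np.column_stack([(batch == b).astype(float) for b in batches])
    group_levels = sorted(set(group))
    # drop-first coding keeps the design full rank next to the batch block
    mod = np.column_stack(
        [(group == g).astype(float) for g in group_levels[1:]]
    ) if len(group_levels) > 1 else np.empty((n_array, 0))
    design = np.column_stack([batch_design, mod])

    b_hat, *_ = np.linalg.lstsq(design, dat.T, rcond=None)  # (p, genes)
    n_batch = len(batches)
    sizes = np.array([counts[b] for b in batches], dtype=float)
    grand_mean = (sizes / n_array) @ b_hat[:n_batch]  # (genes,)
    resid = dat - (design @ b_hat).T
    var_pooled = (resid**2).mean(axis=1)
    n_floored = int((var_pooled < EPS_VAR).sum())
    if n_floored:
        logger.warning("flooring variance of %d degenerate gene(s)", n_floored)
        var_pooled = np.maximum(var_pooled, EPS_VAR)

    stand_mean = grand_mean[:, None] + (mod @ b_hat[n_batch:]).T
    s_data = (dat - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.vstack(
        [s_data[:, batch == b].mean(axis=1) for b in batches]
    )
    delta_sq_hat = np.maximum(
        np.vstack([s_data[:, batch == b].var(axis=1, ddof=1) for b in batches]),
        EPS_VAR,
    )
    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq_bar = gamma_hat.var(axis=1, ddof=1)

    gamma_star = np.empty_like(gamma_hat)
    delta_sq_star = np.ones_like(delta_sq_hat)
    for i, b in enumerate(batches):
        cols = batch == b
        if mode == "mean-only":
            # raw location removal: exact per-gene batch-mean equalization
            # (EB-shrunk locations would leave a residual batch mean)
            gamma_star[i] = gamma_hat[i]
        else:
            a = _aprior(delta_sq_hat[i])
            bp = _bprior(delta_sq_hat[i])
            gamma_star[i], delta_sq_star[i] = _it_sol(
                s_data[:, cols], gamma_hat[i], delta_sq_hat[i],
                gamma_bar[i], tau_sq_bar[i], a, bp,
            )

    bayes = s_data.copy()
    for i, b in enumerate(batches):
        cols = batch == b
        bayes[:, cols] = (bayes[:, cols] - gamma_star[i][:, None]) / np.sqrt(
            delta_sq_star[i]
        )[:, None]
    corrected = bayes * np.sqrt(var_pooled)[:, None] + stand_mean

    model = BatchModel(
        batches=batches,
        gamma_hat=gamma_hat,
        delta_sq_hat=delta_sq_hat,
        gamma_star=gamma_star,
        delta_sq_star=delta_sq_star,
        gamma_bar=gamma_bar,
        tau_sq_bar=tau_sq_bar,
        grand_mean=grand_mean,
        var_pooled=var_pooled,
        mode=mode,
    )
    out = pd.DataFrame(corrected, index=matrix.index, columns=matrix.columns)
    return out, model


# ---------------------------------------------------------------------------
# PCA QC


@dataclass
class PCAReport:
    """Sample scores, variance explained, and factor associations."""

    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray  # fraction per component
    batch_r2: np.ndarray  # per-component R^2 of the batch factor
    group_r2: np.ndarray  # per-component R^2 of the group factor


def _factor_r2(scores: np.ndarray, factor: np.ndarray) -> np.ndarray:
    """Per-column R^2 of a categorical factor (between-group SS / total SS)."""
    levels = sorted(set(factor))
    out = np.empty(scores.shape[1])
    for j in range(scores.shape[1]):
        y = scores[:, j]
        total = ((y - y.mean()) ** 2).sum()
        if total == 0:
            out[j] = 0.0
            continue
        between = sum(
            (factor == lv).sum() * (y[factor == lv].mean() - y.mean()) ** 2
            for lv in levels
        )
        out[j] = between / total
    return out


def pca_qc(
    matrix: pd.DataFrame, annotation: pd.DataFrame, n_components: int = 5
) -> PCAReport:
    """Principal components of samples with batch/group association R^2."""
    if matrix.shape[1] < 3:
        raise ValidationError("PCA QC needs >= 3 samples")
    annotation = align_annotation(annotation, matrix)
    x = matrix.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0)
    if np.allclose(x, 0):
        raise ValidationError("constant matrix: PCA undefined")
    k = min(n_components, x.shape[0] - 1, x.shape[1])
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    var_exp = (s**2 / (s**2).sum())[:k]
    batch = annotation["batch"].astype(str).to_numpy()
    group = annotation["group"].astype(str).to_numpy()
    score_df = pd.DataFrame(
        scores,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PCAReport(
        scores=score_df,
        variance_explained=var_exp,
        batch_r2=_factor_r2(scores, batch),
        group_r2=_factor_r2(scores, group),
    )
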