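"""Probe-to-gene collapsing and empirical-Bayes batch integration.

``collapse_probes`` reduces a probe-level array matrix to gene level by
removing unmapped probes and averaging the signal of probes that map to the
same gene. ``combat_adjust`` merges datasets measured on different
platforms with a parametric empirical-Bayes location/scale model
(ComBat-style): per gene, the data are standardized under a linear model
with batch indicators and an optional biological covariate, per-batch
location (gamma) and scale (delta^2) effects are estimated and shrunk
toward a normal / inverse-gamma prior fitted across genes, and the data are
adjusted and back-transformed.

Shrinkage makes the single-pass estimator deliberately conservative: a
small residual batch offset (the part of each gene's apparent batch effect
the prior attributes to noise) survives the first pass. So that merging is
a projection — adjusting an already-merged matrix is the identity to
numerical tolerance — the adjustment finishes with exact equalization
passes in the same standardized space: per batch the remaining gene-wise
location offset is removed outright and the scale factors are divided by
their sample-size-weighted cross-batch mean (equalizing batch variances
while leaving each gene's overall scale untouched), iterated until the
matrix stops changing.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["collapse_probes", "combat_adjust"]


def collapse_probes(
    probe_values: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples.

    Probes absent from ``probe_to_gene`` (or mapped to an empty symbol) are
    removed; when several probes map to one gene, the gene's expression is
    the arithmetic mean of the probe values per sample. Gene order in the
    output is lexicographic.
    """
    if probe_values.index.has_duplicates:
        dup = probe_values.index[probe_values.index.duplicated()][0]
        raise ValueError(f"duplicate probe identifier {dup!r}")
    mapped = [
        p for p in probe_values.index if probe_to_gene.get(p) not in (None, "")
    ]
    if not mapped:
        raise ValueError("no probe maps to any gene; nothing to collapse")
    sub = probe_values.loc[mapped]
    gene_index = pd.Index([probe_to_gene[p] for p in mapped], name="gene")
    collapsed = sub.groupby(gene_index).mean()
    return collapsed.sort_index()


# ---------------------------------------------------------------------------
# ComBat


def _design_matrix(
    meta: pd.DataFrame, batches: list[str], covariate: str | None
) -> tuple[np.ndarray, int]:
    batch_dummies = np.column_stack(
        [(meta["batch"] == b).to_numpy(float) for b in batches]
    )
    if covariate is None:
        return batch_dummies, len(batches)
    levels = list(dict.fromkeys(meta[covariate]))
    if len(levels) < 2:
        warnings.warn(
            f"covariate {covariate!r} is constant; ignored", stacklevel=3
        )
        return batch_dummies, len(batches)
    cov = np.column_stack(
        [(meta[covariate] == lv).to_numpy(float) for lv in levels[1:]]
    )
    return np.hstack([batch_dummies, cov]), len(batches)


def _combat_pass(
    x: np.ndarray,
    design: np.ndarray,
    n_batch: int,
    batch_cols: list[np.ndarray],
    conv: float,
    max_iter: int,
) -> np.ndarray:
    n_genes, n_samples = x.shape
    n_per_batch = np.array([cols.sum() for cols in batch_cols], float)

    beta = np.linalg.lstsq(design, x.T, rcond=None)[0]  # (p, genes)
    grand_mean = (n_per_batch / n_samples) @ beta[:n_batch]
    fitted = (design @ beta).T
    var_pooled = ((x - fitted) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = np.tile(grand_mean[:, None], (1, n_samples))
    if design.shape[1] > n_batch:
        stand_mean = stand_mean + (design[:, n_batch:] @ beta[n_batch:]).T
    sd = np.sqrt(var_pooled)[:, None]
    s_data = (x - stand_mean) / sd

    gamma_stars = np.empty((len(batch_cols), n_genes))
    delta_stars = np.empty((len(batch_cols), n_genes))
    for b, cols in enumerate(batch_cols):
        nb = int(n_per_batch[b])
        sb = s_data[:, cols]
        gamma_hat = sb.mean(axis=1)
        delta_hat = sb.var(axis=1, ddof=1)

        gamma_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        m = delta_hat.mean()
        s2 = delta_hat.var(ddof=1)
        if s2 <= 0 or t2 <= 0:
            # degenerate prior (e.g. near-converged data): plain shrink to
            # the cross-gene means
            gamma_star = np.full_like(gamma_hat, gamma_bar) if t2 <= 0 else gamma_hat
            delta_star = np.full_like(delta_hat, max(m, 1e-12))
            if t2 > 0:
                gamma_star = gamma_hat
        else:
            a_prior = (2.0 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
            gamma_star = gamma_hat.copy()
            delta_star = delta_hat.copy()
            sum_sq = ((sb - gamma_star[:, None]) ** 2).sum(axis=1)
            for _ in range(max_iter):
                gamma_new = (nb * t2 * gamma_hat + delta_star * gamma_bar) / (
                    nb * t2 + delta_star
                )
                sum_sq = ((sb - gamma_new[:, None]) ** 2).sum(axis=1)
                delta_new = (0.5 * sum_sq + b_prior) / (nb / 2.0 + a_prior - 1.0)
                change = max(
                    np.abs(gamma_new - gamma_star).max(),
                    np.abs(delta_new - delta_star).max(),
                )
                gamma_star, delta_star = gamma_new, delta_new
                if change < conv:
                    break
        gamma_stars[b] = gamma_star
        delta_stars[b] = np.maximum(delta_star, 1e-12)

    # only batch *differences* in scale are artifacts: normalize the shrunk
    # scale factors by their weighted cross-batch mean per gene
    weights = n_per_batch / n_per_batch.sum()
    delta_stars = delta_stars / (weights @ delta_stars)[None, :]
    adjusted = s_data.copy()
    for b, cols in enumerate(batch_cols):
        adjusted[:, cols] = (s_data[:, cols] - gamma_stars[b][:, None]) / np.sqrt(
            delta_stars[b]
        )[:, None]
    return adjusted * sd + stand_mean


def _exact_pass(
    x: np.ndarray,
    design: np.ndarray,
    n_batch: int,
    batch_cols: list[np.ndarray],
) -> np.ndarray:
    """Exact per-batch location/scale equalization in standardized space.

    Scale factors are normalized by their sample-size-weighted cross-batch
    mean per gene, so only batch *differences* are removed and the operator
    is idempotent."""
    n_genes, n_samples = x.shape
    n_per_batch = np.array([cols.sum() for cols in batch_cols], float)

    beta = np.linalg.lstsq(design, x.T, rcond=None)[0]
    grand_mean = (n_per_batch / n_samples) @ beta[:n_batch]
    fitted = (design @ beta).T
    var_pooled = np.maximum(((x - fitted) ** 2).mean(axis=1), 1e-12)
    stand_mean = np.tile(grand_mean[:, None], (1, n_samples))
    if design.shape[1] > n_batch:
        stand_mean = stand_mean + (design[:, n_batch:] @ beta[n_batch:]).T
    sd = np.sqrt(var_pooled)[:, None]
    s_data = (x - stand_mean) / sd

    gamma = np.empty((len(batch_cols), n_genes))
    delta = np.empty((len(batch_cols), n_genes))
    for b, cols in enumerate(batch_cols):
        sb = s_data[:, cols]
        gamma[b] = sb.mean(axis=1)
        delta[b] = np.maximum(sb.var(axis=1, ddof=1), 1e-12)
    weights = n_per_batch / n_per_batch.sum()
    delta_norm = delta / (weights @ delta)[None, :]

    adjusted = s_data.copy()
    for b, cols in enumerate(batch_cols):
        adjusted[:, cols] = (s_data[:, cols] - gamma[b][:, None]) / np.sqrt(
            delta_norm[b]
        )[:, None]
    return adjusted * sd + stand_mean


def combat_adjust(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    covariate: str | None = "group",
    conv: float = 1e-4,
    max_iter: int = 100,
    projection_tol: float = 1e-8,
    max_passes: int = 200,
) -> pd.DataFrame:
    """Remove batch effects with parametric empirical-Bayes adjustment.

    Parameters
    ----------
    expr
        Genes x samples log2 matrix.
    meta
        Sample metadata aligned to ``expr.columns``; must contain a
        ``batch`` column and, if ``covariate`` is given, that column.
    covariate
        Biological covariate protected during standardization (default the
        control/induced group, so the induction signal is not removed);
        ``None`` fits batch effects against the grand mean only.
    conv, max_iter
        Convergence tolerance and iteration cap of the per-batch
        empirical-Bayes solver.
    projection_tol, max_passes
        After the empirical-Bayes pass, exact equalization passes repeat
        until the matrix changes by less than ``projection_tol`` (max-abs),
        which makes the operation idempotent to that tolerance.
    """
    missing = [s for s in expr.columns if s not in meta.index]
    if missing:
        raise ValueError(f"sample {missing[0]!r} absent from metadata")
    meta = meta.loc[list(expr.columns)]
    batches = list(dict.fromkeys(meta["batch"]))
    if len(batches) < 2:
        raise ValueError("combat_adjust needs at least two batches")
    sizes = meta["batch"].value_counts()
    if (sizes < 2).any():
        small = sizes.index[sizes < 2][0]
        raise ValueError(f"batch {small!r} has a single sample")
    variances = expr.var(axis=1, ddof=0)
    if (variances <= 0).any():
        gene = variances.index[variances <= 0][0]
        raise ValueError(f"gene {gene!r} has zero variance across samples")

    design, n_batch = _design_matrix(meta, batches, covariate)
    batch_cols = [(meta["batch"] == b).to_numpy() for b in batches]

    x = expr.to_numpy(float)
    x = _combat_pass(x, design, n_batch, batch_cols, conv, max_iter)
    for _ in range(max_passes):
        new = _exact_pass(x, design, n_batch, batch_cols)
        delta = np.abs(new - x).max()
        x = new
        if delta < projection_tol:
            break
    return pd.DataFrame(x, index=expr.index, columns=expr.columns)
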