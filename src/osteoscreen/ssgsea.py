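"""Single-sample gene-set enrichment scoring (ssGSEA).

For each sample, genes are ranked by expression (average ranks on ties;
rank N = highest). Walking the ranked list from the top, a gene set's
enrichment score is the integrated difference between the weighted in-set
empirical CDF (each in-set gene weighted by rank^alpha, normalized to sum
one) and the unweighted out-of-set ECDF — i.e. the running-sum total over
all positions, not its supremum. Because the score depends on ranks only,
it is invariant under any monotone transform of a sample's values.

Optionally the whole score matrix is normalized by its (max - min), which
keeps scores comparable across samples for clustering and stage-median
summaries.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import GeneSetCollection

__all__ = ["ssgsea_scores", "stage_median_scores"]


def ssgsea_scores(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    min_overlap: int = 3,
    normalize: bool = True,
) -> pd.DataFrame:
    """Score every gene set in every sample; returns sets x samples.

    Sets with fewer than ``min_overlap`` members present in the matrix are
    dropped with a warning, as is the degenerate set that covers every gene
    in the matrix (its out-of-set ECDF is undefined). An empty result after
    dropping is a hard error.
    """
    genes = list(expr.index)
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    kept: dict[str, np.ndarray] = {}
    for name in sets:
        present = [g for g in sets.members(name) if g in gene_pos]
        if len(present) < min_overlap:
            warnings.warn(
                f"set {name!r}: only {len(present)} members in matrix "
                f"(< {min_overlap}); dropped",
                stacklevel=2,
            )
            continue
        if len(present) == n_genes:
            warnings.warn(
                f"set {name!r} covers every gene in the matrix; dropped",
                stacklevel=2,
            )
            continue
        mask = np.zeros(n_genes, dtype=bool)
        mask[[gene_pos[g] for g in present]] = True
        kept[name] = mask
    if not kept:
        raise ValueError("no gene set survives the overlap filter")

    values = expr.to_numpy(float)
    gene_order_key = np.array(genes)
    scores = np.empty((len(kept), expr.shape[1]))
    set_names = list(kept)
    for j in range(expr.shape[1]):
        col = values[:, j]
        ranks = rankdata(col)  # ascending, average ties -> highest gets N
        # descending expression; ties broken by gene symbol for determinism
        order = np.lexsort((gene_order_key, -col))
        ranks_ord = ranks[order]
        for si, name in enumerate(set_names):
            mask_ord = kept[name][order]
            k = mask_ord.sum()
            w = np.where(mask_ord, ranks_ord**alpha, 0.0)
            p_in = np.cumsum(w) / w.sum()
            p_out = np.cumsum(~mask_ord) / (n_genes - k)
            scores[si, j] = float(np.sum(p_in - p_out))

    out = pd.DataFrame(scores, index=set_names, columns=expr.columns)
    if normalize:
        span = float(out.to_numpy().max() - out.to_numpy().min())
        if span > 0:
            out = out / span
    out.attrs["normalized"] = bool(normalize)
    out.attrs["alpha"] = alpha
    return out


def stage_median_scores(scores: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Median enrichment score per (set, osteogenic stage).

    Controls form stage 0 (their metadata day is 0 by invariant); columns
    are the distinct days in ascending order. A stage with zero samples is
    simply absent.
    """
    missing = [s for s in scores.columns if s not in meta.index]
    if missing:
        raise ValueError(f"sample {missing[0]!r} absent from metadata")
    days = meta.loc[list(scores.columns), "day"]
    out = {}
    for day in sorted(days.unique()):
        cols = days.index[days == day]
        out[int(day)] = scores[cols].median(axis=1)
    return pd.DataFrame(out)
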