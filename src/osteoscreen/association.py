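"""Pearson association between genes and pathway activity, and among genes.

``gene_pathway_association`` correlates each differentially expressed
gene's log2 profile with each pathway's per-sample enrichment score,
attaching a two-sided p-value from the exact t transform
``t = r * sqrt((n - 2) / (1 - r^2))`` and a Benjamini-Hochberg adjustment
over the whole gene x pathway table. ``gene_gene_correlation`` returns the
full symmetric Pearson matrix over a gene subset, the substrate for the
threshold-swept co-expression networks.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = ["gene_pathway_association", "gene_gene_correlation", "pearson_with_p"]


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p (t approximation, n - 2 df).

    Constant vectors yield ``(0.0, 1.0)`` with a warning, since the
    correlation is undefined there.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant vector in correlation; reporting r=0, p=1",
                      stacklevel=2)
        return 0.0, 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), n - 2))


def gene_pathway_association(
    expr: pd.DataFrame,
    degs: Sequence[str],
    scores: pd.DataFrame,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Full association table over DEGs x kept pathways.

    ``expr`` and ``scores`` must share the same samples in the same order.
    The significance flag is adjusted p < alpha by default (``use_adjusted=
    False`` switches the flag to the raw p, the table always carries both).
    """
    if list(expr.columns) != list(scores.columns):
        raise ValueError("expression and score matrices must share aligned samples")
    missing = [g for g in degs if g not in expr.index]
    if missing:
        raise KeyError(f"gene {missing[0]!r} not present in expression matrix")
    n = expr.shape[1]
    if n < 3:
        raise ValueError("association needs at least 3 samples")

    rows = []
    for gene in degs:
        gv = expr.loc[gene].to_numpy(float)
        for pathway in scores.index:
            r, p = pearson_with_p(gv, scores.loc[pathway].to_numpy(float))
            rows.append({"gene": gene, "pathway": pathway, "r": r, "p": p})
    table = pd.DataFrame(rows)
    table["padj"] = bh_adjust(table["p"].to_numpy())
    crit = table["padj"] if use_adjusted else table["p"]
    table["significant"] = crit < alpha
    return table


def gene_gene_correlation(expr: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix over the given genes."""
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"gene {missing[0]!r} not present in expression matrix")
    if expr.shape[1] < 3:
        raise ValueError("correlation needs at least 3 samples")
    sub = expr.loc[list(genes)].to_numpy(float)
    sds = sub.std(axis=1)
    if (sds == 0).any():
        bad = list(genes)[int(np.argmax(sds == 0))]
        raise ValueError(f"gene {bad!r} is constant; correlation undefined")
    corr = np.corrcoef(sub)
    corr = np.asarray(corr, float)
    corr = (corr + corr.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=list(genes), columns=list(genes))
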