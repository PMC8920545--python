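"""Over-representation analysis and pre-ranked GSEA.

ORA tests each annotated term for overlap with a query gene list by the
upper-tail hypergeometric probability P(X >= k) given the term size K,
query size n and universe size N, with Benjamini-Hochberg adjustment across
the tested terms.

Pre-ranked GSEA walks a gene list ranked by a statistic (here: log2 fold
change between sample groups) with the classic weighted Kolmogorov-Smirnov
running sum: in-set genes add |stat|^w / sum(|stat|^w over the set), out-of-
set genes subtract 1/(N - K); the enrichment score is the signed maximum
deviation. The null distribution comes from gene-label permutations (random
sets of the same size), so p = (1 + #{|ES_perm| >= |ES|}) / (nperm + 1),
seeded and bit-reproducible. No normalized ES is computed; the permutation
p with BH adjustment is the decision statistic.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io_formats import GeneSetCollection

__all__ = ["hypergeometric_tail_p", "hypergeometric_ora", "preranked_gsea"]


def hypergeometric_tail_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    X is the overlap when drawing ``n`` genes from a universe of ``N``
    containing ``K`` term members.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_ora(
    query: Iterable[str],
    universe: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each annotated term.

    ``query`` must be a subset of ``universe``; each term is intersected
    with the universe before testing and skipped if the intersection is
    empty. Returns one row per tested term, sorted by p, with the overlap
    genes, BH-adjusted p and a significance flag at ``alpha``.
    """
    query_set = set(query)
    universe_set = set(universe)
    if not universe_set or not query_set:
        raise ValueError("query and universe must be non-empty")
    stray = query_set - universe_set
    if stray:
        raise ValueError(f"query gene {sorted(stray)[0]!r} not in universe")
    N = len(universe_set)
    n = len(query_set)

    rows = []
    for term, members in annotation.items():
        term_members = set(members) & universe_set
        K = len(term_members)
        if K == 0:
            continue
        overlap = sorted(term_members & query_set)
        k = len(overlap)
        rows.append(
            {
                "term": term,
                "overlap": k,
                "term_size": K,
                "query_size": n,
                "universe_size": N,
                "p": hypergeometric_tail_p(k, K, n, N),
                "genes": ",".join(overlap),
            }
        )
    if not rows:
        raise ValueError("no annotated term overlaps the universe")
    result = pd.DataFrame(rows)
    result["padj"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = result["padj"] < alpha
    return result.sort_values(["p", "term"], ignore_index=True)


def _es_from_mask(stat_abs_w: np.ndarray, mask: np.ndarray) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    n = mask.size
    k = int(mask.sum())
    hit_w = np.where(mask, stat_abs_w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all in-set stats zero: fall back to unweighted hits
        hit_w = mask.astype(float)
        total = float(k)
    running = np.cumsum(hit_w / total - (~mask) / (n - k))
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    return float(running[i_max] if running[i_max] >= -running[i_min] else running[i_min])


def preranked_gsea(
    ranked: pd.DataFrame,
    sets: GeneSetCollection,
    nperm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_overlap: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pre-ranked GSEA with a gene-permutation null.

    Parameters
    ----------
    ranked
        Frame with columns ``gene`` and ``stat``, ordered by descending
        statistic (as produced by :func:`osteoscreen.diffexpr.
        rank_by_fold_change`). The statistic must be finite.
    sets
        Gene sets; each is filtered to the genes present and dropped below
        ``min_overlap`` (logged).
    nperm, seed
        Permutation count (a warning below 100) and RNG seed; results are
        bit-reproducible for a fixed seed.
    weight
        Exponent on |stat| for hit increments; 0 gives the unweighted KS
        statistic.

    Returns one row per kept set with ``es``, permutation ``p``, ``padj``
    across sets, and the leading-edge genes.
    """
    if nperm < 100:
        warnings.warn(f"nperm={nperm} is small; p-values will be coarse",
                      stacklevel=2)
    genes = list(ranked["gene"])
    stat = ranked["stat"].to_numpy(float)
    if not np.isfinite(stat).all():
        raise ValueError("ranking statistic must be finite")
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    stat_abs_w = np.abs(stat) ** weight

    rng = np.random.default_rng(seed)
    rows = []
    for name in sets:
        present = [g for g in sets.members(name) if g in gene_pos]
        k = len(present)
        if k < min_overlap or k >= n:
            warnings.warn(
                f"set {name!r}: {k} usable members; dropped", stacklevel=2
            )
            continue
        mask = np.zeros(n, dtype=bool)
        mask[[gene_pos[g] for g in present]] = True
        es = _es_from_mask(stat_abs_w, mask)

        null = np.empty(nperm)
        for b in range(nperm):
            perm_mask = np.zeros(n, dtype=bool)
            perm_mask[rng.choice(n, size=k, replace=False)] = True
            null[b] = _es_from_mask(stat_abs_w, perm_mask)
        p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (nperm + 1.0)

        # leading edge: hits at or before the peak (after, for negative ES)
        hit_w = np.where(mask, stat_abs_w, 0.0)
        total = hit_w.sum() if hit_w.sum() > 0 else float(k)
        running = np.cumsum(
            (hit_w / total if hit_w.sum() > 0 else mask / total)
            - (~mask) / (n - k)
        )
        if es >= 0:
            peak = int(np.argmax(running))
            leading = [g for g in genes[: peak + 1] if mask[gene_pos[g]]]
        else:
            peak = int(np.argmin(running))
            leading = [g for g in genes[peak:] if mask[gene_pos[g]]]
        rows.append(
            {
                "set": name,
                "es": es,
                "size": k,
                "p": p,
                "leading_edge": ",".join(leading),
            }
        )
    if not rows:
        raise ValueError("no gene set survives the overlap filter")
    result = pd.DataFrame(rows)
    result["padj"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = result["padj"] < alpha
    return result.sort_values(["p", "set"], ignore_index=True)
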