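"""Evidence integration and candidate prioritization.

Each differentially expressed gene accumulates four evidence lines: being a
DEG at all, the fraction of pathways it is significantly *positively*
associated with, a co-expression consensus-hub flag and a PPI-hub flag. The
evidence score is the weighted sum

    score = w1*[DEG] + w2*(positive associations / n pathways)
          + w3*[co-expression consensus hub] + w4*[PPI hub]

with default weights (1, 1, 1, 1). Genes that are themselves members of the
osteoblast pathway gene sets, or appear on a user-supplied list of
previously studied osteogenesis genes, are moved to an excluded list with
the reason recorded — the novelty filter that leaves only unstudied
candidates. Ties break by positive-association count, then gene symbol, so
the ranking is deterministic and input-order invariant. The full evidence
vector is always emitted so users can re-rank by any rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["CandidateRanking", "integrate_evidence"]

REASON_PATHWAY = "involved in osteoblast-related pathways"
REASON_KNOWN = "previously studied"


@dataclass
class CandidateRanking:
    """Ranked candidate genes plus the genes excluded by the novelty filter."""

    candidates: pd.DataFrame  # rank, gene, score + full evidence vector
    excluded: pd.DataFrame  # gene, reason

    @property
    def top_gene(self) -> str:
        if self.candidates.empty:
            raise ValueError("no candidates")
        return str(self.candidates.iloc[0]["gene"])


def _hub_lookup(report, flag_col: str) -> dict[str, bool]:
    if report is None:
        return {}
    if isinstance(report, Mapping):
        return {g: bool(v) for g, v in report.items()}
    return {g: bool(v) for g, v in report[flag_col].items()}


def integrate_evidence(
    de: pd.DataFrame,
    assoc: pd.DataFrame,
    coexp_hubs,
    ppi_hubs,
    pathway_genes: Iterable[str],
    known: Iterable[str] = (),
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
) -> CandidateRanking:
    """Combine all evidence lines into a ranked candidate list.

    Parameters
    ----------
    de
        Labeled differential-expression result (column ``label``); the DEGs
        (label != "ns") form the candidate universe.
    assoc
        Gene-pathway association table with columns gene/pathway/r/
        significant.
    coexp_hubs, ppi_hubs
        Consensus-hub report(s): either a mapping gene -> bool or a frame
        indexed by gene with a ``consensus`` / ``ppi_hub`` column.
    pathway_genes
        Union of the osteoblast pathway gene sets; members are excluded.
    known
        Previously studied osteogenesis genes (user-supplied); excluded.
    """
    if "label" not in de.columns:
        raise ValueError("de must be classified (run classify_degs first)")
    degs = list(de.index[de["label"] != "ns"])
    if not degs:
        raise ValueError("empty DEG set; nothing to prioritize")

    n_pathways = int(assoc["pathway"].nunique()) if len(assoc) else 0
    pos_counts = {g: 0 for g in degs}
    neg_counts = {g: 0 for g in degs}
    if len(assoc):
        sig = assoc[assoc["significant"]]
        for gene, sub in sig.groupby("gene"):
            if gene in pos_counts:
                pos_counts[gene] = int((sub["r"] > 0).sum())
                neg_counts[gene] = int((sub["r"] < 0).sum())

    coexp = _hub_lookup(coexp_hubs, "consensus")
    ppi = _hub_lookup(ppi_hubs, "ppi_hub")
    pathway_set = set(pathway_genes)
    known_set = set(known)

    w1, w2, w3, w4 = weights
    cand_rows, excl_rows = [], []
    for gene in sorted(degs):
        pos_frac = pos_counts[gene] / n_pathways if n_pathways else 0.0
        row = {
            "gene": gene,
            "de_label": de.loc[gene, "label"],
            "logFC": float(de.loc[gene, "logFC"]),
            "n_pos_assoc": pos_counts[gene],
            "n_neg_assoc": neg_counts[gene],
            "coexpression_hub": bool(coexp.get(gene, False)),
            "ppi_hub": bool(ppi.get(gene, False)),
            "score": (
                w1 * 1.0
                + w2 * pos_frac
                + w3 * float(coexp.get(gene, False))
                + w4 * float(ppi.get(gene, False))
            ),
        }
        reasons = []
        if gene in pathway_set:
            reasons.append(REASON_PATHWAY)
        if gene in known_set:
            reasons.append(REASON_KNOWN)
        if reasons:
            excl_rows.append({"gene": gene, "reason": "; ".join(reasons), **row})
        else:
            cand_rows.append(row)

    candidates = pd.DataFrame(cand_rows)
    if not candidates.empty:
        candidates = candidates.sort_values(
            ["score", "n_pos_assoc", "gene"],
            ascending=[False, False, True],
            ignore_index=True,
        )
        candidates.insert(0, "rank", range(1, len(candidates) + 1))
    excluded = pd.DataFrame(
        excl_rows, columns=["gene", "reason"] + list(candidates.columns[2:])
        if excl_rows
        else ["gene", "reason"],
    )
    return CandidateRanking(candidates=candidates, excluded=excluded)
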