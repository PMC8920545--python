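"""End-to-end discovery pipeline on synthetic data.

``run_all`` wires every stage together in the order of the study design:
simulate a multi-batch osteogenic time course, merge batches with the
empirical-Bayes adjustment (protecting the induction group), call DEGs with
the asymmetric gates, score pathway activity per sample (ssGSEA), associate
DEGs with pathway scores, build the threshold-swept co-expression networks
separately for up- and down-regulated genes, rank PPI degrees, integrate
the evidence into a candidate ranking with the novelty filter, and finally
characterize the top candidate by a median-expression split: differential
expression between the high/low groups (BH only, no fold-change gate),
hypergeometric ORA of the split DEGs against an annotation table, and
pre-ranked GSEA of the fold-change-ranked gene list against the pathway
collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import gene_gene_correlation, gene_pathway_association
from .diffexpr import classify_degs, moderated_de, rank_by_fold_change, split_by_median
from .enrichment import hypergeometric_ora, preranked_gsea
from .io_formats import GeneSetCollection
from .networks import (
    DEFAULT_THRESHOLDS,
    build_threshold_networks,
    consensus_hubs,
    ppi_degree_hubs,
)
from .preprocess import combat_adjust
from .prioritize import CandidateRanking, integrate_evidence
from .ssgsea import ssgsea_scores, stage_median_scores
from .synthetic import (
    GroundTruth,
    SimulationConfig,
    make_annotation_fixture,
    simulate_timecourse,
)

__all__ = ["PipelineResult", "run_all"]


@dataclass
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    config: SimulationConfig
    truth: GroundTruth
    expr_raw: pd.DataFrame = field(repr=False)
    expr: pd.DataFrame = field(repr=False)
    meta: pd.DataFrame = field(repr=False)
    collection: GeneSetCollection = field(repr=False)
    de: pd.DataFrame = field(repr=False)
    scores: pd.DataFrame = field(repr=False)
    stage_medians: pd.DataFrame = field(repr=False)
    assoc: pd.DataFrame = field(repr=False)
    hub_report_up: pd.DataFrame | None = field(repr=False)
    hub_report_down: pd.DataFrame | None = field(repr=False)
    ppi_report: pd.DataFrame = field(repr=False)
    ranking: CandidateRanking = field(repr=False)
    split: pd.Series = field(repr=False)
    de_split: pd.DataFrame = field(repr=False)
    ora: pd.DataFrame = field(repr=False)
    gsea: pd.DataFrame = field(repr=False)

    @property
    def up_genes(self) -> list[str]:
        return list(self.de.index[self.de["label"] == "up"])

    @property
    def down_genes(self) -> list[str]:
        return list(self.de.index[self.de["label"] == "down"])


def _direction_hubs(
    expr: pd.DataFrame,
    genes: list[str],
    thresholds,
    top_k: int,
    consensus_fraction: float,
) -> pd.DataFrame | None:
    if len(genes) < 2:
        return None
    corr = gene_gene_correlation(expr, genes)
    nets = build_threshold_networks(corr, thresholds=thresholds)
    return consensus_hubs(nets, consensus_fraction=consensus_fraction, top_k=top_k)


def run_all(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    *,
    alpha: float = 0.05,
    up_lfc: float = 1.0,
    down_lfc: float = -0.8,
    thresholds=DEFAULT_THRESHOLDS,
    hub_top_k: int = 5,
    consensus_fraction: float = 0.5,
    ppi_top_k: int = 9,
    known_genes=(),
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    nperm: int = 500,
) -> PipelineResult:
    """Run the full discovery pipeline on one simulated dataset.

    ``seed`` (if given) overrides ``config.seed``; every stochastic stage
    (simulation, GSEA permutations) derives its stream from it.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config = config.replace(seed=int(seed))

    expr_raw, meta, collection, ppi_edges, truth = simulate_timecourse(config)
    annotation = make_annotation_fixture(config, truth)

    expr = combat_adjust(expr_raw, meta, covariate="group")

    de = classify_degs(
        moderated_de(expr, meta["group"], contrast=("induced", "control")),
        alpha=alpha,
        up_lfc=up_lfc,
        down_lfc=down_lfc,
    )
    up = list(de.index[de["label"] == "up"])
    down = list(de.index[de["label"] == "down"])
    degs = up + down

    scores = ssgsea_scores(expr, collection)
    stage_medians = stage_median_scores(scores, meta)
    assoc = gene_pathway_association(expr, degs, scores, alpha=alpha)

    hub_up = _direction_hubs(expr, up, thresholds, hub_top_k, consensus_fraction)
    hub_down = _direction_hubs(expr, down, thresholds, hub_top_k, consensus_fraction)
    coexp_flags: dict[str, bool] = {}
    for report in (hub_up, hub_down):
        if report is not None:
            coexp_flags.update(report["consensus"].to_dict())

    ppi_report = ppi_degree_hubs(ppi_edges, restrict_to=degs, top_k=ppi_top_k)

    ranking = integrate_evidence(
        de,
        assoc,
        coexp_flags,
        ppi_report,
        pathway_genes=collection.all_genes(),
        known=known_genes,
        weights=weights,
    )

    top = ranking.top_gene
    split = split_by_median(expr, top)
    de_split = moderated_de(expr, split, contrast=("high", "low"))
    split_degs = list(de_split.index[de_split["padj"] < alpha])

    universe = list(expr.index)
    query = split_degs if split_degs else degs
    ora = hypergeometric_ora(query, universe, annotation, alpha=alpha)

    ranked = rank_by_fold_change(de_split)
    gsea = preranked_gsea(
        ranked, collection, nperm=nperm, seed=config.seed + 1, alpha=alpha
    )

    return PipelineResult(
        config=config,
        truth=truth,
        expr_raw=expr_raw,
        expr=expr,
        meta=meta,
        collection=collection,
        de=de,
        scores=scores,
        stage_medians=stage_medians,
        assoc=assoc,
        hub_report_up=hub_up,
        hub_report_down=hub_down,
        ppi_report=ppi_report,
        ranking=ranking,
        split=split,
        de_split=de_split,
        ora=ora,
        gsea=gsea,
    )
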