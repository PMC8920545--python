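"""Synthetic multi-batch osteogenic time-course generator with known truth.

The generator emulates the structure of a merged microarray compendium of
human bone-marrow mesenchymal stem cells undergoing osteogenic induction:
several datasets (batches) each containing uninduced controls (day 0) and
induced samples at later stages, planted up/down differentially expressed
genes with early-response or ramping kinetics, pathway modules driven by a
latent per-sample activity that increases (or, for one "development"
module, decreases) with the osteogenic day, and a single planted regulator
gene that tracks pathway activity and is hub-like in both the co-expression
and the protein-interaction layers. All noise is Gaussian on the log2 scale
(microarray convention); batch effects are an additive per-(batch, gene)
shift plus an inverse-gamma multiplicative scale on the noise, applied after
the biology, matching the location/scale model the batch-adjustment step
assumes.

One seed drives every random choice through ``numpy.random.SeedSequence``
sub-streams, so a configuration plus seed fully determines the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import GeneSetCollection, edge_list_from_pairs

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_timecourse",
    "make_annotation_fixture",
]

# Category tags for the emitted pathway modules, mirroring the composition of
# the packaged osteoblast collection: 1 transcription-factor set, 9
# differentiation sets, 1 development set, 3 proliferation sets, 1 signaling
# set. The development module is the one with decreasing activity.
_MODULE_CATEGORY_LAYOUT = (
    ["differentiation"] * 9
    + ["proliferation"] * 3
    + ["transcription_factor", "development", "signaling"]
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic osteogenic time course.

    Defaults emulate the merged four-dataset study design: 4 batches, stages
    day 0/1/3/7/14 with 4 samples per batch per stage (16 controls + 64
    induced), 25 up- and 17 down-regulated genes, and 15 pathway modules.
    """

    n_genes: int = 1000
    n_batches: int = 4
    samples_per_batch_per_stage: int = 4
    stages: tuple[int, ...] = (0, 1, 3, 7, 14)
    n_up_degs: int = 25
    n_down_degs: int = 17
    effect_size_lfc: float = 3.0
    early_response_fraction: float = 0.5
    n_pathway_modules: int = 15
    module_size: int = 20
    latent_activity_effect: float = 0.8
    latent_activity_exponent: float = 0.3
    latent_jitter_sd: float = 0.05
    regulator_gene: bool = True
    batch_shift_sd: float = 0.8
    batch_scale_shape: float = 10.0
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_batches": self.n_batches,
            "samples_per_batch_per_stage": self.samples_per_batch_per_stage,
            "n_pathway_modules": self.n_pathway_modules,
            "module_size": self.module_size,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.n_up_degs < 0 or self.n_down_degs < 0:
            raise ValueError("DEG counts must be non-negative")
        if self.regulator_gene and self.n_up_degs < 1:
            raise ValueError("a regulator gene requires at least one up-DEG")
        if 0 not in self.stages or len(self.stages) < 2:
            raise ValueError("stages must contain day 0 and at least one induced day")
        if any(s < 0 for s in self.stages):
            raise ValueError("stages must be non-negative days")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stages must be unique")
        budget = (
            self.n_up_degs
            + self.n_down_degs
            + self.n_pathway_modules * self.module_size
        )
        if budget > self.n_genes:
            raise ValueError(
                f"gene budget infeasible: {budget} planted genes > "
                f"{self.n_genes} total genes"
            )
        if not (0.0 <= self.early_response_fraction <= 1.0):
            raise ValueError("early_response_fraction must be in [0, 1]")
        if self.noise_sd <= 0 or self.batch_scale_shape <= 1:
            raise ValueError("noise_sd must be > 0 and batch_scale_shape > 1")
        if self.latent_activity_exponent <= 0:
            raise ValueError("latent_activity_exponent must be positive")

    def replace(self, **kwargs) -> "SimulationConfig":
        return SimulationConfig(**{**asdict(self), **kwargs})


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    true_up_genes: list[str]
    true_down_genes: list[str]
    module_membership: dict[str, list[str]]
    module_categories: dict[str, str]
    regulator_gene_id: str | None
    regulator_module: str | None
    development_module: str | None
    early_response_genes: list[str]
    batch_shift: pd.DataFrame = field(repr=False, default=None)
    batch_scale: pd.DataFrame = field(repr=False, default=None)
    ppi_truth_edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.true_up_genes) & set(self.true_down_genes):
            raise ValueError("up and down gene sets must be disjoint")
        if self.regulator_gene_id is not None:
            if self.regulator_gene_id not in self.true_up_genes:
                raise ValueError("regulator must be an up-regulated gene")

    def to_jsonable(self) -> dict:
        return {
            "true_up_genes": self.true_up_genes,
            "true_down_genes": self.true_down_genes,
            "module_membership": self.module_membership,
            "module_categories": self.module_categories,
            "regulator_gene_id": self.regulator_gene_id,
            "regulator_module": self.regulator_module,
            "development_module": self.development_module,
            "early_response_genes": self.early_response_genes,
            "ppi_truth_edges": [list(e) for e in self.ppi_truth_edges],
        }


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _sample_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for b in range(1, config.n_batches + 1):
        for day in config.stages:
            for i in range(1, config.samples_per_batch_per_stage + 1):
                rows.append(
                    {
                        "sample_id": f"B{b}_D{day}_S{i}",
                        "group": "control" if day == 0 else "induced",
                        "day": int(day),
                        "batch": f"batch{b}",
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _module_categories(n_modules: int) -> list[str]:
    if n_modules <= len(_MODULE_CATEGORY_LAYOUT):
        cats = list(_MODULE_CATEGORY_LAYOUT[:n_modules])
        # always keep one development (decreasing) module if we have >= 2
        if n_modules >= 2 and "development" not in cats:
            cats[-1] = "development"
    else:
        cats = list(_MODULE_CATEGORY_LAYOUT)
        cats += ["differentiation"] * (n_modules - len(cats))
    return cats


def simulate_timecourse(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GeneSetCollection, pd.DataFrame, GroundTruth]:
    """Simulate expression, metadata, gene sets, a PPI layer and the truth.

    Returns ``(expr, meta, collection, ppi_edges, truth)`` where ``expr`` is
    the genes x samples log2 matrix *with* batch effects applied, ``meta``
    the aligned sample metadata, ``collection`` the planted pathway modules
    tagged with osteoblast-style categories, ``ppi_edges`` a canonical edge
    list in which the regulator has the maximum degree among planted DEGs,
    and ``truth`` the full planted structure.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (
        s_assign,
        s_baseline,
        s_latent,
        s_batch,
        s_noise,
        s_ppi,
    ) = [np.random.default_rng(c) for c in ss.spawn(6)]

    genes = _gene_ids(config.n_genes)
    meta = _sample_frame(config)
    samples = list(meta.index)
    n_samples = len(samples)
    day = meta["day"].to_numpy()
    induced = (meta["group"] == "induced").to_numpy()
    max_day = max(config.stages)
    day_frac = day / max_day

    # --- planted gene assignment (disjoint up / down / module genes) -------
    perm = s_assign.permutation(config.n_genes)
    n_mod_genes = config.n_pathway_modules * config.module_size
    up_idx = perm[: config.n_up_degs]
    down_idx = perm[config.n_up_degs : config.n_up_degs + config.n_down_degs]
    mod_idx = perm[
        config.n_up_degs
        + config.n_down_degs : config.n_up_degs + config.n_down_degs + n_mod_genes
    ]
    up_genes = [genes[i] for i in up_idx]
    down_genes = [genes[i] for i in down_idx]

    module_names = [
        f"SYN_OSTEOBLAST_M{m + 1:02d}" for m in range(config.n_pathway_modules)
    ]
    categories = _module_categories(config.n_pathway_modules)
    module_membership = {
        module_names[m]: [
            genes[i]
            for i in mod_idx[m * config.module_size : (m + 1) * config.module_size]
        ]
        for m in range(config.n_pathway_modules)
    }
    module_categories = dict(zip(module_names, categories))
    development_module = next(
        (n for n, c in module_categories.items() if c == "development"), None
    )

    regulator = up_genes[0] if config.regulator_gene else None
    regulator_module = None
    if regulator is not None:
        non_dev = [n for n in module_names if n != development_module]
        regulator_module = non_dev[0] if non_dev else module_names[0]

    n_early = int(round(config.early_response_fraction * (len(up_genes) + len(down_genes))))
    deg_pool = [g for g in up_genes if g != regulator] + down_genes
    early_pick = s_assign.permutation(len(deg_pool))[: min(n_early, len(deg_pool))]
    early_genes = sorted(deg_pool[i] for i in early_pick)
    early_set = set(early_genes)

    # --- baseline means ----------------------------------------------------
    mu = s_baseline.uniform(6.0, 12.0, size=config.n_genes)
    # induced genes start low, silenced genes start high: keeps per-gene
    # means inside [5, 13] after the planted shifts
    mu[up_idx] = s_baseline.uniform(6.0, 9.0, size=len(up_idx))
    mu[down_idx] = s_baseline.uniform(9.0, 12.0, size=len(down_idx))

    gene_pos = {g: i for i, g in enumerate(genes)}
    bio = np.tile(mu[:, None], (1, n_samples))

    # --- DEG kinetics -------------------------------------------------------
    ramp = np.where(induced, day_frac, 0.0)
    step = np.where(induced, 1.0, 0.0)  # full shift from day 1 on
    for g in up_genes:
        if g == regulator:
            continue
        profile = step if g in early_set else ramp
        bio[gene_pos[g]] += config.effect_size_lfc * profile
    for g in down_genes:
        profile = step if g in early_set else ramp
        bio[gene_pos[g]] -= config.effect_size_lfc * profile

    # --- latent pathway activities -----------------------------------------
    # activity rises steeply after induction then saturates (pathway
    # engagement is early-onset), reaching 1 at the final stage
    activity_curve = day_frac**config.latent_activity_exponent
    activities: dict[str, np.ndarray] = {}
    for name in module_names:
        jitter = s_latent.normal(0.0, config.latent_jitter_sd, size=n_samples)
        base = np.where(induced, activity_curve + jitter, 0.0)
        activities[name] = -base if name == development_module else base
        for g in module_membership[name]:
            bio[gene_pos[g]] += config.latent_activity_effect * activities[name]

    # --- regulator: tracks its module's activity ---------------------------
    if regulator is not None:
        bio[gene_pos[regulator]] += config.effect_size_lfc * activities[regulator_module]

    # --- noise and batch effects -------------------------------------------
    eps = s_noise.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    # heterogeneous per-DEG variability (genes respond with different
    # fidelity), giving the co-expression degrees a realistic spread
    for g in up_genes + down_genes:
        if g != regulator:
            eps[gene_pos[g]] *= s_noise.uniform(1.0, 1.6)
    if regulator is not None:
        # the regulator reports pathway activity with little measurement
        # noise, which is what makes it correlate with and hub among the
        # other induction-responsive genes
        eps[gene_pos[regulator]] *= 0.3

    batches = list(dict.fromkeys(meta["batch"]))
    gamma = s_batch.normal(
        0.0, config.batch_shift_sd, size=(len(batches), config.n_genes)
    )
    # inverse-gamma scale with mean 1: delta^2 = (shape - 1) / Gamma(shape)
    delta2 = (config.batch_scale_shape - 1.0) / s_batch.gamma(
        config.batch_scale_shape, 1.0, size=(len(batches), config.n_genes)
    )
    batch_of = meta["batch"].to_numpy()
    values = bio.copy()
    for bi, b in enumerate(batches):
        cols = batch_of == b
        values[:, cols] += gamma[bi][:, None]
        values[:, cols] += (np.sqrt(delta2[bi])[:, None] - 1.0) * eps[:, cols]
    values += eps  # noise at unit scale where delta2 == 1

    expr = pd.DataFrame(values, index=genes, columns=samples)

    collection = GeneSetCollection(
        sets={n: list(module_membership[n]) for n in module_names},
        categories=dict(module_categories),
    )

    ppi_edges, truth_edges = _simulate_ppi(
        s_ppi, genes, up_genes, down_genes, regulator
    )

    truth = GroundTruth(
        true_up_genes=up_genes,
        true_down_genes=down_genes,
        module_membership=module_membership,
        module_categories=module_categories,
        regulator_gene_id=regulator,
        regulator_module=regulator_module,
        development_module=development_module,
        early_response_genes=early_genes,
        batch_shift=pd.DataFrame(gamma, index=batches, columns=genes),
        batch_scale=pd.DataFrame(delta2, index=batches, columns=genes),
        ppi_truth_edges=truth_edges,
    )
    return expr, meta, collection, ppi_edges, truth


def _simulate_ppi(
    rng: np.random.Generator,
    genes: list[str],
    up_genes: list[str],
    down_genes: list[str],
    regulator: str | None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Random PPI layer: regulator wired to every other DEG, random DEG-DEG
    edges (dense among the down-regulated secreted/inflammatory genes,
    sparse elsewhere), and random background edges among non-DEG genes."""
    degs = up_genes + down_genes
    deg_set = set(degs)
    down_set = set(down_genes)
    pairs: dict[tuple[str, str], float] = {}

    def add(a: str, b: str, w: float) -> None:
        key = (a, b) if a < b else (b, a)
        pairs.setdefault(key, round(float(w), 3))

    truth_edges: list[tuple[str, str]] = []
    if regulator is not None:
        for g in degs:
            if g != regulator:
                add(regulator, g, rng.uniform(0.7, 1.0))
                truth_edges.append((regulator, g) if regulator < g else (g, regulator))
    others = [g for g in degs if g != regulator]
    for i, a in enumerate(others):
        for b in others[i + 1 :]:
            p_edge = 0.4 if (a in down_set and b in down_set) else 0.05
            if rng.random() < p_edge:
                add(a, b, rng.uniform(0.4, 0.9))
    background = [g for g in genes if g not in deg_set]
    n_bg = 2 * len(genes)
    if len(background) >= 2:
        idx = rng.integers(0, len(background), size=(n_bg, 2))
        for a_i, b_i in idx:
            if a_i != b_i:
                add(background[a_i], background[b_i], rng.uniform(0.4, 1.0))

    # guarantee: the regulator's degree within the DEG subgraph strictly
    # exceeds every other DEG's
    if regulator is not None and others:
        deg_count = {g: 0 for g in degs}
        for a, b in pairs:
            if a in deg_set and b in deg_set:
                deg_count[a] += 1
                deg_count[b] += 1
        reg_deg = deg_count[regulator]
        for g in others:
            while deg_count[g] >= reg_deg:
                victims = [
                    (a, b)
                    for (a, b) in pairs
                    if g in (a, b) and regulator not in (a, b)
                ]
                a, b = victims[0]
                del pairs[(a, b)]
                deg_count[a] -= 1
                deg_count[b] -= 1

    edges = edge_list_from_pairs([(a, b, w) for (a, b), w in pairs.items()])
    return edges, truth_edges


def make_annotation_fixture(
    config: SimulationConfig,
    truth: GroundTruth,
    n_background_terms: int = 30,
    term_size: int = 40,
) -> dict[str, list[str]]:
    """Build a GO-style term -> genes table with one planted term.

    The planted "ossification-like" term is composed of the true up-DEGs
    plus pathway-module genes, so that at least half of its members are
    planted up-regulated genes; the remaining terms draw members at random
    from the whole gene universe. Deterministic given the config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    genes = _gene_ids(config.n_genes)
    module_genes = [g for m in truth.module_membership.values() for g in m]

    up = list(truth.true_up_genes)
    planted_size = min(term_size, max(len(up), 2 * len(up)))
    n_fill = max(0, planted_size - len(up))
    n_fill = min(n_fill, len(up), len(module_genes))  # keep >= 50% up-DEG overlap
    fill = [module_genes[i] for i in rng.permutation(len(module_genes))[:n_fill]]
    annotation = {"SYN_OSSIFICATION_LIKE": sorted(set(up)) + fill}

    n_terms = max(n_background_terms, 19)
    for t in range(n_terms):
        size = int(rng.integers(25, 61))
        members = [genes[i] for i in rng.permutation(config.n_genes)[:size]]
        annotation[f"SYN_TERM_{t + 1:03d}"] = members
    return annotation
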