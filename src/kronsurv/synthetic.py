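"""Synthetic trimodal cohorts with a shared latent risk factor.

Stands in for matched expression / methylation / whole-slide data with known
ground truth. A k-dimensional standard-normal latent factor z drives sparse
pathway activities, which propagate to gene expression; methylation beta
values are anti-correlated logistic transforms of the expression of their
mapped gene (so each omics modality predicts the other); slides are patch
grids whose embeddings carry a tumour-infiltrating-lymphocyte (TIL) channel
and a diffuse risk-modulated channel. The linear predictor

    eta_i = beta . z_i + gamma * TILburden_i

feeds exponential event times with baseline hazard lambda0 and independent
exponential censoring, so proportional hazards holds exactly and every
downstream stage (crossmodal prediction, survival training, attribution,
TIL localisation) has planted, testable structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .omics import FeatureAnnotation
from .survival import SurvivalData
from .wsg import PatchSet

__all__ = ["CohortConfig", "CohortTruth", "SyntheticCohort",
           "generate_cohort", "censoring_fraction"]

_TIL_BLOB = 3          # TIL clusters are square blobs of this side length
_TIL_CHANNEL = 0       # embedding channel carrying the TIL signal
_RISK_CHANNEL = 1      # embedding channel modulated by the omics risk score
_TIL_SIGNAL = 2.0
_RISK_SIGNAL = 0.5


@dataclass
class CohortConfig:
    """Generative settings; defaults are the package's reference conditions."""

    n_patients: int = 300
    n_genes: int = 200
    n_cpgs: int = 500
    n_pathways: int = 20
    genes_per_pathway: int = 10
    latent_dim: int = 4
    beta: tuple[float, ...] = (1.0, 0.8, 0.0, 0.0)   # hazard coefficient per latent dim
    baseline_hazard: float = np.log(2) / 730.0        # 1/day; median ~2 years at eta=0
    censor_rate: float = 5e-4                         # 1/day
    til_effect: float = -5.0                          # gamma; negative = TILs protective
    grid_size: int = 12                               # patches per slide side
    patch_embed_dim: int = 32
    til_fraction: float = 0.15                        # mean fraction of TIL patches
    noise_sd: float = 0.7
    methylation_slope: float = 1.0                    # c0 in logistic(-c0*expr + noise)
    add_satellite: bool = False                       # detached patch block (largest-CC exercise)
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_patients, self.n_genes, self.n_cpgs, self.n_pathways,
                  self.genes_per_pathway, self.latent_dim, self.grid_size,
                  self.patch_embed_dim)
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if not (0 <= self.til_fraction <= 1):
            raise ValueError("til_fraction must lie in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")
        if len(self.beta) != self.latent_dim:
            raise ValueError("beta must have one coefficient per latent dimension")


@dataclass
class CohortTruth:
    """Planted ground truth for recovery tests."""

    z: np.ndarray                       # n x k latent factors
    eta: np.ndarray                     # true linear predictor
    risk_score: np.ndarray              # beta . z (omics part of eta)
    til_burden: np.ndarray              # fraction of TIL patches per slide
    causal_pathways: np.ndarray         # pathway indices loading on beta != 0 dims
    causal_genes: np.ndarray            # member genes of causal pathways
    til_masks: list[np.ndarray]         # per-slide boolean mask over patches
    pathway_of_gene: np.ndarray         # gene -> pathway index
    gene_of_cpg: np.ndarray             # cpg -> gene index


@dataclass
class SyntheticCohort:
    config: CohortConfig
    expression: np.ndarray              # n x n_genes, log-scale
    methylation: np.ndarray             # n x n_cpgs, beta values in [0, 1]
    slides: list[PatchSet]
    survival: SurvivalData
    cpg_annotation: FeatureAnnotation   # CpG -> gene
    pathway_annotation: FeatureAnnotation  # gene -> pathway
    truth: CohortTruth
    gene_ids: list[str] = field(default_factory=list)
    cpg_ids: list[str] = field(default_factory=list)
    pathway_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.config.n_patients


def _plant_til_mask(rng: np.random.Generator, grid: int, frac: float) -> np.ndarray:
    """Square TIL blobs placed uniformly at random; returns grid x grid bools."""
    mask = np.zeros((grid, grid), dtype=bool)
    if frac <= 0:
        return mask
    blob = min(_TIL_BLOB, grid)
    lam = frac * grid * grid / (blob * blob)
    n_blobs = rng.poisson(lam)
    for _ in range(n_blobs):
        r = rng.integers(0, grid - blob + 1)
        c = rng.integers(0, grid - blob + 1)
        mask[r:r + blob, c:c + blob] = True
    return mask


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort; identical config + seed gives a bit-identical cohort."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_patients, cfg.latent_dim
    beta = np.asarray(cfg.beta, dtype=np.float64)

    # latent factors and sparse pathway loadings (pathway p loads on dim p % k)
    z = rng.standard_normal((n, k))
    pathway_dim = np.arange(cfg.n_pathways) % k
    activities = z[:, pathway_dim]                        # n x n_pathways
    causal_pathways = np.flatnonzero(beta[pathway_dim] != 0)

    # genes: round-robin pathway membership, positive loadings
    pathway_of_gene = np.arange(cfg.n_genes) % cfg.n_pathways
    loadings = rng.uniform(0.6, 1.4, size=cfg.n_genes)
    expression = (loadings * activities[:, pathway_of_gene]
                  + cfg.noise_sd * rng.standard_normal((n, cfg.n_genes)))
    causal_genes = np.flatnonzero(np.isin(pathway_of_gene, causal_pathways))

    # CpGs: round-robin gene mapping; beta values anti-correlated with expression
    gene_of_cpg = np.arange(cfg.n_cpgs) % cfg.n_genes
    logit = (-cfg.methylation_slope * expression[:, gene_of_cpg]
             + 0.5 * cfg.noise_sd * rng.standard_normal((n, cfg.n_cpgs)))
    methylation = 1.0 / (1.0 + np.exp(-logit))

    # slides: patch grid, TIL blobs, TIL + risk channels on the embeddings
    risk_score = z @ beta
    grid = cfg.grid_size
    rows, cols = np.meshgrid(np.arange(grid), np.arange(grid), indexing="ij")
    base_coords = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    slides, til_masks, til_burden = [], [], np.empty(n)
    for i in range(n):
        mask = _plant_til_mask(rng, grid, cfg.til_fraction)
        flat = mask.ravel()
        til_burden[i] = flat.mean()
        emb = cfg.noise_sd * rng.standard_normal((grid * grid, cfg.patch_embed_dim))
        emb[:, _TIL_CHANNEL] += _TIL_SIGNAL * flat
        emb[:, _RISK_CHANNEL] += _RISK_SIGNAL * risk_score[i]
        coords = base_coords
        if cfg.add_satellite:
            # detached 2x2 block well outside the main grid, no TILs
            off = grid + 5.0
            sat = np.array([[off, off], [off, off + 1], [off + 1, off], [off + 1, off + 1]])
            coords = np.vstack([base_coords, sat])
            emb = np.vstack([emb, cfg.noise_sd * rng.standard_normal((4, cfg.patch_embed_dim))])
        slides.append(PatchSet(slide_id=f"S{i:04d}", coords=coords, embeddings=emb))
        til_masks.append(flat)

    # survival: competing exponentials under proportional hazards
    eta = risk_score + cfg.til_effect * til_burden
    event_time = rng.exponential(1.0 / (cfg.baseline_hazard * np.exp(eta)))
    if cfg.censor_rate > 0:
        censor_time = rng.exponential(1.0 / cfg.censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    observed = np.maximum(np.minimum(event_time, censor_time), 1e-3)
    event = (event_time <= censor_time).astype(int)
    survival = SurvivalData(time=observed, event=event)

    gene_ids = [f"G{g:04d}" for g in range(cfg.n_genes)]
    cpg_ids = [f"cg{c:05d}" for c in range(cfg.n_cpgs)]
    pathway_ids = [f"PW{p:03d}" for p in range(cfg.n_pathways)]
    cpg_annotation = FeatureAnnotation(
        entries=[(cpg_ids[c], gene_ids[gene_of_cpg[c]]) for c in range(cfg.n_cpgs)],
        feature_order=cpg_ids, capsule_order=gene_ids)
    pathway_annotation = FeatureAnnotation(
        entries=[(gene_ids[g], pathway_ids[pathway_of_gene[g]]) for g in range(cfg.n_genes)],
        feature_order=gene_ids, capsule_order=pathway_ids)

    truth = CohortTruth(z=z, eta=eta, risk_score=risk_score, til_burden=til_burden,
                        causal_pathways=causal_pathways, causal_genes=causal_genes,
                        til_masks=til_masks, pathway_of_gene=pathway_of_gene,
                        gene_of_cpg=gene_of_cpg)
    return SyntheticCohort(config=cfg, expression=expression, methylation=methylation,
                           slides=slides, survival=survival,
                           cpg_annotation=cpg_annotation,
                           pathway_annotation=pathway_annotation, truth=truth,
                           gene_ids=gene_ids, cpg_ids=cpg_ids, pathway_ids=pathway_ids)


def censoring_fraction(cohort: SyntheticCohort) -> float:
    """Fraction of records whose event indicator is zero."""
    if len(cohort.survival) == 0:
        raise ValueError("empty cohort")
    return float(np.mean(cohort.survival.event == 0))
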