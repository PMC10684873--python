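"""Synthetic inputs for the pleiotropy-mapping pipeline.

Real inputs of this kind — gene-level GWAS Z-scores for regional cortical
phenotypes, subject-level morphometry, disorder GWAS summary statistics —
sit behind data-access agreements. This module generates stand-ins with the
statistical structure the downstream analysis assumes, together with a
ground-truth record so that recovery of planted signal is testable.

Generative models are deliberately linear-Gaussian so every downstream
statistic has a closed form usable as a test oracle:

* gene associations:  Z[i, g] = a_i * f_g + b_i * h_g(metric) + eps,
  disorder response:  y[g]    = c * f_g + eta,
  with f, h, eps, eta standard normal. The shared factor f carries the
  planted pleiotropy; genes in one chromosome band get inflated |f_g|.
* phenotypes: module factor loadings (modules), a region-strength gradient
  (hubs), a spatially correlated field with exponential distance decay, and
  iid noise.
* GWAS instruments: beta_out = beta_causal * beta_exp + alpha + e with
  directional-pleiotropy intercepts alpha ~ N(mean, tau^2).

All generators are byte-deterministic under a fixed master seed; each draws
from its own named substream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import rng_stream
from .datatypes import DisorderZVector, GeneZMatrix, ParcelGeometry, SyntheticTruth

__all__ = [
    "SyntheticConfig",
    "gen_parcellation",
    "gen_gene_annotations",
    "gen_gene_assoc",
    "gen_phenotypes",
    "gen_gwas_sumstats",
    "gen_expression_panels",
]

ATLAS_CLASS_LABELS = ("primary", "unimodal", "heteromodal", "paralimbic")
CELL_TYPES = ("ExN", "InN", "RG", "IPC", "Mic", "OPC")


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults are the desk-scale conditions.

    Desk scale (60 regions, 2,000 genes, 2,000 subjects) keeps the full
    pipeline, including exact leave-one-out refits, within minutes.
    """

    n_regions: int = 60
    n_genes: int = 2000
    n_subjects: int = 2000
    n_metrics: int = 3
    shared_loading_scale: float = 0.5   # strength a of the pleiotropic factor
    disorder_loading: float = 1.0       # c, loading of the disorder on f
    metric_loading_scale: float = 0.8   # b, metric-private factor strength
    module_count: int = 4
    module_loading: float = 1.0
    spatial_field_scale: float = 0.5
    distance_decay_rate: float = 1.0    # per unit chordal distance
    region_strength_spread: float = 0.5  # r_i ~ U(1-s, 1+s); hubs = high r_i
    noise_sd: float = 1.0
    planted_band: str = "chr17q21"
    band_inflation: float = 3.0
    constrained_prevalence: float = 0.15
    n_atlas_classes: int = 4
    mr_n_instruments: int = 50
    mr_causal_beta: float = 0.26
    mr_pleiotropy_mean: float = 0.0
    mr_pleiotropy_sd: float = 0.0
    mr_se_exp: float = 0.005
    mr_se_out: float = 0.01
    mr_palindromic_frac: float = 0.0
    mr_strand_flip_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_regions", "n_genes", "n_subjects", "n_metrics", "module_count"):
            if int(getattr(self, name)) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.n_regions < 4:
            raise ValueError("n_regions must be >= 4")
        if self.n_regions % 2:
            raise ValueError("n_regions must be even (two hemispheres)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.shared_loading_scale < 0 or self.distance_decay_rate < 0:
            raise ValueError("scales and rates must be >= 0")
        if self.mr_n_instruments < 2:
            raise ValueError("need at least 2 MR instruments")

    # -- shared latent structure ------------------------------------------
    def region_strengths(self) -> np.ndarray:
        """Per-region strength gradient r_i, shared by the gene-association
        and phenotype generators so that hub regions also carry the planted
        pleiotropic loadings."""
        rng = rng_stream(self.seed, "region-strength")
        s = self.region_strength_spread
        return rng.uniform(1.0 - s, 1.0 + s, size=self.n_regions)


def _sphere_points(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def gen_parcellation(config: SyntheticConfig) -> ParcelGeometry:
    """Spherical parcel centroids split evenly across two hemispheres.

    The right hemisphere mirrors the left across the sagittal plane, as in
    real bilaterally symmetric atlases (mirrored spin rotations rely on this
    correspondence). Atlas-class labels are assigned by nearest of a few
    random class seed directions, giving spatially contiguous, bilaterally
    symmetric label patches.
    """
    rng = rng_stream(config.seed, "parcellation")
    n = config.n_regions
    half = n // 2
    left = _sphere_points(rng, half)
    right = left @ np.diag([-1.0, 1.0, 1.0])  # sagittal mirror
    centroids = np.vstack([left, right])
    hemisphere = np.array(["L"] * half + ["R"] * half, dtype=object)
    parcel_ids = [f"{h}_{i:03d}" for i, h in enumerate(hemisphere)]

    k = min(config.n_atlas_classes, len(ATLAS_CLASS_LABELS))
    seeds = _sphere_points(rng, k)
    nearest_left = np.argmax(left @ seeds.T, axis=1)
    nearest = np.concatenate([nearest_left, nearest_left])  # symmetric labels
    classes = np.array([ATLAS_CLASS_LABELS[j] for j in nearest], dtype=object)
    return ParcelGeometry(
        parcel_ids=parcel_ids,
        hemisphere=hemisphere,
        centroids=centroids,
        atlas_class={"cytoarchitecture": classes},
    )


def module_assignment(config: SyntheticConfig, geometry: ParcelGeometry) -> np.ndarray:
    """Planted module labels: nearest of `module_count` seed directions."""
    rng = rng_stream(config.seed, "modules")
    seeds = _sphere_points(rng, config.module_count)
    nearest = np.argmax(geometry.centroids @ seeds.T, axis=1)
    return np.array([f"M{j + 1}" for j in nearest], dtype=object)


def region_structure(
    config: SyntheticConfig, geometry: ParcelGeometry
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared regional latent structure: (loadings, spatial root, module index).

    Both the phenotype generator and the metric-private part of the gene
    association generator draw on the same module loadings lambda_i =
    module_loading * r_i and the same spatial kernel root L (covariance
    exp(-rate * chordal distance)). Sharing this structure is what plants
    the structural-covariance / genetic-similarity network coupling the
    analysis is designed to detect.
    """
    modules = module_assignment(config, geometry)
    labels = sorted(set(modules))
    mod_idx = np.array([labels.index(m) for m in modules])
    lam = config.module_loading * config.region_strengths()
    chord = np.linalg.norm(
        geometry.centroids[:, None, :] - geometry.centroids[None, :, :], axis=-1
    )
    K = np.exp(-config.distance_decay_rate * chord) + 1e-8 * np.eye(config.n_regions)
    L = np.linalg.cholesky(K)
    return lam, L, mod_idx


def gen_gene_annotations(config: SyntheticConfig) -> pd.DataFrame:
    """Gene annotation table: chromosome, band, positions, length, constraint.

    Bands partition the gene universe; one band (``config.planted_band``)
    later receives the positionally clustered pleiotropic genes. Lengths are
    log-normal, mimicking the heavy right tail of real gene lengths.
    """
    rng = rng_stream(config.seed, "annotations")
    g = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(g)]
    chroms = np.array([f"chr{1 + i % 22}" for i in range(g)])
    # ~40 genes per band, bands nested within chromosome
    band_size = max(5, min(40, g // 25))
    bands = np.array(
        [f"{chroms[i]}q{1 + (i // 22) // band_size}" for i in range(g)], dtype=object
    )
    # relabel one band as the planted band so it always exists
    target = bands == bands[0]
    bands[target] = config.planted_band
    lengths = np.maximum(200, rng.lognormal(mean=10.0, sigma=1.0, size=g)).astype(int)
    starts = rng.integers(1, 200_000_000, size=g)
    ends = starts + lengths - 1
    constrained = rng.random(g) < config.constrained_prevalence
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": chroms,
            "band": bands,
            "start": starts,
            "end": ends,
            "length": lengths,
            "log_length": np.log(lengths.astype(float)),
            "constrained": constrained,
        }
    )


def gen_gene_assoc(
    config: SyntheticConfig,
    geometry: ParcelGeometry,
    annotations: pd.DataFrame,
) -> tuple[list[GeneZMatrix], DisorderZVector, SyntheticTruth]:
    """Region x gene Z matrices per metric plus the aligned disorder vector.

    Planted structure: a_i = shared_loading_scale * r_i with r_i the region
    strength gradient; genes in the planted band have |f_g| inflated by
    ``band_inflation`` so top pleiotropic genes cluster positionally.
    """
    if geometry.n_parcels != config.n_regions:
        raise ValueError("geometry inconsistent with config")
    if len(annotations) != config.n_genes:
        raise ValueError("annotation table misaligned with config gene universe")
    rng = rng_stream(config.seed, "gene-assoc")
    R, G = config.n_regions, config.n_genes
    gene_ids = list(annotations["gene_id"])

    f = rng.normal(size=G)
    in_band = (annotations["band"] == config.planted_band).to_numpy()
    f[in_band] *= config.band_inflation

    r_i = config.region_strengths()
    a = config.shared_loading_scale * r_i
    c = config.disorder_loading

    _, L, mod_idx = region_structure(config, geometry)
    n_modules = mod_idx.max() + 1
    metrics = []
    for m in range(config.n_metrics):
        # metric-private structure mirrors the phenotype latent model (same
        # modules and spatial kernel, independent gene factors) so genetic
        # similarity and structural covariance share population network
        # structure; the hub gradient r_i enters the genetic side only via
        # the pleiotropic loadings a_i, otherwise it would inflate hub
        # regions' private variance and mask their planted pleiotropy
        s = config.metric_loading_scale
        h_mod = rng.normal(size=(G, n_modules))
        h_spat = rng.normal(size=(G, R)) @ L.T
        eps = rng.normal(scale=config.noise_sd, size=(R, G))
        z = (
            np.outer(a, f)
            + s * config.module_loading * h_mod[:, mod_idx].T
            + s * config.spatial_field_scale * h_spat.T
            + eps
        )
        metrics.append(
            GeneZMatrix(metric_id=f"metric{m + 1}", region_ids=list(geometry.parcel_ids),
                        gene_ids=gene_ids, z=z)
        )
    y = c * f + rng.normal(scale=config.noise_sd, size=G)
    disorder = DisorderZVector("disorder", gene_ids, y)
    truth = SyntheticTruth(
        region_shared_loadings=a,
        disorder_loading=c,
        pleiotropic_gene_ids=list(annotations.loc[in_band, "gene_id"]),
        module_assignment={
            p: str(m) for p, m in zip(geometry.parcel_ids, module_assignment(config, geometry))
        },
        mr_causal_beta=config.mr_causal_beta,
    )
    return metrics, disorder, truth


def gen_phenotypes(
    config: SyntheticConfig, geometry: ParcelGeometry
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Subject x region phenotype tables, one per metric.

    Latent-factor model: each region loads module_loading * r_i on its
    module's factor (planting modules and hubs), plus a spatially correlated
    Gaussian field whose covariance decays as exp(-rate * chordal distance)
    (planting distance decay in the implied structural covariance), plus
    iid noise.
    """
    if config.n_subjects < 10:
        raise ValueError("need at least 10 subjects")
    rng = rng_stream(config.seed, "phenotypes")
    n, R = config.n_subjects, config.n_regions
    modules = module_assignment(config, geometry)
    lam, L, mod_idx = region_structure(config, geometry)

    tables: dict[str, pd.DataFrame] = {}
    for m in range(config.n_metrics):
        gmod = rng.normal(size=(n, mod_idx.max() + 1))
        fielded = rng.normal(size=(n, R)) @ L.T
        noise = rng.normal(scale=config.noise_sd, size=(n, R))
        pheno = gmod[:, mod_idx] * lam + config.spatial_field_scale * fielded + noise
        tables[f"metric{m + 1}"] = pd.DataFrame(
            pheno,
            index=[f"S{i:05d}" for i in range(n)],
            columns=geometry.parcel_ids,
        )
    truth = SyntheticTruth(
        module_assignment={p: str(m) for p, m in zip(geometry.parcel_ids, modules)}
    )
    return tables, truth


_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def gen_gwas_sumstats(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Exposure and outcome per-SNP GWAS summary tables for two-sample MR.

    Outcome model: beta_out = mr_causal_beta * beta_exp_true + alpha + e,
    alpha ~ N(mr_pleiotropy_mean, mr_pleiotropy_sd^2). Instruments sit in
    well-separated LD blocks; fractions of palindromic SNPs and strand flips
    in the outcome table are configurable for harmonization testing.
    """
    if config.mr_n_instruments < 5:
        raise ValueError("request at least 5 instruments for a powered MR analysis")
    rng = rng_stream(config.seed, "gwas")
    J = config.mr_n_instruments
    snp_ids = [f"rs{100000 + j}" for j in range(J)]
    chrom = np.array([1 + j % 22 for j in range(J)])
    pos = np.array([1_000_000 + 25_000_000 * (j // 22) for j in range(J)])
    ld_block = np.array([f"blk{j}" for j in range(J)])

    beta_true = rng.uniform(0.03, 0.10, size=J) * rng.choice([-1.0, 1.0], size=J)
    se_exp = np.full(J, config.mr_se_exp)
    beta_exp = beta_true + rng.normal(scale=se_exp)
    alpha = rng.normal(config.mr_pleiotropy_mean, max(config.mr_pleiotropy_sd, 0.0), size=J)
    se_out = np.full(J, config.mr_se_out)
    beta_out = config.mr_causal_beta * beta_true + alpha + rng.normal(scale=se_out)

    eaf = rng.uniform(0.05, 0.95, size=J)
    ea, oa = [], []
    n_pal = int(round(config.mr_palindromic_frac * J))
    for j in range(J):
        if j < n_pal:
            pair = ("A", "T") if rng.random() < 0.5 else ("C", "G")
        else:
            pair = tuple(rng.choice(_BASES, size=2, replace=False))
            while pair[0] == _COMPLEMENT[pair[1]]:
                pair = tuple(rng.choice(_BASES, size=2, replace=False))
        ea.append(pair[0])
        oa.append(pair[1])

    def _table(beta, se, n_samples):
        z = beta / se
        return pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": chrom,
                "pos": pos,
                "ld_block": ld_block,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "p": 2.0 * stats.norm.sf(np.abs(z)),
                "n": n_samples,
            }
        )

    exposure = _table(beta_exp, se_exp, 30_000)
    outcome = _table(beta_out, se_out, 300_000)

    # optional strand flips in the outcome table (alleles complemented,
    # effect unchanged) to exercise harmonization
    n_flip = int(round(config.mr_strand_flip_frac * J))
    flip_idx = rng.choice(J, size=n_flip, replace=False) if n_flip else []
    for j in flip_idx:
        outcome.loc[j, "effect_allele"] = _COMPLEMENT[outcome.loc[j, "effect_allele"]]
        outcome.loc[j, "other_allele"] = _COMPLEMENT[outcome.loc[j, "other_allele"]]

    truth = SyntheticTruth(mr_causal_beta=config.mr_causal_beta)
    return exposure, outcome, truth


def gen_expression_panels(
    config: SyntheticConfig,
    annotations: pd.DataFrame,
    target_genes: Sequence[str] | None = None,
    peak_window: int = 4,
    enriched_celltype: str = "RG",
    samples_per_window: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Developmental (9-window) and cell-type expression panels.

    Target genes (default: the planted pleiotropic band) get a log-scale
    expression bump peaking at ``peak_window`` in the developmental panel
    and doubled relative expression in ``enriched_celltype`` in the
    cell-type panel. Returns (dev_panel, dev_metadata, celltype_panel):
    panels are gene x sample / gene x cell-type, non-negative.
    """
    rng = rng_stream(config.seed, "expression")
    gene_ids = list(annotations["gene_id"])
    if target_genes is None:
        target_genes = list(
            annotations.loc[annotations["band"] == config.planted_band, "gene_id"]
        )
    is_target = annotations["gene_id"].isin(set(target_genes)).to_numpy()

    windows = np.repeat(np.arange(1, 10), samples_per_window)
    regions = np.array([f"ctx{(i % samples_per_window) + 1}" for i in range(windows.size)])
    sample_ids = [f"w{w}_s{i}" for i, w in enumerate(windows)]
    base = rng.lognormal(mean=2.0, sigma=0.5, size=len(gene_ids))
    bump = np.exp(-0.5 * ((windows - peak_window) / 1.2) ** 2)  # per sample
    expr = np.outer(base, np.ones(windows.size))
    expr[is_target] *= 1.0 + 2.0 * bump  # multiplicative peak for targets
    expr *= rng.lognormal(mean=0.0, sigma=0.2, size=expr.shape)
    dev_panel = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)
    dev_meta = pd.DataFrame({"sample_id": sample_ids, "window": windows, "region": regions})

    ct_expr = np.outer(base, np.ones(len(CELL_TYPES)))
    ct_idx = CELL_TYPES.index(enriched_celltype)
    ct_expr[is_target, ct_idx] *= 2.0
    ct_expr *= rng.lognormal(mean=0.0, sigma=0.1, size=ct_expr.shape)
    ct_panel = pd.DataFrame(ct_expr, index=gene_ids, columns=list(CELL_TYPES))
    return dev_panel, dev_meta, ct_panel
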