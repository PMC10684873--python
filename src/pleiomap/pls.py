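"""PLS1 covariation between regional gene-Z profiles and a disorder Z vector.

With a univariate response, the first partial-least-squares component has a
closed form: after z-scoring columns over genes, the region weight vector is
w_x = X'y / ||X'y||, so it is computed directly rather than iteratively (the
iterative NIPALS solution coincides for one component). Per-gene scores are
T = X w_x and U = y w_y; R(T, U) is their (by default rank) correlation, and
the leave-one-out influence of gene g is

    delta_g = R(T, U) - R_loo(T, U)

where R_loo is recomputed after dropping gene g from X and y and
re-standardizing. Genes with the largest positive delta contribute most to
the genome-wide brain-disorder covariation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._utils import bh_fdr, rng_stream
from .datatypes import DisorderZVector, GeneZMatrix

__all__ = [
    "PLSModel",
    "PLSInference",
    "LOOInfluence",
    "fit_pls1",
    "varexp_perm_test",
    "bootstrap_weights",
    "tu_correlation",
    "loo_influence",
    "top_pleiotropic",
]


@dataclass
class PLSModel:
    region_ids: list[str]
    gene_ids: list[str]
    w_x: np.ndarray          # per-region weights, unit norm
    w_y: float               # scalar response weight, > 0
    t_scores: np.ndarray     # per-gene T = X w_x
    u_scores: np.ndarray     # per-gene U = y w_y
    varexp_y: float          # corr(T, y)^2
    standardized: bool


@dataclass
class PLSInference:
    perm_p: float | None = None
    n_perm: int = 0
    boot_z: np.ndarray | None = None
    boot_se: np.ndarray | None = None
    fdr_significant: np.ndarray | None = None
    n_boot: int = 0


@dataclass
class LOOInfluence:
    gene_ids: list[str]
    r_tu: float
    r_tu_method: str
    delta: np.ndarray

    def top_sets(self, percents: tuple[float, ...] = (1.0, 3.0)) -> dict[float, set[str]]:
        return {p: top_pleiotropic(self, p) for p in percents}


def _as_xy(
    X: np.ndarray | GeneZMatrix, y: np.ndarray | DisorderZVector
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Coerce inputs to (genes x regions X, gene vector y) with aligned IDs.

    A GeneZMatrix is stored regions x genes and is transposed here.
    """
    if isinstance(X, GeneZMatrix):
        region_ids, gene_ids = list(X.region_ids), list(X.gene_ids)
        Xm = X.z.T.copy()
    else:
        Xm = np.array(X, dtype=float)
        gene_ids = [f"g{i}" for i in range(Xm.shape[0])]
        region_ids = [f"r{j}" for j in range(Xm.shape[1])]
    if isinstance(y, DisorderZVector):
        yv = y.align_to(gene_ids).z.copy() if gene_ids != y.gene_ids else y.z.copy()
        if Xm.shape[0] != yv.size:
            raise ValueError("gene universes misaligned between X and y")
    else:
        yv = np.array(y, dtype=float).ravel()
        if Xm.shape[0] != yv.size:
            raise ValueError("X rows and y length differ")
    return Xm, yv, region_ids, gene_ids


def _standardize_cols(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    return mu, sd


def _fit_core(Xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, float, np.ndarray, np.ndarray, float]:
    """PLS1 on pre-standardized data. Returns (w_x, w_y, T, U, varexp)."""
    cross = Xs.T @ ys
    nrm = np.linalg.norm(cross)
    if nrm < 1e-12:
        raise ValueError("degenerate response: X'y numerically zero")
    w_x = cross / nrm
    w_y = 1.0
    T = Xs @ w_x
    U = ys * w_y
    # orient so corr(T, U) >= 0 (automatic for the closed form, kept for safety)
    tu = float(np.dot(T - T.mean(), U - U.mean()))
    if tu < 0:
        w_x, T = -w_x, -T
    r = float(np.corrcoef(T, ys)[0, 1])
    return w_x, w_y, T, U, r * r


def fit_pls1(
    X: np.ndarray | GeneZMatrix,
    y: np.ndarray | DisorderZVector,
    standardize: bool = True,
) -> PLSModel:
    """Fit the first PLS component of genes x regions X against gene vector y.

    With ``standardize`` (default) both X columns and y are z-scored over
    genes before fitting. Zero-variance region columns are dropped with a
    warning. ``varexp_y`` is the squared Pearson correlation of T with y —
    the fraction of response variance the component explains.
    """
    Xm, yv, region_ids, gene_ids = _as_xy(X, y)
    if Xm.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    mu, sd = _standardize_cols(Xm)
    keep = sd > 0
    if not np.all(keep):
        dropped = [region_ids[j] for j in np.flatnonzero(~keep)]
        warnings.warn(f"dropping zero-variance region columns: {dropped}")
        Xm = Xm[:, keep]
        region_ids = [r for r, k in zip(region_ids, keep) if k]
        mu, sd = mu[keep], sd[keep]
    if standardize:
        Xs = (Xm - mu) / sd
        ysd = yv.std(ddof=1)
        if ysd == 0:
            raise ValueError("response has zero variance")
        ys = (yv - yv.mean()) / ysd
    else:
        Xs, ys = Xm, yv
    w_x, w_y, T, U, varexp = _fit_core(Xs, ys)
    return PLSModel(
        region_ids=region_ids,
        gene_ids=gene_ids,
        w_x=w_x,
        w_y=w_y,
        t_scores=T,
        u_scores=U,
        varexp_y=varexp,
        standardized=standardize,
    )


def varexp_perm_test(
    X: np.ndarray | GeneZMatrix,
    y: np.ndarray | DisorderZVector,
    n_perm: int = 1000,
    seed: int = 0,
    standardize: bool = True,
) -> PLSInference:
    """Permutation test of PLS1 variance explained.

    y is permuted over genes (breaking any gene-wise pairing with X,
    preserving its marginal distribution), the model refit, and the
    empirical upper-tail p reported with +1 smoothing.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    Xm, yv, *_ = _as_xy(X, y)
    obs = fit_pls1(Xm, yv, standardize=standardize).varexp_y
    rng = rng_stream(seed, "pls-perm")
    null = np.empty(n_perm)
    for t in range(n_perm):
        null[t] = fit_pls1(Xm, rng.permutation(yv), standardize=standardize).varexp_y
    p = (1.0 + np.sum(null >= obs)) / (n_perm + 1.0)
    return PLSInference(perm_p=float(p), n_perm=n_perm)


def bootstrap_weights(
    X: np.ndarray | GeneZMatrix,
    y: np.ndarray | DisorderZVector,
    n_boot: int = 1000,
    seed: int = 0,
    q: float = 0.05,
    standardize: bool = True,
    max_retries: int = 50,
) -> PLSInference:
    """Bootstrap (over genes) Z-scores for PLS1 region weights.

    Replicate weight vectors are sign-aligned to the point estimate before
    the SE is taken; boot_z = w_x / SE, with BH-FDR flags at ``q`` on the
    two-sided normal p-values.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    Xm, yv, *_ = _as_xy(X, y)
    point = fit_pls1(Xm, yv, standardize=standardize)
    G = Xm.shape[0]
    rng = rng_stream(seed, "pls-boot")
    reps = np.empty((n_boot, point.w_x.size))
    for b in range(n_boot):
        for attempt in range(max_retries):
            idx = rng.integers(0, G, size=G)
            try:
                m = fit_pls1(Xm[idx], yv[idx], standardize=standardize)
            except ValueError:
                continue
            if m.w_x.size != point.w_x.size:  # a column went constant
                continue
            w = m.w_x if np.dot(m.w_x, point.w_x) >= 0 else -m.w_x
            reps[b] = w
            break
        else:
            raise RuntimeError("too many degenerate bootstrap replicates")
    se = reps.std(axis=0, ddof=1)
    boot_z = point.w_x / se
    pvals = 2.0 * stats.norm.sf(np.abs(boot_z))
    flags = bh_fdr(pvals) < q
    return PLSInference(boot_z=boot_z, boot_se=se, fdr_significant=flags, n_boot=n_boot)


def tu_correlation(model: PLSModel, method: str = "spearman") -> float:
    """Correlation R(T, U) between per-gene T and U scores."""
    T, U = model.t_scores, model.u_scores
    if np.ptp(T) == 0 or np.ptp(U) == 0:
        raise ValueError("constant scores: correlation undefined")
    if method == "spearman":
        return float(stats.spearmanr(T, U).statistic)
    if method == "pearson":
        return float(stats.pearsonr(T, U).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def _r_tu(Xs: np.ndarray, ys: np.ndarray, method: str) -> float:
    w_x, _, T, U, _ = _fit_core(Xs, ys)
    if method == "spearman":
        return float(stats.spearmanr(T, U).statistic)
    return float(stats.pearsonr(T, U).statistic)


def loo_influence(
    X: np.ndarray | GeneZMatrix,
    y: np.ndarray | DisorderZVector,
    method: str = "spearman",
    standardize: bool = True,
) -> LOOInfluence:
    """Leave-one-out influence delta_g = R(T,U) - R_loo(T,U) for every gene.

    Each gene is dropped in turn, columns re-standardized over the remaining
    genes, the component refit, and R(T,U) recomputed on the remaining
    genes. This exact refit is the reference implementation.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    Xm, yv, _, gene_ids = _as_xy(X, y)
    G = Xm.shape[0]
    if G < 10:
        raise ValueError("need at least 10 genes for leave-one-out analysis")

    def _std(M, v):
        if not standardize:
            return M, v
        Ms = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
        vs = (v - v.mean()) / v.std(ddof=1)
        return Ms, vs

    Xs, ys = _std(Xm, yv)
    r_full = _r_tu(Xs, ys, method)
    delta = np.empty(G)
    mask = np.ones(G, dtype=bool)
    for g in range(G):
        mask[g] = False
        Xs_g, ys_g = _std(Xm[mask], yv[mask])
        delta[g] = r_full - _r_tu(Xs_g, ys_g, method)
        mask[g] = True
    return LOOInfluence(gene_ids=gene_ids, r_tu=r_full, r_tu_method=method, delta=delta)


def top_pleiotropic(influence: LOOInfluence, percent: float) -> set[str]:
    """Top ``percent``% of genes by descending delta; size = floor(pct/100 * G).

    Ties are broken lexicographically by gene ID so the set is invariant to
    input order.
    """
    if not 0.0 < percent < 100.0:
        raise ValueError("percent must be in (0, 100)")
    G = len(influence.gene_ids)
    k = int(np.floor(percent / 100.0 * G))
    if k < 1:
        raise ValueError(f"percent {percent} yields an empty set for G={G}")
    order = sorted(
        range(G), key=lambda i: (-influence.delta[i], influence.gene_ids[i])
    )
    return {influence.gene_ids[i] for i in order[:k]}
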