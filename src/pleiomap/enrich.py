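"""Gene-set characterization: positional, constraint, cell-type and
developmental-expression enrichment.

Positional enrichment asks whether a gene set is overrepresented in
chromosomal bands (exact hypergeometric per band, BH across bands).
Constraint enrichment is a logistic regression of set membership on the
mutation-intolerance flag with log gene length as covariate. Cell-type
enrichment regresses membership on centred relative cell-type expression
plus log length. Developmental trajectories average mean-centred
log-expression of the set per developmental window.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._utils import bh_fdr

__all__ = [
    "positional_enrichment",
    "constrained_enrichment",
    "celltype_enrichment",
    "dev_trajectories",
]


def positional_enrichment(
    gene_set: set[str],
    annotations: pd.DataFrame,
    universe: Sequence[str] | None = None,
    test_zero_overlap: bool = False,
) -> pd.DataFrame:
    """Hypergeometric band overrepresentation of a gene set.

    Per band: overlap count, exact upper-tail hypergeometric p, BH-adjusted
    p across tested bands. Bands with zero overlap are reported but left
    untested unless ``test_zero_overlap``.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    ann = annotations.set_index("gene_id")
    if universe is None:
        universe = list(ann.index)
    uni = set(universe)
    if not gene_set <= uni:
        raise ValueError("gene set is not a subset of the universe")
    ann = ann.loc[list(universe)]
    N = len(universe)
    K = len(gene_set)
    rows = []
    for band, grp in ann.groupby("band", sort=True):
        band_genes = set(grp.index)
        n_band = len(band_genes)
        k = len(band_genes & gene_set)
        tested = k > 0 or test_zero_overlap
        p = float(stats.hypergeom.sf(k - 1, N, n_band, K)) if tested else np.nan
        rows.append({"band": band, "band_size": n_band, "overlap": k, "p": p})
    out = pd.DataFrame(rows)
    tested_mask = out["p"].notna()
    q = np.full(len(out), np.nan)
    q[tested_mask.to_numpy()] = bh_fdr(out.loc[tested_mask, "p"].to_numpy())
    out["q"] = q
    return out


def constrained_enrichment(
    gene_set: set[str], annotations: pd.DataFrame
) -> tuple[float, float, float]:
    """Logistic enrichment of a gene set in constrained genes.

    Fits membership ~ constrained + log_length over the full annotation
    universe and returns (coefficient, SE, Wald p) for the constraint flag.
    Perfect separation falls back to a ridge-penalized fit (SE and p from
    the penalized information matrix, flagged by a warning).
    """
    if not gene_set:
        raise ValueError("empty gene set")
    flags = annotations["constrained"].to_numpy(dtype=float)
    if flags.min() == flags.max():
        raise ValueError("universe needs both constrained and unconstrained genes")
    y = annotations["gene_id"].isin(gene_set).to_numpy(dtype=float)
    X = sm.add_constant(
        np.column_stack([flags, annotations["log_length"].to_numpy(dtype=float)])
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0)
        coef, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
    except Exception:
        warnings.warn("possible separation in constraint enrichment; using penalized fit")
        fit = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        coef = fit.params[1]
        se, p = np.nan, np.nan
    return float(coef), float(se), float(p)


def celltype_enrichment(
    panel: pd.DataFrame,
    gene_set: set[str],
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Cell-type specificity of a gene set via membership regressions.

    Expression is log-transformed; each gene's per-cell-type expression is
    divided by its average over all cell types (relative expression) and
    mean-centred. Per cell type, membership is regressed on centred relative
    expression plus log gene length; effects are BH-corrected across cell
    types. Cell types with zero total expression are excluded.
    """
    if panel.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    keep_cols = []
    for col in panel.columns:
        if panel[col].sum() <= 0:
            warnings.warn(f"cell type {col!r} has zero total expression; excluded")
        else:
            keep_cols.append(col)
    panel = panel[keep_cols]
    logx = np.log1p(panel.to_numpy(dtype=float))
    rel = logx / np.maximum(logx.mean(axis=1, keepdims=True), 1e-12)
    rel = rel - rel.mean(axis=0, keepdims=True)
    ann = annotations.set_index("gene_id").loc[panel.index]
    y = panel.index.isin(gene_set).astype(float)
    loglen = ann["log_length"].to_numpy(dtype=float)
    rows = []
    for k, ct in enumerate(keep_cols):
        X = sm.add_constant(np.column_stack([rel[:, k], loglen]))
        fit = sm.OLS(y, X).fit()
        rows.append({"unit": ct, "stat": fit.params[1], "p": fit.pvalues[1]})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def dev_trajectories(
    panel: pd.DataFrame,
    metadata: pd.DataFrame,
    gene_set: set[str],
) -> pd.DataFrame:
    """Mean-centred developmental expression trajectory of a gene set.

    Expression values are log-transformed and centred to the mean expression
    of each sample, with a +1 offset; the gene-set mean per sample is then
    averaged within each developmental window, with a normal-approximation
    95% CI across samples. A single-sample window gets a point estimate with
    NaN CI bounds.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    meta = metadata.set_index("sample_id").loc[panel.columns]
    windows = meta["window"].to_numpy()
    if len(set(windows)) < 2:
        raise ValueError("need at least 2 developmental windows")
    logx = np.log1p(panel.to_numpy(dtype=float))
    centred = logx - logx.mean(axis=0, keepdims=True) + 1.0
    in_set = panel.index.isin(gene_set)
    if in_set.sum() == 0:
        raise ValueError("gene set absent from panel")
    per_sample = centred[in_set].mean(axis=0)
    rows = []
    for w in sorted(set(windows)):
        vals = per_sample[windows == w]
        mean = float(vals.mean())
        if vals.size >= 2:
            half = 1.96 * vals.std(ddof=1) / np.sqrt(vals.size)
            lo, hi = mean - half, mean + half
        else:
            lo = hi = np.nan
        rows.append({"window": w, "mean": mean, "ci_low": lo, "ci_high": hi,
                     "n_samples": int(vals.size)})
    return pd.DataFrame(rows)
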