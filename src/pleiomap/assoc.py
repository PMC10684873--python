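"""Gene-level significance: effective tests, Bonferroni thresholds, set overlap.

Gene-level GWAS Z-scores are tested per region at a Bonferroni threshold of
alpha / (n_genes * N_pheno), where N_pheno is the effective number of
independent regional phenotypes estimated from the eigenvalues of the
inter-regional phenotype correlation matrix. Significant gene sets are then
intersected across metrics and compared against a disorder gene set with
exact hypergeometric and permutation overlap tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import rng_stream
from .datatypes import GeneZMatrix

__all__ = [
    "effective_tests",
    "bonferroni_threshold",
    "significant_genes",
    "set_intersections",
    "overlap_test",
    "SignificanceResult",
    "OverlapResult",
]


@dataclass
class SignificanceResult:
    m_eff: int
    alpha: float
    threshold: float
    per_region_sets: dict[str, set[str]]
    aggregate_set: set[str]
    counts: dict[str, int]

    @property
    def n_associations(self) -> int:
        """Total gene-region associations (with multiplicity across regions)."""
        return sum(self.counts.values())

    def to_frame(self, zmat: GeneZMatrix) -> pd.DataFrame:
        """Long-format significance table (region_id, gene_id, z, p, significant)."""
        p = zmat.two_sided_p()
        rows = []
        for i, rid in enumerate(zmat.region_ids):
            sig = self.per_region_sets.get(rid, set())
            for j, gid in enumerate(zmat.gene_ids):
                if gid in sig:
                    rows.append((rid, gid, zmat.z[i, j], p[i, j], True))
        return pd.DataFrame(rows, columns=["region_id", "gene_id", "z", "p", "significant"])


@dataclass
class OverlapResult:
    overlap_count: int
    expected_overlap: float
    hypergeometric_p: float
    perm_z: float
    perm_p: float
    n_perm: int


def effective_tests(pheno_corr: np.ndarray, method: str = "li_ji") -> int:
    """Effective number of independent phenotypes from a correlation matrix.

    The default estimator scores each eigenvalue lambda as
    f(lambda) = 1[lambda >= 1] + (lambda - floor(lambda)) and sums, then
    rounds to the nearest integer; ``method='nyholt'`` selects the
    Nyholt-style variance-of-eigenvalues estimator instead. Both lie in
    [1, R] and return R for the identity matrix, 1 for a rank-one matrix.
    """
    C = np.asarray(pheno_corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    R = C.shape[0]
    lam = np.linalg.eigvalsh((C + C.T) / 2.0)
    if lam.min() < -1e-8:
        raise ValueError("correlation matrix is not positive semi-definite")
    lam = np.clip(lam, 0.0, None)
    # the floor in the Li-Ji score is unstable at integer eigenvalues
    # (e.g. 6 - 1e-15 has fractional part ~1); round away solver noise
    lam = np.round(lam, 10)
    if method == "li_ji":
        score = (lam >= 1).astype(float) + (lam - np.floor(lam))
        m = float(np.sum(score))
    elif method == "nyholt":
        m = 1.0 + (R - 1.0) * (1.0 - np.var(lam, ddof=0) / R)
    else:
        raise ValueError(f"unknown estimator {method!r}")
    return int(min(max(round(m), 1), R))


def bonferroni_threshold(alpha: float, n_genes: int, m_eff: int) -> float:
    """Per-test significance threshold alpha / (n_genes * m_eff)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_genes < 1 or m_eff < 1:
        raise ValueError("counts must be >= 1")
    return alpha / (n_genes * m_eff)


def significant_genes(
    zmat: GeneZMatrix,
    threshold: float,
    alpha: float = 0.05,
    m_eff: int = 1,
) -> SignificanceResult:
    """Per-region significant gene sets at strict two-sided p < threshold.

    ``alpha`` and ``m_eff`` are recorded for provenance; the decision rule
    uses only ``threshold``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    p = zmat.two_sided_p()
    sig = p < threshold  # strict: boundary ties are not significant
    genes = np.asarray(zmat.gene_ids, dtype=object)
    per_region = {
        rid: set(genes[sig[i]]) for i, rid in enumerate(zmat.region_ids)
    }
    aggregate: set[str] = set().union(*per_region.values()) if per_region else set()
    counts = {rid: int(sig[i].sum()) for i, rid in enumerate(zmat.region_ids)}
    return SignificanceResult(
        m_eff=m_eff,
        alpha=alpha,
        threshold=threshold,
        per_region_sets=per_region,
        aggregate_set=aggregate,
        counts=counts,
    )


def set_intersections(sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Venn-diagram decomposition of up to 6 gene sets.

    Returns one row per non-empty membership pattern plus, per set, the
    number and percentage (nearest percent) of its genes that are specific
    to it alone.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    if len(names) > 6:
        raise ValueError("more than 6 sets unsupported")
    rows = []
    for k in range(1, len(names) + 1):
        for members in combinations(names, k):
            inside = set.intersection(*(sets[m] for m in members))
            outside = set().union(*(sets[m] for m in names if m not in members)) if k < len(names) else set()
            exclusive = inside - outside
            rows.append(
                {
                    "members": "&".join(members),
                    "n_sets": k,
                    "count": len(exclusive),
                }
            )
    table = pd.DataFrame(rows)
    specific = {}
    for name in names:
        only = table.loc[(table["members"] == name), "count"].iloc[0]
        total = len(sets[name])
        specific[name] = {
            "set": name,
            "size": total,
            "specific_count": int(only),
            "specific_percent": int(round(100.0 * only / total)) if total else 0,
        }
    table.attrs["specific"] = pd.DataFrame(specific.values())
    return table


def overlap_test(
    set_a: set[str],
    set_b: set[str],
    universe: Sequence[str] | set[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> OverlapResult:
    """Overlap of two gene sets: exact hypergeometric + permutation null.

    The permutation null redraws set B uniformly from the universe and
    reports Z = (observed - null mean) / null sd and the smoothed empirical
    upper-tail p. The hypergeometric p is the exact upper tail
    P(overlap >= observed).
    """
    universe = list(universe)
    N = len(universe)
    uni = set(universe)
    if not set_a or not set_b:
        raise ValueError("empty gene set")
    if not (set_a <= uni and set_b <= uni):
        raise ValueError("sets must be subsets of the universe")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ka, kb = len(set_a), len(set_b)
    obs = len(set_a & set_b)
    expected = ka * kb / N
    # upper tail P(X >= obs) for X ~ Hypergeom(N, ka, kb)
    hyper_p = float(stats.hypergeom.sf(obs - 1, N, ka, kb))

    rng = rng_stream(seed, "overlap-perm")
    arr = np.asarray(universe, dtype=object)
    in_a = np.isin(arr, list(set_a))
    null = np.empty(n_perm)
    for t in range(n_perm):
        draw = rng.choice(N, size=kb, replace=False)
        null[t] = in_a[draw].sum()
    sd = null.std(ddof=1)
    perm_z = (obs - null.mean()) / sd if sd > 0 else np.inf
    perm_p = (1.0 + np.sum(null >= obs)) / (n_perm + 1.0)
    return OverlapResult(
        overlap_count=obs,
        expected_overlap=expected,
        hypergeometric_p=hyper_p,
        perm_z=float(perm_z),
        perm_p=float(perm_p),
        n_perm=n_perm,
    )
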