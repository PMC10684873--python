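"""Structural covariance (SC) and genetic similarity (GS) networks.

SC is the region x region correlation of a phenotype over subjects; GS is
the region x region Spearman correlation of gene-level association
profiles. The two matrices are compared edge-wise, hierarchically (via
cophenetic correlation of Ward dendrograms with a label-permutation null),
and modularly (Louvain communities, weighted degree, intra/inter-modular
degree). Hubness (weighted degree) is related to regional PLS1 weights with
a spatial spin null.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

from ._utils import empirical_p, rng_stream, upper_triangle
from .datatypes import GeneZMatrix, ParcelGeometry, SymmetricNetwork

__all__ = [
    "ModulePartition",
    "NodeDegreeProfile",
    "structural_covariance",
    "genetic_similarity",
    "edgewise_coupling",
    "distance_adjusted_coupling",
    "cophenetic_test",
    "louvain_modules",
    "degree_profile",
    "hub_pleiotropy_coupling",
]


@dataclass
class ModulePartition:
    node_ids: list[str]
    labels: np.ndarray  # per-node module label
    modularity: float

    def as_dict(self) -> dict[str, str]:
        return {n: str(l) for n, l in zip(self.node_ids, self.labels)}


@dataclass
class NodeDegreeProfile:
    node_ids: list[str]
    degree: np.ndarray
    intra_modular: np.ndarray
    inter_modular: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "degree": self.degree,
                "intra_modular": self.intra_modular,
                "inter_modular": self.inter_modular,
            }
        )


def structural_covariance(
    phenotypes: pd.DataFrame, method: str = "pearson", metric_id: str = ""
) -> SymmetricNetwork:
    """Region x region correlation of regional phenotypes over subjects."""
    if phenotypes.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    X = phenotypes.to_numpy(dtype=float)
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = [phenotypes.columns[j] for j in np.flatnonzero(sds == 0)]
        raise ValueError(f"degenerate phenotype (constant over subjects): {bad}")
    if method == "pearson":
        W = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        ranks = stats.rankdata(X, axis=0)
        W = np.corrcoef(ranks, rowvar=False)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 1.0)
    return SymmetricNetwork(
        node_ids=list(phenotypes.columns.astype(str)), W=W, kind="SC", metric_id=metric_id
    )


def genetic_similarity(zmat: GeneZMatrix, method: str = "spearman") -> SymmetricNetwork:
    """Region x region rank correlation of gene-level Z profiles."""
    if len(zmat.gene_ids) < 3:
        raise ValueError("need at least 3 genes")
    Z = zmat.z
    if np.any(Z.std(axis=1) == 0):
        bad = [zmat.region_ids[i] for i in np.flatnonzero(Z.std(axis=1) == 0)]
        raise ValueError(f"degenerate gene-Z profile: {bad}")
    if method == "spearman":
        ranks = stats.rankdata(Z, axis=1)
        W = np.corrcoef(ranks)
    elif method == "pearson":
        W = np.corrcoef(Z)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 1.0)
    return SymmetricNetwork(node_ids=list(zmat.region_ids), W=W, kind="GS",
                            metric_id=zmat.metric_id)


def _check_aligned(A: SymmetricNetwork, B: SymmetricNetwork) -> None:
    if A.node_ids != B.node_ids:
        raise ValueError("networks have mismatched node orderings")


def edgewise_coupling(A: SymmetricNetwork, B: SymmetricNetwork) -> float:
    """Spearman correlation over the strictly upper-triangular edges."""
    _check_aligned(A, B)
    return float(stats.spearmanr(upper_triangle(A.W), upper_triangle(B.W)).statistic)


def distance_adjusted_coupling(
    A: SymmetricNetwork,
    B: SymmetricNetwork,
    distances: np.ndarray,
    form: str = "linear",
) -> float:
    """Edge coupling after regressing geodesic distance out of both networks.

    Edges of each network are regressed (linearly by default, or on
    ``form='exp'``: on exp(-d)) on distance; residuals are rank-correlated.
    Edge pairs with undefined distance (NaN, e.g. cross-hemisphere) are
    excluded.
    """
    _check_aligned(A, B)
    D = np.asarray(distances, dtype=float)
    if D.shape != A.W.shape:
        raise ValueError("distance matrix shape mismatch")
    a, b, d = upper_triangle(A.W), upper_triangle(B.W), upper_triangle(D)
    keep = np.isfinite(d)
    a, b, d = a[keep], b[keep], d[keep]
    x = np.exp(-d) if form == "exp" else d
    if np.ptp(x) == 0:
        return float(stats.spearmanr(a, b).statistic)
    M = np.column_stack([np.ones_like(x), x])
    ra = a - M @ np.linalg.lstsq(M, a, rcond=None)[0]
    rb = b - M @ np.linalg.lstsq(M, b, rcond=None)[0]
    return float(stats.spearmanr(ra, rb).statistic)


def _cophenetic_distances(W: np.ndarray, linkage_method: str) -> np.ndarray:
    """Condensed cophenetic distance vector of the Ward dendrogram of rows."""
    d = pdist(W, metric="euclidean")
    Zl = linkage(d, method=linkage_method)
    return cophenet(Zl)


def cophenetic_test(
    A: SymmetricNetwork,
    B: SymmetricNetwork,
    linkage_method: str = "ward",
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Cophenetic correlation of the two networks' Ward dendrograms.

    Rows of each matrix are embedded as Euclidean distance profiles,
    clustered with Ward linkage (the squared-increment 'ward' variant), and
    the two cophenetic distance matrices Pearson-correlated (R_c). The null
    permutes the leaf labels of B's dendrogram while keeping both topologies
    fixed; p is the smoothed upper-tail probability.
    """
    _check_aligned(A, B)
    R = A.n_nodes
    if R < 4:
        raise ValueError("need at least 4 nodes")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ca = squareform(_cophenetic_distances(A.W, linkage_method))
    cb = squareform(_cophenetic_distances(B.W, linkage_method))
    iu = np.triu_indices(R, k=1)
    r_c = float(stats.pearsonr(ca[iu], cb[iu]).statistic)
    rng = rng_stream(seed, "cophenetic-perm")
    null = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(R)
        cbp = cb[np.ix_(perm, perm)]
        null[t] = stats.pearsonr(ca[iu], cbp[iu]).statistic
    return r_c, empirical_p(r_c, null, tail="upper")


def _apply_negative_policy(W: np.ndarray, policy: str) -> np.ndarray:
    if policy == "clamp":
        return np.clip(W, 0.0, None)
    if policy == "abs":
        return np.abs(W)
    if policy == "signed":
        return W.copy()
    raise ValueError(f"unknown negative-weight policy {policy!r}")


def louvain_modules(
    net: SymmetricNetwork, negative_policy: str = "clamp", seed: int = 0
) -> ModulePartition:
    """Louvain (multi-level modularity) communities of the weighted network.

    Negative edges are handled by ``negative_policy`` (default clamp to 0,
    matching community-detection routines that require non-negative
    weights). Deterministic under a fixed seed.
    """
    if net.n_nodes < 4:
        raise ValueError("need at least 4 nodes")
    W = _apply_negative_policy(net.W, negative_policy)
    W = (W + W.T) / 2.0  # igraph demands exact symmetry, not 1e-12-close
    np.fill_diagonal(W, 0.0)
    if not np.any(W > 0):
        raise ValueError("all edge weights zero after negative-weight policy")
    g = ig.Graph.Weighted_Adjacency(W.tolist(), mode="undirected", attr="weight", loops=False)
    state = random.Random(seed)
    ig.set_random_number_generator(state)
    try:
        comm = g.community_multilevel(weights="weight")
    finally:
        ig.set_random_number_generator(random)
    labels = np.array([f"M{m + 1}" for m in comm.membership], dtype=object)
    return ModulePartition(
        node_ids=list(net.node_ids), labels=labels, modularity=float(comm.modularity)
    )


def degree_profile(
    net: SymmetricNetwork,
    partition: ModulePartition,
    weight_policy: str = "clamp",
) -> NodeDegreeProfile:
    """Weighted degree plus intra-/inter-modular mean edge weight per node.

    degree_i = sum_{j != i} w_ij (after the weight policy; default keeps
    positive weights only); intra_i = mean w_ij over same-module j != i;
    inter_i = mean over out-of-module j. A singleton module yields intra 0.
    """
    if partition.node_ids != net.node_ids:
        raise ValueError("partition does not cover the network's nodes")
    W = _apply_negative_policy(net.W, weight_policy)
    np.fill_diagonal(W, 0.0)
    n = net.n_nodes
    labels = np.asarray(partition.labels, dtype=object)
    degree = W.sum(axis=1)
    intra = np.zeros(n)
    inter = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i])
        same[i] = False
        other = labels != labels[i]
        intra[i] = W[i, same].mean() if same.any() else 0.0
        inter[i] = W[i, other].mean() if other.any() else 0.0
    return NodeDegreeProfile(
        node_ids=list(net.node_ids), degree=degree, intra_modular=intra, inter_modular=inter
    )


def hub_pleiotropy_coupling(
    profile: NodeDegreeProfile,
    pls_regional: np.ndarray,
    geometry: ParcelGeometry,
    n_spins: int = 1000,
    seed: int = 0,
    which: str = "degree",
) -> tuple[float, float]:
    """Spearman correlation of hubness with the regional PLS1 map, spin p.

    ``which`` selects degree (default), intra_modular or inter_modular.
    Significance comes from the spatial spin null of the PLS map.
    """
    from .spatial import build_spin_null, map_spin_test

    if profile.node_ids != geometry.parcel_ids:
        raise ValueError("degree profile and geometry misaligned")
    hub = getattr(profile, which if which != "degree" else "degree")
    pls_regional = np.asarray(pls_regional, dtype=float)
    if pls_regional.size != len(profile.node_ids):
        raise ValueError("PLS map misaligned with nodes")
    null = build_spin_null(geometry, n_spins=n_spins, seed=seed)
    return map_spin_test(hub, pls_regional, null)
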