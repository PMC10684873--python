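"""Spatial inference for cortical maps: geodesic distance, spin nulls,
atlas-class enrichment.

Cortical maps are spatially autocorrelated, so parcel-wise permutation
overstates significance. The spin null rotates the spherical parcel
centroids by a uniform random 3D rotation (mirrored across hemispheres) and
reassigns parcels to nearest rotated positions, producing permutations that
preserve the spatial autocorrelation structure of the map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_fdr, empirical_p, rng_stream
from .datatypes import ParcelGeometry, SymmetricNetwork

__all__ = [
    "SpinNull",
    "geodesic_distances",
    "build_spin_null",
    "map_spin_test",
    "class_enrichment",
    "within_between_edge_test",
]


@dataclass
class SpinNull:
    n_spins: int
    permutations: np.ndarray  # (n_spins, n_parcels) index map
    seed: int

    def __post_init__(self) -> None:
        n = self.permutations.shape[1]
        ref = np.arange(n)
        for row in self.permutations:
            if not np.array_equal(np.sort(row), ref):
                raise ValueError("spin rows must be permutations")


def geodesic_distances(geometry: ParcelGeometry) -> np.ndarray:
    """Great-circle distances within hemisphere; cross-hemisphere pairs NaN.

    If the geometry carries a precomputed distance matrix (e.g. measured
    along a real cortical surface), it is returned verbatim.
    """
    if geometry.distances is not None:
        return geometry.distances
    C = geometry.centroids
    norms = np.linalg.norm(C, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-10):
        raise ValueError("centroids must be unit vectors")
    cosang = np.clip(C @ C.T, -1.0, 1.0)
    D = np.arccos(cosang)
    np.fill_diagonal(D, 0.0)
    hemi = geometry.hemisphere
    cross = hemi[:, None] != hemi[None, :]
    D = D.copy()
    D[cross] = np.nan
    return D


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian, sign-corrected)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _assign_rotated(orig: np.ndarray, rotated: np.ndarray, how: str) -> np.ndarray:
    """Bijection original -> rotated parcel positions.

    Returns perm with perm[i] = index of the original parcel whose rotated
    position lands on parcel i (each source used exactly once).
    ``how='optimal'`` minimizes the total assignment distance (Hungarian
    algorithm), which best preserves the smoothness of the spun map;
    ``how='greedy'`` repeatedly takes the globally closest remaining pair.
    """
    D = np.linalg.norm(orig[:, None, :] - rotated[None, :, :], axis=-1)
    n = orig.shape[0]
    if how == "optimal":
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(D)
        perm = np.empty(n, dtype=int)
        perm[rows] = cols
        return perm
    if how != "greedy":
        raise ValueError(f"unknown assignment rule {how!r}")
    perm = np.full(n, -1)
    D = D.copy()
    for _ in range(n):
        i, j = np.unravel_index(np.argmin(D), D.shape)
        perm[i] = j
        D[i, :] = np.inf
        D[:, j] = np.inf
    return perm


def build_spin_null(
    geometry: ParcelGeometry,
    n_spins: int = 1000,
    seed: int = 0,
    include_identity: bool = False,
    assignment: str = "optimal",
) -> SpinNull:
    """Hemisphere-preserving spin permutations of the parcellation.

    Each spin draws one uniform rotation for the left hemisphere and applies
    the mirror-image rotation to the right, then reassigns parcels to
    rotated centroid positions by a minimum-total-distance bijection
    (``assignment='greedy'`` selects the closest-pair heuristic instead).
    """
    if n_spins < 100:
        raise ValueError("n_spins must be >= 100")
    rng = rng_stream(seed, "spin")
    n = geometry.n_parcels
    M = np.diag([-1.0, 1.0, 1.0])  # mirror across the sagittal plane
    idx_l = geometry.hemi_indices("L")
    idx_r = geometry.hemi_indices("R")
    perms = np.empty((n_spins, n), dtype=int)
    for s in range(n_spins):
        if include_identity and s == 0:
            perms[s] = np.arange(n)
            continue
        Q = _random_rotation(rng)
        Qr = M @ Q @ M
        perm = np.arange(n)
        for idx, rot in ((idx_l, Q), (idx_r, Qr)):
            if idx.size == 0:
                continue
            pts = geometry.centroids[idx]
            local = _assign_rotated(pts, pts @ rot.T, assignment)
            perm[idx] = idx[local]
        perms[s] = perm
    return SpinNull(n_spins=n_spins, permutations=perms, seed=seed)


def map_spin_test(
    map_a: np.ndarray,
    map_b: np.ndarray,
    null: SpinNull,
    method: str = "spearman",
    tail: str = "two",
) -> tuple[float, float]:
    """Correlation of two cortical maps with spin-permutation significance.

    map_b is spun; the empirical p (two-tailed by default) uses +1
    smoothing, so p >= 1/(n_spins + 1).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.size != b.size or a.size != null.permutations.shape[1]:
        raise ValueError("maps and spin null misaligned")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map: correlation undefined")

    def corr(x, y):
        if method == "spearman":
            return stats.spearmanr(x, y).statistic
        return stats.pearsonr(x, y).statistic

    rho = float(corr(a, b))
    nulls = np.array([corr(a, b[perm]) for perm in null.permutations])
    return rho, empirical_p(rho, nulls, tail=tail)


def _class_stats(values: np.ndarray, classes: np.ndarray, labels: list) -> np.ndarray:
    out = np.empty(len(labels))
    for k, lab in enumerate(labels):
        inside = classes == lab
        out[k] = values[inside].mean() - values[~inside].mean()
    return out


def class_enrichment(
    map_values: np.ndarray,
    classes: np.ndarray,
    null: SpinNull,
) -> pd.DataFrame:
    """Atlas-class enrichment of a cortical map under the spin null.

    Per class: statistic = mean(map inside class) - mean(map outside),
    two-tailed spin p (the map is spun, labels held fixed), BH-FDR q across
    classes. Classes with fewer than 2 parcels are excluded with a warning.
    """
    v = np.asarray(map_values, dtype=float)
    classes = np.asarray(classes, dtype=object)
    labels = sorted(set(classes))
    keep = []
    for lab in labels:
        if np.sum(classes == lab) < 2:
            warnings.warn(f"class {lab!r} has < 2 parcels; excluded")
        else:
            keep.append(lab)
    if len(keep) < 2:
        raise ValueError("need at least 2 usable classes")
    obs = _class_stats(v, classes, keep)
    nulls = np.array(
        [_class_stats(v[perm], classes, keep) for perm in null.permutations]
    )
    p = np.array(
        [empirical_p(obs[k], nulls[:, k], tail="two") for k in range(len(keep))]
    )
    return pd.DataFrame({"unit": keep, "stat": obs, "p": p, "q": bh_fdr(p)})


def _edge_class_stats(W: np.ndarray, classes: np.ndarray, labels: list) -> np.ndarray:
    n = W.shape[0]
    offdiag = ~np.eye(n, dtype=bool)
    out = np.empty(len(labels))
    for k, lab in enumerate(labels):
        inside = classes == lab
        within_mask = np.outer(inside, inside) & offdiag
        between_mask = np.outer(inside, ~inside)
        out[k] = W[within_mask].mean() - W[between_mask].mean()
    return out


def within_between_edge_test(
    net: SymmetricNetwork,
    classes: np.ndarray,
    null: SpinNull,
) -> pd.DataFrame:
    """Within- minus between-class mean edge weight, spin-null p per class.

    The spin permutation is applied to the class labels (the network is held
    fixed); BH-FDR across classes.
    """
    classes = np.asarray(classes, dtype=object)
    if classes.size != net.n_nodes:
        raise ValueError("class labels misaligned with network")
    labels = sorted(set(classes))
    keep = [lab for lab in labels if np.sum(classes == lab) >= 2]
    for lab in labels:
        if lab not in keep:
            warnings.warn(f"class {lab!r} has < 2 parcels; excluded")
    if len(keep) < 2:
        raise ValueError("need at least 2 usable classes")
    W = net.W
    obs = _edge_class_stats(W, classes, keep)
    nulls = np.array(
        [_edge_class_stats(W, classes[perm], keep) for perm in null.permutations]
    )
    p = np.array(
        [empirical_p(obs[k], nulls[:, k], tail="two") for k in range(len(keep))]
    )
    return pd.DataFrame({"unit": keep, "stat": obs, "p": p, "q": bh_fdr(p)})
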