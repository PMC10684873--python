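"""Core data containers and their on-disk formats.

Matrices travel as TSV with an ID header row and an ID first column, gene
sets as GMT, parcel geometry and ground-truth records as JSON. Every
container validates its invariants on construction so that misaligned
inputs fail loudly at the boundary rather than deep inside a stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import check_symmetric

__all__ = [
    "GeneZMatrix",
    "DisorderZVector",
    "SymmetricNetwork",
    "ParcelGeometry",
    "SyntheticTruth",
    "read_gmt",
    "write_gmt",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} IDs")
    return ids


@dataclass
class GeneZMatrix:
    """Regions x genes matrix of gene-level association Z-scores for one MRI metric."""

    metric_id: str
    region_ids: list[str]
    gene_ids: list[str]
    z: np.ndarray

    def __post_init__(self) -> None:
        self.region_ids = _check_unique(self.region_ids, "region")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (len(self.region_ids), len(self.gene_ids)):
            raise ValueError(
                f"z shape {self.z.shape} does not match "
                f"{len(self.region_ids)} regions x {len(self.gene_ids)} genes"
            )
        if len(self.region_ids) < 2 or len(self.gene_ids) < 2:
            raise ValueError("need at least 2 regions and 2 genes")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite Z-scores")

    def two_sided_p(self) -> np.ndarray:
        """Two-sided p-values 2*Phi(-|z|)."""
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.region_ids, columns=self.gene_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="region_id")

    @classmethod
    def from_tsv(cls, path: str | Path, metric_id: str | None = None) -> "GeneZMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            metric_id=metric_id or Path(path).stem,
            region_ids=list(df.index.astype(str)),
            gene_ids=list(df.columns.astype(str)),
            z=df.to_numpy(dtype=float),
        )


@dataclass
class DisorderZVector:
    """Gene-aligned Z-scores for a disorder GWAS (the PLS response)."""

    disorder_id: str
    gene_ids: list[str]
    z: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.z = np.asarray(self.z, dtype=float).ravel()
        if self.z.size != len(self.gene_ids):
            raise ValueError("z length does not match gene_ids")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite Z-scores")

    def two_sided_p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"gene_id": self.gene_ids, "z": self.z}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, disorder_id: str | None = None) -> "DisorderZVector":
        df = pd.read_csv(path, sep="\t")
        return cls(
            disorder_id=disorder_id or Path(path).stem,
            gene_ids=list(df["gene_id"].astype(str)),
            z=df["z"].to_numpy(dtype=float),
        )

    def align_to(self, gene_ids: Sequence[str]) -> "DisorderZVector":
        """Reorder to a target gene universe; error on any mismatch."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise ValueError(f"gene universes misaligned; {len(missing)} genes absent "
                             f"from disorder vector (first: {missing[:3]})")
        order = [idx[g] for g in gene_ids]
        return DisorderZVector(self.disorder_id, list(gene_ids), self.z[order])


@dataclass
class SymmetricNetwork:
    """Signed symmetric region x region network (structural covariance or genetic similarity)."""

    node_ids: list[str]
    W: np.ndarray
    kind: str = "SC"
    metric_id: str = ""

    def __post_init__(self) -> None:
        self.node_ids = _check_unique(self.node_ids, "node")
        self.W = np.asarray(self.W, dtype=float)
        check_symmetric(self.W, tol=1e-12, name=f"{self.kind} matrix")
        if self.W.shape[0] != len(self.node_ids):
            raise ValueError("W size does not match node_ids")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.W, index=self.node_ids, columns=self.node_ids).to_csv(
            path, sep="\t", index_label="node_id"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "SC", metric_id: str = "") -> "SymmetricNetwork":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(node_ids=list(df.index.astype(str)), W=df.to_numpy(dtype=float),
                   kind=kind, metric_id=metric_id)


@dataclass
class ParcelGeometry:
    """Cortical parcel geometry: spherical centroids, hemispheres, atlas labels.

    Centroids are unit 3-vectors on a per-hemisphere sphere; `atlas_class`
    maps one or more label-set names (e.g. a cytoarchitectonic atlas) to a
    per-parcel label array.
    """

    parcel_ids: list[str]
    hemisphere: np.ndarray  # 'L' / 'R'
    centroids: np.ndarray  # (n, 3), unit norm
    atlas_class: dict[str, np.ndarray] = field(default_factory=dict)
    distances: np.ndarray | None = None  # optional precomputed geodesic matrix

    def __post_init__(self) -> None:
        self.parcel_ids = _check_unique(self.parcel_ids, "parcel")
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        self.centroids = np.asarray(self.centroids, dtype=float)
        n = len(self.parcel_ids)
        if self.hemisphere.shape != (n,) or self.centroids.shape != (n, 3):
            raise ValueError("geometry field shapes inconsistent")
        norms = np.linalg.norm(self.centroids, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-10):
            raise ValueError("centroids must be unit vectors")
        for name, labels in self.atlas_class.items():
            arr = np.asarray(labels, dtype=object)
            if arr.shape != (n,):
                raise ValueError(f"label set {name!r} has wrong length")
            self.atlas_class[name] = arr
        if self.distances is not None:
            self.distances = np.asarray(self.distances, dtype=float)
            check_symmetric(np.nan_to_num(self.distances), name="distance matrix")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def hemi_indices(self, hemi: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "parcel_ids": self.parcel_ids,
            "hemisphere": [str(h) for h in self.hemisphere],
            "centroids": self.centroids.tolist(),
            "atlas_class": {k: [str(v) for v in arr] for k, arr in self.atlas_class.items()},
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ParcelGeometry":
        obj = json.loads(Path(path).read_text())
        return cls(
            parcel_ids=obj["parcel_ids"],
            hemisphere=np.array(obj["hemisphere"], dtype=object),
            centroids=np.array(obj["centroids"], dtype=float),
            atlas_class={k: np.array(v, dtype=object) for k, v in obj.get("atlas_class", {}).items()},
        )


@dataclass
class SyntheticTruth:
    """Ground-truth record for parameter-recovery tests on synthetic data."""

    region_shared_loadings: np.ndarray | None = None  # a_i
    disorder_loading: float | None = None  # c
    pleiotropic_gene_ids: list[str] = field(default_factory=list)
    module_assignment: dict[str, str] = field(default_factory=dict)
    mr_causal_beta: float | None = None

    def to_json(self, path: str | Path) -> None:
        obj = {
            "region_shared_loadings": None
            if self.region_shared_loadings is None
            else np.asarray(self.region_shared_loadings).tolist(),
            "disorder_loading": self.disorder_loading,
            "pleiotropic_gene_ids": list(self.pleiotropic_gene_ids),
            "module_assignment": dict(self.module_assignment),
            "mr_causal_beta": self.mr_causal_beta,
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT (name <tab> description <tab> genes...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              description: str = "pleiomap") -> None:
    lines = []
    for name, genes in sets.items():
        lines.append("\t".join([name, description, *sorted(map(str, genes))]))
    Path(path).write_text("\n".join(lines) + "\n")
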