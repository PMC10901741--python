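"""Peak-space analysis: scaling, pluggable embedding/clustering, and
per-cluster provenance and TE-composition reports.

The biological claims about peak clusters rest on *composition*: which
profile(s) a cluster's peaks came from, and which repeat families (and
orientations) its peaks cover relative to the whole peak universe.  The
embedding and density-clustering algorithms are injected dependencies
behind a minimal interface (matrix -> coordinates, matrix -> labels), so
any manifold learner / density clusterer can be plugged in; defaults are
PCA and HDBSCAN from scikit-learn, with a UMAP embedder available when
umap-learn is installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

from .intervals import RepeatElement
from .peaks import Peak, PeakCountMatrix
from .te_enrichment import EnrichmentTable, log2_enrichment, te_fractions

__all__ = [
    "ClusterReport",
    "scale_matrix",
    "embed_and_cluster",
    "cluster_provenance",
    "cluster_te_composition",
    "PCAEmbedder",
    "UMAPEmbedder",
    "HDBSCANClusterer",
    "KMeansClusterer",
]


class Embedder(Protocol):
    def embed(self, matrix: np.ndarray) -> np.ndarray: ...


class Clusterer(Protocol):
    def cluster(self, matrix: np.ndarray) -> np.ndarray: ...


@dataclass
class ClusterReport:
    cluster_id: int
    n_peaks: int
    #: fraction of cluster peaks whose source set is exactly {profile}
    exclusive_fractions: dict[str, float] = field(default_factory=dict)
    #: fraction of cluster peaks with >1 source profile
    shared_fraction: float = 0.0
    te_composition: EnrichmentTable | None = None


def scale_matrix(matrix: PeakCountMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize a peak x profile matrix (mean 0, population sd 1).

    Returns (scaled matrix, boolean flags of constant columns); constant
    columns become all-zero rather than NaN.
    """
    mat = matrix.counts if isinstance(matrix, PeakCountMatrix) else np.asarray(matrix)
    mat = np.asarray(mat, dtype=float)
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need at least 2 peaks and 2 profiles to scale")
    constant = mat.std(axis=0) == 0
    scaled = StandardScaler().fit_transform(mat)  # sklearn zeroes constant columns
    return scaled, constant


class PCAEmbedder:
    """Principal-component embedding (deterministic, no tuning)."""

    def __init__(self, n_components: int = 2, seed: int = 0) -> None:
        self.n_components = n_components
        self.seed = seed

    def embed(self, matrix: np.ndarray) -> np.ndarray:
        from sklearn.decomposition import PCA

        n = min(self.n_components, matrix.shape[1], matrix.shape[0])
        return PCA(n_components=n, random_state=self.seed).fit_transform(matrix)


class UMAPEmbedder:
    """UMAP embedding; requires the optional umap-learn dependency."""

    def __init__(self, n_components: int = 2, n_neighbors: int = 15,
                 min_dist: float = 0.1, seed: int = 42) -> None:
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.seed = seed

    def embed(self, matrix: np.ndarray) -> np.ndarray:
        import umap

        return umap.UMAP(
            n_components=self.n_components,
            n_neighbors=self.n_neighbors,
            min_dist=self.min_dist,
            random_state=self.seed,
        ).fit_transform(matrix)


class HDBSCANClusterer:
    """Density clustering with scikit-learn's HDBSCAN; noise label -1."""

    def __init__(self, min_cluster_size: int = 25, min_samples: int | None = None) -> None:
        self.min_cluster_size = min_cluster_size
        self.min_samples = min_samples

    def cluster(self, matrix: np.ndarray) -> np.ndarray:
        from sklearn.cluster import HDBSCAN

        model = HDBSCAN(
            min_cluster_size=self.min_cluster_size,
            min_samples=self.min_samples,
            copy=True,
        )
        return model.fit_predict(matrix)


class KMeansClusterer:
    def __init__(self, n_clusters: int, seed: int = 0) -> None:
        self.n_clusters = n_clusters
        self.seed = seed

    def cluster(self, matrix: np.ndarray) -> np.ndarray:
        from sklearn.cluster import KMeans

        return KMeans(n_clusters=self.n_clusters, random_state=self.seed, n_init=10).fit_predict(matrix)


def embed_and_cluster(
    scaled: np.ndarray,
    embedder: Embedder | None = None,
    clusterer: Clusterer | None = None,
    cluster_on_embedding: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Embed peaks to 2-D and assign density-cluster labels.

    ``clusterer`` runs on the embedding by default (mirroring the
    embed-then-density-cluster scheme); pass
    ``cluster_on_embedding=False`` to cluster the scaled matrix directly.
    Noise points carry label -1.  Deterministic for fixed seed and
    pinned algorithm versions.
    """
    embedder = embedder or PCAEmbedder(seed=seed)
    clusterer = clusterer or HDBSCANClusterer()
    coords = embedder.embed(scaled)
    labels = clusterer.cluster(coords if cluster_on_embedding else scaled)
    if len(labels) != scaled.shape[0]:
        raise RuntimeError("clusterer returned wrong number of labels")
    return np.asarray(coords), np.asarray(labels)


def cluster_provenance(labels: Sequence[int], peaks: Sequence[Peak]) -> list[ClusterReport]:
    """Per-cluster origin attribution from peak source sets.

    For each non-noise cluster, the fraction of peaks sourced exclusively
    from each profile, plus the fraction shared by several profiles
    (reported separately, so exclusive fractions sum to <= 1).
    """
    labels = np.asarray(labels)
    if len(labels) != len(peaks):
        raise ValueError("label count does not match peak count")
    reports = []
    for cid in sorted(set(labels.tolist()) - {-1}):
        members = [p for p, l in zip(peaks, labels) if l == cid]
        n = len(members)
        profiles = sorted({pr for p in members for pr in p.sources})
        exclusive = {
            pr: sum(1 for p in members if p.sources == frozenset({pr})) / n
            for pr in profiles
        }
        shared = sum(1 for p in members if len(p.sources) > 1) / n
        reports.append(
            ClusterReport(int(cid), n, exclusive_fractions=exclusive, shared_fraction=shared)
        )
    return reports


def cluster_te_composition(
    labels: Sequence[int],
    peaks: Sequence[Peak],
    repeats: Sequence[RepeatElement],
    families: Sequence[str] | None = None,
) -> dict[int, EnrichmentTable]:
    """log2 TE enrichment of each cluster against the full peak universe.

    The expected composition is the TE fraction table over *all* peaks,
    so a cluster sampled uniformly from the universe shows enrichment
    near 0 everywhere; empty clusters are skipped.
    """
    labels = np.asarray(labels)
    if len(labels) != len(peaks):
        raise ValueError("label count does not match peak count")
    expected = te_fractions([p.interval for p in peaks], repeats, families)
    out: dict[int, EnrichmentTable] = {}
    for cid in sorted(set(labels.tolist()) - {-1}):
        members = [p.interval for p, l in zip(peaks, labels) if l == cid]
        if not members:
            continue
        observed = te_fractions(members, repeats, families)
        out[cid] = log2_enrichment(observed, expected)
    return out


def reports_frame(reports: Sequence[ClusterReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for profile, frac in sorted(rep.exclusive_fractions.items()):
            rows.append(
                {
                    "cluster_id": rep.cluster_id,
                    "n_peaks": rep.n_peaks,
                    "profile": profile,
                    "exclusive_fraction": frac,
                    "shared_fraction": rep.shared_fraction,
                }
            )
    return pd.DataFrame(rows)
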