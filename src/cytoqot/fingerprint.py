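"""Fingerprint marker-subset search and benchmark evaluation.

A "fingerprint" is a marker subset under which pairwise QOT distances group
a subject's timepoints together.  Subsets of sizes 2..6 are scored by the
silhouette of the subject partition on the precomputed distance matrix;
hierarchical clustering plus the adjusted Rand index evaluates how well the
distance matrix recovers subject identity on benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from .io import StudyCollection, ValidationError
from .qot import DistanceMatrix, GmmCache, QotConfig, pairwise_distances

__all__ = ["SubsetScore", "ClusterScore", "enumerate_subsets",
           "silhouette_from_distances", "fingerprint_search",
           "cluster_and_score", "connection_graph", "umap_embedding"]


@dataclass
class SubsetScore:
    markers: tuple[str, ...]
    silhouette: float
    subset_size: int
    failed: bool = False
    error: str | None = None

    def __post_init__(self):
        self.markers = tuple(self.markers)
        if self.subset_size != len(self.markers):
            raise ValidationError("subset_size must equal |markers|")
        if not self.failed and not -1.0 - 1e-9 <= self.silhouette <= 1.0 + 1e-9:
            raise ValidationError(f"silhouette {self.silhouette} outside [-1, 1]")


def enumerate_subsets(markers, min_size: int = 2,
                      max_size: int = 6) -> list[tuple[str, ...]]:
    """All marker combinations of each size, ordered by (size, lexicographic)."""
    markers = sorted(markers)
    if not 1 <= min_size <= max_size:
        raise ValidationError(f"invalid size range [{min_size}, {max_size}]")
    if max_size > len(markers):
        raise ValidationError(
            f"max_size {max_size} exceeds {len(markers)} markers")
    out = []
    for size in range(min_size, max_size + 1):
        out.extend(combinations(markers, size))
    return out


def silhouette_from_distances(dm: DistanceMatrix, labels=None
                              ) -> tuple[float, np.ndarray]:
    """Mean and per-sample silhouette on a precomputed distance matrix.

    Labels default to subject identity.  Samples in singleton classes
    contribute a score of 0 (the usual convention).
    """
    labels = np.asarray(dm.subject_ids if labels is None else labels)
    if len(labels) != len(dm.sample_ids):
        raise ValidationError("one label per sample required")
    if len(set(labels.tolist())) < 2:
        raise ValidationError("silhouette needs >= 2 distinct labels")
    scores = silhouette_samples(dm.values, labels, metric="precomputed")
    return float(scores.mean()), scores


def fingerprint_search(collection: StudyCollection,
                       candidate_markers=None,
                       sizes: tuple[int, int] = (2, 6),
                       config: QotConfig = QotConfig(),
                       cache: GmmCache | None = None,
                       max_subsets: int = 20000,
                       force: bool = False) -> list[SubsetScore]:
    """Score every marker subset by how well it fingerprints subjects.

    For each enumerated subset the pairwise QOT distance matrix is computed
    and the silhouette of the subject partition taken; results are sorted
    by descending silhouette (ties by size then name, for a deterministic
    ranking).  Subsets whose distance computation fails are kept with a
    failure flag rather than dropped.
    """
    subjects = {}
    for s in collection.samples:
        subjects.setdefault(s.subject_id, []).append(s)
    if len(subjects) < 2 or any(len(v) < 2 for v in subjects.values()):
        raise ValidationError(
            "fingerprint search needs >= 2 subjects with >= 2 samples each")
    pool = (collection.shared_markers if candidate_markers is None
            else tuple(candidate_markers))
    subsets = enumerate_subsets(pool, sizes[0], sizes[1])
    if len(subsets) > max_subsets and not force:
        raise ValidationError(
            f"{len(subsets)} subsets exceeds the cap of {max_subsets}; "
            "pass force=True to search anyway")
    if cache is None:
        cache = GmmCache()
    scores = []
    for markers in subsets:
        try:
            dm = pairwise_distances(collection, markers, config, cache)
            sil, _ = silhouette_from_distances(dm)
            scores.append(SubsetScore(markers=markers, silhouette=sil,
                                      subset_size=len(markers)))
        except Exception as exc:  # noqa: BLE001 - record, don't drop
            scores.append(SubsetScore(markers=markers, silhouette=float("nan"),
                                      subset_size=len(markers), failed=True,
                                      error=str(exc)))
    scores.sort(key=lambda s: (s.failed,
                               -(s.silhouette if not s.failed else -np.inf),
                               s.subset_size, s.markers))
    return scores


def scores_to_frame(scores: list[SubsetScore]) -> pd.DataFrame:
    return pd.DataFrame([
        {"markers": "|".join(s.markers), "size": s.subset_size,
         "silhouette": s.silhouette, "failed": s.failed, "error": s.error}
        for s in scores])


@dataclass
class ClusterScore:
    assignment: np.ndarray
    ari: float
    silhouette_clusters: float
    silhouette_true: float


def cluster_and_score(dm: DistanceMatrix, n_clusters: int,
                      true_labels=None,
                      linkage: str = "average") -> ClusterScore:
    """Agglomerative clustering of a distance matrix, scored against truth.

    Average linkage on the precomputed distances by default (complete and
    single are also valid on precomputed input).  Returns the adjusted Rand
    index against the true labels plus silhouettes of both the induced
    assignment and the true partition.
    """
    P = len(dm.sample_ids)
    if not 2 <= n_clusters <= P:
        raise ValidationError(f"n_clusters must be in [2, {P}]")
    if linkage not in {"average", "complete", "single"}:
        raise ValidationError(
            f"linkage {linkage!r} not valid for precomputed distances")
    model = AgglomerativeClustering(n_clusters=n_clusters,
                                    metric="precomputed", linkage=linkage)
    assignment = model.fit_predict(dm.values)
    true_labels = np.asarray(dm.subject_ids if true_labels is None
                             else true_labels)
    ari = float(adjusted_rand_score(true_labels, assignment))
    sil_clusters = (silhouette_from_distances(dm, assignment)[0]
                    if len(set(assignment.tolist())) > 1 else 0.0)
    sil_true = (silhouette_from_distances(dm, true_labels)[0]
                if len(set(true_labels.tolist())) > 1 else 0.0)
    return ClusterScore(assignment=assignment, ari=ari,
                        silhouette_clusters=sil_clusters,
                        silhouette_true=sil_true)


def connection_graph(embedding, labels, threshold: float = 0.8
                     ) -> list[tuple[int, int]]:
    """Edges between same-label samples closer than `threshold` in 2-D.

    The embedding is any user-supplied 2-D projection of the distance
    matrix (e.g., UMAP); edges are undirected index pairs (i < j).
    """
    emb = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    if emb.ndim != 2 or emb.shape[0] != labels.shape[0]:
        raise ValidationError("embedding rows must match labels")
    edges = []
    for i, j in combinations(range(emb.shape[0]), 2):
        if labels[i] == labels[j] and np.linalg.norm(emb[i] - emb[j]) < threshold:
            edges.append((i, j))
    return edges


def umap_embedding(dm: DistanceMatrix, seed: int = 0, **kwargs) -> np.ndarray:
    """2-D UMAP of a precomputed distance matrix (illustrative only).

    UMAP is stochastic even at fixed seed across library versions, so the
    embedding and the connection graph built on it are visual aids, not
    quantitative outputs.
    """
    import umap  # deferred: optional dependency

    n = len(dm.sample_ids)
    n_neighbors = kwargs.pop("n_neighbors", min(15, max(2, n - 1)))
    reducer = umap.UMAP(n_components=2, metric="precomputed",
                        random_state=seed, n_neighbors=n_neighbors, **kwargs)
    return np.asarray(reducer.fit_transform(dm.values))
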