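"""Internal integration scorecard: batch mixing, bio-conservation, overall.

A deliberately compact set of scores for tests and user reports: adjusted
Rand index and a rescaled silhouette for bio-conservation, a normalized
KNN batch-mixing entropy for batch correction, aggregated with the 40:60
batch/bio weighting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score, silhouette_samples

__all__ = [
    "ScoreReport",
    "adjusted_rand_index",
    "batch_mixing_entropy",
    "silhouette_by_label",
    "overall_score",
]

logger = logging.getLogger(__name__)

BATCH_WEIGHT = 0.4
BIO_WEIGHT = 0.6


@dataclass
class ScoreReport:
    batch_scores: dict
    bio_scores: dict
    overall: float
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "batch_scores": self.batch_scores,
            "bio_scores": self.bio_scores,
            "overall": self.overall,
            "metadata": self.metadata,
        }


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions (pair-counting form)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("partitions must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))


def batch_mixing_entropy(
    embedding: np.ndarray, batch_ids, k: int = 30
) -> float:
    """Mean normalized Shannon entropy of batch composition among each
    cell's k nearest neighbors (1 = perfectly mixed, 0 = fully separated)."""
    embedding = np.asarray(embedding, dtype=np.float64)
    batch_ids = np.asarray(batch_ids)
    n = embedding.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    ub = np.unique(batch_ids)
    if len(ub) == 1:
        logger.warning("single batch: batch mixing entropy defined as 1.0")
        return 1.0
    d = cdist(embedding, embedding)
    np.fill_diagonal(d, np.inf)
    order = np.argpartition(d, k, axis=1)[:, :k]
    codes = np.searchsorted(ub, batch_ids)
    ent = np.empty(n)
    for i in range(n):
        counts = np.bincount(codes[order[i]], minlength=len(ub))
        p = counts[counts > 0] / k
        ent[i] = -(p * np.log(p)).sum()
    return float(ent.mean() / np.log(len(ub)))


def silhouette_by_label(embedding: np.ndarray, labels) -> float:
    """Mean Euclidean silhouette width rescaled from [-1, 1] to [0, 1].

    Cells in singleton label groups get width 0 (with a warning)."""
    embedding = np.asarray(embedding, dtype=np.float64)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 labels")
    if np.any(counts == 1):
        logger.warning("singleton label(s): their silhouette width set to 0")
        mask = np.isin(labels, uniq[counts > 1])
        widths = np.zeros(len(labels))
        if len(np.unique(labels[mask])) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                widths[mask] = silhouette_samples(embedding[mask], labels[mask])
        s = widths.mean()
    else:
        s = float(silhouette_samples(embedding, labels).mean())
    return float((s + 1.0) / 2.0)


def overall_score(batch_scores, bio_scores) -> float:
    """0.4 x mean(batch scores) + 0.6 x mean(bio scores)."""
    batch = _values(batch_scores)
    bio = _values(bio_scores)
    if len(batch) == 0 or len(bio) == 0:
        raise ValueError("both score groups must be non-empty")
    for v in batch + bio:
        if not 0.0 <= v <= 1.0:
            raise ValueError("scores must lie in [0, 1]")
    return float(BATCH_WEIGHT * np.mean(batch) + BIO_WEIGHT * np.mean(bio))


def _values(scores) -> list:
    if isinstance(scores, dict):
        return [float(v) for v in scores.values()]
    return [float(v) for v in np.atleast_1d(scores)]


def score_embedding(
    embedding: np.ndarray,
    batch_ids,
    labels,
    k: int = 30,
    kmeans_seed: int = 0,
    name: str = "embedding",
) -> ScoreReport:
    """Full scorecard: batch mixing vs ARI(k-means) + silhouette."""
    from sklearn.cluster import KMeans

    labels = np.asarray(labels)
    n_types = len(np.unique(labels))
    km = KMeans(n_clusters=n_types, n_init=10, random_state=kmeans_seed)
    pred = km.fit_predict(np.asarray(embedding, dtype=np.float64))
    batch = {"batch_mixing_entropy": batch_mixing_entropy(embedding, batch_ids, k=k)}
    bio = {
        "kmeans_ari": max(0.0, adjusted_rand_index(labels, pred)),
        "label_silhouette": silhouette_by_label(embedding, labels),
    }
    return ScoreReport(
        batch_scores=batch,
        bio_scores=bio,
        overall=overall_score(batch, bio),
        metadata={"embedding": name, "k": k, "seed": kmeans_seed},
    )
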