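"""Two-step KNN label propagation from reference to mapped query cells.

Step 1 assigns each query cell the majority label among its k nearest
reference cells in the shared (HVG) latent, provided the vote fraction
clears a confidence threshold. Step 2 smooths the leftovers: unresolved
cells take the majority label among their k nearest step-1-labeled query
cells. Remaining ties fall back to the single nearest neighbor's label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = ["LabelAssignment", "propagate_labels", "KNNLabelPropagator"]


@dataclass
class LabelAssignment:
    labels: np.ndarray        # str per query cell
    confidence: np.ndarray    # vote fraction in [0, 1]
    step_provenance: np.ndarray  # 1 | 2 per cell


def _vote(nn_labels: np.ndarray, nearest_label) -> tuple[str, float]:
    """Majority vote with ties broken by the single nearest neighbor."""
    values, counts = np.unique(nn_labels, return_counts=True)
    top = counts.max()
    winners = values[counts == top]
    if len(winners) > 1:
        label = nearest_label if nearest_label in winners else sorted(winners)[0]
    else:
        label = winners[0]
    return label, top / len(nn_labels)


def propagate_labels(
    ref_latent: np.ndarray,
    ref_labels: np.ndarray,
    query_latent: np.ndarray,
    k: int = 15,
    conf_threshold: float = 0.5,
) -> LabelAssignment:
    """Two-step KNN majority-vote label transfer (Euclidean metric)."""
    ref_latent = np.asarray(ref_latent, dtype=np.float64)
    query_latent = np.asarray(query_latent, dtype=np.float64)
    ref_labels = np.asarray(ref_labels, dtype=object)
    if ref_latent.shape[0] == 0:
        raise ValueError("empty reference")
    if ref_latent.shape[1] != query_latent.shape[1]:
        raise ValueError("latent dimensionality mismatch")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_q = query_latent.shape[0]
    k1 = min(k, ref_latent.shape[0])

    d = cdist(query_latent, ref_latent)
    order = np.lexsort(
        (np.broadcast_to(np.arange(d.shape[1]), d.shape), d), axis=1
    )[:, :k1]

    labels = np.empty(n_q, dtype=object)
    conf = np.zeros(n_q)
    step = np.zeros(n_q, dtype=int)
    for i in range(n_q):
        nn = ref_labels[order[i]]
        lab, frac = _vote(nn, ref_labels[order[i, 0]])
        labels[i] = lab
        conf[i] = frac
        step[i] = 1 if frac >= conf_threshold else 0

    unresolved = np.flatnonzero(step == 0)
    resolved = np.flatnonzero(step == 1)
    if len(unresolved) and len(resolved):
        d2 = cdist(query_latent[unresolved], query_latent[resolved])
        k2 = min(k, len(resolved))
        order2 = np.lexsort(
            (np.broadcast_to(np.arange(d2.shape[1]), d2.shape), d2), axis=1
        )[:, :k2]
        for row, i in enumerate(unresolved):
            nn = labels[resolved[order2[row]]]
            lab, frac = _vote(
                nn.astype(object), labels[resolved[order2[row, 0]]]
            )
            labels[i] = lab
            conf[i] = frac
            step[i] = 2
    else:
        # nothing resolved in step 1: keep the step-1 plurality labels
        step[unresolved] = 1
    return LabelAssignment(labels=labels, confidence=conf, step_provenance=step)


class KNNLabelPropagator(ClassifierMixin, BaseEstimator):
    """Scikit-learn-style front end for :func:`propagate_labels`."""

    def __init__(self, k: int = 15, conf_threshold: float = 0.5):
        self.k = k
        self.conf_threshold = conf_threshold

    def fit(self, ref_latent: np.ndarray, ref_labels) -> "KNNLabelPropagator":
        self.ref_latent_ = np.asarray(ref_latent, dtype=np.float64)
        self.ref_labels_ = np.asarray(ref_labels, dtype=object)
        if self.ref_latent_.shape[0] == 0:
            raise ValueError("empty reference")
        self.classes_ = np.unique(self.ref_labels_)
        return self

    def predict(self, query_latent: np.ndarray) -> np.ndarray:
        return self.assign(query_latent).labels

    def assign(self, query_latent: np.ndarray) -> LabelAssignment:
        if not hasattr(self, "ref_latent_"):
            raise RuntimeError("propagator is not fitted")
        return propagate_labels(
            self.ref_latent_, self.ref_labels_, query_latent,
            k=self.k, conf_threshold=self.conf_threshold,
        )
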