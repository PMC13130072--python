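"""Anchor construction: MNN pairs and (anchor, positive, negative) triplets.

Triplets drive the metric-learning term of the HVG block: the anchor and
positive come from different batches and share a biological identity
(same label, or mutual nearest neighbors in a PCA reduction of the scaled
HVG matrix), while the negative is a random cell from the anchor's own
batch. For query mapping, anchors are query cells and positives are their
MNN partners in the reference latent space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .data import PreparedDataset

__all__ = ["TripletSet", "find_mnn_pairs", "build_triplets", "build_query_triplets"]

logger = logging.getLogger(__name__)

MAX_PAIRS_DEFAULT = 100_000


@dataclass
class TripletSet:
    """Cell-index triples (anchor, positive, negative) with hinge margin."""

    triples: np.ndarray  # [n x 3] int
    margin: float = 1.0
    mode: str = "label-based"  # or "mnn-based"
    query_anchored: bool = False
    # anchor/positive pairs are fixed after construction; negatives can be
    # re-drawn each epoch via resample_negatives
    _pairs: np.ndarray | None = None
    _anchor_batch_pool: dict | None = None

    def __len__(self) -> int:
        return len(self.triples)

    @property
    def n_triplets(self) -> int:
        return len(self.triples)

    def resample_negatives(self, rng: np.random.Generator) -> None:
        """Redraw each triple's negative from the anchor's batch pool."""
        if self._pairs is None or self._anchor_batch_pool is None:
            return
        self.triples = _attach_negatives(
            self._pairs, self._anchor_batch_pool, self.negatives_per_anchor, rng
        )

    @property
    def negatives_per_anchor(self) -> int:
        if self._pairs is None or len(self._pairs) == 0:
            return 1
        return max(1, len(self.triples) // len(self._pairs))

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.triples, fmt="%d", delimiter="\t",
                   header="anchor\tpositive\tnegative", comments="")


def _knn_indices(d: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest entries per row; ties broken by index."""
    n = d.shape[1]
    order = np.lexsort((np.broadcast_to(np.arange(n), d.shape), d), axis=1)
    return order[:, :k]


def find_mnn_pairs(
    rep_a: np.ndarray, rep_b: np.ndarray, k: int
) -> list[tuple[int, int]]:
    """Mutual nearest neighbor pairs between two point sets.

    (i, j) is returned iff j is among the k Euclidean nearest neighbors of
    a_i within rep_b AND i is among the k nearest of b_j within rep_a.
    Distance ties break toward the lower index.
    """
    rep_a = np.asarray(rep_a, dtype=np.float64)
    rep_b = np.asarray(rep_b, dtype=np.float64)
    if rep_a.ndim != 2 or rep_b.ndim != 2 or rep_a.shape[1] != rep_b.shape[1]:
        raise ValueError("representations must be 2-D with equal dimensionality")
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, rep_a.shape[0], rep_b.shape[0])
    d = cdist(rep_a, rep_b)
    nn_ab = _knn_indices(d, k)          # for each a-point: k nearest b-points
    nn_ba = _knn_indices(d.T, k)        # for each b-point: k nearest a-points
    in_ba = np.zeros(d.shape, dtype=bool)
    rows = np.repeat(np.arange(rep_b.shape[0]), k)
    in_ba[nn_ba.ravel(), rows] = True   # in_ba[i, j]: i among j's neighbors
    pairs = []
    for i in range(rep_a.shape[0]):
        for j in nn_ab[i]:
            if in_ba[i, j]:
                pairs.append((i, int(j)))
    return pairs


def _attach_negatives(
    pairs: np.ndarray, pool: dict, negatives_per_anchor: int,
    rng: np.random.Generator,
) -> np.ndarray:
    triples = []
    for a, p in pairs:
        candidates = pool[int(a)]
        for _ in range(negatives_per_anchor):
            n = candidates[rng.integers(0, len(candidates))]
            triples.append((a, p, n))
    return np.asarray(triples, dtype=np.intp).reshape(-1, 3)


def _negative_pools(anchors: np.ndarray, batch_ids: np.ndarray) -> dict:
    """Per-anchor candidate negatives: same batch, excluding the anchor."""
    pool = {}
    by_batch = {b: np.flatnonzero(batch_ids == b) for b in np.unique(batch_ids)}
    skipped = 0
    for a in np.unique(anchors):
        cand = by_batch[batch_ids[a]]
        cand = cand[cand != a]
        if len(cand) == 0:
            skipped += 1
            continue
        pool[int(a)] = cand
    if skipped:
        logger.warning("%d anchors skipped: no other cell in their batch", skipped)
    return pool


def build_triplets(
    data: PreparedDataset,
    mode: str = "auto",
    k_mnn: int = 20,
    negatives_per_anchor: int = 1,
    seed: int = 0,
    margin: float = 1.0,
    max_pairs: int = MAX_PAIRS_DEFAULT,
    n_pca: int = 50,
) -> TripletSet:
    """Construct integration triplets from labels or MNN anchors.

    In label mode every cross-batch pair of same-label cells is an
    (anchor, positive) pair (both directions); in MNN mode pairs come from
    mutual nearest neighbors computed batch-against-batch in a PCA
    reduction of the scaled HVG matrix. Pairs beyond ``max_pairs`` are
    subsampled with the given seed.
    """
    rng = np.random.default_rng(seed)
    if mode == "auto":
        mode = "label-based" if data.labels is not None else "mnn-based"
    batch_ids = data.batch_ids
    if len(np.unique(batch_ids)) < 2:
        raise ValueError("triplet construction requires at least two batches")

    pairs: list[tuple[int, int]] = []
    if mode == "label-based":
        if data.labels is None:
            raise ValueError("label-based mode requires cell labels")
        labels = data.labels
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            bids = batch_ids[idx]
            for a_pos, a in enumerate(idx):
                mask = bids != bids[a_pos]
                pairs.extend((int(a), int(p)) for p in idx[mask])
    elif mode == "mnn-based":
        n_comp = min(n_pca, data.X_hvg.shape[1], data.n_cells - 1)
        rep = PCA(n_components=n_comp, random_state=0).fit_transform(data.X_hvg)
        ub = np.unique(batch_ids)
        for bi in range(len(ub)):
            for bj in range(bi + 1, len(ub)):
                ia = np.flatnonzero(batch_ids == ub[bi])
                ib = np.flatnonzero(batch_ids == ub[bj])
                for i, j in find_mnn_pairs(rep[ia], rep[ib], k_mnn):
                    pairs.append((int(ia[i]), int(ib[j])))
                    pairs.append((int(ib[j]), int(ia[i])))
    else:
        raise ValueError(f"unknown triplet mode: {mode!r}")

    if not pairs:
        raise ValueError("no cross-batch anchor/positive pairs found")
    pairs_arr = np.asarray(pairs, dtype=np.intp)
    if len(pairs_arr) > max_pairs:
        keep = rng.choice(len(pairs_arr), size=max_pairs, replace=False)
        pairs_arr = pairs_arr[np.sort(keep)]

    pool = _negative_pools(pairs_arr[:, 0], batch_ids)
    pairs_arr = pairs_arr[np.isin(pairs_arr[:, 0], list(pool.keys()))]
    if len(pairs_arr) == 0:
        raise ValueError("no triplets could be formed")
    triples = _attach_negatives(pairs_arr, pool, negatives_per_anchor, rng)
    return TripletSet(
        triples=triples, margin=margin, mode=mode, query_anchored=False,
        _pairs=pairs_arr, _anchor_batch_pool=pool,
    )


def build_query_triplets(
    ref_latent: np.ndarray,
    query_latent: np.ndarray,
    k_mnn: int = 20,
    negatives_per_anchor: int = 1,
    seed: int = 0,
    margin: float = 1.0,
    max_pairs: int = MAX_PAIRS_DEFAULT,
) -> TripletSet:
    """Query-anchored triplets from MNN pairs between query and reference.

    Indices in the returned triples refer to query rows for anchors and
    negatives and to reference rows (offset by the number of query cells)
    for positives; consumers receive the latents stacked [query; reference].
    """
    ref_latent = np.asarray(ref_latent, dtype=np.float64)
    query_latent = np.asarray(query_latent, dtype=np.float64)
    n_q = query_latent.shape[0]
    rng = np.random.default_rng(seed)
    mnn = find_mnn_pairs(query_latent, ref_latent, k_mnn)
    if not mnn:
        raise ValueError(
            "no mutual nearest neighbor pairs between query and reference; "
            "try a larger k_mnn"
        )
    pairs_arr = np.asarray(
        [(i, n_q + j) for i, j in mnn], dtype=np.intp
    )
    if len(pairs_arr) > max_pairs:
        keep = rng.choice(len(pairs_arr), size=max_pairs, replace=False)
        pairs_arr = pairs_arr[np.sort(keep)]
    # all query cells form one batch
    pool = _negative_pools(pairs_arr[:, 0], np.zeros(n_q, dtype=int))
    pairs_arr = pairs_arr[np.isin(pairs_arr[:, 0], list(pool.keys()))]
    if len(pairs_arr) == 0:
        raise ValueError("no query triplets could be formed")
    triples = _attach_negatives(pairs_arr, pool, negatives_per_anchor, rng)
    return TripletSet(
        triples=triples, margin=margin, mode="mnn-based", query_anchored=True,
        _pairs=pairs_arr, _anchor_batch_pool=pool,
    )
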