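"""Normalization, per-batch scaling and the HVG/LVG gene split.

The pipeline mirrors standard single-cell practice: counts are library-
size normalized to 10,000 and log1p-transformed, genes are split into a
highly-variable set (ranked by a batch-aware dispersion score) and its
lowly-variable complement, and expression is z-scored gene-wise within
each batch so that batch-specific location/scale differences do not
dominate the encoders' input.
"""

from __future__ import annotations

import numpy as np

from .data import PreparedDataset, RawBatchCollection, _validate_counts

__all__ = [
    "normalize_log",
    "zscore_per_batch",
    "select_hvgs",
    "prepare_dataset",
]

SCALE_FACTOR = 10_000.0
SIGMA_CLAMP = 1e-8


def normalize_log(counts: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    """Library-size normalize to 10k counts per cell and log1p-transform.

    ``out[i, j] = ln(1 + 10000 * counts[i, j] / lib_sizes[i])`` (natural log).
    """
    counts = np.asarray(counts)
    lib_sizes = np.asarray(lib_sizes, dtype=np.float64)
    _validate_counts(counts)
    row_nonzero = counts.sum(axis=1) > 0
    if np.any(row_nonzero & (lib_sizes <= 0)):
        raise ValueError("zero or negative library size for a cell with counts")
    safe_lib = np.where(lib_sizes > 0, lib_sizes, 1.0)
    return np.log1p(SCALE_FACTOR * counts / safe_lib[:, None])


def zscore_per_batch(
    normed: np.ndarray, batch_ids: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Z-score each gene within each batch (population sd, ddof 0).

    Genes with within-batch sd below ``SIGMA_CLAMP`` are set to zero for
    that batch. Returns the scaled matrix and per-batch (mean, sd) stats.
    """
    normed = np.asarray(normed, dtype=np.float64)
    batch_ids = np.asarray(batch_ids)
    out = np.empty_like(normed)
    stats: dict = {}
    for b in np.unique(batch_ids):
        mask = batch_ids == b
        if mask.sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 cells")
        block = normed[mask]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=0)
        ok = sd >= SIGMA_CLAMP
        scaled = np.where(ok, (block - mu) / np.where(ok, sd, 1.0), 0.0)
        out[mask] = scaled
        stats[b] = (mu, sd)
    return out, stats


def select_hvgs(
    normed: np.ndarray, batch_ids: np.ndarray, n_top: int = 2000
) -> tuple[np.ndarray, np.ndarray]:
    """Batch-aware highly-variable-gene selection on log-normalized data.

    Within each batch, genes are scored by the variance/mean dispersion
    of their library-normalized (expm1-scale) expression, robust-z-scored
    (median/MAD) within mean-quantile bins so that genes compete against
    genes of similar expression level rather than being rewarded for it —
    the standard binned-dispersion criterion of single-cell toolkits,
    with bin counts scaled down gracefully for small panels. Per-batch
    scores are averaged, making the ranking batch-aware: variability that
    only reflects between-batch shifts does not count. Ties break toward
    the lower gene index, so the split is deterministic.
    """
    normed = np.asarray(normed, dtype=np.float64)
    batch_ids = np.asarray(batch_ids)
    n_genes = normed.shape[1]
    if not 1 <= n_top < n_genes:
        raise ValueError(
            f"n_top must satisfy 1 <= n_top < {n_genes} (LVG set must be non-empty)"
        )
    n_bins = min(20, max(1, n_genes // 10))
    score = np.zeros(n_genes)
    batches = np.unique(batch_ids)
    for b in batches:
        block = np.expm1(normed[batch_ids == b])
        mu = block.mean(axis=0)
        disp = block.var(axis=0) / np.maximum(mu, 1e-12)
        edges = np.quantile(mu, np.linspace(0, 1, n_bins + 1))
        edges[-1] += 1e-9
        bins = np.clip(
            np.searchsorted(edges, mu, side="right") - 1, 0, n_bins - 1
        )
        z = np.zeros(n_genes)
        for k in np.unique(bins):
            mask = bins == k
            med = np.median(disp[mask])
            mad = np.median(np.abs(disp[mask] - med))
            z[mask] = (disp[mask] - med) / max(mad, 1e-12)
        score += z
    score /= len(batches)

    order = np.lexsort((np.arange(n_genes), -score))
    return np.sort(order[:n_top]), np.sort(order[n_top:])


def prepare_dataset(
    raw: RawBatchCollection,
    n_top: int = 2000,
    hvg_lvg: tuple[np.ndarray, np.ndarray] | None = None,
) -> PreparedDataset:
    """Run the full preprocessing pipeline on a raw batch collection.

    The gene universe is the intersection of the batches' gene sets,
    ordered by the first batch. Library sizes are computed on that
    overlapping set, then: normalize_log -> select_hvgs -> zscore_per_batch
    -> concatenate. ``hvg_lvg`` overrides HVG selection with a precomputed
    split (used when preparing query data against a reference).
    """
    first_genes = list(raw.batches[0].gene_ids)
    if len(set(first_genes)) != len(first_genes):
        raise ValueError("duplicated gene ids in batch 0")
    common = set(first_genes)
    for b in raw.batches[1:]:
        ids = list(b.gene_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicated gene ids in a batch")
        common &= set(ids)
    genes = [g for g in first_genes if g in common]
    if len(genes) < 2:
        raise ValueError("fewer than 2 genes shared across batches")

    count_blocks, cell_id_blocks, label_blocks = [], [], []
    batch_id_list = []
    for bi, batch in enumerate(raw.batches):
        col = {g: j for j, g in enumerate(batch.gene_ids)}
        idx = np.array([col[g] for g in genes])
        count_blocks.append(np.asarray(batch.counts, dtype=np.float64)[:, idx])
        cell_id_blocks.append(batch.cell_ids)
        batch_id_list.append(np.full(batch.counts.shape[0], bi))
        if batch.cell_labels is not None:
            label_blocks.append(batch.cell_labels)

    counts = np.concatenate(count_blocks, axis=0)
    batch_ids = np.concatenate(batch_id_list)
    lib = counts.sum(axis=1)
    normed = normalize_log(counts, lib)
    if hvg_lvg is None:
        hvg, lvg = select_hvgs(normed, batch_ids, n_top=n_top)
    else:
        hvg, lvg = (np.asarray(hvg_lvg[0]), np.asarray(hvg_lvg[1]))
    X_scale, stats = zscore_per_batch(normed, batch_ids)

    B = raw.n_batches
    onehot = np.zeros((counts.shape[0], B))
    onehot[np.arange(counts.shape[0]), batch_ids] = 1.0

    labels = labels_onehot = label_names = None
    if len(label_blocks) == len(raw.batches):
        labels = np.concatenate(label_blocks)
        label_names = np.array(sorted(set(labels)), dtype=object)
        lut = {name: k for k, name in enumerate(label_names)}
        labels_onehot = np.zeros((len(labels), len(label_names)))
        labels_onehot[np.arange(len(labels)), [lut[l] for l in labels]] = 1.0

    return PreparedDataset(
        X_scale=X_scale,
        counts=counts,
        lib_sizes=lib,
        batch_onehot=onehot,
        batch_ids=batch_ids,
        hvg_index=hvg,
        lvg_index=lvg,
        gene_ids=np.array(genes, dtype=object),
        cell_ids=np.concatenate(cell_id_blocks),
        batch_names=list(raw.batch_names),
        scale_stats=stats,
        labels_onehot=labels_onehot,
        label_names=label_names,
        labels=labels,
    )
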