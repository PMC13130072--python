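"""In-memory containers for raw multi-batch counts and prepared data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RawBatch", "RawBatchCollection", "PreparedDataset"]


@dataclass
class RawBatch:
    """One batch of raw counts: cells x genes, with identifiers."""

    counts: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cell_labels: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.cell_labels is not None:
            self.cell_labels = np.asarray(self.cell_labels, dtype=object)
        n, p = self.counts.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != p:
            raise ValueError("identifier lengths do not match the count matrix")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids must be unique within a batch")
        if self.cell_labels is not None and len(self.cell_labels) != n:
            raise ValueError("one label per cell required")
        _validate_counts(self.counts)


@dataclass
class RawBatchCollection:
    """Per-batch integer count matrices plus metadata."""

    batches: list[RawBatch]
    batch_names: list[str]

    def __post_init__(self):
        if len(self.batches) != len(self.batch_names):
            raise ValueError("one name per batch required")
        if len(set(self.batch_names)) != len(self.batch_names):
            raise ValueError("batch_names must be unique")
        if not self.batches:
            raise ValueError("at least one batch required")

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    @property
    def has_labels(self) -> bool:
        return all(b.cell_labels is not None for b in self.batches)


@dataclass
class PreparedDataset:
    """Concatenated, normalized, per-batch-scaled expression with gene split.

    ``X_scale`` is the per-batch z-scored log-normalized matrix the encoders
    consume; ``counts`` keeps the raw counts (aligned to the overlapping
    gene set) for the NB reconstruction likelihood; ``lib_sizes`` are row
    sums of those counts.
    """

    X_scale: np.ndarray
    counts: np.ndarray
    lib_sizes: np.ndarray
    batch_onehot: np.ndarray
    batch_ids: np.ndarray
    hvg_index: np.ndarray
    lvg_index: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    batch_names: list[str]
    scale_stats: dict = field(default_factory=dict)  # batch -> (mean, sd)
    labels_onehot: np.ndarray | None = None
    label_names: np.ndarray | None = None
    labels: np.ndarray | None = None
    n_ref_batches: int | None = None  # set for query datasets (B of reference)

    @property
    def n_cells(self) -> int:
        return self.X_scale.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X_scale.shape[1]

    @property
    def n_batches(self) -> int:
        return self.batch_onehot.shape[1]

    @property
    def X_hvg(self) -> np.ndarray:
        return self.X_scale[:, self.hvg_index]

    @property
    def X_lvg(self) -> np.ndarray:
        return self.X_scale[:, self.lvg_index]

    def block_lib(self, block: str) -> np.ndarray:
        """Per-cell library size restricted to one gene block.

        The decoder's mean head is a softmax over the block's genes, so the
        matching NB mean is (block library) x (mean fraction); cells with an
        empty block are floored to avoid a degenerate zero mean.
        """
        idx = self.hvg_index if block == "hvg" else self.lvg_index
        return np.maximum(self.counts[:, idx].sum(axis=1), 1e-3)


def _validate_counts(counts: np.ndarray) -> None:
    if not np.all(np.isfinite(counts)):
        raise ValueError("counts must be finite")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be integers")
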