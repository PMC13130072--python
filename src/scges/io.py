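"""Readers and writers: H5AD / MTX / CSV input, H5AD output, checkpoints."""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .data import RawBatch, RawBatchCollection, PreparedDataset
from .integration import IntegrationResult
from .model import ModelState, build_model

__all__ = [
    "read_h5ad",
    "read_mtx",
    "read_csv",
    "write_result_h5ad",
    "save_checkpoint",
    "load_checkpoint",
]


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


def read_h5ad(
    path,
    batch_key: str = "batch",
    label_key: str | None = None,
    layer: str | None = None,
) -> RawBatchCollection:
    """Load counts from an H5AD file and split cells by a batch column."""
    adata = ad.read_h5ad(path)
    counts = _dense(adata.layers[layer] if layer else adata.X)
    if batch_key not in adata.obs:
        raise KeyError(f"batch key {batch_key!r} not found in obs")
    batch_col = adata.obs[batch_key].astype(str).to_numpy()
    labels = None
    if label_key is not None:
        if label_key not in adata.obs:
            raise KeyError(f"label key {label_key!r} not found in obs")
        labels = adata.obs[label_key].astype(str).to_numpy()
    genes = adata.var_names.to_numpy()
    cells = adata.obs_names.to_numpy()
    batches, names = [], []
    for b in pd.unique(batch_col):
        mask = batch_col == b
        batches.append(
            RawBatch(
                counts=counts[mask],
                cell_ids=cells[mask],
                gene_ids=genes.copy(),
                cell_labels=labels[mask] if labels is not None else None,
            )
        )
        names.append(str(b))
    return RawBatchCollection(batches=batches, batch_names=names)


def read_mtx(
    mtx_path, barcodes_path, features_path, batch_name: str = "batch0",
    labels_path=None,
) -> RawBatchCollection:
    """One batch from an MTX matrix (cells x genes or genes x cells) plus
    barcode and feature TSVs."""
    m = scipy.io.mmread(str(mtx_path))
    counts = _dense(m)
    cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].to_numpy()
    genes = pd.read_csv(features_path, sep="\t", header=None)[0].to_numpy()
    if counts.shape == (len(genes), len(cells)) and counts.shape[0] != counts.shape[1]:
        counts = counts.T
    labels = None
    if labels_path is not None:
        labels = pd.read_csv(labels_path, sep="\t", header=None)[0].to_numpy()
    batch = RawBatch(counts=counts, cell_ids=cells, gene_ids=genes,
                     cell_labels=labels)
    return RawBatchCollection(batches=[batch], batch_names=[batch_name])


def read_csv(path, batch_name: str = "batch0") -> RawBatchCollection:
    """Dense CSV with cells as rows (index column) and genes as columns."""
    df = pd.read_csv(path, index_col=0)
    batch = RawBatch(
        counts=df.to_numpy(),
        cell_ids=df.index.to_numpy(),
        gene_ids=df.columns.to_numpy(),
    )
    return RawBatchCollection(batches=[batch], batch_names=[batch_name])


def write_result_h5ad(
    path,
    data: PreparedDataset,
    result: IntegrationResult | None = None,
    config: dict | None = None,
) -> None:
    """Write scaled expression, embeddings, denoised layers and metadata."""
    obs = pd.DataFrame(index=pd.Index(data.cell_ids.astype(str), name="cell"))
    obs["batch"] = [data.batch_names[b] for b in data.batch_ids]
    if data.labels is not None:
        obs["cell_type"] = data.labels.astype(str)
    var = pd.DataFrame(index=pd.Index(data.gene_ids.astype(str), name="gene"))
    hvg_mask = np.zeros(data.n_genes, dtype=bool)
    hvg_mask[data.hvg_index] = True
    var["highly_variable"] = hvg_mask
    adata = ad.AnnData(X=data.X_scale, obs=obs, var=var)
    adata.layers["counts"] = data.counts
    adata.obs["lib_size"] = data.lib_sizes
    adata.obsm["batch_onehot"] = data.batch_onehot
    if result is not None:
        adata.obsm["X_scges_hvg"] = result.z_hvg
        adata.obsm["X_scges_lvg"] = result.z_lvg
        adata.layers["denoised_norm"] = result.denoised_norm
        adata.layers["denoised_counts_mean"] = result.denoised_counts_mean
        if result.class_probs is not None:
            adata.obsm["class_probs_hvg"] = result.class_probs
            adata.obsm["class_probs_lvg"] = result.class_probs_lvg
    if config is not None:
        adata.uns["scges_config"] = json.dumps(config, default=str)
    adata.write_h5ad(Path(path))


def save_checkpoint(state: ModelState, path, config: dict | None = None) -> None:
    """Single-file checkpoint: parameter arrays + architecture metadata."""
    arrays = {k: v.data for k, v in state.params().items()}
    meta = {
        "arch": state.arch,
        "seed": state.seed,
        "frozen": sorted(state.frozen),
        "extended": state.extended,
        "config": config or {},
        "format_version": 1,
    }
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[ModelState, dict]:
    """Rebuild a ModelState from :func:`save_checkpoint` output."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    arch = meta["arch"]
    state = build_model(
        n_hvg=arch["n_hvg"], n_lvg=arch["n_lvg"], n_batches=arch["n_batches"],
        n_classes=arch["n_classes"], hidden=tuple(arch["hidden"]),
        latent=arch["latent"], seed=meta["seed"],
    )
    if meta["extended"]:
        for blk in (state.hvg, state.lvg):
            blk.encoder.l1.extend()
            blk.decoder.l1.extend()
        state.extended = True
    params = state.params()
    if set(params) != set(arrays):
        raise ValueError("checkpoint does not match the rebuilt architecture")
    for k, p in params.items():
        p.data = arrays[k].astype(np.float64)
    state.frozen = set(meta["frozen"])
    for k in state.frozen:
        params[k].freeze()
    return state, meta.get("config", {})
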