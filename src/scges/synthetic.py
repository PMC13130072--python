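"""Multi-batch negative-binomial count simulator with known ground truth.

Emulates the structure the integration model is built for: several
batches of cells drawn from shared cell types, where a subset of genes
("hvg-like") carries strong between-type differences and the remainder
("lvg-like") carries weak biological signal but — reflecting the typical
situation in real data — stronger batch effects. Counts are sampled from
a negative binomial whose mean factorizes into a gene baseline, a
type effect, a multiplicative (log-normal) batch effect, and a per-cell
size factor. The generating means, batch factors and dispersions are
returned so downstream estimates can be scored against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import RawBatchCollection, RawBatch

__all__ = ["SimTruth", "simulate", "simulate_query"]

# Log-scale spread of between-type mean differences per gene class.
TYPE_EFFECT_SD_HVG = 1.0
TYPE_EFFECT_SD_LVG = 0.15

# Default batch-effect severity (log-scale sd of the multiplicative
# shift); lvg-like genes get the stronger technical distortion.
DEFAULT_BATCH_SD_HVG = 1.0
DEFAULT_BATCH_SD_LVG = 1.5

# gene baselines share one moderate-expression distribution for both
# classes so variability, not expression level, separates them
_BASE_MEAN_LOG_MU = np.log(0.8)
_BASE_MEAN_LOG_SD = 0.7
_SIZE_FACTOR_LOG_SD = 0.3


@dataclass
class SimTruth:
    """Ground truth of a simulation run."""

    cell_types: np.ndarray          # str per cell (concatenated batch order)
    batch_ids: np.ndarray           # int per cell
    true_mean: np.ndarray           # [cells x genes] NB means used for sampling
    batch_factor: np.ndarray        # [batches x genes] log-scale shifts
    gene_class: np.ndarray          # "hvg-like" | "lvg-like" per gene
    theta_true: np.ndarray          # per-gene dispersion
    seed: int
    # internal generative components, needed to draw matched query data
    base_mean: np.ndarray = field(default=None, repr=False)
    type_effect: np.ndarray = field(default=None, repr=False)  # [types x genes]
    type_names: np.ndarray = field(default=None, repr=False)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: np.ndarray):
    # NB(mean, theta) via Gamma-Poisson mixture
    lam = rng.gamma(shape=theta, scale=mean / theta)
    return rng.poisson(lam)


def simulate(
    n_batches: int = 3,
    cells_per_type_per_batch: int = 60,
    n_types: int = 5,
    n_hvg_like: int = 300,
    n_lvg_like: int = 1700,
    batch_sd_hvg: float = DEFAULT_BATCH_SD_HVG,
    batch_sd_lvg: float = DEFAULT_BATCH_SD_LVG,
    theta_range: tuple[float, float] = (5.0, 20.0),
    seed: int = 0,
) -> tuple[RawBatchCollection, SimTruth]:
    """Draw a multi-batch NB count collection plus its generating truth."""
    if min(n_batches, cells_per_type_per_batch, n_types, n_hvg_like, n_lvg_like) < 1:
        raise ValueError("all shape parameters must be >= 1")
    lo, hi = theta_range
    if not (0 < lo <= hi):
        raise ValueError("theta_range must lie in (0, inf)")

    rng = np.random.default_rng(seed)
    n_genes = n_hvg_like + n_lvg_like
    gene_class = np.array(
        ["hvg-like"] * n_hvg_like + ["lvg-like"] * n_lvg_like
    )
    gene_ids = np.array([f"gene{j:05d}" for j in range(n_genes)])
    type_names = np.array([f"type{t}" for t in range(n_types)])

    base_mean = np.exp(
        rng.normal(_BASE_MEAN_LOG_MU, _BASE_MEAN_LOG_SD, size=n_genes)
    )
    type_sd = np.where(gene_class == "hvg-like", TYPE_EFFECT_SD_HVG, TYPE_EFFECT_SD_LVG)
    type_effect = np.exp(rng.normal(0.0, 1.0, size=(n_types, n_genes)) * type_sd)
    batch_sd = np.where(gene_class == "hvg-like", batch_sd_hvg, batch_sd_lvg)
    batch_factor = rng.normal(0.0, 1.0, size=(n_batches, n_genes)) * batch_sd
    theta_true = rng.uniform(lo, hi, size=n_genes)

    batches = []
    all_types, all_bids, all_means = [], [], []
    n_cells_batch = cells_per_type_per_batch * n_types
    for b in range(n_batches):
        types_b = np.repeat(np.arange(n_types), cells_per_type_per_batch)
        size = np.exp(rng.normal(0.0, _SIZE_FACTOR_LOG_SD, size=n_cells_batch))
        mean = (
            base_mean[None, :]
            * type_effect[types_b]
            * np.exp(batch_factor[b])[None, :]
            * size[:, None]
        )
        counts = _nb_sample(rng, mean, theta_true[None, :])
        cell_ids = np.array([f"b{b}_cell{i:04d}" for i in range(n_cells_batch)])
        labels = type_names[types_b]
        batches.append(
            RawBatch(counts=counts, cell_ids=cell_ids, gene_ids=gene_ids.copy(),
                     cell_labels=labels)
        )
        all_types.append(labels)
        all_bids.append(np.full(n_cells_batch, b))
        all_means.append(mean)

    raw = RawBatchCollection(
        batches=batches,
        batch_names=[f"batch{b}" for b in range(n_batches)],
    )
    truth = SimTruth(
        cell_types=np.concatenate(all_types),
        batch_ids=np.concatenate(all_bids),
        true_mean=np.concatenate(all_means, axis=0),
        batch_factor=batch_factor,
        gene_class=gene_class,
        theta_true=theta_true,
        seed=seed,
        base_mean=base_mean,
        type_effect=type_effect,
        type_names=type_names,
    )
    return raw, truth


def simulate_query(
    truth: SimTruth,
    n_cells: int = 300,
    drop_type: str | None = None,
    new_batch_sd: float | None = None,
    seed: int = 1,
) -> tuple[RawBatchCollection, SimTruth]:
    """Draw query cells from the same type-level process under a fresh batch.

    The query shares the reference's gene baselines, type effects and
    dispersions but receives its own multiplicative batch factor (severity
    ``new_batch_sd`` per gene class, defaulting to the reference severities)
    and fresh size factors. ``drop_type`` removes one cell type to mimic a
    query lacking part of the reference's populations.
    """
    if truth.base_mean is None:
        raise ValueError("truth must come from simulate()")
    type_names = list(truth.type_names)
    if drop_type is not None and drop_type not in type_names:
        raise ValueError(f"unknown cell type: {drop_type!r}")
    keep = [t for t in type_names if t != drop_type]

    rng = np.random.default_rng(seed)
    n_genes = truth.true_mean.shape[1]
    if new_batch_sd is None:
        sd = np.where(
            truth.gene_class == "hvg-like", DEFAULT_BATCH_SD_HVG, DEFAULT_BATCH_SD_LVG
        )
    else:
        sd = float(new_batch_sd)
    batch_factor = rng.normal(0.0, 1.0, size=n_genes) * sd

    type_idx = rng.integers(0, len(keep), size=n_cells)
    types_q = np.array([keep[t] for t in type_idx])
    rows = np.array([type_names.index(t) for t in types_q])
    size = np.exp(rng.normal(0.0, _SIZE_FACTOR_LOG_SD, size=n_cells))
    mean = (
        truth.base_mean[None, :]
        * truth.type_effect[rows]
        * np.exp(batch_factor)[None, :]
        * size[:, None]
    )
    counts = _nb_sample(rng, mean, truth.theta_true[None, :])
    gene_ids = np.array([f"gene{j:05d}" for j in range(n_genes)])
    cell_ids = np.array([f"q_cell{i:04d}" for i in range(n_cells)])

    raw = RawBatchCollection(
        batches=[RawBatch(counts=counts, cell_ids=cell_ids, gene_ids=gene_ids,
                          cell_labels=types_q)],
        batch_names=["query"],
    )
    qtruth = SimTruth(
        cell_types=types_q,
        batch_ids=np.zeros(n_cells, dtype=int),
        true_mean=mean,
        batch_factor=batch_factor[None, :],
        gene_class=truth.gene_class,
        theta_true=truth.theta_true,
        seed=seed,
        base_mean=truth.base_mean,
        type_effect=truth.type_effect,
        type_names=truth.type_names,
    )
    return raw, qtruth
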