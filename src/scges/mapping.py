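"""Query mapping onto a frozen reference model via architecture surgery.

A trained integration model is extended with one zero-initialized
batch-input column representing the query; only those extension weights
are trained, so every reference output is exactly invariant. The HVG
extension is fit with a query-anchored triplet loss (MNN pairs between
query and reference latents) plus NB reconstruction; the LVG extension
alternates reconstruction with a soft-label classification loss whose
targets are the HVG branch's predicted class probabilities.
"""

from __future__ import annotations

import copy
import logging

import numpy as np

from ._autodiff import Tensor, concat
from .anchors import TripletSet, build_query_triplets
from .config import TrainConfig
from .data import PreparedDataset, RawBatchCollection
from .integration import (
    IntegrationResult,
    _check_finite,
    _embed,
    denoise,
)
from .model import (
    ModelState,
    cross_entropy,
    extend_for_query,
    forward,
    make_optimizer,
    nb_nll,
    triplet_loss,
)
from .preprocessing import normalize_log, zscore_per_batch

from sklearn.base import BaseEstimator

__all__ = ["align_query", "train_map_hvg", "train_map_lvg", "map_and_denoise",
           "SCGESMapper"]

logger = logging.getLogger(__name__)


def align_query(
    raw_query: RawBatchCollection, reference: PreparedDataset
) -> PreparedDataset:
    """Preprocess a query batch and align its genes to the reference order.

    The query is normalized and z-scored with its own statistics (the same
    per-batch procedure the reference received). Reference genes absent
    from the query are zero-filled; query-only genes are dropped. The
    returned dataset carries a batch one-hot with B+1 columns, the new
    column hot, and reference HVG/LVG indices.
    """
    if raw_query.n_batches != 1:
        raise ValueError("map one query batch at a time")
    batch = raw_query.batches[0]
    ref_genes = list(reference.gene_ids)
    qcol = {g: j for j, g in enumerate(batch.gene_ids)}
    overlap = sum(g in qcol for g in ref_genes)
    frac = overlap / len(ref_genes)
    if frac < 0.5:
        raise ValueError(
            f"query shares only {frac:.0%} of reference genes (< 50%)"
        )
    if frac < 0.8:
        logger.warning("query shares only %.0f%% of reference genes", 100 * frac)

    n_q = batch.counts.shape[0]
    counts = np.zeros((n_q, len(ref_genes)))
    missing = 0
    qc = np.asarray(batch.counts, dtype=np.float64)
    for j, g in enumerate(ref_genes):
        if g in qcol:
            counts[:, j] = qc[:, qcol[g]]
        else:
            missing += 1
    if missing:
        logger.info("%d reference genes absent from query were zero-filled",
                    missing)

    lib = counts.sum(axis=1)
    normed = normalize_log(counts, lib)
    x_scale, stats = zscore_per_batch(normed, np.zeros(n_q, dtype=int))

    n_ref_b = reference.n_batches
    onehot = np.zeros((n_q, n_ref_b + 1))
    onehot[:, n_ref_b] = 1.0

    labels = labels_onehot = label_names = None
    if batch.cell_labels is not None:
        labels = batch.cell_labels

    return PreparedDataset(
        X_scale=x_scale,
        counts=counts,
        lib_sizes=lib,
        batch_onehot=onehot,
        batch_ids=np.full(n_q, n_ref_b),
        hvg_index=reference.hvg_index,
        lvg_index=reference.lvg_index,
        gene_ids=reference.gene_ids,
        cell_ids=batch.cell_ids,
        batch_names=list(reference.batch_names) + list(raw_query.batch_names),
        scale_stats=stats,
        labels_onehot=labels_onehot,
        label_names=label_names,
        labels=labels,
        n_ref_batches=n_ref_b,
    )


def _query_triplet_minibatch(state, x, s, ref_latent, triplets, take, rng):
    """Sample triples and build a mixed latent: live query rows + fixed
    reference rows (the reference side never moves during mapping)."""
    t = triplets.triples
    n_q = x.shape[0]
    if len(t) > take:
        t = t[rng.choice(len(t), size=take, replace=False)]
    qcells = np.unique(t[t < n_q])
    rcells = np.unique(t[t >= n_q]) - n_q
    z_q = state.hvg.encoder(x[qcells], s[qcells])
    parts = [z_q]
    if len(rcells):
        parts.append(Tensor(ref_latent[rcells]))
    stacked = concat(parts, axis=0)
    lut = {int(c): i for i, c in enumerate(qcells)}
    lut.update({int(c) + n_q: len(qcells) + i for i, c in enumerate(rcells)})
    local = np.vectorize(lut.__getitem__)(t)
    sub = TripletSet(triples=local, margin=triplets.margin,
                     mode=triplets.mode, query_anchored=True)
    return stacked, sub


def train_map_hvg(
    query: PreparedDataset,
    state: ModelState,
    cfg: TrainConfig,
    ref_latent: np.ndarray | None = None,
    triplets: TripletSet | None = None,
    k_mnn: int = 20,
    negatives_per_anchor: int = 1,
) -> tuple[ModelState, list[dict]]:
    """Fit the HVG query extensions: β3·L'_tri + L'_recon over W' only."""
    if not state.extended:
        raise ValueError("extend_for_query must be called before mapping")
    w = cfg.weights
    rng = np.random.default_rng(cfg.seed)
    x = query.X_hvg
    s = query.batch_onehot
    if w.beta3 > 0:
        if ref_latent is None:
            raise ValueError("ref_latent required when beta3 > 0")
        if triplets is None:
            q_latent = _embed(state, "hvg", x, s)
            triplets = build_query_triplets(
                ref_latent, q_latent, k_mnn=k_mnn,
                negatives_per_anchor=negatives_per_anchor,
                seed=cfg.seed, margin=w.alpha,
            )
    counts = query.counts[:, query.hvg_index]
    lib = query.block_lib("hvg")
    n = query.n_cells
    opt = make_optimizer(state, ["hvg."], cfg.learning_rate)
    log: list[dict] = []
    best, since_best = np.inf, 0
    for epoch in range(cfg.epochs_hvg):
        if w.beta3 > 0:
            triplets.resample_negatives(rng)
        perm = rng.permutation(n)
        sums = {"recon": 0.0, "tri": 0.0, "total": 0.0}
        steps = 0
        for start in range(0, n, cfg.minibatch_size):
            idx = perm[start:start + cfg.minibatch_size]
            if len(idx) < 2:
                continue
            _, (mu, theta), _ = forward(
                state, "hvg", x[idx], s[idx], as_tensors=True
            )
            recon = nb_nll(counts[idx], lib[idx], mu, theta)
            _check_finite(float(recon.data), "reconstruction")
            loss = recon
            comp_tri = 0.0
            if w.beta3 > 0:
                stacked, sub = _query_triplet_minibatch(
                    state, x, s, ref_latent, triplets, cfg.triplet_batch, rng
                )
                tri = triplet_loss(stacked, sub)
                _check_finite(float(tri.data), "triplet")
                comp_tri = float(tri.data)
                loss = loss + w.beta3 * tri
            opt.zero_grad()
            loss.backward()
            opt.step()
            sums["recon"] += float(recon.data)
            sums["tri"] += comp_tri
            sums["total"] += float(loss.data)
            steps += 1
        entry = {k: v / max(steps, 1) for k, v in sums.items()}
        entry["epoch"] = epoch
        log.append(entry)
        if entry["total"] < best - cfg.early_stop_min_delta:
            best, since_best = entry["total"], 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break
    return state, log


def train_map_lvg(
    query: PreparedDataset,
    state: ModelState,
    cfg: TrainConfig,
) -> tuple[ModelState, list[dict]]:
    """Fit the LVG query extensions, alternating NB reconstruction with a
    soft-label classification step targeting the HVG branch's q'_H."""
    if not state.extended:
        raise ValueError("extend_for_query must be called before mapping")
    x_h = query.X_hvg
    s = query.batch_onehot
    z_h = _embed(state, "hvg", x_h, s)
    soft = None
    if state.hvg.classifier is not None:
        soft = np.exp(state.hvg.classifier.log_probs(Tensor(z_h)).data)
    else:
        logger.warning("reference has no classifier: soft-label phase skipped")

    x = query.X_lvg
    counts = query.counts[:, query.lvg_index]
    lib = query.block_lib("lvg")
    n = query.n_cells
    rng = np.random.default_rng(cfg.seed + 1)
    opt = make_optimizer(state, ["lvg."], cfg.learning_rate)
    log: list[dict] = []
    best, since_best = np.inf, 0
    phase_idx = 0
    for epoch in range(cfg.epochs_lvg):
        perm = rng.permutation(n)
        sums = {"recon": 0.0, "cls": 0.0}
        nsteps = {"recon": 0, "cls": 0}
        phases = []
        for start in range(0, n, cfg.minibatch_size):
            idx = perm[start:start + cfg.minibatch_size]
            if len(idx) < 2:
                continue
            phase = "R" if (phase_idx // cfg.alternating_period) % 2 == 0 else "C"
            if soft is None:
                phase = "R"
            phase_idx += 1
            phases.append(phase)
            _, (mu, theta), logq = forward(
                state, "lvg", x[idx], s[idx], aux_latent=z_h[idx], as_tensors=True
            )
            if phase == "R":
                loss = nb_nll(counts[idx], lib[idx], mu, theta)
                _check_finite(float(loss.data), "reconstruction")
                sums["recon"] += float(loss.data)
                nsteps["recon"] += 1
            else:
                loss = cross_entropy(soft[idx], log_q=logq)
                _check_finite(float(loss.data), "classification")
                sums["cls"] += float(loss.data)
                nsteps["cls"] += 1
            opt.zero_grad()
            loss.backward()
            opt.step()
        entry = {
            "epoch": epoch,
            "recon": sums["recon"] / max(nsteps["recon"], 1),
            "cls": sums["cls"] / max(nsteps["cls"], 1),
            "phases": "".join(phases),
        }
        entry["total"] = entry["recon"] + entry["cls"]
        log.append(entry)
        if entry["total"] < best - cfg.early_stop_min_delta:
            best, since_best = entry["total"], 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break
    return state, log


def map_and_denoise(
    query: PreparedDataset,
    state: ModelState,
    target_batch: int | str = 0,
) -> IntegrationResult:
    """Evaluation-mode forward of the mapped query through both blocks."""
    return denoise(query, state, target_batch=target_batch)


class SCGESMapper(BaseEstimator):
    """Map a query batch onto a frozen, fitted :class:`SCGESIntegrator`.

    ``fit`` performs architecture surgery on a deep copy of the reference
    model (the integrator is left untouched), trains the query extension
    weights, and exposes the mapped embeddings and soft labels.
    """

    def __init__(
        self,
        integrator=None,
        beta3: float = 1.0,
        alpha: float = 1.0,
        epochs_hvg: int = 80,
        epochs_lvg: int = 40,
        minibatch_size: int = 256,
        learning_rate: float = 1e-3,
        early_stop_patience: int = 10,
        alternating_period: int = 1,
        k_mnn: int = 20,
        negatives_per_anchor: int = 1,
        target_batch: int | str = "reference-largest",
        seed: int = 0,
    ):
        self.integrator = integrator
        self.beta3 = beta3
        self.alpha = alpha
        self.epochs_hvg = epochs_hvg
        self.epochs_lvg = epochs_lvg
        self.minibatch_size = minibatch_size
        self.learning_rate = learning_rate
        self.early_stop_patience = early_stop_patience
        self.alternating_period = alternating_period
        self.k_mnn = k_mnn
        self.negatives_per_anchor = negatives_per_anchor
        self.target_batch = target_batch
        self.seed = seed

    def fit(
        self,
        query: PreparedDataset | RawBatchCollection,
        reference: PreparedDataset,
    ) -> "SCGESMapper":
        if self.integrator is None or not hasattr(self.integrator, "state_"):
            raise ValueError("a fitted SCGESIntegrator is required")
        if isinstance(query, RawBatchCollection):
            query = align_query(query, reference)
        if query.n_ref_batches is None:
            raise ValueError("query dataset must come from align_query")

        self.ref_target_batch_ = int(
            np.argmax(reference.batch_onehot.sum(axis=0))
        )
        state = copy.deepcopy(self.integrator.state_)
        extend_for_query(state)
        cfg = TrainConfig(
            weights=self.integrator._train_config().weights,
            epochs_hvg=self.epochs_hvg, epochs_lvg=self.epochs_lvg,
            minibatch_size=self.minibatch_size,
            learning_rate=self.learning_rate,
            early_stop_patience=self.early_stop_patience,
            alternating_period=self.alternating_period, seed=self.seed,
        )
        cfg.weights.beta3 = self.beta3
        cfg.weights.alpha = self.alpha

        ref_latent = self.integrator.z_hvg_
        state, hvg_log = train_map_hvg(
            query, state, cfg, ref_latent=ref_latent,
            k_mnn=self.k_mnn, negatives_per_anchor=self.negatives_per_anchor,
        )
        state, lvg_log = train_map_lvg(query, state, cfg)

        self.state_ = state
        self.query_ = query
        self.training_log_ = {"hvg": hvg_log, "lvg": lvg_log}
        self.z_hvg_ = _embed(state, "hvg", query.X_hvg, query.batch_onehot)
        self.z_lvg_ = _embed(state, "lvg", query.X_lvg, query.batch_onehot)
        if state.hvg.classifier is not None:
            self.q_hvg_ = np.exp(
                state.hvg.classifier.log_probs(Tensor(self.z_hvg_)).data
            )
            joint = np.concatenate([self.z_hvg_, self.z_lvg_], axis=1)
            self.q_lvg_ = np.exp(
                state.lvg.classifier.log_probs(Tensor(joint)).data
            )
        else:
            self.q_hvg_ = self.q_lvg_ = None
        return self

    def map_and_denoise(
        self, target_batch: int | str | None = None
    ) -> IntegrationResult:
        if not hasattr(self, "state_"):
            raise RuntimeError("mapper is not fitted; call fit() first")
        tb = self.target_batch if target_batch is None else target_batch
        if tb == "reference-largest":
            tb = self.ref_target_batch_
        result = map_and_denoise(self.query_, self.state_, target_batch=tb)
        result.class_probs = self.q_hvg_
        result.class_probs_lvg = self.q_lvg_
        return result
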