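"""Reference integration: train the HVG and LVG blocks, embed and denoise.

The HVG block minimizes a weighted sum of triplet, classification and NB
reconstruction losses; the LVG block is then trained with the HVG latent
held fixed, alternating between reconstruction and classification steps.
Denoised expression is the decoded NB mean (library size x mean
fraction); decoding every cell at one shared batch code yields the
batch-harmonized matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .anchors import TripletSet, build_triplets
from .config import TrainConfig
from .data import PreparedDataset
from .model import (
    LossWeights,
    ModelState,
    build_model,
    cross_entropy,
    extend_for_query,  # re-exported for convenience  # noqa: F401
    forward,
    make_optimizer,
    nb_nll,
    triplet_loss,
)
from .preprocessing import SCALE_FACTOR

__all__ = [
    "IntegrationResult",
    "train_hvg_block",
    "train_lvg_block",
    "denoise",
    "SCGESIntegrator",
]

logger = logging.getLogger(__name__)


@dataclass
class IntegrationResult:
    """Embeddings, NB parameters and denoised expression for a dataset."""

    state: ModelState
    z_hvg: np.ndarray
    z_lvg: np.ndarray
    denoised_norm: np.ndarray          # ln(1 + 1e4 * mu): log-scale denoised
    denoised_counts_mean: np.ndarray   # lib * mu: NB mean per cell x gene
    class_probs: np.ndarray | None     # HVG-branch probabilities
    class_probs_lvg: np.ndarray | None
    training_log: dict = field(default_factory=dict)


def _check_finite(value: float, component: str) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite {component} loss encountered")


def _encode_triplet_minibatch(state, x, s, triplets, take, rng, block="hvg"):
    """Sample `take` triples and encode the involved cells only."""
    t = triplets.triples
    if len(t) > take:
        t = t[rng.choice(len(t), size=take, replace=False)]
    cells, local = np.unique(t, return_inverse=True)
    local = local.reshape(t.shape)
    blk = state.hvg if block == "hvg" else state.lvg
    z = blk.encoder(x[cells], s[cells])
    sub = TripletSet(triples=local, margin=triplets.margin,
                     mode=triplets.mode, query_anchored=triplets.query_anchored)
    return z, sub


def train_hvg_block(
    data: PreparedDataset,
    triplets: TripletSet | None,
    cfg: TrainConfig,
    state: ModelState | None = None,
) -> tuple[ModelState, list[dict]]:
    """Fit the HVG block by minibatch Adam on β1·L_tri + β2·L_cls + L_recon."""
    w = cfg.weights
    if w.beta2 > 0 and data.labels_onehot is None:
        raise ValueError("beta2 > 0 requires cell labels (or set beta2 = 0)")
    if w.beta1 > 0 and (triplets is None or len(triplets) == 0):
        raise ValueError("beta1 > 0 requires a non-empty triplet set")

    if state is None:
        n_classes = (
            data.labels_onehot.shape[1] if data.labels_onehot is not None else None
        )
        state = build_model(
            n_hvg=len(data.hvg_index), n_lvg=len(data.lvg_index),
            n_batches=data.n_batches, n_classes=n_classes, seed=cfg.seed,
        )
    rng = np.random.default_rng(cfg.seed)
    opt = make_optimizer(state, ["hvg."], cfg.learning_rate)

    x = data.X_hvg
    s = data.batch_onehot
    counts = data.counts[:, data.hvg_index]
    lib = data.block_lib("hvg")
    n = data.n_cells
    log: list[dict] = []
    best, since_best = np.inf, 0
    for epoch in range(cfg.epochs_hvg):
        if w.beta1 > 0:
            triplets.resample_negatives(rng)
        perm = rng.permutation(n)
        sums = {"recon": 0.0, "cls": 0.0, "tri": 0.0, "total": 0.0}
        steps = 0
        for start in range(0, n, cfg.minibatch_size):
            idx = perm[start:start + cfg.minibatch_size]
            if len(idx) < 2:
                continue
            _, (mu, theta), logq = forward(
                state, "hvg", x[idx], s[idx], as_tensors=True
            )
            recon = nb_nll(counts[idx], lib[idx], mu, theta)
            _check_finite(float(recon.data), "reconstruction")
            loss = recon
            comp = {"recon": float(recon.data), "cls": 0.0, "tri": 0.0}
            if w.beta2 > 0:
                cls = cross_entropy(data.labels_onehot[idx], log_q=logq)
                _check_finite(float(cls.data), "classification")
                comp["cls"] = float(cls.data)
                loss = loss + w.beta2 * cls
            if w.beta1 > 0:
                z_tri, sub = _encode_triplet_minibatch(
                    state, x, s, triplets, cfg.triplet_batch, rng
                )
                tri = triplet_loss(z_tri, sub)
                _check_finite(float(tri.data), "triplet")
                comp["tri"] = float(tri.data)
                loss = loss + w.beta1 * tri
            opt.zero_grad()
            loss.backward()
            opt.step()
            for key in ("recon", "cls", "tri"):
                sums[key] += comp[key]
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


def train_lvg_block(
    data: PreparedDataset,
    hvg_state: ModelState,
    cfg: TrainConfig,
) -> tuple[ModelState, list[dict]]:
    """Fit the LVG block with the HVG latent frozen, alternating R/C phases."""
    state = hvg_state
    z_h = _embed(state, "hvg", data.X_hvg, data.batch_onehot)
    has_labels = data.labels_onehot is not None
    if not has_labels:
        logger.warning("no labels: LVG classification phase skipped")
    opt = make_optimizer(state, ["lvg."], cfg.learning_rate)

    x = data.X_lvg
    s = data.batch_onehot
    counts = data.counts[:, data.lvg_index]
    lib = data.block_lib("lvg")
    n = data.n_cells
    rng = np.random.default_rng(cfg.seed + 1)
    log: list[dict] = []
    best, since_best = np.inf, 0
    phase_idx = 0
    for epoch in range(cfg.epochs_lvg):
        perm = rng.permutation(n)
        sums = {"recon": 0.0, "cls": 0.0}
        counts_phase = {"recon": 0, "cls": 0}
        phases = []
        for start in range(0, n, cfg.minibatch_size):
            idx = perm[start:start + cfg.minibatch_size]
            if len(idx) < 2:
                continue
            phase = "R" if (phase_idx // cfg.alternating_period) % 2 == 0 else "C"
            if not has_labels:
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
                counts_phase["recon"] += 1
            else:
                loss = cross_entropy(data.labels_onehot[idx], log_q=logq)
                _check_finite(float(loss.data), "classification")
                sums["cls"] += float(loss.data)
                counts_phase["cls"] += 1
            opt.zero_grad()
            loss.backward()
            opt.step()
        entry = {
            "epoch": epoch,
            "recon": sums["recon"] / max(counts_phase["recon"], 1),
            "cls": sums["cls"] / max(counts_phase["cls"], 1),
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


def _embed(state: ModelState, block: str, x: np.ndarray, s: np.ndarray,
           chunk: int = 2048) -> np.ndarray:
    blk = state.hvg if block == "hvg" else state.lvg
    outs = [
        blk.encoder(x[i:i + chunk], s[i:i + chunk]).data
        for i in range(0, x.shape[0], chunk)
    ]
    return np.concatenate(outs, axis=0)


def denoise(
    data: PreparedDataset,
    state: ModelState,
    target_batch: int | str = "largest",
) -> IntegrationResult:
    """Evaluation-mode embeddings, NB parameters and denoised expression.

    Cells are always *encoded* with their own batch code; the decoder is
    conditioned on ``target_batch``: an index produces the harmonized
    matrix (every cell decoded as that batch), "per-cell" keeps each
    cell's own code (denoised only), "largest" picks the biggest batch.
    """
    n, p = data.counts.shape
    n_b = data.batch_onehot.shape[1]
    width = state.arch["n_batches"] + (1 if state.extended else 0)
    if target_batch == "largest":
        target_batch = int(np.argmax(data.batch_onehot.sum(axis=0)))
    if isinstance(target_batch, (int, np.integer)):
        if not 0 <= target_batch < width:
            raise ValueError(f"target_batch {target_batch} out of range [0, {width})")
        s_dec = np.zeros((n, width))
        s_dec[:, int(target_batch)] = 1.0
    elif target_batch == "per-cell":
        s_dec = np.zeros((n, width))
        s_dec[:, :n_b] = data.batch_onehot
    else:
        raise ValueError("target_batch must be an index, 'largest' or 'per-cell'")

    s_enc = data.batch_onehot
    z_h = _embed(state, "hvg", data.X_hvg, s_enc)
    z_l = _embed(state, "lvg", data.X_lvg, s_enc)

    from ._autodiff import Tensor, concat

    mu_h, th_h = state.hvg.decoder(Tensor(z_h), s_dec)
    joint = concat([Tensor(z_h), Tensor(z_l)], axis=1)
    mu_l, th_l = state.lvg.decoder(joint, s_dec)
    q_h = q_l = None
    if state.hvg.classifier is not None:
        q_h = np.exp(state.hvg.classifier.log_probs(Tensor(z_h)).data)
    if state.lvg.classifier is not None:
        q_l = np.exp(state.lvg.classifier.log_probs(joint).data)

    lib_h = data.block_lib("hvg")[:, None]
    lib_l = data.block_lib("lvg")[:, None]
    lib = np.maximum(data.lib_sizes, 1e-3)[:, None]
    counts_mean = np.empty((n, p))
    counts_mean[:, data.hvg_index] = lib_h * mu_h.data
    counts_mean[:, data.lvg_index] = lib_l * mu_l.data
    # log-scale denoised expression, normalized by the full library so it is
    # directly comparable to the log-normalized input matrix
    den_norm = np.empty((n, p))
    den_norm[:, data.hvg_index] = np.log1p(SCALE_FACTOR * lib_h * mu_h.data / lib)
    den_norm[:, data.lvg_index] = np.log1p(SCALE_FACTOR * lib_l * mu_l.data / lib)

    return IntegrationResult(
        state=state, z_hvg=z_h, z_lvg=z_l,
        denoised_norm=den_norm, denoised_counts_mean=counts_mean,
        class_probs=q_h, class_probs_lvg=q_l,
    )


class SCGESIntegrator(TransformerMixin, BaseEstimator):
    """Dual-branch conditional NB autoencoder for multi-batch integration.

    Fitting trains the HVG block (triplet + classification + NB
    reconstruction) and then the LVG block (alternating reconstruction /
    classification with the HVG latent frozen). ``transform`` returns the
    harmonized HVG embedding; :meth:`denoise` returns embeddings plus
    denoised whole-transcriptome expression.

    Parameters follow the printed defaults where the method states them
    (margin ``alpha=1``, ``beta1=1``, ``beta2=5``) and conventional values
    elsewhere.
    """

    def __init__(
        self,
        alpha: float = 1.0,
        beta1: float = 1.0,
        beta2: float = 5.0,
        epochs_hvg: int = 120,
        epochs_lvg: int = 120,
        minibatch_size: int = 256,
        learning_rate: float = 1e-3,
        early_stop_patience: int = 20,
        alternating_period: int = 1,
        triplet_mode: str = "auto",
        k_mnn: int = 20,
        negatives_per_anchor: int = 1,
        hidden: tuple = (512, 256),
        latent: int = 32,
        target_batch: int | str = "largest",
        seed: int = 0,
    ):
        self.alpha = alpha
        self.beta1 = beta1
        self.beta2 = beta2
        self.epochs_hvg = epochs_hvg
        self.epochs_lvg = epochs_lvg
        self.minibatch_size = minibatch_size
        self.learning_rate = learning_rate
        self.early_stop_patience = early_stop_patience
        self.alternating_period = alternating_period
        self.triplet_mode = triplet_mode
        self.k_mnn = k_mnn
        self.negatives_per_anchor = negatives_per_anchor
        self.hidden = hidden
        self.latent = latent
        self.target_batch = target_batch
        self.seed = seed

    def _train_config(self) -> TrainConfig:
        beta2 = self.beta2
        return TrainConfig(
            weights=LossWeights(alpha=self.alpha, beta1=self.beta1, beta2=beta2),
            epochs_hvg=self.epochs_hvg, epochs_lvg=self.epochs_lvg,
            minibatch_size=self.minibatch_size,
            learning_rate=self.learning_rate,
            early_stop_patience=self.early_stop_patience,
            alternating_period=self.alternating_period, seed=self.seed,
        )

    def fit(self, data: PreparedDataset, y=None) -> "SCGESIntegrator":
        if not isinstance(data, PreparedDataset):
            raise TypeError("fit expects a PreparedDataset (see prepare_dataset)")
        beta2 = self.beta2 if data.labels_onehot is not None else 0.0
        cfg = self._train_config()
        cfg.weights.beta2 = beta2
        triplets = None
        if self.beta1 > 0:
            triplets = build_triplets(
                data, mode=self.triplet_mode, k_mnn=self.k_mnn,
                negatives_per_anchor=self.negatives_per_anchor,
                seed=self.seed, margin=self.alpha,
            )
        n_classes = (
            data.labels_onehot.shape[1] if data.labels_onehot is not None else None
        )
        state = build_model(
            n_hvg=len(data.hvg_index), n_lvg=len(data.lvg_index),
            n_batches=data.n_batches, n_classes=n_classes,
            hidden=self.hidden, latent=self.latent, seed=self.seed,
        )
        state, hvg_log = train_hvg_block(data, triplets, cfg, state=state)
        state, lvg_log = train_lvg_block(data, state, cfg)
        self.state_ = state
        self.triplets_ = triplets
        self.training_log_ = {"hvg": hvg_log, "lvg": lvg_log}
        self.z_hvg_ = _embed(state, "hvg", data.X_hvg, data.batch_onehot)
        self.z_lvg_ = _embed(state, "lvg", data.X_lvg, data.batch_onehot)
        self.hvg_index_ = data.hvg_index
        self.lvg_index_ = data.lvg_index
        self.gene_ids_ = data.gene_ids
        self.label_names_ = data.label_names
        return self

    def transform(self, data: PreparedDataset) -> np.ndarray:
        """Harmonized HVG-branch embedding z_H."""
        self._require_fitted()
        return _embed(self.state_, "hvg", data.X_hvg, data.batch_onehot)

    def embed(self, data: PreparedDataset, block: str = "hvg") -> np.ndarray:
        self._require_fitted()
        x = data.X_hvg if block == "hvg" else data.X_lvg
        return _embed(self.state_, block, x, data.batch_onehot)

    def denoise(
        self, data: PreparedDataset, target_batch: int | str | None = None
    ) -> IntegrationResult:
        self._require_fitted()
        tb = self.target_batch if target_batch is None else target_batch
        result = denoise(data, self.state_, target_batch=tb)
        result.training_log = self.training_log_
        return result

    def _require_fitted(self):
        if not hasattr(self, "state_"):
            raise RuntimeError("integrator is not fitted; call fit() first")
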