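"""Conditional NB autoencoder blocks, losses, and architecture surgery.

Two blocks share the same anatomy. The HVG block encodes scaled HVG
expression conditioned on a one-hot batch code, decodes batch-conditioned
negative-binomial parameters (per-gene mean fractions via a softmax head,
so library x mean fraction is the NB mean; dispersions via softplus), and
carries a linear softmax classifier on the latent. The LVG block encodes
scaled LVG expression the same way but its decoder and classifier consume
the joint latent [z_H | z_L], letting the HVG geometry guide the noisier
LVG branch.

Query mapping extends every batch-conditioned layer with one
zero-initialized input column for the query indicator; the original
parameter groups are frozen, so reference outputs are exactly invariant
under any amount of query training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln as _gammaln

from ._autodiff import Adam, Parameter, Tensor, concat
from .anchors import TripletSet

__all__ = [
    "LossWeights",
    "ModelState",
    "build_model",
    "forward",
    "nb_log_pmf",
    "nb_nll",
    "triplet_loss",
    "cross_entropy",
    "extend_for_query",
]

THETA_FLOOR = 1e-4
PROB_FLOOR = 1e-12


@dataclass
class LossWeights:
    """Weights of the composite objective.

    alpha is the triplet margin; beta1/beta2 scale the triplet and
    classification terms against the NB reconstruction term in the HVG
    block; beta3 scales the query-anchored triplet term during mapping.
    """

    alpha: float = 1.0
    beta1: float = 1.0
    beta2: float = 5.0
    beta3: float = 1.0

    def __post_init__(self):
        vals = (self.alpha, self.beta1, self.beta2, self.beta3)
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise ValueError("loss weights must be finite and non-negative")
        if self.alpha <= 0:
            raise ValueError("triplet margin alpha must be positive")


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

class _Linear:
    def __init__(self, rng, fan_in, fan_out):
        scale = np.sqrt(2.0 / fan_in)
        self.W = Parameter(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        self.b = Parameter(np.zeros(fan_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self, prefix):
        return {f"{prefix}.W": self.W, f"{prefix}.b": self.b}


class _ConditionalLinear:
    """Affine map over [x | s]; the batch-code weights are kept separable
    so query surgery can append a trainable extension column."""

    def __init__(self, rng, fan_x, n_batches, fan_out):
        scale = np.sqrt(2.0 / (fan_x + n_batches))
        self.W_x = Parameter(rng.normal(0.0, scale, size=(fan_x, fan_out)))
        self.W_s = Parameter(rng.normal(0.0, scale, size=(n_batches, fan_out)))
        self.b = Parameter(np.zeros(fan_out))
        self.W_ext: Parameter | None = None  # [1 x fan_out] after surgery
        self.n_batches = n_batches

    def __call__(self, x: Tensor, s: Tensor) -> Tensor:
        s_arr = s.data if isinstance(s, Tensor) else np.asarray(s, float)
        if self.W_ext is None:
            if s_arr.shape[1] != self.n_batches:
                raise ValueError("batch one-hot width does not match the model")
            return x @ self.W_x + Tensor._wrap(s) @ self.W_s + self.b
        if s_arr.shape[1] == self.n_batches:
            s_arr = np.concatenate(
                [s_arr, np.zeros((s_arr.shape[0], 1))], axis=1
            )
        elif s_arr.shape[1] != self.n_batches + 1:
            raise ValueError("batch one-hot width does not match the model")
        s_base = Tensor(s_arr[:, : self.n_batches])
        s_new = Tensor(s_arr[:, self.n_batches:])
        return x @ self.W_x + s_base @ self.W_s + s_new @ self.W_ext + self.b

    def extend(self):
        if self.W_ext is not None:
            raise ValueError("layer already extended")
        self.W_ext = Parameter(np.zeros((1, self.W_x.shape[1])))

    def params(self, prefix):
        out = {
            f"{prefix}.W_x": self.W_x,
            f"{prefix}.W_s": self.W_s,
            f"{prefix}.b": self.b,
        }
        if self.W_ext is not None:
            out[f"{prefix}.W_ext"] = self.W_ext
        return out


class _Encoder:
    def __init__(self, rng, n_in, n_batches, hidden, latent):
        self.l1 = _ConditionalLinear(rng, n_in, n_batches, hidden[0])
        self.mid = [
            _Linear(rng, hidden[i], hidden[i + 1]) for i in range(len(hidden) - 1)
        ]
        self.out = _Linear(rng, hidden[-1], latent)

    def __call__(self, x, s) -> Tensor:
        h = self.l1(Tensor._wrap(x), s).relu()
        for lin in self.mid:
            h = lin(h).relu()
        return self.out(h)

    def params(self, prefix):
        p = self.l1.params(f"{prefix}.l1")
        for i, lin in enumerate(self.mid):
            p.update(lin.params(f"{prefix}.mid{i}"))
        p.update(self.out.params(f"{prefix}.out"))
        return p


class _Decoder:
    def __init__(self, rng, latent_in, n_batches, hidden, n_genes):
        rev = list(reversed(hidden))
        self.l1 = _ConditionalLinear(rng, latent_in, n_batches, rev[0])
        self.mid = [
            _Linear(rng, rev[i], rev[i + 1]) for i in range(len(rev) - 1)
        ]
        self.mu_head = _Linear(rng, rev[-1], n_genes)
        self.theta_head = _Linear(rng, rev[-1], n_genes)

    def __call__(self, z, s) -> tuple[Tensor, Tensor]:
        h = self.l1(Tensor._wrap(z), s).relu()
        for lin in self.mid:
            h = lin(h).relu()
        mu = self.mu_head(h).softmax()
        theta = self.theta_head(h).softplus() + THETA_FLOOR
        return mu, theta

    def params(self, prefix):
        p = self.l1.params(f"{prefix}.l1")
        for i, lin in enumerate(self.mid):
            p.update(lin.params(f"{prefix}.mid{i}"))
        p.update(self.mu_head.params(f"{prefix}.mu"))
        p.update(self.theta_head.params(f"{prefix}.theta"))
        return p


class _Classifier:
    def __init__(self, rng, latent_in, n_classes):
        self.lin = _Linear(rng, latent_in, n_classes)

    def log_probs(self, z) -> Tensor:
        return self.lin(Tensor._wrap(z)).log_softmax()

    def params(self, prefix):
        return self.lin.params(f"{prefix}.cls")


class _Block:
    def __init__(self, rng, n_genes, n_batches, hidden, latent, n_classes,
                 joint_latent: bool):
        dec_in = 2 * latent if joint_latent else latent
        self.encoder = _Encoder(rng, n_genes, n_batches, hidden, latent)
        self.decoder = _Decoder(rng, dec_in, n_batches, hidden, n_genes)
        self.classifier = (
            _Classifier(rng, dec_in, n_classes) if n_classes else None
        )
        self.joint_latent = joint_latent

    def params(self, prefix):
        p = self.encoder.params(f"{prefix}.enc")
        p.update(self.decoder.params(f"{prefix}.dec"))
        if self.classifier is not None:
            p.update(self.classifier.params(f"{prefix}"))
        return p


@dataclass
class ModelState:
    """All network parameters plus architecture hyperparameters."""

    hvg: _Block
    lvg: _Block
    arch: dict
    seed: int
    frozen: set = field(default_factory=set)
    extended: bool = False

    def params(self) -> dict:
        p = self.hvg.params("hvg")
        p.update(self.lvg.params("lvg"))
        return p

    def trainable_params(self) -> dict:
        return {
            k: v for k, v in self.params().items()
            if k not in self.frozen and v.requires_grad
        }

    def checksum(self) -> dict:
        """Bit-exact snapshot of every parameter array."""
        return {k: v.data.copy() for k, v in self.params().items()}


def build_model(
    n_hvg: int,
    n_lvg: int,
    n_batches: int,
    n_classes: int | None,
    hidden=(512, 256),
    latent: int = 32,
    seed: int = 0,
) -> ModelState:
    rng = np.random.default_rng(seed)
    hvg = _Block(rng, n_hvg, n_batches, list(hidden), latent,
                 n_classes or 0, joint_latent=False)
    lvg = _Block(rng, n_lvg, n_batches, list(hidden), latent,
                 n_classes or 0, joint_latent=True)
    arch = dict(
        n_hvg=n_hvg, n_lvg=n_lvg, n_batches=n_batches,
        n_classes=n_classes, hidden=list(hidden), latent=latent,
    )
    return ModelState(hvg=hvg, lvg=lvg, arch=arch, seed=seed)


# --------------------------------------------------------------------------
# forward
# --------------------------------------------------------------------------

def forward(
    state: ModelState,
    block: str,
    x: np.ndarray,
    s: np.ndarray,
    aux_latent: np.ndarray | Tensor | None = None,
    *,
    as_tensors: bool = False,
):
    """Run one block: returns (latent, (mu, theta), class_probs).

    For the lvg block ``aux_latent`` (the HVG latent z_H) is required by the
    decoder and classifier. Class probs are None when the model carries no
    classifier. With ``as_tensors`` the graph is kept for training; class
    output is then log-probabilities.
    """
    if block not in ("hvg", "lvg"):
        raise ValueError("block must be 'hvg' or 'lvg'")
    blk = state.hvg if block == "hvg" else state.lvg
    x_t = Tensor._wrap(np.asarray(x, dtype=np.float64) if not isinstance(x, Tensor) else x)
    z = blk.encoder(x_t, s)
    if blk.joint_latent:
        if aux_latent is None:
            raise ValueError("lvg block requires aux_latent (the HVG latent)")
        dec_in = concat([Tensor._wrap(aux_latent), z], axis=1)
    else:
        dec_in = z
    mu, theta = blk.decoder(dec_in, s)
    logq = blk.classifier.log_probs(dec_in) if blk.classifier else None
    if as_tensors:
        return z, (mu, theta), logq
    probs = np.exp(logq.data) if logq is not None else None
    return z.data, (mu.data, theta.data), probs


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------

def nb_log_pmf(x, lib, mu, theta):
    """Log pmf of NB counts with mean lib*mu and dispersion theta.

    ln[ Γ(x+θ) / (Γ(θ) Γ(x+1)) · (θ/(θ+lμ))^θ · (lμ/(θ+lμ))^x ],
    evaluated through log-gamma for numerical stability. Accepts scalars
    or broadcastable arrays; x must hold non-negative integers.
    """
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0) or not np.allclose(x, np.round(x)):
        raise ValueError("x must contain non-negative integers")
    lib = np.asarray(lib, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    m = lib * mu
    out = (
        _gammaln(x + theta) - _gammaln(theta) - _gammaln(x + 1.0)
        + theta * (np.log(theta) - np.log(theta + m))
        + x * (np.log(m) - np.log(theta + m))
    )
    # x = 0 contributes no x*log(m) term even when m -> 0
    if out.ndim == 0:
        return float(np.where(x == 0, theta * (np.log(theta) - np.log(theta + m)), out))
    zero = x == 0
    if np.any(zero):
        fix = theta * (np.log(theta) - np.log(theta + m))
        out = np.where(zero, np.broadcast_to(fix, out.shape), out)
    return out


def nb_nll(counts: np.ndarray, lib: np.ndarray, mu: Tensor, theta: Tensor) -> Tensor:
    """Mean NB negative log-likelihood over cells x genes (autodiff graph)."""
    x = np.asarray(counts, dtype=np.float64)
    lib_col = np.asarray(lib, dtype=np.float64).reshape(-1, 1)
    m = mu * lib_col
    tm = theta + m
    ll = (
        (Tensor._wrap(x) + theta).gammaln() - theta.gammaln()
        - _gammaln(x + 1.0)
        + theta * (theta.log() - tm.log())
        + Tensor._wrap(x) * (m.log() - tm.log())
    )
    return -ll.mean()


def triplet_loss(latent, triplets: TripletSet):
    """Mean hinge over triples: max(||z_a−z_p||² − ||z_a−z_n||² + α, 0)."""
    if len(triplets) == 0:
        raise ValueError("empty triplet set")
    t = triplets.triples
    z = latent if isinstance(latent, Tensor) else Tensor(np.asarray(latent, float))
    if t.max() >= z.data.shape[0]:
        raise IndexError("triplet index out of range")
    za = z.take_rows(t[:, 0])
    zp = z.take_rows(t[:, 1])
    zn = z.take_rows(t[:, 2])
    d_ap = ((za - zp) ** 2).sum(axis=1)
    d_an = ((za - zn) ** 2).sum(axis=1)
    hinge = (d_ap - d_an + triplets.margin).relu()
    out = hinge.mean()
    return out if isinstance(latent, Tensor) else float(out.data)


def cross_entropy(p, q=None, *, log_q=None):
    """Mean cross-entropy −(1/N) Σ_i Σ_k p_ik ln q_ik.

    ``p`` may be one-hot or soft targets. Provide either probabilities ``q``
    (clamped at 1e-12 before the log) or an autodiff log-probability tensor
    ``log_q`` for training.
    """
    p_arr = p.data if isinstance(p, Tensor) else np.asarray(p, dtype=np.float64)
    if np.any(p_arr < 0):
        raise ValueError("target probabilities must be non-negative")
    if log_q is not None:
        return -(Tensor._wrap(p_arr) * log_q).sum(axis=1).mean()
    q_arr = np.asarray(q, dtype=np.float64)
    if p_arr.shape != q_arr.shape:
        raise ValueError("p and q must have identical shapes")
    return float(-(p_arr * np.log(np.maximum(q_arr, PROB_FLOOR))).sum(axis=1).mean())


# --------------------------------------------------------------------------
# architecture surgery
# --------------------------------------------------------------------------

def extend_for_query(state: ModelState) -> ModelState:
    """Add a zero-initialized query-batch input column; freeze everything else.

    Mutates and returns ``state``. The four batch-conditioned layers
    (both encoders' and both decoders' first layers) each gain one
    trainable weight row; every pre-existing parameter group — including
    both classifiers, which are reused verbatim on query latents — is
    frozen.
    """
    if state.extended:
        raise ValueError("model has already been extended for a query")
    state.frozen = set(state.params().keys())
    for p in state.params().values():
        p.freeze()
    for blk in (state.hvg, state.lvg):
        blk.encoder.l1.extend()
        blk.decoder.l1.extend()
    state.extended = True
    return state


def make_optimizer(state: ModelState, which: list[str], lr: float) -> Adam:
    """Adam over the trainable parameters whose names start with a prefix
    in ``which`` (e.g. ["hvg.enc", "hvg.dec"])."""
    params = [
        v for k, v in sorted(state.trainable_params().items())
        if any(k.startswith(w) for w in which)
    ]
    return Adam(params, lr=lr)
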