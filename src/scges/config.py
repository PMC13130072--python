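"""Training and pipeline configuration objects."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .model import LossWeights

__all__ = ["TrainConfig", "RunConfig"]


@dataclass
class TrainConfig:
    """Optimization settings shared by integration and mapping runs."""

    weights: LossWeights = field(default_factory=LossWeights)
    epochs_hvg: int = 120
    epochs_lvg: int = 120
    minibatch_size: int = 256
    learning_rate: float = 1e-3
    early_stop_patience: int = 20
    early_stop_min_delta: float = 1e-4
    seed: int = 0
    alternating_period: int = 1
    triplet_batch: int = 256

    def __post_init__(self):
        if self.epochs_hvg < 1 or self.epochs_lvg < 0:
            raise ValueError("epochs must be >= 1")
        if self.minibatch_size < 2:
            raise ValueError("minibatch_size must be >= 2")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.alternating_period < 1:
            raise ValueError("alternating_period must be >= 1")


@dataclass
class RunConfig:
    """Resolved options for one CLI pipeline run."""

    train: TrainConfig = field(default_factory=TrainConfig)
    n_hvg: int = 2000
    batch_key: str = "batch"
    label_key: str | None = None
    k_mnn: int = 20
    negatives_per_anchor: int = 1
    conf_threshold: float = 0.5
    k_label_transfer: int = 15
    hidden: tuple = (512, 256)
    latent: int = 32
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        train_d = d.pop("train", {})
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys are "
                f"{sorted(known)}"
            )
        weights = LossWeights(**train_d.pop("weights", {})) if isinstance(
            train_d.get("weights", {}), dict
        ) else train_d.pop("weights")
        t_known = set(TrainConfig.__dataclass_fields__) - {"weights"}
        t_unknown = set(train_d) - t_known
        if t_unknown:
            raise ValueError(
                f"unknown train config keys {sorted(t_unknown)}; valid keys "
                f"are {sorted(t_known)}"
            )
        train = TrainConfig(weights=weights, **train_d)
        hidden = d.pop("hidden", (512, 256))
        return cls(train=train, hidden=tuple(hidden), **d)
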