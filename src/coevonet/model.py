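"""Residual contact-prediction networks: four configurable variants.

All variants share the same trunk: a 1x1 convolution maps the input
channels (441 covariance channels, or 527 with added features) down to
128, then 30 pre-activation residual blocks (two 3x3 convolutions each;
60 trunk convolutions in total), then a per-pixel linear map (a 1x1
convolution — a literal dense layer over L x L pixels would make the
parameter count depend on protein length) and a sigmoid give contact
probabilities, which are symmetrized as (p + p^T) / 2.

variants
    baseline       441-channel input, unit sequence weights
    weighted       441-channel input, learned sequence weights
    feature_added  527-channel input (query/PSSM/entropy/MI/separation)
    multitask      feature_added input; 20 shared residual blocks then
                   three private 10-block heads for contacts, 3-state
                   secondary structure and ASA regression

Depth and width are configurable so tests can run micro-models; the
defaults are the full-scale values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import Conv2d, Linear, Module, ResidualBlock

VARIANTS = ("baseline", "weighted", "feature_added", "multitask")


@dataclass
class ModelConfig:
    variant: str = "baseline"
    trunk_channels: int = 128
    n_blocks: int = 30
    n_shared_blocks: int = 20  # multitask split of n_blocks
    kernel_size: int = 3
    input_channels: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.input_channels is None:
            self.input_channels = 527 if self.uses_extra_features else 441

    @property
    def uses_extra_features(self) -> bool:
        return self.variant in ("feature_added", "multitask")

    @property
    def is_multitask(self) -> bool:
        return self.variant == "multitask"

    @property
    def n_head_blocks(self) -> int:
        return self.n_blocks - self.n_shared_blocks


@dataclass
class PredictionBundle:
    """Numpy predictions for one protein."""

    contact_prob: np.ndarray
    ss_prob: np.ndarray | None = None
    asa_pred: np.ndarray | None = None


def symmetrize(p):
    """(p + p^T) / 2 — reconciles the two orientations of a residue pair."""
    if isinstance(p, Tensor):
        return (p + p.transpose(1, 0)) * 0.5
    return (p + p.T) * 0.5


def residue_pair_to_residue_features(pair_map):
    """Reduce an (L, L, C) pair map to (L, 2C) per-residue features.

    Residue i gets the concatenation of its mean-pooled i-th row and
    mean-pooled i-th column; pooling over the pair axis makes the feature
    size independent of L.
    """
    row_pool = pair_map.mean(axis=1)  # (L, C): row i averaged over j
    col_pool = pair_map.mean(axis=0)  # (L, C): column i averaged over j
    return ad.concat([row_pool, col_pool], axis=1)


class ContactNetwork(Module):
    """One of the four model variants, built from a :class:`ModelConfig`."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        C = config.trunk_channels
        self.input_conv = Conv2d(config.input_channels, C, 1, rng, dtype=dtype)

        def blocks(n):
            return [
                ResidualBlock(C, rng, dtype=dtype, kernel_size=config.kernel_size)
                for _ in range(n)
            ]

        from .nn.layers import BatchNorm2d

        if config.is_multitask:
            if not 0 < config.n_shared_blocks < config.n_blocks:
                raise ValueError("multitask needs 0 < n_shared_blocks < n_blocks")
            self.shared_blocks = blocks(config.n_shared_blocks)
            self.contact_blocks = blocks(config.n_head_blocks)
            self.ss_blocks = blocks(config.n_head_blocks)
            self.asa_blocks = blocks(config.n_head_blocks)
            self.contact_out = Conv2d(C, 1, 1, rng, dtype=dtype)
            self.ss_out = Linear(2 * C, 3, rng, dtype=dtype)
            self.asa_out = Linear(2 * C, 1, rng, dtype=dtype)
            # pre-activation trunks need a final BN-ReLU before each head
            self.contact_norm = BatchNorm2d(C, dtype=dtype)
            self.ss_norm = BatchNorm2d(C, dtype=dtype)
            self.asa_norm = BatchNorm2d(C, dtype=dtype)
        else:
            self.trunk_blocks = blocks(config.n_blocks)
            self.contact_out = Conv2d(C, 1, 1, rng, dtype=dtype)
            self.contact_norm = BatchNorm2d(C, dtype=dtype)

    # ------------------------------------------------------------------ forward
    def _run(self, x, blocks):
        for block in blocks:
            x = block(x)
        return x

    def _contact_prob(self, h) -> Tensor:
        L = h.shape[1]
        logits = self.contact_out(ad.relu(self.contact_norm(h))).reshape(L, L)
        return symmetrize(ad.sigmoid(logits))

    def forward(self, x) -> dict[str, Tensor]:
        """Input (C, L, L) Tensor/array -> dict of Tensors.

        Keys: 'contact' always; 'ss' (L, 3 softmax rows) and 'asa'
        (L, non-negative) for the multitask variant.
        """
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.shape[0] != self.config.input_channels:
            raise ValueError(
                f"input has {x.shape[0]} channels, model expects "
                f"{self.config.input_channels}"
            )
        h = self.input_conv(x)
        if not self.config.is_multitask:
            h = self._run(h, self.trunk_blocks)
            return {"contact": self._contact_prob(h)}
        shared = self._run(h, self.shared_blocks)
        contact = self._contact_prob(self._run(shared, self.contact_blocks))
        ss_map = ad.relu(self.ss_norm(self._run(shared, self.ss_blocks)))
        ss_feats = residue_pair_to_residue_features(ss_map.transpose(1, 2, 0))
        ss_prob = ad.softmax(self.ss_out(ss_feats), axis=1)
        asa_map = ad.relu(self.asa_norm(self._run(shared, self.asa_blocks)))
        asa_feats = residue_pair_to_residue_features(asa_map.transpose(1, 2, 0))
        L = asa_feats.shape[0]
        # softplus keeps ASA non-negative with gradients everywhere
        asa = ad.softplus(self.asa_out(asa_feats).reshape(L))
        return {"contact": contact, "ss": ss_prob, "asa": asa}

    __call__ = forward

    def predict(self, x) -> PredictionBundle:
        """Evaluation-mode forward pass returning numpy predictions."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(x)
        finally:
            self.train(was_training)
        return PredictionBundle(
            contact_prob=out["contact"].data.copy(),
            ss_prob=out["ss"].data.copy() if "ss" in out else None,
            asa_pred=out["asa"].data.copy() if "asa" in out else None,
        )

    # ------------------------------------------------------------- introspection
    def conv_layer_counts(self) -> dict[str, int]:
        """Number of convolution layers inside residual blocks, per part."""

        def count(blocks):
            return 2 * len(blocks)

        if self.config.is_multitask:
            return {
                "shared": count(self.shared_blocks),
                "contact_head": count(self.contact_blocks),
                "ss_head": count(self.ss_blocks),
                "asa_head": count(self.asa_blocks),
            }
        return {"trunk": count(self.trunk_blocks)}
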