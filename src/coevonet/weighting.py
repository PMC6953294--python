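"""Learned per-sequence weighting of an MSA.

Each alignment row gets seven features — alignment depth, identity with
the target (query), identity with the MSA consensus, gap ratio, and the
alignment-wide means of the last three — and a small fully connected
network (7 -> 7 -> 7 -> 1, ReLU hidden, sigmoid output) maps them to a
weight in (0, 1).  Because the weight enters the covariance computation
multiplicatively, the whole pipeline stays differentiable and the
weighting network trains end-to-end against the contact loss: noisy rows
that blur the covariance signal get pushed toward zero weight.

Feature columns (in order):
    0  log10(N) / 5            (depth, rescaled to the unit range of the rest)
    1  identity with target
    2  identity with consensus
    3  gap ratio
    4  mean identity with target
    5  mean identity with consensus
    6  mean gap ratio
"""

from __future__ import annotations

import numpy as np

from .msa import GAP_CODE, N_SYMBOLS, EncodedAlignment
from .nn import MLP
from .nn.autodiff import Tensor, sigmoid

FEATURE_NAMES = (
    "n_sequences",
    "identity_with_target",
    "identity_with_consensus",
    "gap_ratio",
    "mean_identity_with_target",
    "mean_identity_with_consensus",
    "mean_gap_ratio",
)

# Ablations: dropping a feature removes it together with its mean column.
_DROPPABLE = {
    "identity": (1, 4),
    "consensus": (2, 5),
    "gap_ratio": (3, 6),
}


def consensus_sequence(enc) -> np.ndarray:
    """Per-column most frequent non-gap code; all-gap columns give the gap
    code; ties break to the lowest code.  Accepts an EncodedAlignment or a
    raw (N, L) code array."""
    codes = enc.codes if isinstance(enc, EncodedAlignment) else np.asarray(enc)
    length = codes.shape[1]
    counts = np.zeros((length, N_SYMBOLS), dtype=np.int64)
    for a in range(N_SYMBOLS):
        counts[:, a] = (codes == a).sum(axis=0)
    consensus = counts[:, :GAP_CODE].argmax(axis=1).astype(np.int8)
    consensus[counts[:, :GAP_CODE].sum(axis=1) == 0] = GAP_CODE
    return consensus


def pairwise_identity(row: np.ndarray, ref: np.ndarray) -> float:
    """Fraction of positions with equal codes (gap counted as a symbol),
    normalized by the full length."""
    row, ref = np.asarray(row), np.asarray(ref)
    if row.shape != ref.shape:
        raise ValueError(f"length mismatch: {row.shape} vs {ref.shape}")
    return float(np.mean(row == ref))


def gap_ratio(row: np.ndarray) -> float:
    return float(np.mean(np.asarray(row) == GAP_CODE))


def build_weight_features(enc: EncodedAlignment, drop: str | None = None) -> np.ndarray:
    """Assemble the (N, 7) feature matrix (or (N, 5) for an ablation).

    `drop` in {'identity', 'consensus', 'gap_ratio'} removes that feature
    and its alignment-mean column, matching the Drop-* ablation models.
    """
    codes = enc.codes
    N, L = codes.shape
    query = codes[0]
    cons = consensus_sequence(enc)
    id_target = (codes == query).mean(axis=1)
    id_consensus = (codes == cons).mean(axis=1)
    gaps = (codes == GAP_CODE).mean(axis=1)
    feats = np.empty((N, 7), dtype=np.float64)
    feats[:, 0] = np.log10(N) / 5.0
    feats[:, 1] = id_target
    feats[:, 2] = id_consensus
    feats[:, 3] = gaps
    feats[:, 4] = id_target.mean()
    feats[:, 5] = id_consensus.mean()
    feats[:, 6] = gaps.mean()
    if drop is not None:
        if drop not in _DROPPABLE:
            raise ValueError(f"unknown feature to drop: {drop!r}")
        keep = [c for c in range(7) if c not in _DROPPABLE[drop]]
        feats = feats[:, keep]
    return feats


class WeightMLP(MLP):
    """The weighting network: in_features -> 7 -> 7 -> 1, sigmoid output.

    `in_features` is 7, or 5 for the Drop-* ablations.
    """

    def __init__(self, in_features: int = 7, seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        super().__init__((in_features, 7, 7, 1), rng, dtype=dtype)
        self.in_features = in_features

    def __call__(self, feats) -> Tensor:
        feats_arr = feats.data if isinstance(feats, Tensor) else np.asarray(feats)
        if feats_arr.ndim != 2 or feats_arr.shape[1] != self.in_features:
            raise ValueError(
                f"features have shape {feats_arr.shape}, expected (N, {self.in_features})"
            )
        logits = super().__call__(feats if isinstance(feats, Tensor) else Tensor(feats_arr))
        return sigmoid(logits.reshape(feats_arr.shape[0]))


def weight_forward(mlp: WeightMLP, feats: np.ndarray) -> Tensor:
    """Row-wise weights in (0, 1)^N, differentiable in `mlp` parameters."""
    return mlp(feats)


def export_weights_tsv(path, enc: EncodedAlignment, feats: np.ndarray, weights) -> None:
    """Per-sequence TSV (identifier, features, weight) — the data behind
    weight-vs-feature scatter plots."""
    w = weights.data if isinstance(weights, Tensor) else np.asarray(weights)
    names = FEATURE_NAMES if feats.shape[1] == 7 else tuple(
        f"f{i}" for i in range(feats.shape[1])
    )
    with open(path, "w") as fh:
        fh.write("identifier\t" + "\t".join(names) + "\tweight\n")
        for ident, row, wi in zip(enc.identifiers, feats, w):
            vals = "\t".join(f"{v:.6f}" for v in row)
            fh.write(f"{ident}\t{vals}\t{wi:.6f}\n")
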