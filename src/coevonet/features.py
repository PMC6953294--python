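"""Covariance tensors and auxiliary MSA features — the model inputs.

The core object is the (L, L, 441) weighted covariance tensor

    S[i, j, 21a + b] = f(a_i, b_j) - f(a_i) f(b_j)

over the 21-symbol alphabet (20 amino acids + gap), where the single and
pair frequencies are weighted by one weight per alignment row.  With unit
weights these are plain counts; with weights produced by the weighting
MLP the computation stays differentiable, which is what lets the whole
model train end-to-end from the MSA.

Every function here accepts the weights either as a plain ndarray (fast
evaluation path) or as an autodiff :class:`~coevonet.nn.autodiff.Tensor`
(training path); the return type follows the input.

The Feature-Added / Multi-task variants append to the 441 covariance
channels: tiled query one-hot (20 x 2), tiled PSSM (21 x 2), tiled column
entropy (1 x 2), mutual information (1) and scaled sequence separation
(1) — 527 channels in total.  Channel order is fixed and documented in
:func:`tile_and_concat`.
"""

from __future__ import annotations

import numpy as np

from .msa import N_SYMBOLS, EncodedAlignment
from .nn import autodiff as ad
from .nn.autodiff import Tensor

N_COV_CHANNELS = N_SYMBOLS * N_SYMBOLS  # 441
N_FULL_CHANNELS = N_COV_CHANNELS + 2 * 20 + 2 * N_SYMBOLS + 2 + 1 + 1  # 527

_TINY = 1e-30  # guards log(0); exact zeros still contribute exactly zero
SEPARATION_SCALE = 100.0  # |i-j| is fed as min(|i-j|/100, 1)


def one_hot(codes: np.ndarray, dtype=np.float32) -> np.ndarray:
    """(N, L) integer codes -> (N, L, 21) one-hot array."""
    codes = np.asarray(codes)
    out = np.zeros(codes.shape + (N_SYMBOLS,), dtype=dtype)
    np.put_along_axis(out, codes[..., None].astype(np.int64), 1.0, axis=-1)
    return out


def _codes_of(enc) -> np.ndarray:
    return enc.codes if isinstance(enc, EncodedAlignment) else np.asarray(enc)


def weighted_frequencies(enc, weights):
    """Weighted single and pair frequencies of an encoded alignment.

    Returns ``(single, pair)`` with shapes (L, 21) and (L, L, 21, 21):
    ``single[i, a]`` is the weighted frequency of symbol ``a`` in column
    ``i`` and ``pair[i, j, a, b]`` the weighted joint frequency.  Each
    single row and each (i, j) pair slab sums to 1.  Differentiable in
    `weights` when given a Tensor.
    """
    codes = _codes_of(enc)
    N, L = codes.shape
    is_tensor = isinstance(weights, Tensor)
    w_arr = weights.data if is_tensor else np.asarray(weights)
    if w_arr.shape != (N,):
        raise ValueError(f"weights have shape {w_arr.shape}, expected ({N},)")
    if np.any(w_arr <= 0):
        raise ValueError("all sequence weights must be positive")
    X = one_hot(codes, dtype=w_arr.dtype).reshape(N, L * N_SYMBOLS)
    sw = weights.sum() if is_tensor else float(w_arr.sum())
    wX = weights.reshape(N, 1) * X if is_tensor else w_arr[:, None] * X
    single = wX.sum(axis=0).reshape(L, N_SYMBOLS) / sw
    pair = (X.T @ wX) / sw
    pair = pair.reshape(L, N_SYMBOLS, L, N_SYMBOLS).transpose(0, 2, 1, 3)
    return single, pair


def covariance(single, pair):
    """(L, L, 441) covariance tensor S = f(ab) - f(a) f(b).

    Channel c = 21 a + b for symbol codes a (at the first position) and b
    (at the second); hence S[i, j, 21a+b] == S[j, i, 21b+a].
    """
    L = single.shape[0]
    outer = single.reshape(L, 1, N_SYMBOLS, 1) * single.reshape(1, L, 1, N_SYMBOLS)
    return (pair - outer).reshape(L, L, N_COV_CHANNELS)


def pssm(single):
    """Position-specific scores: the weighted 21-symbol column frequencies."""
    return single


def column_entropy(single):
    """Shannon entropy (nats) per column; in [0, ln 21]."""
    return -(single * ad.log(ad.clip(single, _TINY, 1.0))).sum(axis=1)


def mutual_information(pair, single):
    """(L, L) mutual information (nats); symmetric, MI[i, i] = entropy."""
    L = single.shape[0]
    outer = single.reshape(L, 1, N_SYMBOLS, 1) * single.reshape(1, L, 1, N_SYMBOLS)
    log_ratio = ad.log(ad.clip(pair, _TINY, 1.0)) - ad.log(ad.clip(outer, _TINY, 1.0))
    return (pair * log_ratio).sum(axis=(2, 3))


def sequence_separation(L: int, dtype=np.float64) -> np.ndarray:
    """(L, L) matrix of min(|i - j| / 100, 1): symmetric, zero diagonal."""
    idx = np.arange(L)
    sep = np.abs(idx[:, None] - idx[None, :]).astype(dtype)
    return np.minimum(sep / SEPARATION_SCALE, 1.0)


def query_one_hot(enc) -> np.ndarray:
    """(L, 20) one-hot of the query row (the query contains no gaps)."""
    codes = _codes_of(enc)
    return one_hot(codes[0])[:, :20]


def _tile_rows(feat, L):
    """1-D per-residue feature (L, d) -> (L, L, d) block where entry (i, j)
    depends only on j (the feature is stacked L times vertically)."""
    d = feat.shape[1]
    return ad.broadcast_to(feat.reshape(1, L, d), (L, L, d))


def _tile_cols(feat, L):
    """Transposed copy: entry (i, j) depends only on i."""
    d = feat.shape[1]
    return ad.broadcast_to(feat.reshape(L, 1, d), (L, L, d))


def tile_and_concat(cov, query_oh, pssm_mat, entropy, mi, sep):
    """Assemble the (L, L, 527) feature tensor of the Feature-Added models.

    Channel order (fixed):
        0:441    covariance
        441:461  query one-hot, row copy   (entry (i,j) depends on j)
        461:481  query one-hot, transpose  (depends on i)
        481:502  PSSM, row copy
        502:523  PSSM, transpose
        523:524  entropy, row copy
        524:525  entropy, transpose
        525:526  mutual information
        526:527  sequence separation
    """
    L = cov.shape[0]
    for name, arr, expected in (
        ("query_oh", query_oh, (L, 20)),
        ("pssm", pssm_mat, (L, N_SYMBOLS)),
        ("entropy", entropy, (L,)),
        ("mi", mi, (L, L)),
        ("sep", sep, (L, L)),
    ):
        if tuple(arr.shape) != expected:
            raise ValueError(f"{name} has shape {tuple(arr.shape)}, expected {expected}")
    ent = entropy.reshape(L, 1)
    parts = [
        cov,
        _tile_rows(query_oh, L),
        _tile_cols(query_oh, L),
        _tile_rows(pssm_mat, L),
        _tile_cols(pssm_mat, L),
        _tile_rows(ent, L),
        _tile_cols(ent, L),
        mi.reshape(L, L, 1),
        sep.reshape(L, L, 1),
    ]
    return ad.concat(parts, axis=2)


def channel_manifest() -> list[tuple[str, int, int]]:
    """(name, start, stop) for each block of the 527-channel tensor."""
    return [
        ("covariance", 0, 441),
        ("query_one_hot_row", 441, 461),
        ("query_one_hot_col", 461, 481),
        ("pssm_row", 481, 502),
        ("pssm_col", 502, 523),
        ("entropy_row", 523, 524),
        ("entropy_col", 524, 525),
        ("mutual_information", 525, 526),
        ("sequence_separation", 526, 527),
    ]


def build_input_tensor(enc, weights=None, extra_features: bool = False):
    """Model input (C, L, L): C = 441, or 527 with the added features.

    `weights` defaults to unit weights (the unweighted Baseline path); a
    Tensor of weights keeps the output differentiable end-to-end.
    """
    codes = _codes_of(enc)
    N, L = codes.shape
    if weights is None:
        weights = np.ones(N)
    single, pair = weighted_frequencies(codes, weights)
    cov = covariance(single, pair)
    if not extra_features:
        return cov.transpose(2, 0, 1)
    is_tensor = isinstance(cov, Tensor)
    dtype = cov.data.dtype if is_tensor else cov.dtype
    full = tile_and_concat(
        cov,
        query_one_hot(codes).astype(dtype),
        pssm(single),
        column_entropy(single),
        mutual_information(pair, single),
        sequence_separation(L, dtype=dtype),
    )
    return full.transpose(2, 0, 1)
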