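"""Stacked bidirectional recurrent encoder (numpy).

Layer 1 is a bidirectional LSTM returning per-position features of
width 768 (384 per direction); layer 2 is a second bidirectional LSTM
whose final forward and backward hidden states concatenate to the
768-wide sequence feature.  Padding rows (all-zero tail rows) are
masked out of the recurrence.

Parameters are generated deterministically from a seed and kept fixed
during training (no deep-learning framework is assumed); the
classification head on top of these features is what training fits.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np

from paduavte.vectorize import EMBED_DIM

HIDDEN_PER_DIR = 384  # 768-wide bidirectional output => 384 per direction
FEATURE_DIM = 2 * HIDDEN_PER_DIR

__all__ = ["HIDDEN_PER_DIR", "FEATURE_DIM", "EncoderParams", "encode", "encode_batch", "sequence_lengths"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class EncoderParams:
    """Weight arrays for the two stacked bidirectional layers."""

    #: (layer, direction) -> dict with W (in,4H), U (H,4H), b (4H)
    def __init__(self, weights: Dict[tuple, Dict[str, np.ndarray]]):
        self.weights = weights

    @classmethod
    def init(cls, seed: int = 0, scale: float = 1.0) -> "EncoderParams":
        rng = np.random.Generator(np.random.Philox(key=np.uint64(seed) ^ np.uint64(0x9E3779B97F4A7C15)))
        weights: Dict[tuple, Dict[str, np.ndarray]] = {}
        for layer, in_dim in ((0, EMBED_DIM), (1, FEATURE_DIM)):
            for direction in ("fwd", "bwd"):
                h = HIDDEN_PER_DIR
                weights[(layer, direction)] = {
                    "W": rng.standard_normal((in_dim, 4 * h)) * (scale / np.sqrt(in_dim)),
                    "U": rng.standard_normal((h, 4 * h)) * (scale / np.sqrt(h)),
                    "b": np.zeros(4 * h),
                }
        return cls(weights)

    @classmethod
    def zeros(cls) -> "EncoderParams":
        weights: Dict[tuple, Dict[str, np.ndarray]] = {}
        for layer, in_dim in ((0, EMBED_DIM), (1, FEATURE_DIM)):
            for direction in ("fwd", "bwd"):
                h = HIDDEN_PER_DIR
                weights[(layer, direction)] = {
                    "W": np.zeros((in_dim, 4 * h)),
                    "U": np.zeros((h, 4 * h)),
                    "b": np.zeros(4 * h),
                }
        return cls(weights)


def sequence_lengths(batch: np.ndarray) -> np.ndarray:
    """Number of leading non-padding rows per sample (padding = all-zero tail)."""
    nonzero = np.any(batch != 0.0, axis=2)  # (n, L)
    # length = index of last nonzero row + 1 (0 if none)
    rev = nonzero[:, ::-1]
    has = nonzero.any(axis=1)
    lengths = np.where(has, batch.shape[1] - rev.argmax(axis=1), 0)
    return lengths.astype(np.int64)


def _lstm_pass(x: np.ndarray, lengths: np.ndarray, p: Dict[str, np.ndarray], reverse: bool):
    """Masked unidirectional LSTM over a batch; returns (outputs, final_h)."""
    n, L, _ = x.shape
    h = np.zeros((n, HIDDEN_PER_DIR))
    c = np.zeros((n, HIDDEN_PER_DIR))
    outputs = np.zeros((n, L, HIDDEN_PER_DIR))
    steps = range(L - 1, -1, -1) if reverse else range(L)
    for t in steps:
        mask = (lengths > t).astype(np.float64)[:, None]
        z = x[:, t, :] @ p["W"] + h @ p["U"] + p["b"]
        i = _sigmoid(z[:, :HIDDEN_PER_DIR])
        f = _sigmoid(z[:, HIDDEN_PER_DIR : 2 * HIDDEN_PER_DIR])
        g = np.tanh(z[:, 2 * HIDDEN_PER_DIR : 3 * HIDDEN_PER_DIR])
        o = _sigmoid(z[:, 3 * HIDDEN_PER_DIR :])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        c = mask * c_new + (1 - mask) * c
        h = mask * h_new + (1 - mask) * h
        outputs[:, t, :] = h * mask
    return outputs, h


def encode_batch(matrices: Sequence[np.ndarray] | np.ndarray, params: EncoderParams) -> np.ndarray:
    """Encode a batch of equal-length L x 768 matrices to (n, 768) features."""
    batch = np.asarray(matrices, dtype=np.float64)
    if batch.ndim != 3 or batch.shape[2] != EMBED_DIM:
        raise ValueError(f"expected (n, L, {EMBED_DIM}) input, got {batch.shape}")
    lengths = sequence_lengths(batch)

    out_f, _ = _lstm_pass(batch, lengths, params.weights[(0, "fwd")], reverse=False)
    out_b, _ = _lstm_pass(batch, lengths, params.weights[(0, "bwd")], reverse=True)
    layer1 = np.concatenate([out_f, out_b], axis=2)  # (n, L, 768)

    _, h_fwd = _lstm_pass(layer1, lengths, params.weights[(1, "fwd")], reverse=False)
    _, h_bwd = _lstm_pass(layer1, lengths, params.weights[(1, "bwd")], reverse=True)
    return np.concatenate([h_fwd, h_bwd], axis=1)  # (n, 768)


def encode(matrix: np.ndarray, params: EncoderParams) -> np.ndarray:
    """Encode one L x 768 embedding matrix to a 768-wide feature vector."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[1] != EMBED_DIM:
        raise ValueError(f"expected (L, {EMBED_DIM}) matrix, got {matrix.shape}")
    return encode_batch(matrix[None, :, :], params)[0]
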