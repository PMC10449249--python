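"""Text vectorization behind a pluggable contract.

The default embedder maps each token to a deterministic 768-wide
Gaussian vector seeded from a stable hash of the token, so the whole
pipeline runs offline with no model downloads.  A pretrained
transformer encoder can be plugged in by implementing
:class:`Vectorizer`; the output contract (L x 768, tail truncation,
zero-row padding) is fixed.
"""

from __future__ import annotations

import hashlib
import re
from typing import Dict, List, Sequence, Union

import numpy as np

EMBED_DIM = 768
DIAGNOSIS_LEN = 20
SYMPTOM_LEN = 50

__all__ = ["EMBED_DIM", "DIAGNOSIS_LEN", "SYMPTOM_LEN", "Vectorizer", "HashingVectorizer", "tokenize_text", "role_length"]


def role_length(role: str) -> int:
    if role == "diagnosis":
        return DIAGNOSIS_LEN
    if role == "symptom":
        return SYMPTOM_LEN
    raise ValueError(f"bad role {role!r}")


_CJK = re.compile(r"[一-鿿]")


def tokenize_text(text: str) -> List[str]:
    """Whitespace/word tokenization; CJK characters are single tokens."""
    out: List[str] = []
    for piece in re.findall(r"[一-鿿]|[A-Za-z0-9_]+|[^\sA-Za-z0-9_一-鿿]", text):
        out.append(piece)
    return out


class Vectorizer:
    """Contract: ``vectorize(input, role) -> (role_length(role), 768)``."""

    def vectorize(self, text_or_terms: Union[str, Sequence[str]], role: str) -> np.ndarray:
        raise NotImplementedError

    def spec(self) -> dict:
        raise NotImplementedError


class HashingVectorizer(Vectorizer):
    """Deterministic hashed token embedder.

    Each token's 768 coordinates are drawn from a Philox generator
    keyed by a BLAKE2b digest of the token plus a vectorizer seed, so
    embeddings are reproducible across platforms and sessions.
    """

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self._cache: Dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(f"{self.seed}\x00{token}".encode("utf-8"), digest_size=8).digest()
            key = int.from_bytes(digest, "little")
            rng = np.random.Generator(np.random.Philox(key=key))
            vec = rng.standard_normal(EMBED_DIM).astype(np.float64) / np.sqrt(EMBED_DIM)
            self._cache[token] = vec
        return vec

    def vectorize(self, text_or_terms: Union[str, Sequence[str]], role: str) -> np.ndarray:
        length = role_length(role)
        if isinstance(text_or_terms, str):
            tokens = tokenize_text(text_or_terms)
        else:
            # symptom terms are atomic tokens; order preserved
            tokens = [t for t in text_or_terms if t]
        tokens = tokens[:length]  # tail truncation
        mat = np.zeros((length, EMBED_DIM), dtype=np.float64)
        for i, tok in enumerate(tokens):
            mat[i] = self._token_vector(tok)
        return mat

    def spec(self) -> dict:
        return {"kind": "hashing", "seed": self.seed, "dim": EMBED_DIM}

    @classmethod
    def from_spec(cls, spec: dict) -> "HashingVectorizer":
        if spec.get("kind") != "hashing":
            raise ValueError(f"unsupported vectorizer spec {spec!r}")
        return cls(seed=spec.get("seed", 0))
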