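"""Pluggable text-embedding contract and the built-in deterministic embedder.

Retrieval needs only a callable that maps a list of texts to a fixed-width
matrix of dense vectors. The production configuration mirrors a 512-dim
Chinese/English sentence-embedding model served out of process; the package
itself ships :class:`HashedNGramEmbedder`, a seeded character-n-gram
feature-hashing embedder that is fully deterministic, needs no downloads,
and is script-agnostic (it never tokenizes, so Chinese text needs no word
segmenter). It is the default for tests, fixtures and offline runs.
"""

from __future__ import annotations

import hashlib
from typing import Protocol, runtime_checkable

import numpy as np

__all__ = ["Embedder", "HashedNGramEmbedder", "EmbedderContractError"]


class EmbedderContractError(RuntimeError):
    """An embedder returned vectors violating its declared contract."""


@runtime_checkable
class Embedder(Protocol):
    """Contract: ``embed(texts)`` returns one ``dim``-wide row per text."""

    dim: int

    def embed(self, texts: list[str]) -> np.ndarray: ...

    @property
    def fingerprint(self) -> str:
        """Stable identifier recorded in index sidecars and run manifests."""
        ...


class HashedNGramEmbedder:
    """Character n-gram feature hashing into a fixed-width dense vector.

    Each overlapping character n-gram of a text is hashed (BLAKE2, salted
    with the seed) to a bucket and a sign; the text's vector is the signed
    bucket count vector. Identical (text, n, dim, seed) always produce the
    same bytes, across processes and platforms.

    Parameters
    ----------
    dim
        Vector width. Default 512, matching the dense-retrieval setup the
        package is designed around.
    n
        Character n-gram order. 3 by default; texts shorter than ``n`` are
        hashed whole.
    seed
        Hash salt. Changing it yields an unrelated random projection.
    """

    def __init__(self, dim: int = 512, n: int = 3, seed: int = 0):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        if n < 1:
            raise ValueError("n must be >= 1")
        self.dim = int(dim)
        self.n = int(n)
        self.seed = int(seed)
        self._salt = str(self.seed).encode()

    def _grams(self, text: str) -> list[str]:
        text = text.strip()
        if len(text) < self.n:
            return [text] if text else []
        return [text[i : i + self.n] for i in range(len(text) - self.n + 1)]

    def embed(self, texts: list[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dim), dtype=np.float64)
        for i, text in enumerate(texts):
            for gram in self._grams(text):
                digest = hashlib.blake2b(gram.encode("utf-8"), digest_size=8, salt=self._salt).digest()
                value = int.from_bytes(digest, "big")
                bucket = value % self.dim
                sign = 1.0 if (value >> 32) & 1 else -1.0
                out[i, bucket] += sign
        return out

    @property
    def fingerprint(self) -> str:
        return f"hashed-ngram(dim={self.dim},n={self.n},seed={self.seed})"


def check_matrix(matrix: np.ndarray, n_texts: int, dim: int) -> np.ndarray:
    """Validate an embedder's output against its declared contract."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape != (n_texts, dim):
        raise EmbedderContractError(
            f"embedder returned shape {matrix.shape}, expected ({n_texts}, {dim})"
        )
    if not np.all(np.isfinite(matrix)):
        raise EmbedderContractError("embedder returned non-finite values")
    return matrix
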