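"""Term embedding providers and cosine similarity.

The built-in provider is a deterministic stand-in for a pretrained
sentence-embedding model: hashed character-trigram counts of the
normalized term are projected to a fixed dimension (default 700) with a
fixed-seed Gaussian random projection and L2-normalized. It needs no
model download, is reproducible across processes, and preserves enough
lexical similarity for seed-list validation. Precomputed vectors from a
real embedding model can be supplied via ``PrecomputedEmbedding`` for
fidelity runs.
"""

from __future__ import annotations

import zlib
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from .extraction import normalize

_N_FEATURES = 4096
_PROJECTION_SEED = 20220523  # fixed: embeddings never depend on pipeline seeds


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Contract: map a term string to a finite vector of fixed dimension."""

    dimension: int

    def embed(self, term: str) -> np.ndarray: ...


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two equal-dimension nonzero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


class TrigramHashEmbedding:
    """Hashed character-trigram counts + fixed-seed random projection."""

    def __init__(self, dimension: int = 700):
        if dimension < 1:
            raise ValueError("dimension must be positive")
        self.dimension = dimension
        rng = np.random.default_rng(_PROJECTION_SEED)
        self._projection = rng.standard_normal((_N_FEATURES, dimension))

    @staticmethod
    def _trigram_counts(term: str) -> np.ndarray:
        text = f"  {normalize(term)}  "
        counts = np.zeros(_N_FEATURES)
        for i in range(len(text) - 2):
            tri = text[i : i + 3]
            # crc32 is stable across processes, unlike builtin hash()
            counts[zlib.crc32(tri.encode("utf-8")) % _N_FEATURES] += 1.0
        return counts

    def embed(self, term: str) -> np.ndarray:
        if not term or not term.strip():
            raise ValueError("cannot embed an empty term")
        vec = self._trigram_counts(term) @ self._projection
        return vec / np.linalg.norm(vec)


class PrecomputedEmbedding:
    """Vectors read from a TSV of ``term<TAB>v1<TAB>v2...`` rows.

    Lookup is under the matching normalization; unknown terms raise.
    """

    def __init__(self, path: str | Path):
        self._vectors: dict[str, np.ndarray] = {}
        dim = None
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, 1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}: malformed vector row on line {i}")
                vec = np.array([float(x) for x in parts[1:]])
                if dim is None:
                    dim = len(vec)
                elif len(vec) != dim:
                    raise ValueError(f"{path}: inconsistent dimension on line {i}")
                if not np.all(np.isfinite(vec)):
                    raise ValueError(f"{path}: non-finite vector on line {i}")
                self._vectors[normalize(parts[0])] = vec
        if dim is None:
            raise ValueError(f"{path}: no vectors found")
        self.dimension = dim

    def embed(self, term: str) -> np.ndarray:
        key = normalize(term)
        if key not in self._vectors:
            raise KeyError(f"no precomputed vector for {term!r}")
        return self._vectors[key]
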