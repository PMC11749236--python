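"""Fixed-width per-protein feature vectors from sequences.

Backends implement a tiny contract: a name, an output width and a
deterministic ``embed(sequence) -> vector``.  The hashed backend needs no
model downloads and is the default for offline runs; the pretrained backend
wraps a protein language model when ``fair-esm`` is installed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from .graphio import FeatureMatrix, ProteinRecord


class EmbedderBackend(Protocol):
    name: str
    dim: int

    def embed(self, sequence: str) -> np.ndarray: ...


class EmbeddingError(RuntimeError):
    pass


def hashed_embedding(sequence: str, dim: int, seed: int = 0) -> np.ndarray:
    """Unit-norm pseudo-random vector keyed by (sequence hash, seed).

    Built from 3-mer-seeded random projections so that related sequences are
    not trivially identical, while any fixed sequence always maps to the same
    vector.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if not sequence:
        raise EmbeddingError("cannot embed an empty sequence")
    vec = np.zeros(dim)
    k = 3
    kmers = (
        [sequence[i : i + k] for i in range(len(sequence) - k + 1)]
        if len(sequence) >= k
        else [sequence]
    )
    for kmer in kmers:
        digest = hashlib.blake2b(
            kmer.encode(), digest_size=8, key=str(seed).encode()
        ).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "little"))
        vec += rng.standard_normal(dim)
    norm = float(np.linalg.norm(vec))
    if norm == 0.0:  # astronomically unlikely; keep the contract total
        vec[0] = 1.0
        norm = 1.0
    return vec / norm


@dataclass(frozen=True)
class HashedBackend:
    """Offline deterministic stand-in for the pretrained language model."""

    dim: int = 1280
    seed: int = 0
    name: str = "hashed"

    def embed(self, sequence: str) -> np.ndarray:
        return hashed_embedding(sequence, self.dim, self.seed)


class PretrainedBackend:
    """Protein-language-model backend (optional; requires ``fair-esm``).

    Per-protein vector = mean over residue positions of the final-layer
    representations.
    """

    name = "pretrained"
    dim = 1280

    def __init__(self, model_name: str = "esm1b_t33_650M_UR50S"):
        try:
            import esm  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise EmbeddingError(
                "the pretrained backend requires the 'fair-esm' package; "
                "use the hashed backend for offline runs"
            ) from exc
        self._model, self._alphabet = esm.pretrained.load_model_and_alphabet(model_name)
        self._model.eval()
        self._layer = 33

    def embed(self, sequence: str) -> np.ndarray:  # pragma: no cover - optional
        import torch  # type: ignore

        converter = self._alphabet.get_batch_converter()
        _, _, toks = converter([("seq", sequence)])
        with torch.no_grad():
            out = self._model(toks, repr_layers=[self._layer])
        rep = out["representations"][self._layer][0, 1 : len(sequence) + 1]
        return rep.mean(dim=0).numpy().astype(float)


def get_backend(name: str, dim: int = 1280, seed: int = 0) -> EmbedderBackend:
    if name == "hashed":
        return HashedBackend(dim=dim, seed=seed)
    if name == "pretrained":
        return PretrainedBackend()
    raise ValueError(f"unknown embedder backend {name!r}")


def embed_sequences(
    records: Sequence[ProteinRecord], backend: EmbedderBackend
) -> FeatureMatrix:
    """Embed each record; row order matches record order."""
    rows = []
    for rec in records:
        try:
            vec = np.asarray(backend.embed(rec.sequence), dtype=float)
        except Exception as exc:
            raise EmbeddingError(f"backend {backend.name!r} failed on record {rec.id!r}: {exc}") from exc
        if vec.shape != (backend.dim,):
            raise EmbeddingError(
                f"backend {backend.name!r} returned shape {vec.shape} for record "
                f"{rec.id!r}; expected ({backend.dim},)"
            )
        rows.append(vec)
    values = np.array(rows) if rows else np.empty((0, backend.dim))
    return FeatureMatrix(node_ids=tuple(r.id for r in records), values=values)
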