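"""Sequence embedding providers.

Two providers map amino-acid sequences to fixed-length vectors:

``kmer_hash``
    Deterministic, fully offline: k-mer counts accumulated into ``width``
    bins through a seeded cryptographic hash, then L2-normalized.  The
    default width (320) matches the hidden size of the 8M-parameter tier of
    the ESM-2 protein language model so the rest of the stack is
    provider-agnostic.

``plm``
    Mean-pooled final-layer residue embeddings from a pretrained protein
    language model (ESM-2).  Requires the optional ``esm`` (fair-esm)
    dependency and a checkpoint download; when unavailable an explicit
    error is raised — never a silent fallback.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import is_valid_sequence


class EmbeddingProviderUnavailable(RuntimeError):
    """Raised when a provider needs an external resource that is absent."""


@dataclass(frozen=True)
class EmbedderSpec:
    provider: str = "kmer_hash"
    width: int = 320
    k: int = 3
    hash_seed: int = 17
    checkpoint: str = "esm2_t6_8M_UR50D"
    pooling: str = "mean"

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.provider not in {"kmer_hash", "plm"}:
            raise ValueError(f"unknown provider {self.provider!r}")

    def cache_key(self) -> str:
        if self.provider == "kmer_hash":
            return f"kmer_hash-k{self.k}-w{self.width}-s{self.hash_seed}"
        return f"plm-{self.checkpoint}-{self.pooling}"


@dataclass
class EmbeddingMatrix:
    """Dense n×m matrix with a sequence → row index."""

    matrix: np.ndarray
    index: dict = field(repr=False)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, seq: str) -> bool:
        return seq in self.index

    def row(self, seq: str) -> np.ndarray:
        return self.matrix[self.index[seq]]

    def submatrix(self, sequences) -> np.ndarray:
        return self.matrix[[self.index[s] for s in sequences]]


def _hash_bin(kmer: str, hash_seed: int, width: int) -> int:
    digest = hashlib.blake2b(
        f"{hash_seed}:{kmer}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % width


def kmer_hash_embed(sequence: str, k: int = 3, width: int = 320,
                    hash_seed: int = 17) -> np.ndarray:
    """Hashed k-mer count vector, L2-normalized.

    Counts every length-k sliding window into one of ``width`` bins chosen
    by a seeded deterministic hash.  Collisions are seed-stable; changing
    the seed relocates bins but preserves the unit norm.
    """
    if len(sequence) < k:
        raise ValueError(
            f"sequence of length {len(sequence)} shorter than k={k}"
        )
    vec = np.zeros(width, dtype=np.float64)
    for i in range(len(sequence) - k + 1):
        vec[_hash_bin(sequence[i:i + k], hash_seed, width)] += 1.0
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec /= norm
    return vec


def _plm_embed_batch(sequences, spec: EmbedderSpec) -> np.ndarray:
    try:
        import esm  # noqa: F401
    except ImportError as exc:
        raise EmbeddingProviderUnavailable(
            "external resource required: the 'plm' provider needs the "
            "fair-esm package and a pretrained ESM-2 checkpoint "
            f"({spec.checkpoint}); install fair-esm or use the offline "
            "'kmer_hash' provider"
        ) from exc
    model, alphabet = esm.pretrained.load_model_and_alphabet(spec.checkpoint)
    model.eval()
    converter = alphabet.get_batch_converter()
    import torch

    rows = []
    with torch.no_grad():
        for seq in sequences:
            _, _, toks = converter([("q", seq)])
            out = model(toks, repr_layers=[model.num_layers])
            rep = out["representations"][model.num_layers][0, 1:len(seq) + 1]
            rows.append(rep.mean(0).numpy() if spec.pooling == "mean"
                        else rep.max(0).values.numpy())
    return np.asarray(rows, dtype=np.float64)


def embed_sequences(sequences, spec: EmbedderSpec | None = None,
                    cache_dir=None) -> EmbeddingMatrix:
    """Embed unique sequences; same sequence always yields identical rows.

    With ``cache_dir`` set, per-sequence vectors are persisted keyed by
    (provider, options, sequence) and reused across calls and processes.
    """
    spec = spec or EmbedderSpec()
    unique: list[str] = []
    seen = set()
    for s in sequences:
        if not is_valid_sequence(s):
            raise ValueError(f"invalid sequence: {s!r}")
        if s not in seen:
            seen.add(s)
            unique.append(s)

    cached: dict[str, np.ndarray] = {}
    if cache_dir is not None:
        cached = _load_cache(Path(cache_dir), spec)

    missing = [s for s in unique if s not in cached]
    if missing:
        if spec.provider == "kmer_hash":
            fresh = np.array([
                kmer_hash_embed(s, spec.k, spec.width, spec.hash_seed)
                for s in missing
            ]).reshape(len(missing), spec.width)
        else:
            fresh = _plm_embed_batch(missing, spec)
        for s, row in zip(missing, fresh):
            cached[s] = row
        if cache_dir is not None:
            _store_cache(Path(cache_dir), spec, cached)

    matrix = (np.array([cached[s] for s in unique])
              if unique else np.empty((0, spec.width)))
    return EmbeddingMatrix(matrix, {s: i for i, s in enumerate(unique)})


def _cache_paths(cache_dir: Path, spec: EmbedderSpec):
    base = cache_dir / spec.cache_key()
    return base.with_suffix(".npy"), base.with_suffix(".json")


def _load_cache(cache_dir: Path, spec: EmbedderSpec) -> dict:
    npy, manifest = _cache_paths(cache_dir, spec)
    if not (npy.exists() and manifest.exists()):
        return {}
    matrix = np.load(npy)
    index = json.loads(manifest.read_text())
    return {seq: matrix[i] for seq, i in index.items()}


def _store_cache(cache_dir: Path, spec: EmbedderSpec, vectors: dict) -> None:
    cache_dir.mkdir(parents=True, exist_ok=True)
    npy, manifest = _cache_paths(cache_dir, spec)
    seqs = sorted(vectors)
    np.save(npy, np.array([vectors[s] for s in seqs]))
    manifest.write_text(json.dumps({s: i for i, s in enumerate(seqs)}))
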