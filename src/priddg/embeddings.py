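"""Per-residue embedding providers and the on-disk embedding cache.

Each provider maps an amino-acid string to an L×D matrix, one row per
residue.  Two protein-language-model adapters are declared — an ESM-2-class
provider (D=1280, the hidden size of the 650M-parameter 33-layer checkpoint)
and a ProtT5-XL-class provider (D=1024) — plus a deterministic synthetic
provider for download-free testing.  The PLM adapters fail loudly when their
backends are not installed; they never fall back to synthetic vectors.

Windows shorter than the target length are zero-padded *after* embedding,
so tokenizers never see padding characters.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .windowing import WindowedSample

__all__ = [
    "EmbeddingProvider",
    "SyntheticProvider",
    "ESM2Provider",
    "ProtT5Provider",
    "EmbeddingMatrix",
    "embed_window",
    "cached_embed",
    "synthetic_provider",
    "sequence_hash",
]

logger = logging.getLogger(__name__)


def sequence_hash(seq: str) -> str:
    return hashlib.sha256(seq.encode("ascii")).hexdigest()[:16]


@dataclass
class EmbeddingMatrix:
    """Fixed-shape per-residue feature matrix for one windowed sample.

    ``values`` has ``target_len`` rows: the real window rows followed by
    ``pad_len`` all-zero rows.
    """

    values: np.ndarray
    provider_name: str
    seq_hash: str
    local_index: int
    pad_len: int


class EmbeddingProvider:
    """Deterministic map from an amino-acid string to an (L, dim) matrix."""

    name: str
    dim: int

    def embed(self, seq: str) -> np.ndarray:
        raise NotImplementedError


class SyntheticProvider(EmbeddingProvider):
    """Deterministic pseudo-embeddings with local sequence context.

    Each residue's vector is a fixed convex combination of (a) a per-residue
    identity pattern and (b) a pattern keyed by the ±2-residue context
     5-mer, both derived from the provider seed via a stable hash.  Entries
    are bounded in [−1, 1]; editing one site changes rows i−2..i+2 only.
    """

    def __init__(self, dim: int, seed: int, identity_weight: float = 0.9):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.name = f"synthetic-d{dim}-s{seed}"
        self.dim = dim
        self.seed = seed
        self.identity_weight = identity_weight
        self._cache: dict[tuple[str, str], np.ndarray] = {}

    def _pattern(self, tag: str) -> np.ndarray:
        digest = hashlib.sha256(f"{self.seed}:{tag}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        return rng.uniform(-1.0, 1.0, size=self.dim)

    def residue_vector(self, residue: str, context: str) -> np.ndarray:
        key = (residue, context)
        vec = self._cache.get(key)
        if vec is None:
            w = self.identity_weight
            vec = w * self._pattern(f"res:{residue}") + (1 - w) * self._pattern(f"ctx:{context}")
            self._cache[key] = vec
        return vec

    def embed(self, seq: str) -> np.ndarray:
        padded = "--" + seq + "--"  # boundary markers for terminal contexts
        rows = [
            self.residue_vector(seq[i], padded[i : i + 5])
            for i in range(len(seq))
        ]
        return np.stack(rows)


def synthetic_provider(dim: int, seed: int) -> SyntheticProvider:
    return SyntheticProvider(dim, seed)


class _PLMProvider(EmbeddingProvider):
    """Base for adapters around pretrained protein language models."""

    _backend_hint: str

    def __init__(self):
        raise RuntimeError(
            f"The {type(self).__name__} backend is not available in this "
            f"environment: {self._backend_hint}. Install the backend and the "
            f"model weights, or use the synthetic provider "
            f"(priddg.embeddings.synthetic_provider) for testing. Synthetic "
            f"vectors are never substituted implicitly."
        )


class ESM2Provider(_PLMProvider):
    """ESM-2 650M (33 layers, hidden size 1280), final-layer residue states."""

    name = "esm2"
    dim = 1280
    checkpoint = "esm2_t33_650M_UR50D"
    _backend_hint = "requires `torch` and `fair-esm` plus the esm2_t33_650M_UR50D weights"


class ProtT5Provider(_PLMProvider):
    """ProtT5-XL encoder (hidden size 1024), final-layer residue states."""

    name = "prottrans"
    dim = 1024
    checkpoint = "Rostlab/prot_t5_xl_half_uniref50-enc"
    _backend_hint = "requires `torch` and `transformers` plus the ProtT5-XL encoder weights"


def embed_window(provider: EmbeddingProvider, sample: WindowedSample,
                 target_len: int = 181) -> EmbeddingMatrix:
    """Embed one window and zero-pad the rows to ``target_len``."""
    rows = np.asarray(provider.embed(sample.window_seq), dtype=np.float64)
    if rows.shape != (len(sample.window_seq), provider.dim):
        raise ValueError(
            f"provider {provider.name} returned shape {rows.shape}, expected "
            f"({len(sample.window_seq)}, {provider.dim})"
        )
    if not np.isfinite(rows).all():
        raise ValueError(f"provider {provider.name} produced non-finite entries")
    pad = target_len - rows.shape[0]
    if pad != sample.pad_len:
        raise ValueError(
            f"window/pad mismatch: window {rows.shape[0]} + declared pad "
            f"{sample.pad_len} != target {target_len}"
        )
    values = np.vstack([rows, np.zeros((pad, provider.dim))]) if pad else rows
    return EmbeddingMatrix(
        values=values,
        provider_name=provider.name,
        seq_hash=sequence_hash(sample.window_seq),
        local_index=sample.local_index,
        pad_len=pad,
    )


def _digest(values: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(values).tobytes()).hexdigest()


def cached_embed(provider: EmbeddingProvider, samples: list[WindowedSample],
                 cache_path: str | Path, target_len: int = 181) -> list[EmbeddingMatrix]:
    """Embed windows through an HDF5 cache keyed by (provider, window hash).

    Each matrix is computed at most once per (provider_name, seq_hash); a
    second call returns byte-identical matrices without invoking the
    provider.  Corrupt entries (digest mismatch) are recomputed with a
    warning.
    """
    out: list[EmbeddingMatrix] = []
    with h5py.File(str(cache_path), "a") as f:
        grp = f.require_group(provider.name)
        for sample in samples:
            key = sequence_hash(sample.window_seq)
            mat = None
            if key in grp:
                dset = grp[key]
                values = dset[...]
                if _digest(values) == dset.attrs.get("digest", ""):
                    mat = EmbeddingMatrix(values, provider.name, key,
                                          sample.local_index, int(dset.attrs["pad_len"]))
                else:
                    warnings.warn(f"embedding cache entry {provider.name}/{key} "
                                  f"is corrupt; recomputing")
                    del grp[key]
            if mat is None:
                mat = embed_window(provider, sample, target_len)
                dset = grp.create_dataset(key, data=mat.values)
                dset.attrs["dim"] = provider.dim
                dset.attrs["pad_len"] = mat.pad_len
                dset.attrs["digest"] = _digest(mat.values)
            out.append(mat)
    return out
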