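"""Assemble model-ready arrays from a mutation dataset and two providers.

For every record the mutant chain is built, the mutation-centered window
extracted, and both embedding streams computed and zero-padded to the
window target length.  The result is a bundle of dense arrays (one sample
per record) that the trainer and the cross-validation drivers consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .dataset import MutationDataset, MutationRecord
from .embeddings import EmbeddingProvider, cached_embed, embed_window
from .windowing import WindowConfig, apply_mutation, extract_window

__all__ = ["FeatureArrays", "build_features"]


@dataclass
class FeatureArrays:
    """Dense per-sample inputs: two embedding stacks, site indices, labels."""

    E: Optional[np.ndarray]  # (N, L, esm_dim)
    P: Optional[np.ndarray]  # (N, L, pt_dim)
    local_index: np.ndarray  # (N,) 0-based mutation-site rows
    y: np.ndarray  # (N,) ΔΔG in kcal/mol
    records: list[MutationRecord]
    pair_keys: list[tuple]

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx) -> "FeatureArrays":
        idx = np.asarray(idx, dtype=int)
        return FeatureArrays(
            E=None if self.E is None else self.E[idx],
            P=None if self.P is None else self.P[idx],
            local_index=self.local_index[idx],
            y=self.y[idx],
            records=[self.records[i] for i in idx],
            pair_keys=[self.pair_keys[i] for i in idx],
        )


def build_features(dataset: MutationDataset,
                   esm_provider: Optional[EmbeddingProvider],
                   pt_provider: Optional[EmbeddingProvider],
                   window_config: WindowConfig = WindowConfig(),
                   cache_path: str | Path | None = None,
                   dtype=np.float32) -> FeatureArrays:
    samples = []
    for rec in dataset.records:
        ctx = dataset.sequence_for(rec)
        mutant = apply_mutation(ctx, rec.position, rec.wt_residue, rec.mut_residue)
        samples.append(extract_window(mutant, rec.position, window_config))

    target = window_config.target_len

    def _stack(provider):
        if provider is None:
            return None
        if cache_path is not None:
            mats = cached_embed(provider, samples, cache_path, target)
        else:
            mats = [embed_window(provider, s, target) for s in samples]
        return np.stack([m.values for m in mats]).astype(dtype)

    return FeatureArrays(
        E=_stack(esm_provider),
        P=_stack(pt_provider),
        local_index=np.array([s.local_index for s in samples], dtype=int),
        y=np.array([r.ddg for r in dataset.records], dtype=np.float64),
        records=list(dataset.records),
        pair_keys=[r.pair_key for r in dataset.records],
    )
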