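"""Model/Results facade over the ΔΔG regression pipeline.

`DDGModel` is constructed from data (a mutation dataset plus embedding
providers, or prebuilt feature arrays) and a :class:`ModelConfig`;
``fit()`` trains the dual-branch network and returns a :class:`DDGResults`
carrying the fitted network, the optimisation history, training/validation
diagnostics and a ``summary()`` table.  Cross-validation and ablation runs
hang off the model object.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Optional

import numpy as np

from .dataset import MutationDataset
from .embeddings import EmbeddingProvider
from .features import FeatureArrays, build_features
from .network import DualBranchNetwork, ModelConfig
from .training import (
    CVReport,
    FoldMetrics,
    TrainSpec,
    TrainingHistory,
    compute_metrics,
    run_ablation,
    run_cv,
)
from .windowing import WindowConfig

__all__ = ["DDGModel", "DDGResults", "save_checkpoint", "load_checkpoint"]


class DDGModel:
    """Sequence-based ΔΔG regressor bound to a training data bundle."""

    def __init__(self, data: FeatureArrays, config: ModelConfig = ModelConfig()):
        if len(data) == 0:
            raise ValueError("empty feature bundle")
        self.data = data
        self.config = config

    @classmethod
    def from_dataset(cls, dataset: MutationDataset,
                     esm_provider: Optional[EmbeddingProvider],
                     pt_provider: Optional[EmbeddingProvider],
                     config: ModelConfig = ModelConfig(),
                     window_config: Optional[WindowConfig] = None,
                     cache_path=None) -> "DDGModel":
        window_config = window_config or WindowConfig((config.window_len - 1) // 2)
        if window_config.target_len != config.window_len:
            raise ValueError("window_config.target_len must equal config.window_len")
        data = build_features(dataset, esm_provider, pt_provider, window_config,
                              cache_path)
        return cls(data, config)

    def fit(self, spec: TrainSpec = TrainSpec(), val_fraction: float = 0.1,
            seed: Optional[int] = None) -> "DDGResults":
        """Train on the bound data; a random ``val_fraction`` of samples is
        held out for early stopping (0 disables it)."""
        seed = spec.seed if seed is None else seed
        from .training import train_model

        n = len(self.data)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_val = int(np.floor(val_fraction * n))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        train = self.data.subset(train_idx)
        val = self.data.subset(val_idx) if n_val else None
        if val is None and spec.patience is not None:
            spec = TrainSpec(batch_size=spec.batch_size, max_epochs=spec.max_epochs,
                             patience=None, seed=spec.seed)
        net = DualBranchNetwork(self.config, seed=seed)
        history = train_model(net, train, val, self.config, spec)
        return DDGResults(self, net, history, train, val, spec)

    def cross_validate(self, strategy: str, spec: TrainSpec = TrainSpec(),
                       seed: int = 0, repeats: int = 20,
                       pair_grouping: bool = False) -> CVReport:
        return run_cv(self.data, strategy, self.config, spec, seed, repeats,
                      pair_grouping)

    def ablate(self, grid, spec: TrainSpec = TrainSpec(), seed: int = 0,
               strategy: str = "cv3", repeats: int = 20,
               pair_grouping: bool = False):
        return run_ablation(self.data, grid, self.config, spec, seed,
                            strategy, repeats, pair_grouping)


class DDGResults:
    """Fitted-model results: parameters, diagnostics and prediction."""

    def __init__(self, model: DDGModel, network: DualBranchNetwork,
                 history: TrainingHistory, train: FeatureArrays,
                 val: Optional[FeatureArrays], spec: TrainSpec):
        self.model = model
        self.network = network
        self.history = history
        self.spec = spec
        self._train = train
        self._val = val
        self.fittedvalues = network.predict(train.E, train.P, train.local_index)
        self.train_metrics = compute_metrics(train.y, self.fittedvalues)
        self.val_metrics: Optional[FoldMetrics] = None
        if val is not None and len(val) >= 2:
            pred = network.predict(val.E, val.P, val.local_index)
            self.val_metrics = compute_metrics(val.y, pred)

    @property
    def resid(self) -> np.ndarray:
        return self.fittedvalues - self._train.y

    def predict(self, data: FeatureArrays) -> np.ndarray:
        return self.network.predict(data.E, data.P, data.local_index)

    def predict_dataset(self, dataset: MutationDataset,
                        esm_provider, pt_provider,
                        window_config: Optional[WindowConfig] = None) -> np.ndarray:
        cfg = self.model.config
        window_config = window_config or WindowConfig((cfg.window_len - 1) // 2)
        data = build_features(dataset, esm_provider, pt_provider, window_config)
        return self.predict(data)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "ΔΔG regression results",
            "=" * 58,
            f"branches:            esm={cfg.esm_branch_mode}, pt={cfg.pt_branch_mode}",
            f"architecture:        layers={cfg.num_layers}, d_model={cfg.d_model}, "
            f"heads={cfg.num_heads}, kernels={cfg.conv_kernels}",
            f"parameters:          {self.network.n_parameters():,}",
            f"samples:             train={len(self._train)}, "
            f"val={0 if self._val is None else len(self._val)}",
            f"epochs run:          {len(self.history.train_loss)} "
            f"(best epoch {self.history.best_epoch})",
            f"final train loss:    {self.history.train_loss[-1]:.4f}",
        ]
        m = self.train_metrics
        pcc = "undefined" if m.pcc is None else f"{m.pcc:.3f}"
        lines.append(f"train metrics:       PCC={pcc}, RMSE={m.rmse:.3f} kcal/mol, "
                     f"MAE={m.mae:.3f} kcal/mol")
        if self.val_metrics is not None:
            m = self.val_metrics
            pcc = "undefined" if m.pcc is None else f"{m.pcc:.3f}"
            lines.append(f"validation metrics:  PCC={pcc}, RMSE={m.rmse:.3f} kcal/mol, "
                         f"MAE={m.mae:.3f} kcal/mol")
        lines.append("=" * 58)
        return "\n".join(lines)

    def save(self, path) -> None:
        save_checkpoint(path, self.network)


def save_checkpoint(path, network: DualBranchNetwork) -> None:
    """Single-archive checkpoint: config (JSON) plus all state arrays."""
    cfg = asdict(network.config)
    arrays = {f"arr_{i}": a for i, a in enumerate(network.state_arrays())}
    np.savez(str(path), config=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> DualBranchNetwork:
    with np.load(str(path)) as f:
        cfg_dict = json.loads(bytes(f["config"].tobytes()).decode())
        for key in ("conv_kernels", "conv_channels", "head_widths", "seq_len_range"):
            if key in cfg_dict and isinstance(cfg_dict[key], list):
                cfg_dict[key] = tuple(cfg_dict[key])
        config = ModelConfig(**cfg_dict)
        net = DualBranchNetwork(config, seed=0)
        arrays = [f[f"arr_{i}"] for i in range(len(net.state_arrays()))]
        net.load_state(arrays)
    return net
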