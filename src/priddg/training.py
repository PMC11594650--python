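"""Training loop, regression metrics, cross-validation and ablation drivers.

The model is fitted by minibatch Adam on mean-squared error plus an explicit
L2 penalty on all weight matrices, with early stopping on validation RMSE.
Evaluation follows three protocols: CV1 (repeated random 90/10 split), CV2
(repeated random 80/20 split) — both averaged over 20 repetitions by
default — and CV3 (10-fold cross-validation).  In CV1/CV2/CV3 alike, 10% of
each training portion is held out for validation.  Metrics are the Pearson
correlation coefficient, RMSE and MAE (both in kcal/mol).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .features import FeatureArrays
from .network import DualBranchNetwork, ModelConfig, normalize_mode
from .nn import Adam, Tensor

__all__ = [
    "FoldMetrics",
    "CVReport",
    "TrainSpec",
    "TrainingHistory",
    "compute_metrics",
    "train_model",
    "run_cv",
    "run_ablation",
    "ABLATION_GRIDS",
]

logger = logging.getLogger(__name__)

#: Branch-mode grids of the three ablation studies: encoder contribution,
#: multiscale-convolution contribution, and the combined-module study whose
#: last entry is the default full model.
ABLATION_GRIDS: dict[str, list[tuple[str, str]]] = {
    "encoder": [("p", "p"), ("Ep", "p"), ("p", "Ep"), ("Ep", "Ep")],
    "conv": [("m", "p"), ("p", "m"), ("m", "m")],
    "combined": [("Ep", "off"), ("off", "m"), ("Ep", "m")],
}


@dataclass(frozen=True)
class FoldMetrics:
    """PCC / RMSE / MAE for one evaluated split.

    ``pcc`` is ``None`` when either vector is constant (the correlation is
    undefined there — it is reported as missing, never as zero).
    """

    pcc: Optional[float]
    rmse: float
    mae: float
    n: int


def compute_metrics(y_true, y_pred) -> FoldMetrics:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D of equal length")
    if len(y_true) < 2:
        raise ValueError("metrics need at least 2 samples")
    resid = y_pred - y_true
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mae = float(np.mean(np.abs(resid)))
    st, sp = y_true.std(), y_pred.std()
    if st == 0.0 or sp == 0.0:
        pcc = None
    else:
        pcc = float(((y_true - y_true.mean()) * (y_pred - y_pred.mean())).mean() / (st * sp))
    return FoldMetrics(pcc=pcc, rmse=rmse, mae=mae, n=len(y_true))


@dataclass(frozen=True)
class TrainSpec:
    """Optimisation settings (the architecture's lr/L2/dropout live in
    :class:`ModelConfig`)."""

    batch_size: int = 32
    max_epochs: int = 200
    patience: Optional[int] = 20  # early-stopping patience on validation RMSE
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience is not None and self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_rmse: list[float] = field(default_factory=list)
    best_epoch: int = -1


def train_model(net: DualBranchNetwork, train: FeatureArrays,
                val: Optional[FeatureArrays], config: ModelConfig,
                spec: TrainSpec) -> TrainingHistory:
    """Fit ``net`` in place; returns the per-epoch loss history.

    Minimises ``MSE + l2_reg · Σ‖W‖²`` by minibatch Adam.  When a validation
    set is given, the parameters of the best validation-RMSE epoch are
    restored at the end; early stopping requires a validation set.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    if val is None and spec.patience is not None:
        raise ValueError("early stopping (patience) requires a validation set")
    net.reset_rng(spec.seed)
    rng = np.random.default_rng(spec.seed + 1)
    opt = Adam(net.parameters(), lr=config.lr)
    history = TrainingHistory()
    best_state = None
    best_rmse = np.inf
    since_best = 0
    n = len(train)
    for epoch in range(spec.max_epochs):
        net.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, spec.batch_size):
            idx = order[lo : lo + spec.batch_size]
            opt.zero_grad()
            pred = net.forward(None if train.E is None else train.E[idx],
                               None if train.P is None else train.P[idx],
                               train.local_index[idx])
            err = pred - Tensor(train.y[idx])
            loss = (err * err).mean() + config.l2_reg * net.l2_penalty()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (lr={config.lr}, "
                    f"batch={len(idx)}); check input scaling"
                )
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history.train_loss.append(epoch_loss / n)
        if val is not None:
            pred = net.predict(val.E, val.P, val.local_index)
            rmse = float(np.sqrt(np.mean((pred - val.y) ** 2)))
            history.val_rmse.append(rmse)
            if rmse < best_rmse - 1e-12:
                best_rmse = rmse
                best_state = net.copy_state()
                history.best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if spec.patience is not None and since_best > spec.patience:
                    break
    if best_state is not None:
        net.load_state(best_state)
    return history


# ---------------------------------------------------------------------------
# split construction

_TEST_FRACTION = {"cv1": 0.1, "cv2": 0.2}
_VAL_FRACTION = 0.1  # of the training portion, in every protocol


def _group_indices(data: FeatureArrays, pair_grouping: bool) -> list[np.ndarray]:
    """Unit of assignment: single samples, or forward/reverse pairs."""
    if not pair_grouping:
        return [np.array([i]) for i in range(len(data))]
    members: dict[tuple, list[int]] = {}
    order = []
    for i, key in enumerate(data.pair_keys):
        if key not in members:
            members[key] = []
            order.append(key)
        members[key].append(i)
    return [np.array(members[k]) for k in order]


def _flatten(groups: list[np.ndarray], picks: np.ndarray) -> np.ndarray:
    if len(picks) == 0:
        return np.array([], dtype=int)
    return np.concatenate([groups[i] for i in picks])


def _random_split_3way(groups: list[np.ndarray], rng: np.random.Generator,
                       test_fraction: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(train, val, test) indices; floor rounding, remainder to the pool."""
    g = len(groups)
    perm = rng.permutation(g)
    n_test = int(np.floor(test_fraction * g))
    test = perm[:n_test]
    pool = perm[n_test:]
    n_val = int(np.floor(_VAL_FRACTION * len(pool)))
    val = pool[:n_val]
    tr = pool[n_val:]
    return _flatten(groups, tr), _flatten(groups, val), _flatten(groups, test)


def _kfold_splits(groups: list[np.ndarray], rng: np.random.Generator,
                  k: int) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    perm = rng.permutation(len(groups))
    folds = np.array_split(perm, k)
    out = []
    for f in range(k):
        test = folds[f]
        pool = np.concatenate([folds[j] for j in range(k) if j != f])
        n_val = int(np.floor(_VAL_FRACTION * len(pool)))
        val, tr = pool[:n_val], pool[n_val:]
        out.append((_flatten(groups, tr), _flatten(groups, val), _flatten(groups, test)))
    return out


def make_splits(data: FeatureArrays, strategy: str, repeats: int, seed: int,
                pair_grouping: bool = False) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Deterministic (train, val, test) index triples for a protocol.

    CV1/CV2 produce ``repeats`` random splits seeded ``seed+i``; CV3
    produces 10 disjoint, exhaustive folds from a single shuffle at
    ``seed``.
    """
    strategy = strategy.lower()
    groups = _group_indices(data, pair_grouping)
    if strategy in _TEST_FRACTION:
        frac = _TEST_FRACTION[strategy]
        return [
            _random_split_3way(groups, np.random.default_rng(seed + i), frac)
            for i in range(repeats)
        ]
    if strategy == "cv3":
        return _kfold_splits(groups, np.random.default_rng(seed), 10)
    raise ValueError(f"unknown CV strategy {strategy!r}; expected cv1, cv2 or cv3")


@dataclass
class CVReport:
    strategy: str
    per_fold: list[FoldMetrics]
    seeds: list[int]
    pair_grouping: bool
    histories: list[TrainingHistory] = field(default_factory=list)

    def _values(self, name: str) -> np.ndarray:
        vals = [getattr(m, name) for m in self.per_fold]
        return np.array([v for v in vals if v is not None], dtype=float)

    def mean(self, name: str) -> float:
        return float(self._values(name).mean())

    def std(self, name: str) -> float:
        v = self._values(name)
        return float(v.std(ddof=1)) if len(v) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "strategy": self.strategy,
            "n_folds": len(self.per_fold),
            "pair_grouping": self.pair_grouping,
            "pcc": self.mean("pcc"),
            "pcc_sd": self.std("pcc"),
            "rmse": self.mean("rmse"),
            "rmse_sd": self.std("rmse"),
            "mae": self.mean("mae"),
            "mae_sd": self.std("mae"),
        }

    def to_dict(self) -> dict:
        return {
            **self.summary(),
            "seeds": self.seeds,
            "per_fold": [
                {"pcc": m.pcc, "rmse": m.rmse, "mae": m.mae, "n": m.n}
                for m in self.per_fold
            ],
        }


def run_cv(data: FeatureArrays, strategy: str, config: ModelConfig,
           spec: TrainSpec, seed: int, repeats: int = 20,
           pair_grouping: bool = False) -> CVReport:
    """Train and evaluate under one cross-validation protocol.

    Every fold trains a freshly initialised network (seeded ``seed+i``) and
    evaluates on its held-out portion; identical seeds reproduce identical
    reports bitwise.
    """
    splits = make_splits(data, strategy, repeats, seed, pair_grouping)
    report = CVReport(strategy=strategy.lower(), per_fold=[], seeds=[],
                      pair_grouping=pair_grouping)
    for i, (tr, va, te) in enumerate(splits):
        fold_seed = seed + i
        if len(te) < 2:
            raise ValueError(f"fold {i} has fewer than 2 test samples")
        net = DualBranchNetwork(config, seed=fold_seed)
        hist = train_model(net, data.subset(tr),
                           data.subset(va) if len(va) else None,
                           config,
                           TrainSpec(batch_size=spec.batch_size,
                                     max_epochs=spec.max_epochs,
                                     patience=spec.patience if len(va) else None,
                                     seed=fold_seed))
        test = data.subset(te)
        pred = net.predict(test.E, test.P, test.local_index)
        report.per_fold.append(compute_metrics(test.y, pred))
        report.seeds.append(fold_seed)
        report.histories.append(hist)
        logger.info("%s fold %d: %s", strategy, i, report.per_fold[-1])
    return report


def run_ablation(data: FeatureArrays, grid: list[tuple[str, str]],
                 config: ModelConfig, spec: TrainSpec, seed: int,
                 strategy: str = "cv3", repeats: int = 20,
                 pair_grouping: bool = False) -> dict[tuple[str, str], CVReport]:
    """Evaluate branch-mode combinations under identical fold assignments.

    ``grid`` entries are (esm_mode, pt_mode) pairs using either the long
    tokens or the shorthand ``p`` / ``Ep`` / ``m`` / ``off``.  Fold
    assignments depend only on (seed, strategy, data), so every
    configuration sees the same splits.
    """
    if not grid:
        raise ValueError("empty ablation grid")
    results: dict[tuple[str, str], CVReport] = {}
    for esm_mode, pt_mode in grid:
        cfg = config.with_modes(normalize_mode(esm_mode), normalize_mode(pt_mode))
        results[(esm_mode, pt_mode)] = run_cv(
            data, strategy, cfg, spec, seed, repeats, pair_grouping
        )
    return results
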