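"""Training protocol shared by the quantum, hybrid and classical models.

Minibatch Adam on the mean-squared error in Hartree^2, with periodic
validation and lowest-validation-loss model selection.  Defaults follow the
common protocol for this model family: learning rate 0.01, beta1 = 0.9,
beta2 = 0.999, batch size 128, 150 epochs with validation every 10 epochs.
Quantum angles and readout coefficients start at exactly 1; classical and
encoding-network weights use seeded Glorot draws, with 3 restarts for the
classical models (best validation loss wins overall).

Gradients: quantum circuits use the exact parameter-shift rule (see
:mod:`eduqgc.qgnn`), classical layers use analytic reverse mode; both are
checked against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import classical as cls_mod
from . import qgnn
from .molgraph import MolecularGraph, add_master_node


@dataclass
class TrainingConfig:
    lr: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 128
    epochs: int = 150
    val_every: int = 10
    seed: int = 0
    n_restarts: int = 1  # 3 for classical models, 1 for quantum/hybrid


@dataclass
class RunResult:
    train_curve: list  # mean train MSE per epoch, Ha^2
    val_curve: list  # validation MSE at each validation point, Ha^2
    val_epochs: list  # 1-based epoch number of each validation point
    best_params: object
    best_val: float
    metrics: Optional[dict] = None


def mse_loss(preds, targets) -> float:
    preds = np.asarray(preds, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if preds.shape != targets.shape or preds.size == 0:
        raise ValueError("predictions and targets must be equal-length, non-empty")
    return float(np.mean((preds - targets) ** 2))


def _is_quantum(model_config) -> bool:
    return isinstance(model_config, qgnn.ModelConfig)


def _prepare(model_config, g: MolecularGraph) -> MolecularGraph:
    if _is_quantum(model_config) and model_config.master_node and not g.has_master:
        return add_master_node(g)
    return g


def predict(model_config, params, g: MolecularGraph) -> float:
    g = _prepare(model_config, g)
    if _is_quantum(model_config):
        return qgnn.forward(g, model_config, params)
    return cls_mod.classical_forward(g, model_config, params)


def _predict_with_grad(model_config, params, g):
    g = _prepare(model_config, g)
    if _is_quantum(model_config):
        return qgnn.forward_with_grad(g, model_config, params)
    return cls_mod.classical_forward_with_grad(g, model_config, params)


def gradient(model_config, params, batch):
    """Batch-MSE gradient wrt every trainable scalar.

    Returns ``(loss, grads)`` with ``grads`` keyed like
    ``params.as_arrays()``.  For an N-graph batch the loss is
    ``mean((pred - y)^2)``, so each per-graph prediction gradient enters
    with weight ``2 (pred - y) / N``.
    """
    n = len(batch)
    if n == 0:
        raise ValueError("empty batch")
    grads = {name: np.zeros_like(arr) for name, arr in params.as_arrays().items()}
    sq = 0.0
    for g in batch:
        if g.target_ha is None:
            raise ValueError(f"graph {g.id or '<unnamed>'} has no target")
        pred, pgrads = _predict_with_grad(model_config, params, g)
        resid = pred - g.target_ha
        sq += resid**2
        w = 2.0 * resid / n
        for name, arr in pgrads.items():
            grads[name] += w * arr
    return sq / n, grads


@dataclass
class AdamState:
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0


def adam_step(params, grads: dict, state: AdamState, config: TrainingConfig):
    """One in-place Adam update (bias-corrected moments)."""
    arrays = params.as_arrays()
    if not state.m:
        state.m = {k: np.zeros_like(a) for k, a in arrays.items()}
        state.v = {k: np.zeros_like(a) for k, a in arrays.items()}
    state.t += 1
    b1, b2 = config.beta1, config.beta2
    for k, a in arrays.items():
        gk = grads[k]
        state.m[k] = b1 * state.m[k] + (1 - b1) * gk
        state.v[k] = b2 * state.v[k] + (1 - b2) * gk**2
        m_hat = state.m[k] / (1 - b1**state.t)
        v_hat = state.v[k] / (1 - b2**state.t)
        a -= config.lr * m_hat / (np.sqrt(v_hat) + config.eps)
    return params, state


def split_dataset(graphs, sizes, seed: int):
    """Disjoint (train, val, test) split, deterministic per seed."""
    n_train, n_val, n_test = sizes
    if n_train + n_val + n_test > len(graphs):
        raise ValueError("split sizes exceed dataset size")
    perm = np.random.default_rng(seed).permutation(len(graphs))
    idx = perm.tolist()
    train = [graphs[i] for i in idx[:n_train]]
    val = [graphs[i] for i in idx[n_train : n_train + n_val]]
    test = [graphs[i] for i in idx[n_train + n_val : n_train + n_val + n_test]]
    return train, val, test


def _copy_params(params):
    return params.copy()


def _init_for_restart(model_config, rng: np.random.Generator):
    if _is_quantum(model_config):
        return qgnn.init_params(model_config)
    return cls_mod.init_classical_params(model_config, rng)


def train(model_config, train_graphs, val_graphs, config: TrainingConfig) -> RunResult:
    """Run the full protocol and return the best-validation weights.

    Classical models repeat the run ``config.n_restarts`` times from fresh
    seeded initializations and keep the overall best validation loss;
    quantum and hybrid models run once from the all-ones initialization.
    """
    if not train_graphs:
        raise ValueError("empty training set")
    restarts = config.n_restarts if not _is_quantum(model_config) else 1
    master_rng = np.random.default_rng(config.seed)

    best = None
    for restart in range(restarts):
        params = _init_for_restart(model_config, master_rng)
        state = AdamState()
        shuffle_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, restart, 0x5EED])
        )
        train_curve, val_curve, val_epochs = [], [], []
        best_val, best_params = np.inf, _copy_params(params)
        if config.epochs == 0 and val_graphs:
            best_val = _val_loss(model_config, params, val_graphs)
        for epoch in range(1, config.epochs + 1):
            order = shuffle_rng.permutation(len(train_graphs))
            sq_sum = 0.0
            for lo in range(0, len(order), config.batch_size):
                batch = [train_graphs[i] for i in order[lo : lo + config.batch_size]]
                loss, grads = gradient(model_config, params, batch)
                sq_sum += loss * len(batch)
                params, state = adam_step(params, grads, state, config)
            train_curve.append(sq_sum / len(train_graphs))
            if epoch % config.val_every == 0 or epoch == config.epochs:
                vloss = _val_loss(model_config, params, val_graphs or train_graphs)
                val_curve.append(vloss)
                val_epochs.append(epoch)
                if vloss < best_val:
                    best_val = vloss
                    best_params = _copy_params(params)
        if config.epochs == 0:
            best_params = params
            best_val = best_val if val_graphs else np.inf
        result = RunResult(train_curve, val_curve, val_epochs, best_params, best_val)
        if best is None or result.best_val < best.best_val:
            best = result
    return best


def _val_loss(model_config, params, graphs) -> float:
    preds = [predict(model_config, params, g) for g in graphs]
    return mse_loss(preds, [g.target_ha for g in graphs])


def evaluate(model_config, params, graphs) -> dict:
    """MSE (Ha^2), RMSE and MAE (Ha) on labeled graphs, plus MAE stratified
    by the presence of aromatic bonds."""
    if not graphs:
        raise ValueError("empty evaluation set")
    preds = np.array([predict(model_config, params, g) for g in graphs])
    targets = np.array([g.target_ha for g in graphs])
    err = preds - targets
    metrics = {
        "mse_ha2": float(np.mean(err**2)),
        "rmse_ha": float(np.sqrt(np.mean(err**2))),
        "mae_ha": float(np.mean(np.abs(err))),
    }
    arom = np.array([g.has_aromatic_bond for g in graphs])
    if arom.any():
        metrics["mae_ha_aromatic"] = float(np.mean(np.abs(err[arom])))
    if (~arom).any():
        metrics["mae_ha_non_aromatic"] = float(np.mean(np.abs(err[~arom])))
    return metrics
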