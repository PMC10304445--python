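"""Matched classical message-passing baselines.

To isolate the effect of the quantum circuit, the classical models are kept
deliberately small: 3 message-passing layers on 2-dimensional node features
(the same two encoding angles the quantum model consumes), a mean readout
over nodes and a scalar linear head.  Two layer types are available:

* GGNN-type convolution:  x_i' = Phi x_i + aggr_{j in N(i)} NN(e_ij) x_j,
  where NN maps the one-hot bond type through a width-2 ReLU hidden layer
  to a 2x2 matrix; aggr is add, mean or max (empty neighborhoods give 0).
  No nonlinearity is applied between GGNN layers.
* GCN convolution:  x' = relu(D^{-1/2} (A + I) D^{-1/2} x W^T), where A
  holds bond-order weights (single 1, aromatic 1.5, double 2, triple 3)
  and D is the row-sum diagonal of A + I.

Analytic reverse-mode gradients are provided for every weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .encoding import EncodingSpec, fixed_angles
from .molgraph import CHEMICAL_BOND_TYPES, MolecularGraph

FEATURE_DIM = 2
AGGREGATIONS = ("add", "mean", "max")
GCN_BOND_WEIGHT = {"single": 1.0, "aromatic": 1.5, "double": 2.0, "triple": 3.0}


class ClassicalModelError(ValueError):
    pass


@dataclass
class GGNNLayerParams:
    phi: np.ndarray  # (2, 2)
    w1: np.ndarray  # (2, 4): one-hot bond type -> hidden
    b1: np.ndarray  # (2,)
    w2: np.ndarray  # (4, 2): hidden -> flattened 2x2 matrix
    b2: np.ndarray  # (4,)


@dataclass
class GCNLayerParams:
    w: np.ndarray  # (2, 2)


@dataclass
class ClassicalParams:
    layers: list  # GGNNLayerParams | GCNLayerParams, matching the config
    head_w: np.ndarray  # (2,)
    head_b: float

    def as_arrays(self) -> dict:
        out = {}
        for i, lp in enumerate(self.layers):
            if isinstance(lp, GGNNLayerParams):
                out[f"l{i}_phi"] = lp.phi
                out[f"l{i}_w1"] = lp.w1
                out[f"l{i}_b1"] = lp.b1
                out[f"l{i}_w2"] = lp.w2
                out[f"l{i}_b2"] = lp.b2
            else:
                out[f"l{i}_w"] = lp.w
        out["head_w"] = self.head_w
        out["head_b"] = self._head_b_arr
        return out

    def __post_init__(self):
        # store the scalar bias as a 1-element array so optimizers can
        # update it in place through as_arrays()
        self._head_b_arr = np.atleast_1d(np.asarray(self.head_b, dtype=float))

    @property
    def head_bias(self) -> float:
        return float(self._head_b_arr[0])

    def copy(self) -> "ClassicalParams":
        layers = []
        for lp in self.layers:
            if isinstance(lp, GGNNLayerParams):
                layers.append(
                    GGNNLayerParams(
                        lp.phi.copy(), lp.w1.copy(), lp.b1.copy(), lp.w2.copy(), lp.b2.copy()
                    )
                )
            else:
                layers.append(GCNLayerParams(lp.w.copy()))
        out = ClassicalParams(layers, self.head_w.copy(), self.head_bias)
        return out


@dataclass
class ClassicalModelConfig:
    layer_sequence: tuple = ("ggnn", "ggnn", "ggnn")
    aggregation: str = "add"
    encoding: EncodingSpec = field(default_factory=lambda: EncodingSpec("an_nh"))

    def __post_init__(self):
        self.layer_sequence = tuple(s.lower() for s in self.layer_sequence)
        if any(s not in ("ggnn", "gcn") for s in self.layer_sequence):
            raise ClassicalModelError(f"bad layer sequence {self.layer_sequence}")
        if self.aggregation not in AGGREGATIONS:
            raise ClassicalModelError(f"unknown aggregation {self.aggregation!r}")
        if self.encoding.is_net:
            raise ClassicalModelError("classical models use fixed encodings only")


def init_classical_params(
    config: ClassicalModelConfig, rng: np.random.Generator
) -> ClassicalParams:
    """Seeded Glorot-uniform weights, zero biases."""

    def glorot(shape):
        limit = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-limit, limit, size=shape)

    layers = []
    for kind in config.layer_sequence:
        if kind == "ggnn":
            layers.append(
                GGNNLayerParams(
                    phi=glorot((2, 2)),
                    w1=glorot((2, 4)),
                    b1=np.zeros(2),
                    w2=glorot((4, 2)),
                    b2=np.zeros(4),
                )
            )
        else:
            layers.append(GCNLayerParams(w=glorot((2, 2))))
    return ClassicalParams(layers, glorot((1, 2))[0], 0.0)


def count_classical_parameters(config: ClassicalModelConfig) -> int:
    count = 3  # head
    for kind in config.layer_sequence:
        count += 4 + 8 + 2 + 8 + 4 if kind == "ggnn" else 4
    return count


# ---------------------------------------------------------------------------
# Layers


def _bond_one_hot(bond_type: str) -> np.ndarray:
    if bond_type not in CHEMICAL_BOND_TYPES:
        raise ClassicalModelError(
            f"bond type {bond_type!r} not supported by classical models"
        )
    e = np.zeros(4)
    e[CHEMICAL_BOND_TYPES.index(bond_type)] = 1.0
    return e


def edge_network(bond_type: str, lp: GGNNLayerParams) -> np.ndarray:
    """2x2 message matrix for one bond type (ReLU hidden, linear output,
    row-major reshape)."""
    e = _bond_one_hot(bond_type)
    h = np.maximum(lp.w1 @ e + lp.b1, 0.0)
    return (lp.w2 @ h + lp.b2).reshape(2, 2)


def _check_no_master(g: MolecularGraph) -> None:
    if g.has_master:
        raise ClassicalModelError("classical models take graphs without a master node")


def ggnn_layer(
    x: np.ndarray, g: MolecularGraph, lp: GGNNLayerParams, aggregation: str
) -> np.ndarray:
    _check_no_master(g)
    x = np.asarray(x, dtype=float)
    out = x @ lp.phi.T
    for i in range(g.n_nodes):
        msgs = [
            edge_network(bt, lp) @ x[j]
            for j, bt in _neighbors_with_types(g, i)
        ]
        if not msgs:
            continue  # empty neighborhood contributes zero for every aggr
        m = np.stack(msgs)
        if aggregation == "add":
            out[i] += m.sum(axis=0)
        elif aggregation == "mean":
            out[i] += m.mean(axis=0)
        else:
            out[i] += m.max(axis=0)
    return out


def _neighbors_with_types(g: MolecularGraph, i: int):
    for b in g.bonds:
        if b.i == i:
            yield b.j, b.bond_type
        elif b.j == i:
            yield b.i, b.bond_type


def gcn_propagation_matrix(g: MolecularGraph) -> np.ndarray:
    """D^{-1/2} (A + I) D^{-1/2} with bond-order adjacency weights."""
    _check_no_master(g)
    n = g.n_nodes
    a = np.eye(n)
    for b in g.bonds:
        w = GCN_BOND_WEIGHT[b.bond_type]
        a[b.i, b.j] = w
        a[b.j, b.i] = w
    d_inv_sqrt = 1.0 / np.sqrt(a.sum(axis=1))
    return a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_layer(x: np.ndarray, g: MolecularGraph, lp: GCNLayerParams) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.maximum(gcn_propagation_matrix(g) @ x @ lp.w.T, 0.0)


def initial_features(g: MolecularGraph, spec: EncodingSpec) -> np.ndarray:
    """|V| x 2 matrix of the two fixed-encoding angles per atom."""
    _check_no_master(g)
    return np.array([fixed_angles(a, spec.method) for a in g.nodes], dtype=float)


def classical_forward(
    g: MolecularGraph, config: ClassicalModelConfig, params: ClassicalParams
) -> float:
    x = initial_features(g, config.encoding)
    for kind, lp in zip(config.layer_sequence, params.layers):
        if kind == "ggnn":
            x = ggnn_layer(x, g, lp, config.aggregation)
        else:
            x = gcn_layer(x, g, lp)
    mean = x.mean(axis=0)
    return float(params.head_w @ mean + params.head_bias)


# ---------------------------------------------------------------------------
# Analytic gradients (manual reverse mode)


def classical_forward_with_grad(
    g: MolecularGraph, config: ClassicalModelConfig, params: ClassicalParams
):
    """Prediction and d(prediction)/d(weight) for every trainable scalar,
    keyed like :meth:`ClassicalParams.as_arrays`."""
    _check_no_master(g)
    n = g.n_nodes
    x = initial_features(g, config.encoding)
    caches = []
    for kind, lp in zip(config.layer_sequence, params.layers):
        if kind == "ggnn":
            # forward, recording per-node messages and (for max) the argmax
            mats = {bt: edge_network(bt, lp) for bt in CHEMICAL_BOND_TYPES}
            neigh = [list(_neighbors_with_types(g, i)) for i in range(n)]
            msgs = [
                [mats[bt] @ x[j] for j, bt in neigh[i]] for i in range(n)
            ]
            out = x @ lp.phi.T
            argmax = [None] * n
            for i in range(n):
                if not msgs[i]:
                    continue
                m = np.stack(msgs[i])
                if config.aggregation == "add":
                    out[i] += m.sum(axis=0)
                elif config.aggregation == "mean":
                    out[i] += m.mean(axis=0)
                else:
                    argmax[i] = m.argmax(axis=0)
                    out[i] += m.max(axis=0)
            caches.append(("ggnn", lp, x, neigh, msgs, argmax))
            x = out
        else:
            p = gcn_propagation_matrix(g)
            pre = p @ x @ lp.w.T
            caches.append(("gcn", lp, x, p, pre))
            x = np.maximum(pre, 0.0)

    mean = x.mean(axis=0)
    pred = float(params.head_w @ mean + params.head_bias)

    grads = {name: np.zeros_like(arr) for name, arr in params.as_arrays().items()}
    grads["head_w"][:] = mean
    grads["head_b"][0] = 1.0
    dx = np.tile(params.head_w / n, (n, 1))  # d pred / d x_final

    for li in range(len(caches) - 1, -1, -1):
        cache = caches[li]
        if cache[0] == "gcn":
            _, lp, x_in, p, pre = cache
            dpre = dx * (pre > 0)
            grads[f"l{li}_w"] += dpre.T @ (p @ x_in)
            dx = p.T @ dpre @ lp.w
        else:
            _, lp, x_in, neigh, msgs, argmax = cache
            grads[f"l{li}_phi"] += dx.T @ x_in
            dx_in = dx @ lp.phi
            # accumulate loss gradient per message matrix entry, per bond type
            dmat = {bt: np.zeros((2, 2)) for bt in CHEMICAL_BOND_TYPES}
            mats = {bt: edge_network(bt, lp) for bt in CHEMICAL_BOND_TYPES}
            for i in range(n):
                if not neigh[i]:
                    continue
                k = len(neigh[i])
                for mi, (j, bt) in enumerate(neigh[i]):
                    if config.aggregation == "add":
                        dmsg = dx[i]
                    elif config.aggregation == "mean":
                        dmsg = dx[i] / k
                    else:
                        dmsg = dx[i] * (argmax[i] == mi)
                    dmat[bt] += np.outer(dmsg, x_in[j])
                    dx_in[j] += mats[bt].T @ dmsg
            # push message-matrix gradients through the edge network
            for bt, dm in dmat.items():
                e = _bond_one_hot(bt)
                h_pre = lp.w1 @ e + lp.b1
                h = np.maximum(h_pre, 0.0)
                dflat = dm.reshape(4)
                grads[f"l{li}_w2"] += np.outer(dflat, h)
                grads[f"l{li}_b2"] += dflat
                dh = lp.w2.T @ dflat
                dh_pre = dh * (h_pre > 0)
                grads[f"l{li}_w1"] += np.outer(dh_pre, e)
                grads[f"l{li}_b1"] += dh_pre
            dx = dx_in
    return pred, grads


# ---------------------------------------------------------------------------
# Checkpoint I/O (mirrors the quantum checkpoint layout)


def save_checkpoint(path, config: ClassicalModelConfig, params: ClassicalParams) -> None:
    doc = {
        "kind": "classical",
        "model": {
            "architecture": ",".join(config.layer_sequence),
            "aggregation": config.aggregation,
            "encoding": config.encoding.method,
        },
        "params": {name: np.asarray(arr).tolist() for name, arr in params.as_arrays().items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def load_checkpoint(path):
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    m = doc["model"]
    config = ClassicalModelConfig(
        layer_sequence=tuple(m["architecture"].split(",")),
        aggregation=m["aggregation"],
        encoding=EncodingSpec(m["encoding"]),
    )
    raw = {name: np.asarray(arr, dtype=float) for name, arr in doc["params"].items()}
    layers = []
    for i, kind in enumerate(config.layer_sequence):
        if kind == "ggnn":
            layers.append(
                GGNNLayerParams(
                    raw[f"l{i}_phi"], raw[f"l{i}_w1"], raw[f"l{i}_b1"],
                    raw[f"l{i}_w2"], raw[f"l{i}_b2"],
                )
            )
        else:
            layers.append(GCNLayerParams(raw[f"l{i}_w"]))
    params = ClassicalParams(layers, raw["head_w"], float(raw["head_b"][0]))
    return config, params
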