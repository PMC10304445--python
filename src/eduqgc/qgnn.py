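"""The EDU-QGC quantum graph model.

The circuit alternates *node layers* and *link layers* on a register with
one qubit per graph node:

* A node layer applies the same single-qubit unitary to every atom qubit
  (an arbitrary ZYZ unitary with 3 angles for the ``default`` variant, a
  single RY for ``simple``); a master qubit, if present, gets its own
  per-layer angles.
* A link layer applies an equivariantly diagonalizable unitary (EDU)

      EDU = (V* (x) V*) D (V (x) V)

  to every bonded qubit pair, where V is node-local (U3 or RY, sharing the
  angles of the bond's type across all layers) and D = RZZ with one angle
  per layer shared by every EDU in that layer.  Because EDUs of equal
  parameters commute and commute with qubit swaps, applying all EDUs of one
  bond type as a block keeps the circuit node-permutation equivariant; the
  blocks follow the fixed order single, aromatic, double, triple, master.

The readout is a permutation-invariant measurement: the trainable affine
combination r0 + (r1/|V|) * sum_v <Z_v> (``local``), optionally plus
r2 * <(x)_v Z_v> (``global``).  Combined with an optional re-uploading of
the encoding after every layer, the forward pass maps a molecular graph to
a scalar prediction in Hartree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import json

import numpy as np

from . import qsim
from .encoding import AngleExtractionNet, EncodingSpec, MASTER_RY_ANGLE, node_angles
from .molgraph import BOND_TYPES, MolecularGraph

EDU_VARIANTS = ("default", "simple")
READOUTS = ("local", "global")


class ModelError(ValueError):
    pass


@dataclass
class ModelConfig:
    n_layers: int = 3
    edu_variant: str = "default"
    readout: str = "local"
    re_uploading: bool = False
    master_node: bool = False
    encoding: EncodingSpec = field(default_factory=lambda: EncodingSpec("an_nh"))

    def __post_init__(self):
        if self.n_layers < 1:
            raise ModelError("n_layers must be >= 1")
        if self.edu_variant not in EDU_VARIANTS:
            raise ModelError(f"unknown EDU variant {self.edu_variant!r}")
        if self.readout not in READOUTS:
            raise ModelError(f"unknown readout {self.readout!r}")

    @property
    def angles_per_unitary(self) -> int:
        return 3 if self.edu_variant == "default" else 1

    @property
    def n_bond_types(self) -> int:
        return 5 if self.master_node else 4


@dataclass
class QGNNParams:
    """All trainable variables of the quantum model.

    Shapes (L layers, k = 3 for the default variant or 1 for simple,
    T = 4 bond types, or 5 with a master node):
    ``node_angles`` (L, k), ``d_angles`` (L,), ``v_angles`` (T, k),
    ``r`` (2 for local readout, 3 for global), ``master_angles`` (L, k) when
    a master node is used, and ``enc_net`` for the hybrid encodings.
    """

    node_angles: np.ndarray
    d_angles: np.ndarray
    v_angles: np.ndarray
    r: np.ndarray
    master_angles: Optional[np.ndarray] = None
    enc_net: Optional[AngleExtractionNet] = None

    def copy(self) -> "QGNNParams":
        net = self.enc_net
        return QGNNParams(
            node_angles=self.node_angles.copy(),
            d_angles=self.d_angles.copy(),
            v_angles=self.v_angles.copy(),
            r=self.r.copy(),
            master_angles=None if self.master_angles is None else self.master_angles.copy(),
            enc_net=None
            if net is None
            else AngleExtractionNet(net.w1.copy(), net.b1.copy(), net.w2.copy(), net.b2.copy()),
        )

    def as_arrays(self) -> dict:
        """Name -> array views over every trainable tensor (shared memory)."""
        out = {
            "node_angles": self.node_angles,
            "d_angles": self.d_angles,
            "v_angles": self.v_angles,
            "r": self.r,
        }
        if self.master_angles is not None:
            out["master_angles"] = self.master_angles
        if self.enc_net is not None:
            out["enc_w1"] = self.enc_net.w1
            out["enc_b1"] = self.enc_net.b1
            out["enc_w2"] = self.enc_net.w2
            out["enc_b2"] = self.enc_net.b2
        return out


def init_params(config: ModelConfig) -> QGNNParams:
    """Initial weights: every quantum angle and readout coefficient is 1;
    the hybrid encoding net starts from the net stored in the config."""
    L, k = config.n_layers, config.angles_per_unitary
    net = None
    if config.encoding.is_net:
        src = config.encoding.net
        net = AngleExtractionNet(src.w1.copy(), src.b1.copy(), src.w2.copy(), src.b2.copy())
    return QGNNParams(
        node_angles=np.ones((L, k)),
        d_angles=np.ones(L),
        v_angles=np.ones((config.n_bond_types, k)),
        r=np.ones(2 if config.readout == "local" else 3),
        master_angles=np.ones((L, k)) if config.master_node else None,
        enc_net=net,
    )


def random_params(config: ModelConfig, rng: np.random.Generator) -> QGNNParams:
    """Random draw used e.g. for frozen teacher models: angles uniform in
    (-pi, pi); readout offset near a plausible HOMO-LUMO gap (~0.25 Ha) and
    small slopes so predictions stay in a realistic energy range."""
    p = init_params(config)
    p.node_angles = rng.uniform(-np.pi, np.pi, p.node_angles.shape)
    p.d_angles = rng.uniform(-np.pi, np.pi, p.d_angles.shape)
    p.v_angles = rng.uniform(-np.pi, np.pi, p.v_angles.shape)
    if p.master_angles is not None:
        p.master_angles = rng.uniform(-np.pi, np.pi, p.master_angles.shape)
    p.r = np.concatenate(
        [rng.uniform(0.2, 0.3, 1), rng.uniform(-0.15, 0.15, p.r.size - 1)]
    )
    if p.enc_net is not None:
        p.enc_net = AngleExtractionNet.glorot(p.enc_net.input_dim, rng)
    return p


def check_params(config: ModelConfig, params: QGNNParams) -> None:
    L, k = config.n_layers, config.angles_per_unitary
    if params.node_angles.shape != (L, k):
        raise ModelError(f"node_angles shape {params.node_angles.shape} != {(L, k)}")
    if params.d_angles.shape != (L,):
        raise ModelError(f"d_angles shape {params.d_angles.shape} != {(L,)}")
    if params.v_angles.shape != (config.n_bond_types, k):
        raise ModelError(
            f"v_angles shape {params.v_angles.shape} != {(config.n_bond_types, k)}"
        )
    want_r = 2 if config.readout == "local" else 3
    if params.r.shape != (want_r,):
        raise ModelError(f"r shape {params.r.shape} != {(want_r,)}")
    if config.master_node and (
        params.master_angles is None or params.master_angles.shape != (L, k)
    ):
        raise ModelError("master_angles missing or mis-shaped for a master-node model")
    if config.encoding.is_net and params.enc_net is None:
        raise ModelError("enc_net missing for a network-encoding model")


# ---------------------------------------------------------------------------
# Circuit construction.  Ops carry a provenance reference so the
# parameter-shift rule can differentiate each gate occurrence.


@dataclass(frozen=True)
class _Op:
    kind: str  # RY | RZ | RZZ
    qubits: tuple
    angle: float
    ref: Optional[tuple] = None  # trainable-scalar key, or None for constants
    coeff: float = 1.0  # angle = coeff * scalar(ref)


def _single_unitary_ops(q, angles, refbase, variant, coeff=1.0, dagger=False):
    """Gate sequence of V (U3 = RZ(a) RY(b) RZ(c), RZ(c) first) or RY on one
    qubit, or its inverse when ``dagger``."""
    if variant == "simple":
        (b,) = angles
        sign = -1.0 if dagger else 1.0
        return [_Op("RY", (q,), sign * b, refbase + (0,), sign * coeff)]
    a, b, c = angles
    if dagger:
        return [
            _Op("RZ", (q,), -a, refbase + (0,), -coeff),
            _Op("RY", (q,), -b, refbase + (1,), -coeff),
            _Op("RZ", (q,), -c, refbase + (2,), -coeff),
        ]
    return [
        _Op("RZ", (q,), c, refbase + (2,), coeff),
        _Op("RY", (q,), b, refbase + (1,), coeff),
        _Op("RZ", (q,), a, refbase + (0,), coeff),
    ]


def _bonds_by_type(g: MolecularGraph):
    """Bonds grouped in the enforced type order; within a block the
    (min, max)-lexicographic order is fixed for reproducibility (EDUs of one
    block commute, so this is presentation only)."""
    for t_idx, t in enumerate(BOND_TYPES):
        block = sorted((b for b in g.bonds if b.bond_type == t), key=lambda b: b.key())
        if block:
            yield t_idx, block


def _encoding_ops(g, config, params) -> list:
    spec = config.encoding
    if spec.is_net and params is not None and params.enc_net is not None:
        spec = EncodingSpec(spec.method, params.enc_net)
    trainable = spec.is_net
    ops = []
    for q, ang in enumerate(node_angles(g, spec)):
        if ang is None:
            ops.append(_Op("RY", (q,), MASTER_RY_ANGLE))
        else:
            ry, rz = ang
            ops.append(_Op("RY", (q,), ry, ("enc_ry", q) if trainable else None))
            ops.append(_Op("RZ", (q,), rz, ("enc_rz", q) if trainable else None))
    return ops


def _node_layer_ops(g, config, params, layer) -> list:
    ops = []
    variant = config.edu_variant
    for q, atom in enumerate(g.nodes):
        if atom.is_master:
            if params.master_angles is None:
                raise ModelError("graph has a master node but params lack master_angles")
            ops += _single_unitary_ops(
                q, params.master_angles[layer], ("master", layer), variant
            )
        else:
            ops += _single_unitary_ops(
                q, params.node_angles[layer], ("node", layer), variant
            )
    return ops


def _link_layer_ops(g, config, params, layer) -> list:
    ops = []
    variant = config.edu_variant
    d = params.d_angles[layer]
    for t_idx, block in _bonds_by_type(g):
        if t_idx >= params.v_angles.shape[0]:
            raise ModelError(f"bond type {BOND_TYPES[t_idx]!r} has no v_angles row")
        v = params.v_angles[t_idx]
        for b in block:
            i, j = b.key()
            ops += _single_unitary_ops(i, v, ("v", t_idx), variant)
            ops += _single_unitary_ops(j, v, ("v", t_idx), variant)
            ops.append(_Op("RZZ", (i, j), d, ("d", layer)))
            ops += _single_unitary_ops(i, v, ("v", t_idx), variant, dagger=True)
            ops += _single_unitary_ops(j, v, ("v", t_idx), variant, dagger=True)
    return ops


def build_circuit(g: MolecularGraph, config: ModelConfig, params: QGNNParams) -> list:
    """The full op list: encode, then [node layer, link layer, (re-upload)]
    repeated ``n_layers`` times."""
    check_params(config, params)
    if config.master_node and not g.has_master:
        raise ModelError(f"graph {g.id or '<unnamed>'} lacks the required master node")
    ops = _encoding_ops(g, config, params)
    for layer in range(config.n_layers):
        ops += _node_layer_ops(g, config, params, layer)
        ops += _link_layer_ops(g, config, params, layer)
        if config.re_uploading:
            ops += _encoding_ops(g, config, params)
    return ops


def _run(ops, n_qubits: int) -> qsim.StateVector:
    state = qsim.init_state(n_qubits)
    for op in ops:
        state = qsim.apply_gate(state, qsim.GateSpec(op.kind, op.qubits, (op.angle,)))
    return state


def apply_node_layer(state, g, config, params, layer):
    for op in _node_layer_ops(g, config, params, layer):
        state = qsim.apply_gate(state, qsim.GateSpec(op.kind, op.qubits, (op.angle,)))
    return state


def apply_link_layer(state, g, config, params, layer):
    for op in _link_layer_ops(g, config, params, layer):
        state = qsim.apply_gate(state, qsim.GateSpec(op.kind, op.qubits, (op.angle,)))
    return state


# ---------------------------------------------------------------------------
# EDU matrix and readout


def edu_matrix(v_angles, d_angle: float, variant: str) -> np.ndarray:
    """Explicit 4x4 EDU: (V* (x) V*) RZZ(d) (V (x) V)."""
    v_angles = np.atleast_1d(np.asarray(v_angles, dtype=float))
    if variant == "default":
        if v_angles.shape != (3,):
            raise ModelError("default variant needs 3 node-local angles")
        V = qsim.u3_matrix(*v_angles)
    elif variant == "simple":
        if v_angles.shape != (1,):
            raise ModelError("simple variant needs 1 node-local angle")
        V = qsim.ry_matrix(v_angles[0])
    else:
        raise ModelError(f"unknown EDU variant {variant!r}")
    VV = np.kron(V, V)
    return VV.conj().T @ qsim.rzz_matrix(d_angle) @ VV


def readout(state: qsim.StateVector, params_r: np.ndarray, mode: str) -> float:
    """Permutation-invariant readout over ALL qubits (master included)."""
    n = state.n_qubits
    mean_z = sum(qsim.expval_z(state, q) for q in range(n)) / n
    value = params_r[0] + params_r[1] * mean_z
    if mode == "global":
        value += params_r[2] * qsim.expval_z_all(state)
    return float(value)


def forward(g: MolecularGraph, config: ModelConfig, params: QGNNParams) -> float:
    """Scalar prediction in Hartree for one molecular graph."""
    ops = build_circuit(g, config, params)
    state = _run(ops, g.n_nodes)
    return readout(state, params.r, config.readout)


# ---------------------------------------------------------------------------
# Gradients: parameter-shift per gate occurrence, with prefix-state caching.
# Every gate is exp(-i * angle * P / 2) for a Pauli word P, so
# d pred / d angle = (pred(angle + pi/2) - pred(angle - pi/2)) / 2 holds
# exactly; a shared scalar's gradient is the coefficient-weighted sum over
# its gate occurrences.


def forward_with_grad(g: MolecularGraph, config: ModelConfig, params: QGNNParams):
    """Prediction and d(prediction)/d(theta) for every trainable scalar.

    Returns ``(pred, grads)`` where ``grads`` maps the array names of
    :meth:`QGNNParams.as_arrays` to same-shaped gradient arrays.
    """
    enc_caches = None
    if config.encoding.is_net:
        # recompute the per-node angles keeping the net intermediates so the
        # chain rule can push circuit gradients into the net weights
        enc_caches = {}
        from .encoding import one_hot

        for q, atom in enumerate(g.nodes):
            if not atom.is_master:
                x = one_hot(atom, config.encoding.method)
                _, cache = params.enc_net.forward_with_cache(x)
                enc_caches[q] = cache

    ops = build_circuit(g, config, params)
    n = g.n_nodes

    # prefix[k] = state before op k
    prefix = [qsim.init_state(n)]
    for op in ops:
        prefix.append(
            qsim.apply_gate(prefix[-1], qsim.GateSpec(op.kind, op.qubits, (op.angle,)))
        )
    final = prefix[-1]
    pred = readout(final, params.r, config.readout)

    # readout coefficients: analytic
    mean_z = sum(qsim.expval_z(final, q) for q in range(n)) / n
    grads = {name: np.zeros_like(arr) for name, arr in params.as_arrays().items()}
    grads["r"][0] = 1.0
    grads["r"][1] = mean_z
    if config.readout == "global":
        grads["r"][2] = qsim.expval_z_all(final)

    # circuit angles: shift each occurrence, resuming from its prefix state
    angle_grads = {}  # ref -> d pred / d scalar
    for k, op in enumerate(ops):
        if op.ref is None:
            continue
        shifted = []
        for delta in (np.pi / 2, -np.pi / 2):
            state = qsim.apply_gate(
                prefix[k], qsim.GateSpec(op.kind, op.qubits, (op.angle + delta,))
            )
            for later in ops[k + 1 :]:
                state = qsim.apply_gate(
                    state, qsim.GateSpec(later.kind, later.qubits, (later.angle,))
                )
            shifted.append(readout(state, params.r, config.readout))
        d_occurrence = 0.5 * (shifted[0] - shifted[1])
        angle_grads[op.ref] = angle_grads.get(op.ref, 0.0) + op.coeff * d_occurrence

    ref_to_array = {
        "node": "node_angles",
        "master": "master_angles",
        "v": "v_angles",
    }
    for ref, val in angle_grads.items():
        tag = ref[0]
        if tag == "d":
            grads["d_angles"][ref[1]] += val
        elif tag in ref_to_array:
            grads[ref_to_array[tag]][ref[1], ref[2]] += val
        elif tag in ("enc_ry", "enc_rz"):
            q = ref[1]
            d_angles = np.array(
                [val if tag == "enc_ry" else 0.0, val if tag == "enc_rz" else 0.0]
            )
            net_grads = params.enc_net.backward(enc_caches[q], d_angles)
            for wname, garr in net_grads.items():
                grads[f"enc_{wname}"] += garr
        else:  # pragma: no cover - construction guarantees known tags
            raise ModelError(f"unknown gradient tag {tag!r}")
    return pred, grads


# ---------------------------------------------------------------------------
# Structural accounting


def count_trainable_parameters(config: ModelConfig) -> int:
    """Exact number of trainable scalars implied by the configuration."""
    from .encoding import net_input_dim

    L, k = config.n_layers, config.angles_per_unitary
    count = L * k  # node layers
    if config.master_node:
        count += L * k
    count += L  # diagonal angle per layer
    count += config.n_bond_types * k  # EDU node-local angles per bond type
    count += 2 if config.readout == "local" else 3
    if config.encoding.is_net:
        d = net_input_dim(config.encoding.method)
        count += 4 * d + 4 + 8 + 2
    return count


def count_single_qubit_gate_layers(config: ModelConfig, n_bond_types_present: int) -> int:
    """Sequential single-qubit gate layers under a fixed counting convention:
    each encoding application contributes 2 (RY, RZ; never merged into
    neighbouring blocks); a node layer contributes 3 (default) or 1 (simple);
    each EDU block contributes twice the gate count of V; adjacent RZ layers
    of consecutive EDU blocks merge into one."""
    gates_in_v = 3 if config.edu_variant == "default" else 1
    enc_applications = 1 + (config.n_layers if config.re_uploading else 0)
    total = 2 * enc_applications
    b = n_bond_types_present
    per_link_layer = b * 2 * gates_in_v
    if config.edu_variant == "default" and b >= 1:
        per_link_layer -= b - 1  # V ends / V* starts with an RZ layer
    total += config.n_layers * (config.angles_per_unitary + per_link_layer)
    return total


# ---------------------------------------------------------------------------
# Link-layer scheduling (parallel EDU rounds via exact edge coloring)


def _min_edge_coloring(edges) -> list:
    """Exact minimum proper edge coloring by backtracking; returns a list of
    color classes.  Chromatic index is Delta or Delta+1 (Vizing), so at most
    two values of k are tried.  Intended for molecule-scale blocks."""
    if not edges:
        return []
    degree = {}
    for (u, v) in edges:
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1
    delta = max(degree.values())
    # order edges by degree sum: constrains the search early
    order = sorted(edges, key=lambda e: -(degree[e[0]] + degree[e[1]]))

    def try_k(k):
        colors = {}

        def feasible(e, c):
            u, v = e
            for e2, c2 in colors.items():
                if c2 == c and (u in e2 or v in e2):
                    return False
            return True

        def rec(idx):
            if idx == len(order):
                return True
            e = order[idx]
            # symmetry break: first edge only tries color 0
            limit = 1 if idx == 0 else k
            for c in range(limit):
                if feasible(e, c):
                    colors[e] = c
                    if rec(idx + 1):
                        return True
                    del colors[e]
            return False

        return colors if rec(0) else None

    for k in (delta, delta + 1):
        colors = try_k(k)
        if colors is not None:
            classes = [[] for _ in range(max(colors.values()) + 1)]
            for e, c in colors.items():
                classes[c].append(e)
            return [cls for cls in classes if cls]
    raise AssertionError("edge coloring exceeded Vizing bound")  # pragma: no cover


def schedule_link_layer(g: MolecularGraph) -> list:
    """Rounds of simultaneously applicable EDUs.

    Each round is a list of bonds of one type sharing no endpoint; rounds of
    one bond-type block are contiguous and the blocks follow the enforced
    type order, so executing rounds sequentially reproduces the link layer.
    """
    rounds = []
    for t_idx, block in _bonds_by_type(g):
        key_to_bond = {b.key(): b for b in block}
        for color_class in _min_edge_coloring(list(key_to_bond)):
            rounds.append(sorted((key_to_bond[e] for e in color_class), key=lambda b: b.key()))
    return rounds


def apply_link_layer_scheduled(state, g, config, params, layer):
    """Link layer executed round by round (same result as sequential)."""
    variant = config.edu_variant
    t_index = {t: i for i, t in enumerate(BOND_TYPES)}
    for rnd in schedule_link_layer(g):
        for b in rnd:
            i, j = b.key()
            mat = edu_matrix(
                params.v_angles[t_index[b.bond_type]], params.d_angles[layer], variant
            )
            state = qsim._apply_2q(state, mat, i, j)
    return state


# ---------------------------------------------------------------------------
# Checkpoint I/O (flat key -> array JSON with the config embedded)


def save_checkpoint(path, config: ModelConfig, params: QGNNParams) -> None:
    doc = {
        "kind": "quantum",
        "model": {
            "layers": config.n_layers,
            "edu_variant": config.edu_variant,
            "readout": config.readout,
            "re_uploading": config.re_uploading,
            "master_node": config.master_node,
            "encoding": config.encoding.method,
        },
        "params": {name: arr.tolist() for name, arr in params.as_arrays().items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def load_checkpoint(path):
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    m = doc["model"]
    raw = {name: np.asarray(arr, dtype=float) for name, arr in doc["params"].items()}
    net = None
    if m["encoding"].startswith("net_"):
        net = AngleExtractionNet(raw["enc_w1"], raw["enc_b1"], raw["enc_w2"], raw["enc_b2"])
    config = ModelConfig(
        n_layers=int(m["layers"]),
        edu_variant=m["edu_variant"],
        readout=m["readout"],
        re_uploading=bool(m["re_uploading"]),
        master_node=bool(m["master_node"]),
        encoding=EncodingSpec(m["encoding"], net),
    )
    params = QGNNParams(
        node_angles=raw["node_angles"],
        d_angles=raw["d_angles"],
        v_angles=raw["v_angles"],
        r=raw["r"],
        master_angles=raw.get("master_angles"),
        enc_net=net,
    )
    check_params(config, params)
    return config, params
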