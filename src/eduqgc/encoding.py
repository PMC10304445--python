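"""Atom-feature quantum encodings.

Each heavy atom is assigned one qubit and its initial state is prepared by
an RY rotation followed by an RZ rotation.  The two angles come either from
one of three fixed schemes or from a small trainable "angle extraction"
network applied to a one-hot feature vector:

* ``an`` — atomic number only.  The four element states (C, N, O, F) are
  placed at the vertices of a tetrahedron inscribed in the Bloch sphere
  (maximally spread: pairwise Bloch-vector inner products of -1/3), reading
  the RY angle as the polar and the RZ angle as the azimuthal Bloch angle.
* ``an_nh`` — atomic number drives RY via (2z-7)*pi/4 and the bonded
  hydrogen count drives RZ via 2*pi*nh/5; both sets of angles are evenly
  spaced in [0, 2*pi].
* ``an_arom_hyb`` — same RY; RZ combines aromaticity a in {0,1} and
  hybridization h in {1,2,3} (sp, sp2, sp3) as (-1)^a * (2h-1) * pi/6.
* ``net_an_nh`` / ``net_an_arom_hyb`` — the corresponding features, one-hot
  encoded, pass through a fully connected net (hidden width 4, ReLU; output
  width 2, 2*pi*sigmoid) whose outputs are the RY and RZ angles.  The same
  network is shared by every node so permutation equivariance is preserved.

A master node, when present, is prepared in the fixed |+> state (a single
RY(pi/2)), distinct from every atom state above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import qsim
from .molgraph import AtomNode, MolecularGraph, ELEMENTS, HYBRIDIZATIONS

FIXED_METHODS = ("an", "an_nh", "an_arom_hyb")
NET_METHODS = ("net_an_nh", "net_an_arom_hyb")
METHODS = FIXED_METHODS + NET_METHODS

MASTER_RY_ANGLE = np.pi / 2  # master qubit state |+>

_TETRA_POLAR = np.arccos(-1.0 / 3.0)
# element -> (polar, azimuth) tetrahedron vertices, order C, N, O, F
_AN_ANGLES = {
    6: (0.0, 0.0),
    7: (_TETRA_POLAR, 0.0),
    8: (_TETRA_POLAR, 2 * np.pi / 3),
    9: (_TETRA_POLAR, -2 * np.pi / 3),
}

_HYB_LEVEL = {"sp": 1, "sp2": 2, "sp3": 3}


class EncodingError(ValueError):
    pass


@dataclass
class AngleExtractionNet:
    """Fully connected 1-hidden-layer net: input -> 4 (ReLU) -> 2
    (2*pi*sigmoid).  Output components are the (RY, RZ) angles in (0, 2*pi).
    """

    w1: np.ndarray  # (4, input_dim)
    b1: np.ndarray  # (4,)
    w2: np.ndarray  # (2, 4)
    b2: np.ndarray  # (2,)

    @property
    def input_dim(self) -> int:
        return self.w1.shape[1]

    @classmethod
    def zeros(cls, input_dim: int) -> "AngleExtractionNet":
        return cls(np.zeros((4, input_dim)), np.zeros(4), np.zeros((2, 4)), np.zeros(2))

    @classmethod
    def glorot(cls, input_dim: int, rng: np.random.Generator) -> "AngleExtractionNet":
        def glorot(shape):
            limit = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-limit, limit, size=shape)

        return cls(glorot((4, input_dim)), np.zeros(4), glorot((2, 4)), np.zeros(2))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.input_dim:
            raise EncodingError(
                f"input dim {x.shape[-1]} != net input dim {self.input_dim}"
            )
        h = np.maximum(self.w1 @ x + self.b1, 0.0)
        return 2 * np.pi * _sigmoid(self.w2 @ h + self.b2)

    def forward_with_cache(self, x: np.ndarray):
        """Forward pass retaining intermediates for backpropagation."""
        pre = self.w1 @ x + self.b1
        h = np.maximum(pre, 0.0)
        u = self.w2 @ h + self.b2
        s = _sigmoid(u)
        return 2 * np.pi * s, (x, pre, h, s)

    def backward(self, cache, d_angles: np.ndarray) -> dict:
        """Gradients of a scalar loss wrt the net weights, given the loss
        gradient wrt the two output angles."""
        x, pre, h, s = cache
        du = d_angles * 2 * np.pi * s * (1.0 - s)
        dw2 = np.outer(du, h)
        db2 = du
        dh = self.w2.T @ du
        dpre = dh * (pre > 0)
        dw1 = np.outer(dpre, x)
        db1 = dpre
        return {"w1": dw1, "b1": db1, "w2": dw2, "b2": db2}


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class EncodingSpec:
    method: str
    net: Optional[AngleExtractionNet] = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise EncodingError(f"unknown encoding method {self.method!r}")
        if self.is_net and self.net is None:
            raise EncodingError(f"method {self.method!r} requires a net")
        if not self.is_net and self.net is not None:
            raise EncodingError(f"fixed method {self.method!r} must not carry a net")
        if self.is_net and self.net.input_dim != net_input_dim(self.method):
            raise EncodingError(
                f"net input dim {self.net.input_dim} != "
                f"{net_input_dim(self.method)} required by {self.method!r}"
            )

    @property
    def is_net(self) -> bool:
        return self.method in NET_METHODS


def net_input_dim(method: str) -> int:
    if method == "net_an_nh":
        return 9  # 4 (element) + 5 (hydrogen count)
    if method == "net_an_arom_hyb":
        return 8  # 4 (element) + 1 (aromatic flag) + 3 (hybridization)
    raise EncodingError(f"{method!r} is not a network encoding method")


def fixed_angles(a: AtomNode, method: str) -> tuple:
    """The (RY, RZ) angle pair of a fixed encoding scheme for one atom."""
    if a.is_master:
        raise EncodingError("master node has no feature encoding")
    if method == "an":
        return _AN_ANGLES[a.atomic_number]
    theta_ry = (2 * a.atomic_number - 7) * np.pi / 4
    if method == "an_nh":
        return theta_ry, 2 * np.pi * a.n_hydrogens / 5
    if method == "an_arom_hyb":
        h = _HYB_LEVEL[a.hybridization]
        sign = -1.0 if a.aromatic else 1.0
        return theta_ry, sign * (2 * h - 1) * np.pi / 6
    raise EncodingError(f"{method!r} is not a fixed encoding method")


def one_hot(a: AtomNode, method: str) -> np.ndarray:
    """One-hot feature vector consumed by the angle extraction network."""
    if a.is_master:
        raise EncodingError("master node has no feature encoding")
    z_vec = np.zeros(4)
    z_vec[ELEMENTS.index(a.atomic_number)] = 1.0
    if method == "net_an_nh":
        nh_vec = np.zeros(5)
        nh_vec[a.n_hydrogens] = 1.0
        return np.concatenate([z_vec, nh_vec])
    if method == "net_an_arom_hyb":
        hyb_vec = np.zeros(3)
        hyb_vec[HYBRIDIZATIONS.index(a.hybridization)] = 1.0
        return np.concatenate([z_vec, [float(a.aromatic)], hyb_vec])
    raise EncodingError(f"{method!r} is not a network encoding method")


def extract_angles(net: AngleExtractionNet, a: AtomNode, method: str) -> tuple:
    """(RY, RZ) angles produced by the shared angle extraction network."""
    out = net.forward(one_hot(a, method))
    return float(out[0]), float(out[1])


def count_net_parameters(net: AngleExtractionNet) -> int:
    return net.w1.size + net.b1.size + net.w2.size + net.b2.size


def node_angles(g: MolecularGraph, spec: EncodingSpec) -> list:
    """Per-node (RY, RZ) encoding angles; ``None`` for the master node."""
    out = []
    for a in g.nodes:
        if a.is_master:
            out.append(None)
        elif spec.is_net:
            out.append(extract_angles(spec.net, a, spec.method))
        else:
            out.append(fixed_angles(a, spec.method))
    return out


def encode(g: MolecularGraph, spec: EncodingSpec) -> qsim.StateVector:
    """Prepare the encoded register: RY then RZ per atom qubit, RY(pi/2) on
    the master qubit."""
    state = qsim.init_state(g.n_nodes)
    for q, angles in enumerate(node_angles(g, spec)):
        if angles is None:
            state = qsim.apply_gate(state, qsim.GateSpec("RY", (q,), (MASTER_RY_ANGLE,)))
        else:
            ry, rz = angles
            state = qsim.apply_gate(state, qsim.GateSpec("RY", (q,), (ry,)))
            state = qsim.apply_gate(state, qsim.GateSpec("RZ", (q,), (rz,)))
    return state
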