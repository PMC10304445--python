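"""Exact dense statevector simulation of the gate set used by the quantum
graph models.

The simulator is deliberately minimal: the models only need single-qubit
rotations (RY, RZ, an arbitrary single-qubit unitary in ZYZ form) and the
two-qubit RZZ rotation, plus Pauli-Z observables.  Everything is computed in
double precision on the full 2^n amplitude vector; no shot sampling or noise
is modelled, so expectation values are exact.

Conventions
-----------
* A rotation generated by a Pauli word P is ``exp(-i * theta * P / 2)``.
* Basis ordering: qubit 0 is the *most significant* bit of the basis index,
  i.e. for two qubits the amplitudes are ordered |00>, |01>, |10>, |11> with
  qubit 0 the left bit.
* ``U3(a, b, c) = RZ(a) @ RY(b) @ RZ(c)`` (applied right to left), the
  standard ZYZ decomposition of an arbitrary single-qubit unitary up to a
  global phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MAX_QUBITS = 12

__all__ = [
    "StateVector",
    "GateSpec",
    "init_state",
    "apply_gate",
    "expval_z",
    "expval_z_all",
    "ry_matrix",
    "rz_matrix",
    "rzz_matrix",
    "u3_matrix",
]


@dataclass
class StateVector:
    """A pure n-qubit state as a dense complex amplitude vector."""

    n_qubits: int
    amplitudes: np.ndarray

    def copy(self) -> "StateVector":
        return StateVector(self.n_qubits, self.amplitudes.copy())

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))


@dataclass(frozen=True)
class GateSpec:
    """A gate application request: kind, target qubit(s) and angle(s)."""

    kind: str  # RY | RZ | RZZ | U3
    qubits: tuple
    angles: tuple


def init_state(n_qubits: int) -> StateVector:
    """Return |0...0> on ``n_qubits`` qubits (1 <= n <= 12)."""
    if not 1 <= n_qubits <= MAX_QUBITS:
        raise ValueError(f"n_qubits must be in [1, {MAX_QUBITS}], got {n_qubits}")
    amps = np.zeros(2**n_qubits, dtype=np.complex128)
    amps[0] = 1.0
    return StateVector(n_qubits, amps)


def ry_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    return np.array([[c, -s], [s, c]], dtype=np.complex128)


def rz_matrix(theta: float) -> np.ndarray:
    e = np.exp(-0.5j * theta)
    return np.array([[e, 0], [0, np.conj(e)]], dtype=np.complex128)


def u3_matrix(a: float, b: float, c: float) -> np.ndarray:
    """ZYZ product RZ(a) RY(b) RZ(c); RZ(c) acts first."""
    return rz_matrix(a) @ ry_matrix(b) @ rz_matrix(c)


def rzz_matrix(theta: float) -> np.ndarray:
    """exp(-i theta Z(x)Z / 2): diagonal, symmetric under qubit exchange."""
    e = np.exp(-0.5j * theta)
    return np.diag([e, np.conj(e), np.conj(e), e]).astype(np.complex128)


def _apply_1q(state: StateVector, mat: np.ndarray, q: int) -> StateVector:
    n = state.n_qubits
    psi = state.amplitudes.reshape((2,) * n)
    psi = np.moveaxis(np.tensordot(mat, psi, axes=([1], [q])), 0, q)
    return StateVector(n, np.ascontiguousarray(psi).reshape(-1))


def _apply_2q(state: StateVector, mat: np.ndarray, q0: int, q1: int) -> StateVector:
    n = state.n_qubits
    psi = state.amplitudes.reshape((2,) * n)
    m = mat.reshape(2, 2, 2, 2)
    psi = np.tensordot(m, psi, axes=([2, 3], [q0, q1]))
    psi = np.moveaxis(psi, [0, 1], [q0, q1])
    return StateVector(n, np.ascontiguousarray(psi).reshape(-1))


def apply_gate(state: StateVector, gate: GateSpec) -> StateVector:
    """Apply a gate and return the new state (input untouched)."""
    n = state.n_qubits
    for q in gate.qubits:
        if not 0 <= q < n:
            raise IndexError(f"qubit {q} out of range for {n}-qubit state")
    kind = gate.kind
    if kind == "RY":
        (q,) = gate.qubits
        return _apply_1q(state, ry_matrix(gate.angles[0]), q)
    if kind == "RZ":
        (q,) = gate.qubits
        return _apply_1q(state, rz_matrix(gate.angles[0]), q)
    if kind == "U3":
        (q,) = gate.qubits
        return _apply_1q(state, u3_matrix(*gate.angles), q)
    if kind == "RZZ":
        q0, q1 = gate.qubits
        if q0 == q1:
            raise IndexError("RZZ requires two distinct qubits")
        return _apply_2q(state, rzz_matrix(gate.angles[0]), q0, q1)
    raise ValueError(f"unknown gate kind {kind!r}")


def _z_signs(n: int, qubit: int) -> np.ndarray:
    idx = np.arange(2**n)
    bit = (idx >> (n - 1 - qubit)) & 1  # qubit 0 = MSB
    return 1.0 - 2.0 * bit


def expval_z(state: StateVector, qubit: int) -> float:
    """<Z_qubit> of the state, in [-1, 1]."""
    if not 0 <= qubit < state.n_qubits:
        raise IndexError(f"qubit {qubit} out of range")
    probs = np.abs(state.amplitudes) ** 2
    return float(np.dot(_z_signs(state.n_qubits, qubit), probs))


def expval_z_all(state: StateVector) -> float:
    """Expectation of the tensor product of Z over every qubit (parity)."""
    n = state.n_qubits
    idx = np.arange(2**n)
    # parity of the number of set bits -> product of per-qubit Z eigenvalues
    parity = np.bitwise_count(idx.astype(np.uint64)).astype(np.int64) & 1
    signs = 1.0 - 2.0 * parity
    probs = np.abs(state.amplitudes) ** 2
    return float(np.dot(signs, probs))
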