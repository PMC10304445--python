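"""Molecular graph data model, JSON-lines interchange I/O, master-node
augmentation, and the synthetic molecule generator.

Molecules are heavy-atom graphs in the QM9 regime: up to 9 atoms drawn from
{C, N, O, F}, with per-atom features (atomic number, bonded hydrogen count,
aromaticity, hybridization) and typed bonds (single / aromatic / double /
triple).  An optional *master node* may be appended; it carries no chemical
features and is bonded to every other node with a dedicated fifth bond type,
modelling long-range interactions.

The interchange format is JSON lines, one graph per line::

    {"id": str,
     "atoms": [{"z": int, "nh": int, "aromatic": bool, "hyb": "sp"|"sp2"|"sp3"}
               | {"master": true}],
     "bonds": [[i, j, "single"|"aromatic"|"double"|"triple"|"master"]],
     "y_gap_ha": float | null}

Node indices are 0-based everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import numpy as np

ELEMENTS = (6, 7, 8, 9)  # C, N, O, F
BOND_TYPES = ("single", "aromatic", "double", "triple", "master")
CHEMICAL_BOND_TYPES = BOND_TYPES[:4]
HYBRIDIZATIONS = ("sp", "sp2", "sp3")
MAX_HEAVY_ATOMS = 9

# simplified valence budgets; aromatic bonds cost 1.5 units per endpoint
VALENCE_BUDGET = {6: 4.0, 7: 3.0, 8: 2.0, 9: 1.0}
BOND_ORDER = {"single": 1.0, "aromatic": 1.5, "double": 2.0, "triple": 3.0}


class GraphValidationError(ValueError):
    """A molecular graph violates a structural invariant."""


class GraphParseError(ValueError):
    """A JSON-lines record could not be parsed."""


@dataclass(frozen=True)
class AtomNode:
    atomic_number: int = 0
    n_hydrogens: int = 0
    aromatic: bool = False
    hybridization: str = "sp3"
    is_master: bool = False


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    bond_type: str

    def key(self) -> tuple:
        return (min(self.i, self.j), max(self.i, self.j))


@dataclass
class MolecularGraph:
    nodes: list
    bonds: list
    target_ha: Optional[float] = None
    id: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def has_master(self) -> bool:
        return any(a.is_master for a in self.nodes)

    @property
    def has_aromatic_bond(self) -> bool:
        return any(b.bond_type == "aromatic" for b in self.bonds)

    def neighbors(self, i: int) -> list:
        out = []
        for b in self.bonds:
            if b.i == i:
                out.append(b.j)
            elif b.j == i:
                out.append(b.i)
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from((b.i, b.j, {"bond_type": b.bond_type}) for b in self.bonds)
        return g


def validate_graph(g: MolecularGraph) -> None:
    """Raise :class:`GraphValidationError` if any invariant is violated."""
    label = g.id or "<unnamed>"
    n = g.n_nodes
    if n == 0:
        raise GraphValidationError(f"graph {label}: no nodes")
    masters = [i for i, a in enumerate(g.nodes) if a.is_master]
    if len(masters) > 1:
        raise GraphValidationError(f"graph {label}: more than one master node")
    n_heavy = n - len(masters)
    if n_heavy > MAX_HEAVY_ATOMS:
        raise GraphValidationError(
            f"graph {label}: {n_heavy} heavy atoms exceeds {MAX_HEAVY_ATOMS}"
        )
    for i, a in enumerate(g.nodes):
        if a.is_master:
            continue
        if a.atomic_number not in ELEMENTS:
            raise GraphValidationError(
                f"graph {label}: atom {i} has atomic number {a.atomic_number}"
            )
        if a.n_hydrogens not in range(5):
            raise GraphValidationError(
                f"graph {label}: atom {i} has n_hydrogens {a.n_hydrogens}"
            )
        if a.hybridization not in HYBRIDIZATIONS:
            raise GraphValidationError(
                f"graph {label}: atom {i} has hybridization {a.hybridization!r}"
            )
    seen = set()
    for b in g.bonds:
        if not (0 <= b.i < n and 0 <= b.j < n):
            raise GraphValidationError(f"graph {label}: bond index out of range")
        if b.i == b.j:
            raise GraphValidationError(f"graph {label}: self-loop on node {b.i}")
        if b.bond_type not in BOND_TYPES:
            raise GraphValidationError(
                f"graph {label}: unknown bond type {b.bond_type!r}"
            )
        if b.key() in seen:
            raise GraphValidationError(f"graph {label}: duplicate bond {b.key()}")
        seen.add(b.key())
        endpoint_masters = g.nodes[b.i].is_master + g.nodes[b.j].is_master
        if (b.bond_type == "master") != (endpoint_masters == 1):
            raise GraphValidationError(
                f"graph {label}: bond {b.key()} master-type/endpoint mismatch"
            )
    if masters:
        m = masters[0]
        bonded = {j for b in g.bonds if m in (b.i, b.j) for j in (b.i, b.j)} - {m}
        if bonded != set(range(n)) - {m}:
            raise GraphValidationError(
                f"graph {label}: master node not bonded to every other node"
            )
    if n > 1 and not nx.is_connected(g.to_networkx()):
        raise GraphValidationError(f"graph {label}: graph is not connected")


# ---------------------------------------------------------------------------
# JSON-lines I/O


def _atom_to_record(a: AtomNode) -> dict:
    if a.is_master:
        return {"master": True}
    return {
        "z": a.atomic_number,
        "nh": a.n_hydrogens,
        "aromatic": a.aromatic,
        "hyb": a.hybridization,
    }


def _atom_from_record(rec: dict) -> AtomNode:
    if rec.get("master"):
        return AtomNode(is_master=True)
    return AtomNode(
        atomic_number=int(rec["z"]),
        n_hydrogens=int(rec["nh"]),
        aromatic=bool(rec["aromatic"]),
        hybridization=str(rec["hyb"]),
    )


def graph_to_record(g: MolecularGraph) -> dict:
    return {
        "id": g.id,
        "atoms": [_atom_to_record(a) for a in g.nodes],
        "bonds": [[b.i, b.j, b.bond_type] for b in g.bonds],
        "y_gap_ha": g.target_ha,
    }


def graph_from_record(rec: dict) -> MolecularGraph:
    g = MolecularGraph(
        nodes=[_atom_from_record(a) for a in rec["atoms"]],
        bonds=[Bond(int(i), int(j), str(t)) for i, j, t in rec["bonds"]],
        target_ha=None if rec.get("y_gap_ha") is None else float(rec["y_gap_ha"]),
        id=str(rec.get("id", "")),
    )
    validate_graph(g)
    return g


def read_graphs(path) -> list:
    """Read and validate a JSON-lines molecule file."""
    graphs = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                if not isinstance(rec, dict) or "atoms" not in rec:
                    raise KeyError("atoms")
            except (json.JSONDecodeError, KeyError) as exc:
                raise GraphParseError(f"{path}: line {lineno}: {exc}") from exc
            graphs.append(graph_from_record(rec))
    return graphs


def write_graphs(graphs: Iterable[MolecularGraph], path) -> None:
    """Write molecules as JSON lines (UTF-8, LF endings)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in graphs:
            validate_graph(g)
            fh.write(json.dumps(graph_to_record(g)) + "\n")


# ---------------------------------------------------------------------------
# Master-node augmentation


def add_master_node(g: MolecularGraph) -> MolecularGraph:
    """Return a copy of ``g`` with a master node appended as the LAST node,
    bonded to every prior node with the master bond type."""
    if g.has_master:
        raise GraphValidationError(f"graph {g.id or '<unnamed>'}: master already present")
    m = g.n_nodes
    nodes = list(g.nodes) + [AtomNode(is_master=True)]
    bonds = list(g.bonds) + [Bond(i, m, "master") for i in range(m)]
    return MolecularGraph(nodes=nodes, bonds=bonds, target_ha=g.target_ha, id=g.id)


def permute_graph(g: MolecularGraph, perm) -> MolecularGraph:
    """Relabel nodes by ``perm`` (node i moves to index perm[i])."""
    perm = list(perm)
    if sorted(perm) != list(range(g.n_nodes)):
        raise ValueError("perm must be a permutation of the node indices")
    nodes = [None] * g.n_nodes
    for i, a in enumerate(g.nodes):
        nodes[perm[i]] = a
    bonds = [Bond(perm[b.i], perm[b.j], b.bond_type) for b in g.bonds]
    return MolecularGraph(nodes=nodes, bonds=bonds, target_ha=g.target_ha, id=g.id)


# ---------------------------------------------------------------------------
# Synthetic molecule generator

# element draw weights roughly mimicking heavy-atom composition of small
# organic molecules (carbon-dominated)
_ELEMENT_WEIGHTS = np.array([0.68, 0.14, 0.14, 0.04])
_P_AROMATIC_RING = 0.30  # chance of seeding a 6-ring of aromatic bonds
_P_DOUBLE = 0.25  # per-bond chance of upgrading single -> double
_P_TRIPLE = 0.05  # per-bond chance of upgrading single -> triple


def _remaining(budgets, bonds, i):
    used = sum(BOND_ORDER[b.bond_type] for b in bonds if i in (b.i, b.j))
    return budgets[i] - used


def _sample_molecule(rng: np.random.Generator, max_atoms: int) -> Optional[MolecularGraph]:
    n = int(rng.integers(1, max_atoms + 1))
    bonds = []
    aromatic_ring = n >= 6 and rng.random() < _P_AROMATIC_RING
    if aromatic_ring:
        # benzene-like core: 6 ring atoms of C/N joined by aromatic bonds,
        # remaining atoms attached afterwards by single bonds
        ring_elems = [int(rng.choice([6, 7], p=[0.85, 0.15])) for _ in range(6)]
        other = [int(rng.choice(ELEMENTS, p=_ELEMENT_WEIGHTS)) for _ in range(n - 6)]
        elems = ring_elems + other
        bonds = [Bond(k, (k + 1) % 6, "aromatic") for k in range(6)]
        tree_start = 6
    else:
        elems = [int(rng.choice(ELEMENTS, p=_ELEMENT_WEIGHTS)) for _ in range(n)]
        tree_start = 1
    budgets = {i: VALENCE_BUDGET[z] for i, z in enumerate(elems)}
    for i in range(tree_start, n):
        anchors = [j for j in range(i) if _remaining(budgets, bonds, j) >= 1.0]
        if not anchors or budgets[i] < 1.0:
            return None
        j = int(rng.choice(anchors))
        bonds.append(Bond(j, i, "single"))
    # bond-order upgrades where both endpoints still have budget; mutating in
    # place keeps later remaining-valence checks consistent
    for idx, b in enumerate(bonds):
        if b.bond_type != "single":
            continue
        room = min(_remaining(budgets, bonds, b.i), _remaining(budgets, bonds, b.j))
        r = rng.random()
        if room >= 2.0 and r < _P_TRIPLE:
            bonds[idx] = replace(b, bond_type="triple")
        elif room >= 1.0 and r < _P_TRIPLE + _P_DOUBLE:
            bonds[idx] = replace(b, bond_type="double")

    nodes = []
    for i, z in enumerate(elems):
        incident = [b.bond_type for b in bonds if i in (b.i, b.j)]
        rem = budgets[i] - sum(BOND_ORDER[t] for t in incident)
        nh = int(np.clip(np.floor(rem + 1e-9), 0, 4))
        if "triple" in incident:
            hyb = "sp"
        elif "double" in incident or "aromatic" in incident:
            hyb = "sp2"
        else:
            hyb = "sp3"
        nodes.append(
            AtomNode(
                atomic_number=z,
                n_hydrogens=nh,
                aromatic="aromatic" in incident,
                hybridization=hyb,
            )
        )
    return MolecularGraph(nodes=nodes, bonds=bonds)


def generate_molecules(n: int, seed: int, max_atoms: int = MAX_HEAVY_ATOMS) -> list:
    """Sample ``n`` valence-plausible connected molecules, deterministically
    per seed."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        g = _sample_molecule(rng, max_atoms)
        if g is None:
            continue
        g.id = f"m{len(out)}"
        try:
            validate_graph(g)
        except GraphValidationError:
            continue
        out.append(g)
    return out


def teacher_label(
    graphs,
    teacher_config,
    teacher_params,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list:
    """Label molecules with a frozen teacher model plus Gaussian noise.

    The teacher is a quantum graph model (config + parameters); its forward
    output in Hartree, plus N(0, noise_sd) noise, becomes each graph's
    ``target_ha``.  If the teacher uses a master node, the augmentation is
    applied on a temporary copy; the stored graphs keep their original
    topology.
    """
    from . import qgnn  # local import: avoids a module cycle

    rng = np.random.default_rng(seed)
    out = []
    for g in graphs:
        gg = add_master_node(g) if (teacher_config.master_node and not g.has_master) else g
        y = qgnn.forward(gg, teacher_config, teacher_params)
        if noise_sd > 0:
            y += rng.normal(0.0, noise_sd)
        labelled = MolecularGraph(
            nodes=list(g.nodes), bonds=list(g.bonds), target_ha=float(y), id=g.id
        )
        out.append(labelled)
    return out
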