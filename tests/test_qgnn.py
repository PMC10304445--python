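"""EDU-QGC model: EDU algebra, layer application, invariance, readouts,
structural counters, link-layer scheduling and checkpoints."""

import itertools

import numpy as np
import pytest

from eduqgc import qgnn, qsim
from eduqgc.encoding import AngleExtractionNet, EncodingSpec, encode
from eduqgc.molgraph import (
    AtomNode,
    Bond,
    MolecularGraph,
    add_master_node,
    generate_molecules,
    permute_graph,
)
from eduqgc.qgnn import ModelConfig, edu_matrix, forward, init_params, random_params

SWAP = np.array(
    [[1, 0, 0, 0], [0, 0, 1, 0], [0, 1, 0, 0], [0, 0, 0, 1]], dtype=complex
)


def apply_edu_to_state(state, mat, i, j):
    return qsim._apply_2q(state, mat, i, j)


class TestEduMatrix:
    def test_identity_v_reduces_to_rzz(self):
        np.testing.assert_allclose(
            edu_matrix([0.0, 0.0, 0.0], 0.8, "default"),
            qsim.rzz_matrix(0.8),
            atol=1e-12,
        )

    @pytest.mark.parametrize(
        "variant,v", [("default", [0.3, -1.1, 2.0]), ("simple", [0.7])]
    )
    def test_unitary_and_swap_symmetric(self, variant, v):
        m = edu_matrix(v, 1.4, variant)
        np.testing.assert_allclose(m @ m.conj().T, np.eye(4), atol=1e-12)
        np.testing.assert_allclose(SWAP @ m @ SWAP, m, atol=1e-12)

    def test_simple_with_zero_diagonal_is_identity(self):
        m = edu_matrix([1.234], 0.0, "simple")
        np.testing.assert_allclose(m, np.eye(4), atol=1e-12)

    def test_equals_three_factor_product(self):
        v = [0.2, 0.9, -0.4]
        V = qsim.u3_matrix(*v)
        vv = np.kron(V, V)
        expected = vv.conj().T @ qsim.rzz_matrix(0.6) @ vv
        np.testing.assert_allclose(edu_matrix(v, 0.6, "default"), expected, atol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(qgnn.ModelError):
            edu_matrix([0.1], 0.2, "default")


def chain(n, types):
    """n-carbon path with the given bond types."""
    nodes = [AtomNode(6, 2)] * n
    bonds = [Bond(i, i + 1, t) for i, t in enumerate(types)]
    return MolecularGraph(nodes=nodes, bonds=bonds, id="chain")


class TestLayers:
    def test_node_layer_zero_angle_is_identity(self):
        g = chain(3, ["single", "single"])
        config = ModelConfig(n_layers=1, edu_variant="simple")
        p = init_params(config)
        p.node_angles[:] = 0.0
        s0 = encode(g, config.encoding)
        s1 = qgnn.apply_node_layer(s0.copy(), g, config, p, 0)
        np.testing.assert_allclose(s1.amplitudes, s0.amplitudes, atol=1e-12)

    def test_node_layer_ry_pi_flips_ground_state(self):
        g = chain(3, ["single", "single"])
        config = ModelConfig(n_layers=1, edu_variant="default")
        p = init_params(config)
        p.node_angles[0] = [0.0, np.pi, 0.0]
        s = qgnn.apply_node_layer(qsim.init_state(3), g, config, p, 0)
        for q in range(3):
            assert qsim.expval_z(s, q) == pytest.approx(-1.0)

    def test_node_layer_matches_dense_oracle(self, rng):
        g = chain(3, ["single", "double"])
        config = ModelConfig(n_layers=1)
        p = random_params(config, rng)
        s0 = encode(g, config.encoding)
        s1 = qgnn.apply_node_layer(s0.copy(), g, config, p, 0)
        u = qsim.u3_matrix(*p.node_angles[0])
        expected = s0.copy()
        for q in range(3):
            expected = qsim._apply_1q(expected, u, q)
        np.testing.assert_allclose(s1.amplitudes, expected.amplitudes, atol=1e-12)

    def test_link_layer_no_bonds_is_identity(self, rng):
        g = MolecularGraph(nodes=[AtomNode(6, 4)], bonds=[])
        config = ModelConfig(n_layers=1)
        p = random_params(config, rng)
        s0 = encode(g, config.encoding)
        s1 = qgnn.apply_link_layer(s0.copy(), g, config, p, 0)
        np.testing.assert_allclose(s1.amplitudes, s0.amplitudes, atol=1e-12)

    def test_same_type_edus_commute(self, rng):
        g = chain(4, ["single", "single", "single"])
        config = ModelConfig(n_layers=1)
        p = random_params(config, rng)
        s0 = encode(g, config.encoding)
        s_fwd = qgnn.apply_link_layer(s0.copy(), g, config, p, 0)
        mat = edu_matrix(p.v_angles[0], p.d_angles[0], "default")
        s_rev = s0.copy()
        for b in reversed(g.bonds):
            s_rev = apply_edu_to_state(s_rev, mat, b.i, b.j)
        np.testing.assert_allclose(s_fwd.amplitudes, s_rev.amplitudes, atol=1e-10)

    def test_block_order_matters_across_types(self, rng):
        # A-B single, B-C double: swapping the block order changes the state,
        # which is why the fixed type ordering is enforced
        g = chain(3, ["single", "double"])
        config = ModelConfig(n_layers=1)
        p = random_params(config, rng)
        s0 = encode(g, config.encoding)
        s_enforced = qgnn.apply_link_layer(s0.copy(), g, config, p, 0)
        m_single = edu_matrix(p.v_angles[0], p.d_angles[0], "default")
        m_double = edu_matrix(p.v_angles[2], p.d_angles[0], "default")
        s_swapped = apply_edu_to_state(s0.copy(), m_double, 1, 2)
        s_swapped = apply_edu_to_state(s_swapped, m_single, 0, 1)
        assert np.max(np.abs(s_enforced.amplitudes - s_swapped.amplitudes)) > 1e-4

    def test_link_layer_matches_dense_oracle(self, rng):
        g = chain(3, ["single", "double"])
        config = ModelConfig(n_layers=1)
        p = random_params(config, rng)
        s0 = encode(g, config.encoding)
        s1 = qgnn.apply_link_layer(s0.copy(), g, config, p, 0)
        m_single = edu_matrix(p.v_angles[0], p.d_angles[0], "default")
        m_double = edu_matrix(p.v_angles[2], p.d_angles[0], "default")
        expected = apply_edu_to_state(s0.copy(), m_single, 0, 1)
        expected = apply_edu_to_state(expected, m_double, 1, 2)
        np.testing.assert_allclose(s1.amplitudes, expected.amplitudes, atol=1e-10)


class TestReadout:
    def test_local_on_ground_state(self):
        s = qsim.init_state(3)
        assert qgnn.readout(s, np.array([0.1, 0.5]), "local") == pytest.approx(0.6)

    def test_global_r2_zero_equals_local(self, rng):
        for _ in range(100):
            amps = rng.normal(size=8) + 1j * rng.normal(size=8)
            amps /= np.linalg.norm(amps)
            s = qsim.StateVector(3, amps)
            r = rng.normal(size=3)
            r2_zero = np.array([r[0], r[1], 0.0])
            assert qgnn.readout(s, r2_zero, "global") == pytest.approx(
                qgnn.readout(s, r[:2], "local"), abs=1e-12
            )

    def test_balanced_product_state_keeps_only_offset(self):
        s = qsim.init_state(2)
        for q in (0, 1):
            s = qsim.apply_gate(s, qsim.GateSpec("RY", (q,), (np.pi / 2,)))
        assert qgnn.readout(s, np.array([0.7, 0.3]), "local") == pytest.approx(0.7)
        assert qgnn.readout(s, np.array([0.7, 0.3, 0.9]), "global") == pytest.approx(0.7)


class TestForward:
    def test_single_atom_all_zero_angles(self):
        g = MolecularGraph(nodes=[AtomNode(6, 4)], bonds=[], id="c")
        config = ModelConfig(n_layers=1, edu_variant="simple", encoding=EncodingSpec("an"))
        p = init_params(config)
        p.node_angles[:] = 0.0
        p.d_angles[:] = 0.0
        p.v_angles[:] = 0.0
        p.r[:] = [0.0, 1.0]
        assert forward(g, config, p) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "variant,readout_mode,reup",
        [("default", "local", False), ("simple", "global", True)],
    )
    def test_permutation_invariance(self, variant, readout_mode, reup, rng):
        g = next(
            m for m in generate_molecules(20, seed=31, max_atoms=6) if m.n_nodes == 6
        )
        config = ModelConfig(
            n_layers=2, edu_variant=variant, readout=readout_mode, re_uploading=reup
        )
        p = random_params(config, rng)
        base = forward(g, config, p)
        for _ in range(20):
            perm = rng.permutation(g.n_nodes).tolist()
            assert forward(permute_graph(g, perm), config, p) == pytest.approx(
                base, abs=1e-9
            )

    def test_one_layer_equals_manual_composition(self, rng):
        g = chain(4, ["single", "aromatic", "double"])
        config = ModelConfig(n_layers=1)
        p = random_params(config, rng)
        s = encode(g, config.encoding)
        s = qgnn.apply_node_layer(s, g, config, p, 0)
        s = qgnn.apply_link_layer(s, g, config, p, 0)
        expected = qgnn.readout(s, p.r, "local")
        assert forward(g, config, p) == pytest.approx(expected, abs=1e-12)

    def test_output_bound(self, rng, molecules):
        for g in molecules[:5]:
            config = ModelConfig(n_layers=2, readout="global")
            p = random_params(config, rng)
            bound = abs(p.r[0]) + abs(p.r[1]) + abs(p.r[2])
            assert abs(forward(g, config, p)) <= bound + 1e-12

    def test_master_graph_required(self, rng):
        config = ModelConfig(n_layers=1, master_node=True)
        p = random_params(config, rng)
        g = chain(2, ["single"])
        with pytest.raises(qgnn.ModelError):
            forward(g, config, p)
        forward(add_master_node(g), config, p)  # augmented graph accepted


class TestCounts:
    def test_default_three_layer_count(self):
        config = ModelConfig(n_layers=3)
        assert qgnn.count_trainable_parameters(config) == 26  # 9 + 3 + 12 + 2

    def test_net_encoding_adds_50(self, rng):
        base = ModelConfig(n_layers=3)
        net = AngleExtractionNet.glorot(9, rng)
        hybrid = ModelConfig(n_layers=3, encoding=EncodingSpec("net_an_nh", net))
        assert (
            qgnn.count_trainable_parameters(hybrid)
            - qgnn.count_trainable_parameters(base)
            == 50
        )

    def test_simple_one_layer_count(self):
        config = ModelConfig(n_layers=1, edu_variant="simple")
        assert qgnn.count_trainable_parameters(config) == 8  # 1 + 1 + 4 + 2

    def test_count_matches_param_arrays(self, rng):
        for kwargs in (
            dict(n_layers=2, master_node=True),
            dict(n_layers=1, edu_variant="simple", readout="global"),
        ):
            config = ModelConfig(**kwargs)
            p = init_params(config)
            total = sum(a.size for a in p.as_arrays().values())
            assert total == qgnn.count_trainable_parameters(config)

    def test_reuploading_adds_six_gate_layers(self):
        base = ModelConfig(n_layers=3)
        reup = ModelConfig(n_layers=3, re_uploading=True)
        for b in range(5):
            diff = qgnn.count_single_qubit_gate_layers(
                reup, b
            ) - qgnn.count_single_qubit_gate_layers(base, b)
            assert diff == 6

    def test_bondless_simple_single_layer(self):
        config = ModelConfig(n_layers=1, edu_variant="simple")
        assert qgnn.count_single_qubit_gate_layers(config, 0) == 3  # 2 enc + 1 node

    def test_monotone_in_layers(self):
        for variant in ("default", "simple"):
            counts = [
                qgnn.count_single_qubit_gate_layers(
                    ModelConfig(n_layers=n, edu_variant=variant), 3
                )
                for n in range(1, 5)
            ]
            assert all(b > a for a, b in zip(counts, counts[1:]))


def brute_force_chromatic_index(edges):
    """Smallest k admitting a proper edge coloring, by exhaustive search."""
    if not edges:
        return 0
    for k in range(1, len(edges) + 1):
        for assignment in itertools.product(range(k), repeat=len(edges)):
            ok = True
            for a in range(len(edges)):
                for b in range(a + 1, len(edges)):
                    if assignment[a] == assignment[b] and set(edges[a]) & set(edges[b]):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                return k
    raise AssertionError


class TestScheduling:
    def test_single_bond_one_round(self):
        g = chain(2, ["single"])
        assert len(qgnn.schedule_link_layer(g)) == 1

    def test_path_of_two_same_type_bonds(self):
        g = chain(3, ["single", "single"])
        assert len(qgnn.schedule_link_layer(g)) == 2

    def test_triangle_needs_three_rounds(self):
        nodes = [AtomNode(6, 2)] * 3
        bonds = [Bond(0, 1, "single"), Bond(1, 2, "single"), Bond(0, 2, "single")]
        g = MolecularGraph(nodes=nodes, bonds=bonds)
        assert len(qgnn.schedule_link_layer(g)) == 3

    def test_rounds_partition_bonds_and_share_no_endpoint(self, molecules):
        for g in molecules:
            rounds = qgnn.schedule_link_layer(g)
            seen = []
            for rnd in rounds:
                endpoints = [q for b in rnd for q in (b.i, b.j)]
                assert len(endpoints) == len(set(endpoints))
                assert len({b.bond_type for b in rnd}) <= 1
                seen += [b.key() for b in rnd]
            assert sorted(seen) == sorted(b.key() for b in g.bonds)

    def test_per_block_rounds_match_exhaustive_minimum(self, molecules):
        from eduqgc.molgraph import BOND_TYPES

        for g in molecules:
            rounds = qgnn.schedule_link_layer(g)
            for t in BOND_TYPES:
                edges = [b.key() for b in g.bonds if b.bond_type == t]
                if not edges or len(edges) > 8:
                    continue
                block_rounds = [
                    rnd for rnd in rounds if rnd and rnd[0].bond_type == t
                ]
                k_exact = brute_force_chromatic_index(edges)
                assert len(block_rounds) == k_exact
                degree = {}
                for u, v in edges:
                    degree[u] = degree.get(u, 0) + 1
                    degree[v] = degree.get(v, 0) + 1
                delta = max(degree.values())
                assert delta <= k_exact <= delta + 1  # Vizing

    def test_scheduled_execution_equals_sequential(self, rng, molecules):
        g = next(m for m in molecules if len(m.bonds) >= 4)
        config = ModelConfig(n_layers=1)
        p = random_params(config, rng)
        s0 = encode(g, config.encoding)
        seq = qgnn.apply_link_layer(s0.copy(), g, config, p, 0)
        sched = qgnn.apply_link_layer_scheduled(s0.copy(), g, config, p, 0)
        np.testing.assert_allclose(seq.amplitudes, sched.amplitudes, atol=1e-10)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, rng):
        net = AngleExtractionNet.glorot(9, rng)
        config = ModelConfig(
            n_layers=2, readout="global", master_node=True,
            encoding=EncodingSpec("net_an_nh", net),
        )
        p = random_params(config, rng)
        path = tmp_path / "ckpt.json"
        qgnn.save_checkpoint(path, config, p)
        config2, p2 = qgnn.load_checkpoint(path)
        assert config2.n_layers == 2 and config2.master_node
        g = add_master_node(chain(3, ["single", "double"]))
        assert forward(g, config2, p2) == pytest.approx(forward(g, config, p))
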