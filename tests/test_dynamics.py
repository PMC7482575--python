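"""Dynamics unit and property tests for both time-steppers."""

import numpy as np
import pytest

import netflock as nf
from netflock.exceptions import DegenerateGeometryError, InvalidInputError


class TestInitAndRestLengths:
    def test_aligned_state_is_fully_polarized(self, lattice9):
        positions, _ = lattice9
        for heading in (0.0, np.pi / 2, -2.5):
            state = nf.init_aligned(positions, heading)
            assert nf.polarization(state) == pytest.approx(1.0, abs=1e-14)

    def test_rest_lengths_on_lattice(self):
        positions, net = nf.build_nn_lattice(3)
        netr = nf.assign_rest_lengths(net, positions)
        # horizontal/vertical bonds 1, diagonals sqrt(2)
        assert set(np.round(netr.rest_lengths, 12)) == {1.0, round(np.sqrt(2), 12)}

    def test_rest_length_long_range_link(self):
        net = nf.InteractionNetwork(2, [(0, 1)])
        netr = nf.assign_rest_lengths(net, [[0.0, 0.0], [3.0, 4.0]])
        assert netr.rest_lengths[0] == pytest.approx(5.0)

    def test_coincident_linked_agents_rejected(self):
        net = nf.InteractionNetwork(2, [(0, 1)])
        with pytest.raises(DegenerateGeometryError):
            nf.assign_rest_lengths(net, [[1.0, 1.0], [1.0, 1.0]])


class TestVNStep:
    def test_isolated_agent_keeps_heading_without_noise(self):
        net = nf.InteractionNetwork(2, [(0, 1)])
        # agent 2 isolated in a 3-node network
        net3 = nf.InteractionNetwork(3, [(0, 1)])
        state = nf.SwarmState(headings=[0.3, 0.3, -1.2])
        new = nf.vn_step(state, net3, nf.VNParams(eta=0.0), np.random.default_rng(0))
        assert new.headings[2] == pytest.approx(-1.2, abs=1e-12)

    def test_mutual_pair_averages_headings(self):
        net = nf.InteractionNetwork(2, [(0, 1)])
        state = nf.SwarmState(headings=[0.0, np.pi / 2])
        new = nf.vn_step(state, net, nf.VNParams(eta=0.0), np.random.default_rng(0))
        assert np.allclose(new.headings, np.pi / 4, atol=1e-12)

    def test_aligned_state_is_fixed_point(self, lattice9):
        positions, net = lattice9
        state = nf.init_aligned(positions.shape[0], 1.0)
        new = nf.vn_step(state, net, nf.VNParams(eta=0.0), np.random.default_rng(0))
        assert np.allclose(new.headings, 1.0, atol=1e-12)

    def test_size_mismatch_rejected(self, lattice9):
        _, net = lattice9
        with pytest.raises(InvalidInputError):
            nf.vn_step(
                nf.SwarmState(headings=[0.0]), net, nf.VNParams(eta=0.0),
                np.random.default_rng(0),
            )


class TestAEForce:
    def test_pair_at_rest_length_has_zero_force(self, toys):
        net, state = toys["spring_pair"]
        relaxed = nf.SwarmState(headings=state.headings,
                                positions=[[0.0, 0.0], [1.0, 0.0]])
        F = nf.ae_force(relaxed, net, nf.AEParams(eta=0.0))
        assert np.allclose(F, 0.0)

    def test_stretched_spring_hand_value(self):
        net = nf.InteractionNetwork(2, [(0, 1)], rest_lengths=[1.0])
        state = nf.SwarmState(headings=[0.0, 0.0], positions=[[0, 0], [0, 2]])
        F = nf.ae_force(state, net, nf.AEParams(eta=0.0, kappa=5.0))
        assert np.allclose(F[0], [0.0, 5.0])
        assert np.allclose(F[1], [0.0, -5.0])

    def test_initial_lattice_is_stress_free(self, lattice9):
        positions, net = lattice9
        netr = nf.assign_rest_lengths(net, positions)
        state = nf.init_aligned(positions, np.pi / 2)
        F = nf.ae_force(state, netr, nf.AEParams(eta=0.0))
        assert np.all(F == 0.0)

    def test_newtons_third_law_on_random_state(self, lattice9, rng):
        positions, net = lattice9
        netr = nf.assign_rest_lengths(net, positions)
        jittered = positions + rng.normal(0, 0.3, positions.shape)
        state = nf.SwarmState(headings=rng.uniform(-np.pi, np.pi, 81),
                              positions=jittered)
        F = nf.ae_force(state, netr, nf.AEParams(eta=0.0))
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-9)


class TestAEStep:
    def test_force_free_translation(self, toys):
        net, _ = toys["spring_pair"]
        relaxed = nf.SwarmState(headings=[0.7, 0.7],
                                positions=[[0.0, 0.0], [np.cos(0.7), np.sin(0.7)]])
        netr = nf.assign_rest_lengths(net, relaxed.positions)
        params = nf.AEParams(eta=0.0)
        new = nf.ae_step(relaxed, netr, params, np.random.default_rng(0))
        shift = params.v0 * params.dt * np.array([np.cos(0.7), np.sin(0.7)])
        assert np.allclose(new.positions - relaxed.positions, shift, atol=1e-14)
        assert np.allclose(new.headings, relaxed.headings, atol=1e-14)

    def test_torque_hand_value(self):
        # heading +x, neighbour straight above at twice the rest length:
        # pure torque dt*beta*F = 0.1*0.12*5 = 0.06, no speed change
        net = nf.InteractionNetwork(2, [(0, 1)], rest_lengths=[1.0])
        state = nf.SwarmState(headings=[0.0, 0.0], positions=[[0, 0], [0, 2]])
        params = nf.AEParams(eta=0.0, kappa=5.0, beta=0.12, dt=0.1)
        new = nf.ae_step(state, net, params, np.random.default_rng(0))
        assert new.headings[0] == pytest.approx(0.06, abs=1e-12)
        assert new.positions[0, 0] == pytest.approx(params.v0 * params.dt, abs=1e-15)
        assert new.positions[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_two_agent_spring_relaxes_to_rest_length(self, toys):
        # heads pinned along the bond axis by the torque; separation must
        # creep toward the natural length like an overdamped spring
        net, state = toys["spring_pair"]
        params = nf.AEParams(eta=0.0)
        st = state.copy()
        for _ in range(3000):
            st = nf.ae_step(st, net, params, np.random.default_rng(0))
        sep = np.linalg.norm(st.positions[1] - st.positions[0])
        assert abs(sep - 1.0) < 0.05


class TestRunModel:
    def test_vn_noiseless_aligned_stays_polarized(self, lattice9):
        _, net = lattice9
        state = nf.init_aligned(81, np.pi / 2)
        psi, _ = nf.run_model("vn", net, nf.VNParams(eta=0.0), 1000, seed=0,
                              initial_state=state)
        assert np.all(np.abs(psi - 1.0) < 1e-12)

    def test_ae_noiseless_aligned_stays_polarized(self, lattice9):
        positions, net = lattice9
        netr = nf.assign_rest_lengths(net, positions)
        state = nf.init_aligned(positions, np.pi / 2)
        psi, _ = nf.run_model("ae", netr, nf.AEParams(eta=0.0), 1000, seed=0,
                              initial_state=state)
        assert np.all(np.abs(psi - 1.0) < 1e-12)

    def test_full_noise_reaches_finite_size_floor(self, lattice9):
        # with eta = 2*pi headings are iid uniform: stationary psi should sit
        # at the random-walk floor ~N**-0.5 (E[psi] = sqrt(pi)/2/sqrt(N))
        _, net = lattice9
        state = nf.init_aligned(81, 0.0)
        psi, _ = nf.run_model("vn", net, nf.VNParams(eta=2 * np.pi), 4000,
                              seed=3, initial_state=state)
        floor = np.sqrt(np.pi) / 2 / np.sqrt(81)
        mean_tail = psi[2000:].mean()
        assert 0.3 * floor < mean_tail < 3 * floor

    def test_same_seed_bitwise_identical(self, lattice9):
        positions, net = lattice9
        netr = nf.assign_rest_lengths(net, positions)
        state = nf.init_aligned(positions, np.pi / 2)
        for model, params in (("vn", nf.VNParams(eta=1.5)),
                              ("ae", nf.AEParams(eta=0.6))):
            net_used = netr if model == "ae" else net
            a, _ = nf.run_model(model, net_used, params, 500, seed=77,
                                initial_state=state)
            b, _ = nf.run_model(model, net_used, params, 500, seed=77,
                                initial_state=state)
            assert np.array_equal(a, b)

    def test_chunked_equals_stepwise_draws(self, lattice9):
        # run_model's chunked noise consumption matches a loop of single steps
        _, net = lattice9
        state = nf.init_aligned(81, 0.3)
        psi, final = nf.run_model("vn", net, nf.VNParams(eta=2.0), 40, seed=5,
                                  initial_state=state)
        st = state.copy()
        rng = np.random.default_rng(5)
        for _ in range(40):
            st = nf.vn_step(st, net, nf.VNParams(eta=2.0), rng)
        assert np.allclose(st.headings, final.headings, atol=1e-10)

    def test_vn_consensus_without_noise(self, rng):
        # connected network, eta=0: headings contract to a common value
        net = nf.build_er(20, 40, seed=2)
        state = nf.SwarmState(headings=rng.uniform(-1.5, 1.5, 20))
        psi, _ = nf.run_model("vn", net, nf.VNParams(eta=0.0), 400, seed=0,
                              initial_state=state)
        assert psi[-1] > 0.9999

    def test_rotational_equivariance(self, lattice9):
        positions, net = lattice9
        netr = nf.assign_rest_lengths(net, positions)
        phi = 0.83
        for model in ("vn", "ae"):
            base = nf.SwarmState(
                headings=np.linspace(-1, 1, 81),
                positions=None if model == "vn" else positions,
            )
            rot = base.copy()
            rot.headings = nf.wrap_angle(rot.headings + phi)
            if model == "ae":
                R = np.array([[np.cos(phi), -np.sin(phi)],
                              [np.sin(phi), np.cos(phi)]])
                rot.positions = positions @ R.T
            params = nf.VNParams(eta=1.0) if model == "vn" else nf.AEParams(eta=0.3)
            net_used = net if model == "vn" else netr
            net_rot = net_used
            if model == "ae":
                net_rot = nf.assign_rest_lengths(net_used, rot.positions)
            psi_a, fin_a = nf.run_model(model, net_used, params, 50, seed=9,
                                        initial_state=base)
            psi_b, fin_b = nf.run_model(model, net_rot, params, 50, seed=9,
                                        initial_state=rot)
            assert np.allclose(psi_a, psi_b, atol=1e-7)
            d = nf.wrap_angle(fin_b.headings - fin_a.headings - phi)
            assert np.allclose(d, 0.0, atol=1e-6)

    def test_record_stride(self, lattice9):
        _, net = lattice9
        state = nf.init_aligned(81, 0.0)
        full, _ = nf.run_model("vn", net, nf.VNParams(eta=1.0), 100, seed=1,
                               initial_state=state)
        strided, _ = nf.run_model("vn", net, nf.VNParams(eta=1.0), 100, seed=1,
                                  initial_state=state, record_stride=10)
        assert np.array_equal(strided, full[9::10])
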