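"""Network mechanics: tuning curves, competitive learning, fields, decoding.

The weighted-average operations (field centers and population-vector
decoding) are checked against explicit brute-force loop implementations.
"""

import numpy as np
import pytest

from placenergy import (
    Arena,
    NetworkParams,
    PlaceNetwork,
    Trajectory,
    decode_location,
    decode_trajectory,
    evaluate_fields,
    firing_power,
    init_weights,
    run_exploration,
    update_weights,
)
from placenergy.place_network import PowerResponse, _powers

L = 20.0


def make_network(weights, c=None, sigma=None):
    w = np.asarray(weights, float)
    n = w.shape[1]
    return PlaceNetwork(
        weights=w,
        c=np.full(n, 188.0) if c is None else np.asarray(c, float),
        sigma=np.full(n, 0.03) if sigma is None else np.asarray(sigma, float),
    )


class TestInitWeights:
    def test_matches_sigmoidal_map_of_uniform_draws(self):
        w = init_weights(1000, sigma_w=0.1, rng=5)
        gamma = np.random.default_rng(5).uniform(size=(3, 1000))
        expected = 1.0 / (1.0 + np.exp((gamma - 0.5) / (2.0 * 0.1**2)))
        np.testing.assert_array_equal(w, expected)
        # gamma = 0.5 maps to exactly 0.5; the limits pin 0 and 1
        assert 1.0 / (1.0 + np.exp(0.0)) == 0.5
        assert np.all((w > 0.0) & (w < 1.0))

    def test_distribution_symmetric_about_half(self):
        w = init_weights(40_000, sigma_w=0.1, rng=6).ravel()  # >1e5 entries
        assert 0.49 < w.mean() < 0.51

    def test_small_width_is_bimodal_toward_corners(self):
        w = init_weights(2000, sigma_w=0.05, rng=7).ravel()
        assert np.mean((w < 0.1) | (w > 0.9)) > 0.8


class TestFiringPower:
    def test_peak_power_at_preferred_position(self):
        x = np.array([4.0, 8.0, 16.0])
        net = make_network(x[:, None] / L)
        resp = firing_power(x, net, L, NetworkParams(n_cells=1))
        assert resp.powers[0] == pytest.approx(188.0 * 20.0)  # 3760 nW

    def test_power_at_one_tuning_width(self):
        # place the input so that (1/3)*||x/L - w|| equals sigma exactly
        sigma = 0.03
        w = np.full((3, 1), 0.5)
        offset = 3.0 * sigma / np.sqrt(3.0)  # per-axis normalized offset
        x = (0.5 + offset) * L * np.ones(3)
        net = make_network(w, sigma=[sigma])
        resp = firing_power(x, net, L, NetworkParams(n_cells=1))
        assert resp.powers[0] == pytest.approx(3760.0 * np.exp(-0.5), rel=1e-12)

    def test_response_set_and_winner(self):
        net = make_network(np.array([[0.1, 0.5], [0.1, 0.5], [0.1, 0.5]]))
        x = np.array([10.0, 10.0, 10.0])  # exactly on cell 1's preferred point
        resp = firing_power(x, net, L, NetworkParams(n_cells=2))
        assert resp.winner == 1
        assert list(resp.response_set) == [1]  # cell 0 is far below threshold

    def test_winner_tie_breaks_to_lowest_index(self):
        net = make_network(np.full((3, 3), 0.5))
        resp = firing_power(np.array([10.0, 10.0, 10.0]), net, L, NetworkParams(n_cells=3))
        assert resp.winner == 0

    def test_power_never_exceeds_cap(self):
        rng = np.random.default_rng(8)
        net = PlaceNetwork.initialize(NetworkParams(n_cells=50), rng)
        x = rng.uniform(0, L, size=(200, 3))
        p = _powers(net, x / L, 20.0)
        assert np.all(p <= net.c * 20.0 + 1e-9)

    def test_reading_outside_arena_rejected(self):
        net = make_network(np.full((3, 1), 0.5))
        with pytest.raises(ValueError):
            firing_power(np.array([21.0, 0.0, 0.0]), net, L, NetworkParams(n_cells=1))


class TestUpdateWeights:
    def test_zero_rate_leaves_network_unchanged(self):
        net = make_network(np.array([[0.2], [0.4], [0.6]]))
        before = net.weights.copy()
        update_weights(net, np.array([0]), np.array([10.0, 10.0, 10.0]), 0.0, L)
        np.testing.assert_array_equal(net.weights, before)

    def test_preferred_point_is_a_fixed_point(self):
        x = np.array([4.0, 8.0, 12.0])
        net = make_network(x[:, None] / L)
        update_weights(net, np.array([0]), x, 0.5, L)
        np.testing.assert_allclose(net.weights[:, 0], x / L, rtol=1e-15)

    def test_exact_contraction_identity(self):
        rng = np.random.default_rng(9)
        for mu in (0.001, 0.1, 0.9):
            net = make_network(rng.uniform(size=(3, 4)))
            x = rng.uniform(0, L, 3)
            before = np.linalg.norm(net.weights[:, 2] - x / L)
            update_weights(net, np.array([2]), x, mu, L)
            after = np.linalg.norm(net.weights[:, 2] - x / L)
            assert after == pytest.approx((1.0 - mu) * before, rel=1e-12)

    def test_only_responding_columns_move(self):
        rng = np.random.default_rng(10)
        net = make_network(rng.uniform(size=(3, 5)))
        before = net.weights.copy()
        update_weights(net, np.array([1, 3]), np.array([1.0, 2.0, 3.0]), 0.2, L)
        untouched = [0, 2, 4]
        np.testing.assert_array_equal(net.weights[:, untouched], before[:, untouched])
        assert not np.allclose(net.weights[:, [1, 3]], before[:, [1, 3]])


class TestRunExploration:
    def test_empty_trajectory_leaves_network_at_initialization(self):
        net = make_network(np.full((3, 2), 0.3))
        before = net.weights.copy()
        traj = Trajectory(positions=np.empty((0, 3)), step_length=1.0)
        log = run_exploration(traj, np.empty((0, 3)), net, NetworkParams(n_cells=2), L)
        assert log.shape == (0, 2)
        np.testing.assert_array_equal(net.weights, before)

    def test_single_cell_converges_geometrically(self):
        net = make_network(np.full((3, 1), 0.9))
        x = np.array([4.0, 4.0, 4.0])
        positions = np.tile(x, (200, 1))
        traj = Trajectory(positions=positions, step_length=0.0)
        params = NetworkParams(n_cells=1, mu=0.2)
        run_exploration(traj, positions, net, params, L)
        assert np.linalg.norm(net.weights[:, 0] - x / L) < 1e-6

    def test_weights_stay_in_unit_cube(self):
        rng = np.random.default_rng(11)
        net = PlaceNetwork.initialize(NetworkParams(n_cells=20), rng)
        positions = rng.uniform(0, L, size=(500, 3))
        traj = Trajectory(positions=positions, step_length=1.0)
        run_exploration(traj, positions, net, NetworkParams(n_cells=20, mu=0.5), L)
        assert np.all((net.weights >= 0.0) & (net.weights <= 1.0))

    def test_misaligned_inputs_rejected(self):
        net = make_network(np.full((3, 1), 0.5))
        traj = Trajectory(positions=np.zeros((5, 3)), step_length=1.0)
        with pytest.raises(ValueError):
            run_exploration(traj, np.zeros((4, 3)), net, NetworkParams(n_cells=1), L)


class TestEvaluateFields:
    def brute_force_centers(self, powers, readings):
        n = powers.shape[1]
        out = np.full((n, 3), np.nan)
        for j in range(n):
            s = powers[:, j].sum()
            if s > 0:
                acc = np.zeros(3)
                for t in range(len(readings)):
                    acc += powers[t, j] * readings[t]
                out[j] = acc / s
        return out

    def test_centers_match_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        net = PlaceNetwork.initialize(NetworkParams(n_cells=10), rng)
        positions = rng.uniform(0, L, size=(50, 3))
        traj = Trajectory(positions=positions, step_length=1.0)
        summary = evaluate_fields(net, traj, positions, NetworkParams(n_cells=10), L)
        powers = _powers(net, positions / L, 20.0)
        expected = self.brute_force_centers(powers, positions)
        np.testing.assert_allclose(summary.centers, expected, rtol=1e-12)

    def test_two_point_weighted_center(self):
        # powers (1, 3) at positions (0,0,0) and (4,4,4) average to (3,3,3)
        p = np.array([[1.0], [3.0]])
        r = np.array([[0.0, 0.0, 0.0], [4.0, 4.0, 4.0]])
        net = make_network(np.full((3, 1), 0.5))
        traj = Trajectory(positions=r, step_length=1.0)
        summary = evaluate_fields(net, traj, r, NetworkParams(n_cells=1), L, powers=p)
        np.testing.assert_allclose(summary.centers[0], [3.0, 3.0, 3.0], rtol=1e-14)

    def test_constant_power_energy_accumulation(self):
        p = np.full((10, 1), 2.0)
        r = np.tile([5.0, 5.0, 5.0], (10, 1))
        net = make_network(np.full((3, 1), 0.5))
        traj = Trajectory(positions=r, step_length=1.0)
        summary = evaluate_fields(
            net, traj, r, NetworkParams(n_cells=1), L, dt_step=1.0, powers=p
        )
        assert summary.total_energy[0] == pytest.approx(20.0)
        np.testing.assert_allclose(summary.centers[0], [5.0, 5.0, 5.0])

    def test_silent_cell_reports_empty_field_not_crash(self):
        p = np.zeros((5, 1))
        r = np.tile([5.0, 5.0, 5.0], (5, 1))
        net = make_network(np.full((3, 1), 0.5))
        traj = Trajectory(positions=r, step_length=1.0)
        summary = evaluate_fields(net, traj, r, NetworkParams(n_cells=1), L, powers=p)
        assert summary.field_size[0] == 0
        assert np.all(np.isnan(summary.centers[0]))
        assert summary.total_energy[0] == 0.0


class TestDecoding:
    def test_single_responder_returns_its_center(self):
        centers = np.array([[1.0, 2.0, 3.0], [9.0, 9.0, 9.0]])
        resp = PowerResponse(
            powers=np.array([500.0, 1.0]), response_set=np.array([0]), winner=0
        )
        np.testing.assert_array_equal(decode_location(resp, centers), centers[0])

    def test_equal_powers_give_midpoint(self):
        centers = np.array([[0.0, 0.0, 0.0], [10.0, 4.0, 2.0]])
        resp = PowerResponse(
            powers=np.array([7.0, 7.0]), response_set=np.array([0, 1]), winner=0
        )
        np.testing.assert_allclose(decode_location(resp, centers), [5.0, 2.0, 1.0])

    def test_three_cell_weighted_average(self):
        centers = np.eye(3)
        resp = PowerResponse(
            powers=np.array([1.0, 2.0, 3.0]), response_set=np.array([0, 1, 2]), winner=2
        )
        np.testing.assert_allclose(
            decode_location(resp, centers), [1 / 6, 2 / 6, 3 / 6], rtol=1e-14
        )

    def test_empty_response_set_falls_back_to_winner(self):
        centers = np.array([[2.0, 2.0, 2.0], [8.0, 8.0, 8.0]])
        resp = PowerResponse(
            powers=np.array([0.5, 0.4]), response_set=np.array([], dtype=int), winner=0
        )
        np.testing.assert_array_equal(decode_location(resp, centers), centers[0])

    def test_batch_decoding_matches_per_step_oracle(self):
        rng = np.random.default_rng(13)
        n_cells, n_steps = 10, 40
        powers = rng.uniform(0, 4000, size=(n_steps, n_cells))
        thresholds = np.full(n_cells, 1128.0)
        centers = rng.uniform(0, L, size=(n_cells, 3))
        got = decode_trajectory(powers, thresholds, centers)
        for t in range(n_steps):
            j = np.flatnonzero(powers[t] > thresholds)
            if j.size == 0:
                j = np.array([np.argmax(powers[t])])
            expected = np.zeros(3)
            for idx in j:
                expected += powers[t, idx] * centers[idx]
            expected /= powers[t, j].sum()
            np.testing.assert_allclose(got[t], expected, rtol=1e-12)

    def test_decoded_location_stays_in_convex_hull(self):
        rng = np.random.default_rng(14)
        powers = rng.uniform(0, 4000, size=(30, 6))
        centers = rng.uniform(0, L, size=(6, 3))
        got = decode_trajectory(powers, np.full(6, 1000.0), centers)
        assert np.all(got >= centers.min(axis=0) - 1e-9)
        assert np.all(got <= centers.max(axis=0) + 1e-9)


class TestParameterRecovery:
    def test_center_recovered_near_seeded_position(self):
        # a cell seeded at a known normalized position, trained on a cloud
        # confined near that position, recovers its field center within 1 unit
        p = np.array([0.3, 0.6, 0.2])
        rng = np.random.default_rng(15)
        net = make_network(p[:, None] + 0.02)
        positions = np.clip(p * L + rng.uniform(-0.8, 0.8, size=(300, 3)), 0, L)
        traj = Trajectory(positions=positions, step_length=1.0)
        params = NetworkParams(n_cells=1, mu=0.05)
        run_exploration(traj, positions, net, params, L)
        summary = evaluate_fields(net, traj, positions, params, L)
        assert np.linalg.norm(summary.centers[0] - p * L) < 1.0


class TestCenterDispersion:
    def test_learned_centers_fill_all_octants(self, default_runs):
        hits = 0
        for res in default_runs.values():
            octants = {tuple(row) for row in (res.summary.centers > 10.0).astype(int)}
            hits += len(octants) == 8
        assert hits >= 9  # >= 90% of seeds
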