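"""Value geodesics, ε-infodesic search, histograms, sampling, chaining."""

from itertools import permutations

import numpy as np
import pytest
from scipy.stats import spearmanr

from infomdp import (
    GridSpec,
    Policy,
    build_gridworld,
    chain_free_energy,
    epsilon_infodesic_search,
    interim_histogram,
    normalized_difference,
    sample_trajectories,
    segment_route,
    symmetrize,
    value_geodesic_test,
)
from infomdp.infodesics import validate_sequence

from conftest import bfs_distances


class TestValueGeodesics:
    def test_single_leg_is_always_geodesic(self, bfs5):
        assert value_geodesic_test([0, 17], bfs5)

    def test_on_path_interim_states_pass(self, bfs5):
        # 0 -> 6 -> 12 runs down the diagonal: 2 + 2 == 4
        assert value_geodesic_test([0, 6, 12], bfs5)

    def test_detour_fails(self, bfs5):
        # 0 -> 20 -> 4: 4 + 8 != 4
        assert not value_geodesic_test([0, 20, 4], bfs5)

    def test_every_shortest_path_prefix_is_geodesic(self, bfs7):
        # contiguous Chebyshev path 42 -> 6 along the anti-diagonal
        path = [42, 36, 30, 24, 18, 12, 6]
        for k in range(2, len(path) + 1):
            assert value_geodesic_test(path[:k], bfs7)

    def test_sequence_validation(self):
        with pytest.raises(ValueError):
            validate_sequence([3])
        with pytest.raises(ValueError):
            validate_sequence([3, 4, 3])


class TestNormalizedDifference:
    def test_trivial_sequence_is_zero(self, dm3_manhattan_beta1e7):
        route = segment_route(dm3_manhattan_beta1e7, [0, 8])
        assert route.normalized_diff == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_in_shortest_path_regime(self, dm3_manhattan_beta1e7):
        """At large beta the value quasi-metric's triangle inequality makes
        every segmentation at least as dear as the direct route."""
        for seq in permutations(range(9), 3):
            route = segment_route(dm3_manhattan_beta1e7, seq)
            assert route.normalized_diff >= -1e-6

    def test_matches_matrix_entries(self, dm3_manhattan_beta1e7):
        spec = GridSpec(3, 3, "manhattan")
        nd = normalized_difference(spec, 1e7, [0, 4, 8])
        D = dm3_manhattan_beta1e7.D
        expected = (D[0, 4] + D[4, 8] - D[0, 8]) / D[0, 8]
        assert nd == pytest.approx(expected, abs=1e-6)

    def test_rejects_symmetrized_matrix(self, dm3_manhattan_beta1e7):
        with pytest.raises(ValueError):
            segment_route(symmetrize(dm3_manhattan_beta1e7), [0, 4, 8])


class TestEpsilonInfodesicSearch:
    def test_infinite_band_returns_every_candidate(self, dm3_manhattan_beta1e7):
        routes = epsilon_infodesic_search(
            dm3_manhattan_beta1e7, 0, 8, epsilon=np.inf, max_len=4
        )
        # 7 interim singletons + 7*6 ordered pairs
        assert len(routes) == 7 + 42

    @pytest.mark.parametrize("eps", [1e-9, 1e-6])
    def test_agrees_with_brute_force(self, dm3_manhattan_beta1e7, eps):
        """Independent scan of the distance matrix over all interim triples.

        At the wider band every on-path interim state qualifies (the value
        triangle equality holds to solver precision)."""
        D = dm3_manhattan_beta1e7.D
        expected = set()
        for mid in range(9):
            if mid in (0, 8):
                continue
            nd = (D[0, mid] + D[mid, 8] - D[0, 8]) / D[0, 8]
            if abs(nd) < eps:
                expected.add((0, mid, 8))
        found = {
            r.states
            for r in epsilon_infodesic_search(dm3_manhattan_beta1e7, 0, 8, eps)
        }
        assert found == expected
        if eps == 1e-6:
            # every interior state of the 3x3 grid lies on some shortest path
            assert expected == {(0, mid, 8) for mid in range(1, 8)}

    def test_sorted_by_deviation_magnitude(self, dm7_beta007):
        routes = epsilon_infodesic_search(dm7_beta007, 0, 18, epsilon=0.5, max_len=3)
        mags = [abs(r.normalized_diff) for r in routes]
        assert mags == sorted(mags)

    def test_budget_guard(self, dm7_beta007):
        with pytest.raises(ValueError):
            epsilon_infodesic_search(
                dm7_beta007, 0, 18, epsilon=0.1, max_len=5, max_candidates=10
            )


class TestInterimHistogram:
    def test_matches_brute_force_on_small_grid(self, dm3_manhattan_beta1e7):
        D = dm3_manhattan_beta1e7.D
        eps = 1e-9
        counts = np.zeros(9, dtype=int)
        for s in range(9):
            for m in range(9):
                for g in range(9):
                    if len({s, m, g}) < 3:
                        continue
                    nd = (D[s, m] + D[m, g] - D[s, g]) / D[s, g]
                    if abs(nd) < eps:
                        counts[m] += 1
        hist = interim_histogram(dm3_manhattan_beta1e7, eps)
        np.testing.assert_array_equal(hist.counts, counts)
        assert hist.total == counts.sum()

    def test_zero_band_gives_empty_histogram(self, dm3_manhattan_beta1e7):
        hist = interim_histogram(dm3_manhattan_beta1e7, 0.0)
        assert hist.total == 0

    def test_corners_dominate_in_information_limited_regime(self, dm7_beta007):
        """With information severely constrained, corner states are the most
        frequent interim waypoints of three-state ε-infodesics."""
        hist = interim_histogram(dm7_beta007, epsilon=0.05)
        corners = {0, 6, 42, 48}
        top4 = set(np.argsort(hist.counts)[-4:].tolist())
        assert top4 == corners


class TestSampleTrajectories:
    def test_deterministic_path_visits_exactly_path(self, spec5):
        mdp = build_gridworld(spec5, {12})
        probs = np.zeros((25, 4))
        probs[:, 3] = 1.0  # right everywhere
        # start on the goal row: 10 -> 11 -> 12
        traj = sample_trajectories(mdp, Policy(probs), 10, n_episodes=100, seed=1)
        on_path = {10, 11, 12}
        assert np.all(traj.proportions[sorted(on_path)] == 1.0)
        off = [s for s in range(25) if s not in on_path]
        assert np.all(traj.proportions[off] == 0.0)

    def test_visit_proportions_track_expected_visits(
        self, spec7, sol7_goal6_beta100
    ):
        """Spearman correlation with the fundamental-matrix prediction over
        the states the policy can actually reach from the start."""
        mdp = build_gridworld(spec7, {6})
        sol = sol7_goal6_beta100
        traj = sample_trajectories(mdp, sol.policy, 0, n_episodes=10_000, seed=11)
        chain = mdp.policy_transition(sol.policy.probs)
        transient = mdp.transient_states
        Q = chain[np.ix_(transient, transient)]
        N = np.linalg.inv(np.eye(len(transient)) - Q)
        expected = N[list(transient).index(0)]
        reachable = expected > 1e-9
        rho = spearmanr(
            traj.proportions[transient][reachable], expected[reachable]
        ).statistic
        assert rho > 0.9

    def test_seed_required_and_reproducible(self, spec5):
        mdp = build_gridworld(spec5, {12})
        pol = Policy.uniform(25, 4)
        with pytest.raises(ValueError):
            sample_trajectories(mdp, pol, 0, n_episodes=10, seed=None)
        a = sample_trajectories(mdp, pol, 0, n_episodes=200, seed=9)
        b = sample_trajectories(mdp, pol, 0, n_episodes=200, seed=9)
        np.testing.assert_array_equal(a.proportions, b.proportions)


class TestChainFreeEnergy:
    def test_two_state_chain_equals_direct(self, spec5):
        route = chain_free_energy(spec5, 100.0, [0, 12])
        assert sum(route.segment_F) == pytest.approx(route.direct_F)
        assert route.normalized_diff == pytest.approx(0.0, abs=1e-12)

    def test_legs_nonnegative_and_sum_bounds(self, spec7):
        route = chain_free_energy(spec7, 100.0, [0, 12, 6])
        assert all(f >= 0 for f in route.segment_F)
        assert sum(route.segment_F) >= max(route.segment_F)

    def test_remaining_free_energy_decreases_along_infodesic(
        self, dm3_manhattan_beta1e7
    ):
        """Along any sequence meeting the triangle equality within 1e-3, the
        remaining direct free energy to the goal strictly decreases."""
        routes = epsilon_infodesic_search(
            dm3_manhattan_beta1e7, 0, 8, epsilon=1e-3, max_len=4
        )
        assert routes
        D = dm3_manhattan_beta1e7.D
        for route in routes:
            remaining = [D[s, route.states[-1]] for s in route.states]
            assert all(a > b for a, b in zip(remaining, remaining[1:]))
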