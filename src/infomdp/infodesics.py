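"""Value geodesics, infodesics and subgoal policy chaining.

A *value geodesic* is a state sequence ⟨s_0, …, s_N⟩ whose leg distances
under the shortest-path quasi-metric −V* sum exactly to the direct
distance, so every interim state is reached optimally en route.  The
free-energy analogue — an *infodesic* — scores each leg s_i → s_{i+1}
under that leg's own free-energy-optimal policy and asks the same triangle
equality of the directed free-energy distance.  Because optimal policies
become stochastic at finite beta, exact infodesics are rare; an
*ε-infodesic* relaxes the criterion to a band on the normalized difference

    nd = ( Σ_i F_{s_{i+1}}(s_i)  −  F_goal(s_0) ) / F_goal(s_0),
    −ε < nd < ε,

which can be *negative*: chaining per-segment policies at subgoals may be
cheaper than the single direct policy, violating the triangle inequality
(no policy-switching cost is charged).  All leg values are entries of the
all-pairs free-energy matrix, one solve per goal column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Sequence

import numpy as np

from .geometry import DistanceMatrix
from .gridworld import GridSpec, TabularMDP, build_gridworld
from .solver import Policy, free_energy_solve

__all__ = [
    "SegmentedRoute",
    "InterimHistogram",
    "TrajectorySample",
    "validate_sequence",
    "value_geodesic_test",
    "segment_route",
    "normalized_difference",
    "chain_free_energy",
    "epsilon_infodesic_search",
    "interim_histogram",
    "sample_trajectories",
]


def validate_sequence(states: Sequence[int], n_states: int | None = None) -> tuple[int, ...]:
    """Check a candidate (info)desic sequence: ≥ 2 distinct state indices."""
    seq = tuple(int(s) for s in states)
    if len(seq) < 2:
        raise ValueError("a state sequence needs at least a start and a goal")
    if len(set(seq)) != len(seq):
        raise ValueError(f"repeated states in sequence {seq}")
    if n_states is not None and any(not (0 <= s < n_states) for s in seq):
        raise ValueError(f"sequence {seq} contains states outside 0..{n_states - 1}")
    return seq


@dataclass
class SegmentedRoute:
    """A candidate (info)desic with per-leg and direct free energies.

    ``segment_F[i]`` is the free energy of leg states[i] → states[i+1]
    under that leg's own optimal policy; ``direct_F`` the unsegmented
    start → goal free energy; ``normalized_diff`` their relative gap,
    negative when segmentation is cheaper.
    """

    states: tuple[int, ...]
    segment_F: tuple[float, ...]
    direct_F: float
    beta: float | None = None

    @property
    def normalized_diff(self) -> float:
        return (sum(self.segment_F) - self.direct_F) / self.direct_F


@dataclass
class InterimHistogram:
    """Per-state counts of participation as the middle of a three-state
    ε-infodesic, over all ordered distinct triples (s, s', g)."""

    counts: np.ndarray
    epsilon: float
    beta: float | None = None

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class TrajectorySample:
    """Visit statistics of sampled absorbing episodes."""

    proportions: np.ndarray  # fraction of episodes visiting each state
    n_episodes: int
    n_capped: int  # episodes stopped at max_steps before absorbing
    seed: int

    @property
    def cap_warning(self) -> bool:
        return self.n_capped > 0.01 * self.n_episodes


def value_geodesic_test(
    states: Sequence[int], dist: np.ndarray, atol: float = 1e-9
) -> bool:
    """True iff the summed leg distances equal the direct distance.

    ``dist`` is the all-pairs shortest-path matrix −V* (dist[i, j] = cost
    i → j); on deterministic grids the comparison is effectively integer.
    """
    seq = validate_sequence(states, dist.shape[0])
    legs = sum(dist[a, b] for a, b in zip(seq[:-1], seq[1:]))
    return bool(abs(legs - dist[seq[0], seq[-1]]) <= atol)


def segment_route(dm: DistanceMatrix, states: Sequence[int]) -> SegmentedRoute:
    """Score a sequence against a precomputed all-pairs distance matrix."""
    seq = validate_sequence(states, dm.n)
    if dm.symmetrized:
        raise ValueError("infodesic legs are directed; use the raw matrix")
    legs = tuple(float(dm.D[a, b]) for a, b in zip(seq[:-1], seq[1:]))
    direct = float(dm.D[seq[0], seq[-1]])
    if direct <= 0:
        raise ValueError("direct free energy must be positive (start != goal)")
    return SegmentedRoute(states=seq, segment_F=legs, direct_F=direct, beta=dm.beta)


def chain_free_energy(
    spec: GridSpec,
    beta: float,
    states: Sequence[int],
    log_base: float = 2.0,
) -> SegmentedRoute:
    """Chain subgoal policies along a sequence, one fresh solve per goal.

    Each leg s_i → s_{i+1} is scored as F under the free-energy-optimal
    policy for goal s_{i+1}; the direct route start → final goal is solved
    as well for comparison.
    """
    seq = validate_sequence(states, spec.n_states)
    solutions = {
        g: free_energy_solve(build_gridworld(spec, {g}), beta, log_base=log_base)
        for g in set(seq[1:])
    }
    legs = tuple(float(solutions[b].F[a]) for a, b in zip(seq[:-1], seq[1:]))
    direct = float(solutions[seq[-1]].F[seq[0]])
    if direct <= 0:
        raise ValueError("direct free energy must be positive (start != goal)")
    return SegmentedRoute(states=seq, segment_F=legs, direct_F=direct, beta=beta)


def normalized_difference(
    spec: GridSpec,
    beta: float,
    states: Sequence[int],
    log_base: float = 2.0,
) -> float:
    """Normalized triangle deviation (Σ legs − direct)/direct of a sequence;
    negative when per-segment policy chaining beats the direct policy."""
    return chain_free_energy(spec, beta, states, log_base=log_base).normalized_diff


def epsilon_infodesic_search(
    dm: DistanceMatrix,
    start: int,
    goal: int,
    epsilon: float,
    max_len: int = 3,
    max_candidates: int = 2_000_000,
) -> list[SegmentedRoute]:
    """Exhaustive ε-infodesic search between fixed endpoints.

    Enumerates every non-repeating interim-state combination giving total
    sequence lengths 3 .. ``max_len`` (3–5), scores each against the
    precomputed matrix, and returns those with |normalized diff| < ε
    sorted by |normalized diff|.
    """
    if not (3 <= max_len <= 5):
        raise ValueError("max_len must be 3, 4 or 5")
    if start == goal:
        raise ValueError("start and goal must differ")
    validate_sequence((start, goal), dm.n)
    interim_pool = [s for s in range(dm.n) if s not in (start, goal)]
    n_cand = sum(
        int(np.prod([len(interim_pool) - i for i in range(k)]))
        for k in range(1, max_len - 1)
    )
    if n_cand > max_candidates:
        raise ValueError(
            f"{n_cand} candidate sequences exceed the budget of "
            f"{max_candidates}; reduce max_len"
        )
    results: list[SegmentedRoute] = []
    for k in range(1, max_len - 1):
        for interim in permutations(interim_pool, k):
            route = segment_route(dm, (start, *interim, goal))
            if abs(route.normalized_diff) < epsilon:
                results.append(route)
    results.sort(key=lambda r: abs(r.normalized_diff))
    return results


def interim_histogram(dm: DistanceMatrix, epsilon: float) -> InterimHistogram:
    """Count, per state, the ordered triples (s, s', g) of distinct states
    forming a three-state ε-infodesic with that state in the middle."""
    if dm.symmetrized:
        raise ValueError("infodesic legs are directed; use the raw matrix")
    D = dm.D
    n = dm.n
    with np.errstate(divide="ignore", invalid="ignore"):
        nd = (D[:, :, None] + D[None, :, :] - D[:, None, :]) / np.where(
            D[:, None, :] > 0, D[:, None, :], np.inf
        )
    idx = np.arange(n)
    distinct = (
        (idx[:, None, None] != idx[None, :, None])
        & (idx[None, :, None] != idx[None, None, :])
        & (idx[:, None, None] != idx[None, None, :])
    )
    qualifies = distinct & (np.abs(nd) < epsilon)
    counts = qualifies.sum(axis=(0, 2)).astype(int)
    return InterimHistogram(counts=counts, epsilon=epsilon, beta=dm.beta)


def sample_trajectories(
    mdp: TabularMDP,
    policy: Policy,
    start: int,
    n_episodes: int = 10_000,
    seed: int | None = None,
    max_steps: int = 100_000,
) -> TrajectorySample:
    """Simulate episodes to absorption and report per-state visit fractions.

    Episodes run from ``start`` under the given policy until a goal state
    is entered (or ``max_steps``, counted in ``n_capped``).  The returned
    proportions give, for each state, the fraction of episodes visiting it
    at least once.  A seed is required for reproducibility.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    rng = np.random.default_rng(seed)
    n = mdp.n_states
    policy_cdf = np.cumsum(policy.probs, axis=1)
    succ_cdf = np.cumsum(mdp.transition, axis=2)
    goal_mask = mdp.goal_mask

    states = np.full(n_episodes, start, dtype=int)
    active = ~goal_mask[states]
    visited = np.zeros((n_episodes, n), dtype=bool)
    visited[:, start] = True
    for _ in range(max_steps):
        if not active.any():
            break
        cur = states[active]
        u = rng.random(cur.size)
        actions = (u[:, None] > policy_cdf[cur]).sum(axis=1)
        u2 = rng.random(cur.size)
        nxt = (u2[:, None] > succ_cdf[cur, actions]).sum(axis=1)
        states[active] = nxt
        visited[np.flatnonzero(active), nxt] = True
        active[active] = ~goal_mask[nxt]
    n_capped = int(active.sum())
    return TrajectorySample(
        proportions=visited.mean(axis=0),
        n_episodes=n_episodes,
        n_capped=n_capped,
        seed=seed,
    )
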