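"""Cost-only gridworld MDPs.

Empty rectangular gridworlds are modelled as undiscounted, episodic tabular
MDPs ⟨S, A, r, P⟩: every step from a transient state costs 1 (reward −1),
goal states are absorbing with reward 0, and a move off the boundary is a
"wall bump" — the agent stays put but still pays the step cost.  With this
reward structure the negative optimal value −V*(s) is exactly the graph
distance from s to the nearest goal, so the MDP doubles as a discrete
geometry whose distances can later be deformed by information costs.

States are numbered row-major from the top-left corner: state 0 is (row 0,
col 0) and indices increase first along columns, then row by row.  Actions
come in a fixed order — the four cardinal moves ↑, ←, ↓, → for a Manhattan
neighborhood, with the diagonals ↖, ↙, ↘, ↗ appended for Moore — so that
serialized policies are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Neighborhood",
    "GridSpec",
    "TabularMDP",
    "coord_to_state",
    "state_to_coord",
    "build_gridworld",
]


class Neighborhood(str, Enum):
    """Grid connectivity: 4 cardinal actions or 8 actions with diagonals."""

    MANHATTAN = "manhattan"
    MOORE = "moore"


#: action name -> (row delta, col delta); cardinal moves first, diagonals after.
_CARDINAL: tuple[tuple[str, tuple[int, int]], ...] = (
    ("up", (-1, 0)),
    ("left", (0, -1)),
    ("down", (1, 0)),
    ("right", (0, 1)),
)
_DIAGONAL: tuple[tuple[str, tuple[int, int]], ...] = (
    ("up-left", (-1, -1)),
    ("down-left", (1, -1)),
    ("down-right", (1, 1)),
    ("up-right", (-1, 1)),
)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an empty rectangular gridworld.

    Parameters
    ----------
    width, height
        Number of columns / rows; both must be ≥ 1.
    neighborhood
        ``Neighborhood.MANHATTAN`` (4 actions) or ``Neighborhood.MOORE``
        (8 actions).  A string value is accepted and coerced.
    """

    width: int
    height: int
    neighborhood: Neighborhood = Neighborhood.MANHATTAN

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(
                f"grid must be at least 1x1, got {self.width}x{self.height}"
            )
        object.__setattr__(self, "neighborhood", Neighborhood(self.neighborhood))

    @property
    def n_states(self) -> int:
        return self.width * self.height

    @property
    def moves(self) -> tuple[tuple[str, tuple[int, int]], ...]:
        """Ordered (name, (drow, dcol)) pairs for this neighborhood."""
        if self.neighborhood is Neighborhood.MOORE:
            return _CARDINAL + _DIAGONAL
        return _CARDINAL

    @property
    def action_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.moves)

    @property
    def n_actions(self) -> int:
        return len(self.moves)


def coord_to_state(row: int, col: int, spec: GridSpec) -> int:
    """Map a (row, col) coordinate (0-based, row 0 at the top) to a state index."""
    if not (0 <= row < spec.height and 0 <= col < spec.width):
        raise ValueError(
            f"coordinate ({row}, {col}) outside {spec.height}x{spec.width} grid"
        )
    return row * spec.width + col


def state_to_coord(state: int, spec: GridSpec) -> tuple[int, int]:
    """Inverse of :func:`coord_to_state`."""
    if not (0 <= state < spec.n_states):
        raise ValueError(f"state {state} outside grid with {spec.n_states} states")
    return divmod(state, spec.width)


@dataclass
class TabularMDP:
    """Finite MDP ⟨S, A, r, P⟩ with absorbing goals.

    Attributes
    ----------
    transition
        Array of shape (n_states, n_actions, n_states); ``transition[s, a]``
        is the successor distribution P(s'|s, a).  Gridworld transitions are
        deterministic but the representation permits stochastic entries.
    reward
        Expected immediate reward of shape (n_states, n_actions): −1 from
        every transient state, 0 from goals.
    goals
        Indices of absorbing goal states.
    """

    transition: np.ndarray
    reward: np.ndarray
    goals: frozenset[int]
    action_names: tuple[str, ...]
    spec: GridSpec | None = None

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    @property
    def n_actions(self) -> int:
        return self.transition.shape[1]

    @property
    def goal_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_states, dtype=bool)
        mask[list(self.goals)] = True
        return mask

    @property
    def transient_states(self) -> np.ndarray:
        return np.flatnonzero(~self.goal_mask)

    def validate(self, atol: float = 1e-12) -> None:
        """Raise ``ValueError`` if the MDP contract is broken."""
        n, a, n2 = self.transition.shape
        if n != n2 or self.reward.shape != (n, a):
            raise ValueError("transition/reward shape mismatch")
        if not np.allclose(self.transition.sum(axis=2), 1.0, atol=atol):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.transition < -atol):
            raise ValueError("negative transition probability")
        for g in self.goals:
            if not np.allclose(self.transition[g, :, g], 1.0, atol=atol):
                raise ValueError(f"goal {g} is not absorbing")
            if not np.allclose(self.reward[g], 0.0, atol=atol):
                raise ValueError(f"goal {g} has non-zero reward")
        transient = self.transient_states
        if transient.size and not np.allclose(self.reward[transient], -1.0, atol=atol):
            raise ValueError("transient states must have reward -1")

    def policy_transition(self, probs: np.ndarray) -> np.ndarray:
        """State chain P_pi(s'|s) induced by policy probabilities (n, a)."""
        return np.einsum("sa,san->sn", probs, self.transition)


def build_gridworld(spec: GridSpec, goals: set[int] | frozenset[int]) -> TabularMDP:
    """Construct the cost-only MDP for an empty gridworld.

    Moves are deterministic; a move that would leave the grid keeps the agent
    in place (wall bump) and, from a transient state, still costs a step.
    Goal states self-loop under every action at zero reward.
    """
    goals = frozenset(int(g) for g in goals)
    if not goals:
        raise ValueError("goal set must be non-empty")
    for g in goals:
        if not (0 <= g < spec.n_states):
            raise ValueError(f"goal {g} outside grid with {spec.n_states} states")

    n, a = spec.n_states, spec.n_actions
    transition = np.zeros((n, a, n))
    reward = np.full((n, a), -1.0)
    for s in range(n):
        row, col = state_to_coord(s, spec)
        if s in goals:
            transition[s, :, s] = 1.0
            reward[s, :] = 0.0
            continue
        for ai, (_, (dr, dc)) in enumerate(spec.moves):
            r2, c2 = row + dr, col + dc
            if 0 <= r2 < spec.height and 0 <= c2 < spec.width:
                s2 = coord_to_state(r2, c2, spec)
            else:
                s2 = s  # wall bump
            transition[s, ai, s2] = 1.0

    mdp = TabularMDP(
        transition=transition,
        reward=reward,
        goals=goals,
        action_names=spec.action_names,
        spec=spec,
    )
    mdp.validate()
    return mdp
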