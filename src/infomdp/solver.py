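"""Value- and free-energy-optimal policies for cost-only tabular MDPs.

The solver trades path cost against the information the agent must process
to act differently from its own habitual behaviour.  Decision information

    I_D(s) = E_pi [ log( pi(a|s) / p_hat(a) ) + I_D(s') ],      I_D(g) = 0,

accumulates, over the remaining trajectory to the goal, the divergence of
the per-state policy from a fixed marginal action prior p_hat(a).  The prior
is the policy marginalized over the "live" state distribution — the
probability of finding the agent at each transient state at a random moment
while its episode is still running, computed from the absorbing chain's
fundamental matrix with a uniform start over transient states.

Free energy combines both costs with a trade-off parameter beta > 0:

    F(s; beta) = (1/beta) * I_D(s) - V(s),

and the free-energy-optimal policy pi_F minimizes it.  Since the prior
itself depends on pi_F, the fixed point is found by a double iteration: an
inner Bellman/Blahut–Arimoto sweep (soft-min Bellman update of F and a
Boltzmann reweighting of the prior) holding the prior fixed, and an outer
loop that recomputes the live distribution and prior from the current
policy.  beta -> infinity recovers shortest paths; beta -> 0 drives the
policy toward the state-independent (open-loop) action marginal.

Information quantities are measured in bits by default (``log_base=2``);
the free-energy recursion uses the same base, which matters because F mixes
(1/beta)*I_D with step costs.  Natural log is available via ``log_base``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .gridworld import TabularMDP

__all__ = [
    "Policy",
    "ValueSolution",
    "FreeEnergySolution",
    "SolverError",
    "value_iteration",
    "live_distribution",
    "action_prior",
    "decision_information",
    "free_energy_solve",
    "evaluate_free_energy",
]

#: floor applied to prior entries inside logarithms only
_PRIOR_FLOOR = 1e-300


class SolverError(RuntimeError):
    """Raised when an iterative solve fails to converge or a linear system
    backing the absorbing-chain computations is singular."""


@dataclass
class Policy:
    """Per-state probability distribution over actions, pi(a|s)."""

    probs: np.ndarray  # shape (n_states, n_actions)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("policy must be a (n_states, n_actions) array")
        if np.any(self.probs < 0):
            raise ValueError("policy probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each state's action distribution must sum to 1")

    @classmethod
    def uniform(cls, n_states: int, n_actions: int) -> "Policy":
        return cls(np.full((n_states, n_actions), 1.0 / n_actions))


@dataclass
class ValueSolution:
    """Optimal value function and a value-optimal policy.

    ``V`` is the expected return (≤ 0); on deterministic cost-only grids
    −V(s) is the graph distance to the nearest goal.  ``policy`` spreads
    probability uniformly over all co-optimal actions.
    """

    V: np.ndarray
    policy: Policy
    iterations: int = 0
    residual: float = 0.0


@dataclass
class FreeEnergySolution:
    """Converged free-energy-optimal solution for one goal set and beta.

    Attributes
    ----------
    F
        Free energy per state (≥ 0, zero at goals), in the units implied by
        ``log_base`` for the information term.
    policy
        pi_F; rows at goal states are set to the action prior, a display
        convention only (behaviour at absorbing states is irrelevant).
    decision_info
        I_D per state under pi_F, in units of ``log_base`` (bits for 2).
    prior
        Marginal action distribution p_hat(a; pi_F).
    live
        Live state distribution (sums to 1 over transient states, zero on
        goals).
    """

    F: np.ndarray
    policy: Policy
    decision_info: np.ndarray
    prior: np.ndarray
    live: np.ndarray
    beta: float
    log_base: float
    diagnostics: dict[str, Any] = field(default_factory=dict)

    @property
    def V(self) -> np.ndarray:
        """Value of pi_F recovered from F = (1/beta) I_D − V."""
        return self.decision_info / self.beta - self.F


def value_iteration(
    mdp: TabularMDP, tol: float = 1e-10, max_iter: int = 100_000, tie_tol: float = 1e-9
) -> ValueSolution:
    """Solve the optimal Bellman equation V(s) = max_a E[r + V(s')].

    The returned policy puts equal mass on every action whose backup is
    within ``tie_tol`` of the maximum (uniform tie-breaking).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    V = np.zeros(mdp.n_states)
    goal_mask = mdp.goal_mask
    for it in range(1, max_iter + 1):
        backups = mdp.reward + np.einsum("san,n->sa", mdp.transition, V)
        V_new = backups.max(axis=1)
        V_new[goal_mask] = 0.0
        residual = float(np.max(np.abs(V_new - V)))
        V = V_new
        if residual < tol:
            break
    else:
        raise SolverError(
            f"value iteration did not converge in {max_iter} iterations "
            f"(residual {residual:.3e})"
        )
    backups = mdp.reward + np.einsum("san,n->sa", mdp.transition, V)
    best = backups.max(axis=1, keepdims=True)
    argmax = backups >= best - tie_tol
    probs = argmax / argmax.sum(axis=1, keepdims=True)
    return ValueSolution(V=V, policy=Policy(probs), iterations=it, residual=residual)


def live_distribution(mdp: TabularMDP, policy: Policy) -> np.ndarray:
    """Live (visitation) state distribution of an absorbing chain.

    The probability of finding the agent at each transient state at a
    uniformly random moment of a still-running episode, started uniformly
    over transient states.  With Q the transient-to-transient transition
    matrix under the policy and N = (I − Q)^{-1} the fundamental matrix,
    row s of N holds the expected visit counts from start s and its row sum
    t(s) the expected absorption time; each row is normalized to a
    distribution (a random time within *that* episode) and the rows are
    averaged over starts:

        live(s') = (1/n_t) * sum_s N[s, s'] / t(s).

    Goal states carry zero mass and the result sums to 1 exactly.  Both
    steps are linear solves, no explicit inverse.
    """
    transient = mdp.transient_states
    live = np.zeros(mdp.n_states)
    if transient.size == 0:
        return live
    chain = mdp.policy_transition(policy.probs)
    Q = chain[np.ix_(transient, transient)]
    identity = np.eye(transient.size)
    try:
        # absorption times t = N @ 1
        times = np.linalg.solve(identity - Q, np.ones(transient.size))
    except np.linalg.LinAlgError as exc:
        raise SolverError(
            "absorbing-chain system singular: the policy does not reach the "
            "goal set (absorption time unbounded)"
        ) from exc
    if not np.all(np.isfinite(times)) or np.any(times < 1.0 - 1e-9):
        raise SolverError(
            "ill-conditioned absorbing-chain solve: absorption times are "
            "not finite and >= 1"
        )
    weights = (1.0 / times) / transient.size
    # live = weights^T N  <=>  (I-Q)^T live = weights
    visits = np.linalg.solve(identity - Q.T, weights)
    if not np.all(np.isfinite(visits)) or np.any(visits < -1e-9):
        raise SolverError(
            "ill-conditioned absorbing-chain solve: visitation mass is not "
            "finite and non-negative"
        )
    visits = np.maximum(visits, 0.0)
    live[transient] = visits / visits.sum()
    return live


def action_prior(policy: Policy, live: np.ndarray) -> np.ndarray:
    """Marginal action distribution p_hat(a) = sum_s pi(a|s) * live(s)."""
    live = np.asarray(live, dtype=float)
    total = live.sum()
    if total <= 0:
        # degenerate world with no transient states: fall back to uniform
        return np.full(policy.probs.shape[1], 1.0 / policy.probs.shape[1])
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError("live distribution must be normalized")
    return policy.probs.T @ live


def _stepwise_divergence(
    policy: Policy, prior: np.ndarray, log_base: float
) -> np.ndarray:
    """Per-state KL divergence sum_a pi log(pi/p_hat), with 0·log 0 := 0."""
    probs = policy.probs
    safe_prior = np.maximum(prior, _PRIOR_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(probs > 0, np.log(probs / safe_prior), 0.0)
    return (probs * logs).sum(axis=1) / math.log(log_base)


def decision_information(
    mdp: TabularMDP,
    policy: Policy,
    prior: np.ndarray,
    log_base: float = 2.0,
) -> np.ndarray:
    """Cumulative decision information I_D per state, by linear solve.

    Solves I_D(s) = KL(pi(·|s) || p_hat) + sum_{s'} P_pi(s'|s) I_D(s') with
    I_D(g) = 0 over the transient block.  Units follow ``log_base`` (bits
    for the default base 2).
    """
    prior = np.asarray(prior, dtype=float)
    if np.any((policy.probs > 1e-6) & (prior[None, :] < 1e-15)):
        raise ValueError(
            "policy places non-negligible mass on actions with zero prior "
            "probability; the divergence is undefined"
        )
    cost = _stepwise_divergence(policy, prior, log_base)
    info = np.zeros(mdp.n_states)
    transient = mdp.transient_states
    if transient.size == 0:
        return info
    chain = mdp.policy_transition(policy.probs)
    Q = chain[np.ix_(transient, transient)]
    try:
        info[transient] = np.linalg.solve(
            np.eye(transient.size) - Q, cost[transient]
        )
    except np.linalg.LinAlgError as exc:
        raise SolverError("decision-information system singular") from exc
    return info


def _policy_value(mdp: TabularMDP, policy: Policy) -> np.ndarray:
    """Policy evaluation V^pi by linear solve on the transient block."""
    V = np.zeros(mdp.n_states)
    transient = mdp.transient_states
    if transient.size == 0:
        return V
    chain = mdp.policy_transition(policy.probs)
    Q = chain[np.ix_(transient, transient)]
    r_pi = (policy.probs * mdp.reward).sum(axis=1)
    try:
        V[transient] = np.linalg.solve(np.eye(transient.size) - Q, r_pi[transient])
    except np.linalg.LinAlgError as exc:
        raise SolverError("policy-evaluation system singular") from exc
    return V


def evaluate_free_energy(
    mdp: TabularMDP,
    policy: Policy,
    prior: np.ndarray,
    beta: float,
    log_base: float = 2.0,
) -> np.ndarray:
    """Free energy F = (1/beta)·I_D − V of a *fixed* policy against a prior.

    Policy-evaluation counterpart of :func:`free_energy_solve`; both terms
    come from linear solves on the induced absorbing chain.
    """
    if beta <= 0:
        raise ValueError("beta must be strictly positive")
    info = decision_information(mdp, policy, prior, log_base=log_base)
    V = _policy_value(mdp, policy)
    return info / beta - V


def free_energy_solve(
    mdp: TabularMDP,
    beta: float,
    log_base: float = 2.0,
    inner_tol: float = 1e-9,
    outer_tol: float = 1e-9,
    max_inner: int = 10_000,
    max_outer: int = 50_000,
    damping: float = 0.0,
) -> FreeEnergySolution:
    """Find the free-energy-optimal policy pi_F and its free energy F.

    Double iteration from a deterministic uniform-policy start.  Holding
    the prior p_hat fixed, the inner loop alternates exact policy
    evaluation with Boltzmann improvement until F is stationary:

        F_pi(s) = sum_a pi(a|s) [ (1/beta) log_b(pi(a|s)/p_hat(a))
                                  - r(s, a) ] + sum_{s'} P_pi(s'|s) F_pi(s'),
        pi(a|s) ∝ p_hat(a) b^{beta * Q_F(s, a)},
        Q_F(s, a) = sum_{s'} P(s'|s, a) [ r(s, a) - F(s') ].

    The evaluation step is linear in F (one solve on the transient block
    per sweep), so convergence does not degrade when absorption times grow
    at small beta; the fixed point is the soft-min Bellman solution
    F(s) = -(1/beta) log_b sum_a p_hat(a) b^{beta Q_F(s, a)} with F = 0 at
    goals.  The outer loop recomputes the live distribution and the action
    prior from the current policy and repeats until the prior is
    stationary.

    The coupled system can possess several self-consistent fixed points at
    small beta; the deterministic schedule above makes the returned one
    reproducible.

    Parameters
    ----------
    beta
        Strictly positive trade-off parameter.
    damping
        Optional relaxation of the prior update, ``new = (1-d)*update +
        d*old``; 0 (undamped) by default.
    """
    if beta <= 0:
        raise ValueError("beta must be strictly positive")
    if not (0 <= damping < 1):
        raise ValueError("damping must lie in [0, 1)")

    n, a = mdp.n_states, mdp.n_actions
    goal_mask = mdp.goal_mask
    transient = mdp.transient_states
    identity = np.eye(transient.size)
    # natural-units inverse temperature: log-base-b recursion at beta equals
    # the natural-log recursion at beta*ln(b) with F unchanged
    b_nat = beta * math.log(log_base)

    policy = Policy.uniform(n, a)
    live = live_distribution(mdp, policy)
    prior = action_prior(policy, live)
    F = np.zeros(n)
    probs = policy.probs

    if transient.size == 0:
        info = np.zeros(n)
        probs = np.tile(prior, (n, 1))
        return FreeEnergySolution(
            F=F, policy=Policy(probs), decision_info=info, prior=prior,
            live=live, beta=beta, log_base=log_base,
            diagnostics={"outer_iterations": 0, "inner_iterations": [],
                         "final_inner_residual": 0.0,
                         "final_prior_residual": 0.0, "log_base": log_base},
        )

    inner_counts: list[int] = []
    prior_residual = np.inf
    for outer in range(1, max_outer + 1):
        log_prior = np.log(np.maximum(prior, _PRIOR_FLOOR))
        # inner loop: exact evaluation + Boltzmann improvement at fixed prior
        for inner in range(1, max_inner + 1):
            with np.errstate(divide="ignore", invalid="ignore"):
                log_ratio = np.where(
                    probs > 0, np.log(probs) - log_prior[None, :], 0.0
                )
            u = (probs * (log_ratio / b_nat - mdp.reward)).sum(axis=1)
            chain = np.einsum("sa,san->sn", probs, mdp.transition)
            F_new = np.zeros(n)
            try:
                F_new[transient] = np.linalg.solve(
                    identity - chain[np.ix_(transient, transient)], u[transient]
                )
            except np.linalg.LinAlgError as exc:
                raise SolverError(
                    f"policy evaluation singular at beta={beta}: the interim "
                    "policy does not reach the goal set"
                ) from exc
            q = mdp.reward - np.einsum("san,n->sa", mdp.transition, F_new)
            logits = b_nat * q + log_prior[None, :]
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            f_residual = float(np.max(np.abs(F_new - F)))
            F = F_new
            if f_residual < inner_tol:
                break
        else:
            raise SolverError(
                f"inner free-energy loop did not converge at beta={beta} "
                f"(residual {f_residual:.3e} after {max_inner} sweeps)"
            )
        inner_counts.append(inner)

        policy = Policy(probs)
        live = live_distribution(mdp, policy)
        new_prior = action_prior(policy, live)
        prior_residual = float(np.max(np.abs(new_prior - prior)))
        prior = (1.0 - damping) * new_prior + damping * prior
        if prior_residual < outer_tol:
            break
    else:
        raise SolverError(
            f"outer prior loop did not converge at beta={beta} "
            f"(prior residual {prior_residual:.3e} after {max_outer} updates)"
        )

    info = decision_information(mdp, policy, prior, log_base=log_base)
    # display convention: the goal-state row shows the action prior
    probs = policy.probs.copy()
    probs[goal_mask] = prior
    policy = Policy(probs)

    diagnostics = {
        "outer_iterations": outer,
        "inner_iterations": inner_counts,
        "final_inner_residual": f_residual,
        "final_prior_residual": prior_residual,
        "log_base": log_base,
    }
    return FreeEnergySolution(
        F=F,
        policy=policy,
        decision_info=info,
        prior=prior,
        live=live,
        beta=beta,
        log_base=log_base,
        diagnostics=diagnostics,
    )
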