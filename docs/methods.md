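# Methods

## Model

The environment is a cost-only, undiscounted, episodic tabular MDP on an
empty rectangular grid. States are numbered row-major from the top-left
corner. The action set is ↑, ←, ↓, → (Manhattan) optionally followed by
↖, ↙, ↘, ↗ (Moore); this order is fixed so serialized policies are
reproducible. Transitions are deterministic; a move off the boundary
leaves the agent in place (wall bump). Every transition out of a
transient state yields reward −1; goal states self-loop with reward 0.
The transition tensor admits stochastic entries, so the solver would
carry over unchanged to noisy actuators, but only the deterministic case
is exercised by the tests. The reward is stored as the expected immediate
reward R[s, a]; on these MDPs the full r(s′, s, a) form carries no extra
information.

Under this reward structure −V*(s) equals the BFS graph distance to the
nearest goal (Manhattan or Chebyshev metric), and it satisfies
non-negativity, identity of indiscernibles and the triangle inequality —
a quasi-metric, asymmetric in general. The test suite verifies all three
axioms exhaustively on the 5×5 and 7×7 grids.

## Decision information and the live distribution

Decision information charges each decision its divergence from a fixed
marginal action prior and accumulates the charge over the remaining
trajectory:

    I_D(s) = Σ_a π(a|s) log_b( π(a|s)/p̂(a) ) + Σ_{s′} P_π(s′|s) I_D(s′),

with I_D = 0 at goals. Given π and p̂ this is a linear system on the
transient block and is solved exactly.

The prior p̂(a) = Σ_s π(a|s)·live(s) marginalizes the policy over the
**live distribution**: start a trajectory uniformly over transient
states, pick a uniformly random *moment of that still-running episode*,
and record the state. With Q the transient-to-transient chain under π and
N = (I − Q)⁻¹ the fundamental matrix, row s of N holds expected visit
counts from start s and its row sum t(s) the expected absorption time, so

    live(s′) = (1/n_t) Σ_s N[s, s′] / t(s).

The per-start normalization matters: it weights every episode equally
rather than every *step* equally, so long episodes do not dominate the
prior. The alternative (normalizing the pooled visit counts once at the
end) was implemented and rejected because it changes the converged
answers materially (e.g. the decision information just below an
off-centre goal rises from 3.22 to 3.81 bits on the 5×5 grid) and
disagrees with the worked-example values the acceptance suite pins down.
Both steps are linear solves; no matrix inverse is formed.

## Free energy and the solver

F(s; β) = (1/β)·I_D(s) − V(s) is minimized over policies for a single
global β (no per-state information thresholds). The fixed point couples
three unknowns — policy, value/free energy, and prior — and is found by a
double iteration, initialized deterministically with the uniform policy
(whose live distribution and marginal give the initial prior) and F = 0:

1. **Inner loop** (prior fixed): exact policy evaluation of the linear
   free-energy recursion for the current policy (one solve on the
   transient block), then Boltzmann improvement
   π(a|s) ∝ p̂(a)·b^{β Q_F(s,a)} with
   Q_F(s,a) = Σ_{s′} P(s′|s,a)[r − F(s′)], until the L∞ change of F is
   below `inner_tol` (default 1e-9). The fixed point is the soft-min
   Bellman solution F(s) = −(1/β) log_b Σ_a p̂(a) b^{β Q_F(s,a)}.
   Evaluation-based sweeps are used instead of value-iteration-style
   sweeps because the latter contract at rate ≈ 1 − 1/T (T the expected
   absorption time) and become impractically slow in the near-open-loop
   regime where T ≈ 100.
2. **Outer loop**: recompute the live distribution and prior from the
   improved policy; stop when the prior's L∞ change is below `outer_tol`
   (default 1e-9). The update is undamped (a `damping` option exists);
   caps are 10⁴ inner sweeps and 5×10⁴ outer updates — at β ≈ 0.07 the
   outer iteration converges geometrically at rate ≈ 0.99 and needs a
   few thousand updates.

Numerical safeguards: logits are max-shifted before exponentiation,
0·log 0 := 0, and prior entries are floored at 1e-300 inside logarithms
only. Degenerate inputs (a grid that is all goal states) return the
trivial solution. Policy rows at goal states are reported as the action
prior — a display convention only; absorbing-state behaviour affects
nothing.

**Log base.** Information is measured in bits (base 2) by default, and the
same base is used inside the free-energy recursion — equivalent to running
the natural-log recursion at β·ln 2 — so the base changes the optimal
policy, not just the reported units. Base 2 reproduces the package's
pinned worked-example values (both the bit-valued decision informations
and the β-scaled free energies simultaneously); natural log is available
via `log_base`.

**Multi-stability.** At small β the coupled fixed point is not unique:
random policy initializations on the 7×7 grid at β = 0.07 reach distinct
self-consistent solutions, and acceleration tricks on the prior sequence
(Aitken extrapolation was prototyped) can silently switch basins — one
reason the outer loop is kept plain and the initialization deterministic.
Annealing β downward or upward merely selects other basins and is not
used. Consequently all solver outputs should be read as "the fixed point
reached by this fixed, documented schedule". Two worked-example
quantities in the near-open-loop regime are sensitive to this: the
direct corner free energy at β = 0.01 (we converge to 77.0; intermediate
iterates pass through ≈ 74) and the multi-subgoal route deviation at
β = 0.07 (we find −0.053; no fixed point or iterate of our schedule
reaches ≈ −0.20). The corresponding acceptance checks are left failing
rather than tuned.

## Distance geometry

`pairwise_free_energy` runs one solve per goal column, so d_ij is always
evaluated under the policy optimized for its own goal j; the chained-leg
semantics of the infodesic definitions (each segment under its own
optimal policy) is therefore automatic, and the "single-policy" and
"re-optimized segments" audit variants coincide on this matrix (the
report labels the mode `per-goal-policy`). The audit enumerates all
n(n−1)(n−2) ordered triples exactly; a triple violates the triangle
inequality when (d_ij + d_jk − d_ik)/d_ik < −tol.

Symmetrization is the element-wise mean with the transpose; it is only a
visualization device. Embeddings use metric MDS (SMACOF) on the
symmetrized matrix: the first start is the classical (Torgerson)
solution, remaining restarts are random (4 total), the best stress is
kept, and normalized stress-1 is reported. Coordinates are defined only
up to rigid motion; tests compare via stress or Procrustes alignment,
never coordinate-wise.

The "corner contraction" of the geometry under information constraints is
quantified *within* each β's metric: the symmetrized corner-to-corner
distance divided by the centre-to-corner distance on the 11×11 Moore grid
is 2.0 in the flat (large-β) regime and falls strictly as β decreases
through 100, 5, 0.3, 0.1. Normalizing instead by the flat-metric diameter
would show every distance inflating (the (1/β)·I_D term grows without
bound) and would miss the relative contraction.

## Infodesics

A sequence ⟨s₀ … s_N⟩ (2–5 distinct states) is scored by its per-leg free
energies, each leg read from the all-pairs matrix (equivalently, one
fresh solve per distinct goal in `chain_free_energy`). The normalized
difference is (Σ legs − direct)/direct — *negative when segmentation is
cheaper*. An ε-infodesic satisfies |normalized difference| < ε. The
exhaustive search fixes both endpoints and enumerates interim
permutations for total lengths 3–5 behind a candidate budget; the
full-grid interim histogram enumerates ordered three-state triples only,
keeping the combinatorics quadratic per middle state. No policy-switching
cost is charged anywhere; pricing the switch is exactly what the
triangle-inequality violations quantify, and a switching-cost term is out
of scope.

Trajectory sampling draws episodes under a fixed policy with an explicit
integer seed (mandatory), caps episodes at `max_steps` (default 10⁵,
counted and flagged if > 1% of episodes hit it) and reports the fraction
of episodes visiting each state at least once. Defaults: 10⁴ episodes.

## Problem sizes and test design

All quantitative checks run on 3×3–11×11 grids (≤ 121 states), the sizes
the framework's worked examples are defined on; the full suite solves a
few hundred free-energy problems, the largest single computation being
the 49-goal all-pairs matrix at β = 0.07 (about a minute). The synthetic
oracles are independent of the code paths they check: BFS distances come
from networkx on a separately constructed adjacency graph, search and
histogram results are compared against brute-force scans of the distance
matrix, Monte-Carlo rollouts cross-check the linear decision-information
solve (within 3 standard errors), and small-grid live distributions and
free energies are frozen from hand computations (e.g. the 1×3 grid's
live distribution (1/4, 3/4) and F(0) = 6 at β = 1 under a uniform
prior).

## Known limitations

- Only deterministic wall-bump dynamics are exercised; stochastic
  transitions are representable but untested.
- The solver returns one fixed point of a multi-stable system (see
  above); quantities in the β ≲ 0.1 regime depend on the schedule.
- Free energies mix units (bits with step counts) through 1/β; comparing
  F across different log bases requires rescaling β.
- MDS embeddings are qualitative; only stress and alignment-invariant
  statements are meaningful.
- Obstacles, penalized walls, discounting, memoryful agents and
  policy-switching costs are out of scope.
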