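"""Distance geometry induced by free energy.

Solving the free-energy problem once per goal state fills an n × n matrix
D with entries d_ij = F_{s_j}(s_i), the free energy of travelling from
state i to goal j under the policy optimized for that goal.  At large beta
D reduces to the plain grid distance; as beta shrinks, information costs
deform it — routes hugging walls and corners become relatively cheaper, and
D grows increasingly asymmetric.  This module assembles D, symmetrizes it
(D_sym = (D + D^T)/2) for visualization, embeds D_sym with metric MDS, and
audits the (quasi-)metric axioms exhaustively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.manifold import MDS

from .gridworld import GridSpec, build_gridworld
from .solver import SolverError, free_energy_solve

__all__ = [
    "DistanceMatrix",
    "QuasimetricReport",
    "EmbeddingResult",
    "pairwise_free_energy",
    "symmetrize",
    "mds_embed",
    "quasimetric_audit",
]


@dataclass
class DistanceMatrix:
    """All-pairs directed distances d_ij = cost of travelling i -> j."""

    D: np.ndarray
    beta: float | None = None
    symmetrized: bool = False
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2 or self.D.shape[0] != self.D.shape[1]:
            raise ValueError("distance matrix must be square")

    @property
    def n(self) -> int:
        return self.D.shape[0]


@dataclass
class QuasimetricReport:
    """Exhaustive audit of the quasi-metric axioms for a directed distance.

    ``d1_ok``/``d2_ok`` report non-negativity and identity of
    indiscernibles; ``triangle_violations`` counts ordered triples
    (i, j, k) with d_ik > d_ij + d_jk beyond the normalized tolerance.  The
    worst triple is the one with the largest normalized deviation
    (d_ij + d_jk − d_ik)/d_ik below zero; its magnitude is reported as a
    positive number.  Enumeration is exact, not sampled.
    """

    n: int
    d1_ok: bool
    d2_ok: bool
    triangle_violations: int
    total_triples: int
    worst_triple: tuple[int, int, int] | None
    worst_normalized_magnitude: float
    normalized_tol: float
    mode: str = "per-goal-policy"

    @property
    def is_quasimetric(self) -> bool:
        return self.d1_ok and self.d2_ok and self.triangle_violations == 0


@dataclass
class EmbeddingResult:
    """Low-dimensional MDS embedding of a symmetric distance matrix.

    Coordinates are defined only up to rotation/reflection/translation;
    compare embeddings via ``stress`` (normalized stress-1) or after
    Procrustes alignment, never coordinate-wise.
    """

    coordinates: np.ndarray
    stress: float
    dim: int
    seed: int


def pairwise_free_energy(
    spec: GridSpec, beta: float, log_base: float = 2.0, **solver_opts: Any
) -> DistanceMatrix:
    """All-pairs free-energy distance matrix for one gridworld and beta.

    Runs one :func:`free_energy_solve` per goal column, so every entry
    d_ij is evaluated under the policy optimized for *its own* goal j.
    The diagonal is exactly zero.
    """
    n = spec.n_states
    D = np.empty((n, n))
    for goal in range(n):
        try:
            sol = free_energy_solve(
                build_gridworld(spec, {goal}), beta, log_base=log_base, **solver_opts
            )
        except SolverError as exc:
            raise SolverError(f"goal {goal}: {exc}") from exc
        D[:, goal] = sol.F
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D=D, beta=beta, meta={"log_base": log_base})


def symmetrize(dm: DistanceMatrix) -> DistanceMatrix:
    """Element-wise mean of D and its transpose; idempotent."""
    return DistanceMatrix(
        D=(dm.D + dm.D.T) / 2.0,
        beta=dm.beta,
        symmetrized=True,
        meta=dict(dm.meta),
    )


def mds_embed(
    dm: DistanceMatrix,
    dim: int = 2,
    seed: int = 0,
    n_init: int = 4,
    max_iter: int = 2000,
    eps: float = 1e-12,
) -> EmbeddingResult:
    """Metric MDS embedding of a symmetric, zero-diagonal distance matrix.

    Keeps the best of ``n_init`` SMACOF restarts and reports normalized
    stress-1, sqrt(sum (d_emb − d)^2 / sum d^2).
    """
    if dim not in (2, 3):
        raise ValueError("embedding dimension must be 2 or 3")
    D = dm.D
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("MDS requires a symmetric matrix; symmetrize() first")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("MDS requires a zero diagonal")
    # classical (Torgerson) solution seeds the first SMACOF run; the
    # remaining restarts are random so curved geometries can still escape it
    best = None
    for k in range(n_init):
        mds = MDS(
            n_components=dim,
            metric="precomputed",
            metric_mds=True,
            n_init=1,
            init="classical_mds" if k == 0 else "random",
            max_iter=max_iter,
            eps=eps,
            random_state=seed + k,
            normalized_stress=False,
        )
        coords_k = mds.fit_transform(D)
        if best is None or mds.stress_ < best[0]:
            best = (mds.stress_, coords_k)
    coords = best[1]
    diff = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)) - D
    denom = (D**2).sum()
    stress1 = float(np.sqrt((diff**2).sum() / denom)) if denom > 0 else 0.0
    return EmbeddingResult(coordinates=coords, stress=stress1, dim=dim, seed=seed)


def quasimetric_audit(
    dm: DistanceMatrix, normalized_tol: float = 1e-9
) -> QuasimetricReport:
    """Exhaustively test the quasi-metric axioms on a directed distance.

    Checks non-negativity, identity of indiscernibles and, over all ordered
    triples (i, j, k) of distinct states, the triangle inequality
    d_ik <= d_ij + d_jk.  A triple counts as a violation when its
    normalized deviation (d_ij + d_jk − d_ik)/d_ik is below
    ``-normalized_tol``.
    """
    D = dm.D
    n = D.shape[0]
    d1_ok = bool(np.all(D >= -1e-12))
    off_diag = ~np.eye(n, dtype=bool)
    d2_ok = bool(np.allclose(np.diag(D), 0.0, atol=1e-12) and np.all(D[off_diag] > 0))

    # deviation[i, j, k] = (d_ij + d_jk - d_ik) / d_ik for distinct triples
    through = D[:, :, None] + D[None, :, :]
    direct = D[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        deviation = (through - direct) / np.where(direct > 0, direct, np.inf)
    idx = np.arange(n)
    distinct = (
        (idx[:, None, None] != idx[None, :, None])
        & (idx[None, :, None] != idx[None, None, :])
        & (idx[:, None, None] != idx[None, None, :])
    )
    deviation = np.where(distinct, deviation, np.inf)
    violating = deviation < -normalized_tol
    n_viol = int(violating.sum())
    total = int(n * (n - 1) * (n - 2))

    worst_triple = None
    worst_mag = 0.0
    if n >= 3:
        flat = int(np.argmin(deviation))
        i, j, k = np.unravel_index(flat, deviation.shape)
        if deviation[i, j, k] < -normalized_tol:
            worst_triple = (int(i), int(j), int(k))
            worst_mag = float(-deviation[i, j, k])

    return QuasimetricReport(
        n=n,
        d1_ok=d1_ok,
        d2_ok=d2_ok,
        triangle_violations=n_viol,
        total_triples=total,
        worst_triple=worst_triple,
        worst_normalized_magnitude=worst_mag,
        normalized_tol=normalized_tol,
    )
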