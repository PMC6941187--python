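"""Random walk with restart (Markov random walk) over the DEG network.

The walk iterates

    p^{t+1} = (1 − r) A' p^t + r p^0

from p^0 (uniform mass on the seed genes) until the L1 difference between
consecutive iterates drops below ``tol``.  Because A' is column-stochastic
the map is a contraction with factor (1 − r) in L1, so for the default
r = 0.5 and tol = 1e-4 convergence takes at most ~20 iterations and total
probability mass is conserved at every step.  The fixed point solves the
linear system (I − (1 − r) A') p = r p^0, which :func:`closed_form`
computes directly and serves as an independent check on the iteration.

The walk is fully deterministic: it is the power iteration of the expected
visiting-probability recurrence, not a Monte-Carlo simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, UsageError
from .ppi_network import PpiGraph, TransitionMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PropagationParams:
    """Walk parameters.

    r : restart rate in (0, 1]; each step this fraction of mass returns to
        the seed distribution, controlling how local the propagation is.
    tol : L1 stop tolerance on consecutive iterates.
    max_iter : safety cap; unreachable for sane inputs given the geometric
        contraction, guards pathological user-supplied matrices.
    """

    r: float = 0.5
    tol: float = 1e-4
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.r <= 1.0:
            raise UsageError(f"restart rate must be in (0, 1], got {self.r}")
        if self.tol <= 0:
            raise UsageError(f"tolerance must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise UsageError(f"max_iter must be >= 1, got {self.max_iter}")


@dataclass
class SeedVector:
    """p^0: uniform mass 1/k on each of the k seed genes present in the graph."""

    p0: np.ndarray
    seed_genes: set[str]
    dropped: set[str] = field(default_factory=set)


@dataclass
class ScoreVector:
    """Converged (or capped) propagation scores aligned to the node ordering."""

    p: np.ndarray
    iterations: int
    converged: bool


def make_seed_vector(graph: PpiGraph, seed_genes: set[str]) -> SeedVector:
    """Build p^0 from the seed genes, dropping any absent from the graph."""
    present = seed_genes & set(graph.nodes)
    dropped = seed_genes - present
    if not present:
        raise AnalysisError("no seed genes present in network")
    if dropped:
        log.warning(
            "%d seed genes absent from the network and dropped: %s",
            len(dropped),
            ", ".join(sorted(dropped)[:10]),
        )
    p0 = np.zeros(len(graph.nodes))
    for g in present:
        p0[graph.index[g]] = 1.0
    p0 /= p0.sum()
    return SeedVector(p0=p0, seed_genes=present, dropped=dropped)


def propagate(
    A_prime: TransitionMatrix,
    seed: SeedVector,
    params: PropagationParams = PropagationParams(),
) -> ScoreVector:
    """Iterate the restart walk to its fixed point.

    Stops when ||p^{t+1} − p^t||_1 < tol; if max_iter is hit first the last
    iterate is still returned with ``converged=False``.
    """
    M = A_prime.matrix
    p0 = seed.p0
    if M.shape[0] != p0.shape[0]:
        raise UsageError(
            f"dimension mismatch: matrix is {M.shape[0]}x{M.shape[1]}, "
            f"seed vector has {p0.shape[0]} entries"
        )
    r = params.r
    p = p0.copy()
    for t in range(1, params.max_iter + 1):
        p_next = (1.0 - r) * (M @ p) + r * p0
        if np.abs(p_next - p).sum() < params.tol:
            return ScoreVector(p=p_next, iterations=t, converged=True)
        p = p_next
    log.warning("propagation hit max_iter=%d without converging", params.max_iter)
    return ScoreVector(p=p, iterations=params.max_iter, converged=False)


def closed_form(
    A_prime: TransitionMatrix,
    seed: SeedVector,
    r: float = 0.5,
) -> ScoreVector:
    """Solve the stationary system (I − (1 − r) A') p = r p^0 exactly.

    For r > 0 and column-stochastic A' the system matrix is strictly
    diagonally dominant by columns, hence nonsingular.  Used as the
    independent oracle for the iterative path.
    """
    if r <= 0:
        raise UsageError(f"restart rate must be positive, got {r}")
    M = A_prime.matrix
    n = M.shape[0]
    try:
        p = np.linalg.solve(np.eye(n) - (1.0 - r) * M, r * seed.p0)
    except np.linalg.LinAlgError as exc:  # unreachable for stochastic A'
        raise AnalysisError(f"stationary system is singular: {exc}") from exc
    return ScoreVector(p=p, iterations=0, converged=True)
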