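"""Division kernels, transition matrix, and stationary size distribution.

States are 1-based cell sizes in ``l0`` units.  The transition matrix is
column-stochastic with ``P[n-1, m-1]`` the probability of moving from
size ``m`` to size ``n`` in one growth step: a cell of size ``m < N``
either grows to ``m + 1`` (probability ``1 - alpha``) or grows and
immediately divides (probability ``alpha``), in which case the followed
daughter's size is drawn from the division kernel.  A cell at the maximal
size ``N`` cannot grow; its column is the division kernel evaluated at
``m = N`` with the division probability forced to one, so the ``n = N``
outcome plays the role of "remain at the maximal size".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .errors import DomainError, NumericalError
from .params import ModelParams, validate_pattern

__all__ = [
    "TransitionMatrix",
    "SizeDistribution",
    "division_kernel",
    "build_transition_matrix",
    "stationary_distribution",
]


def division_kernel(pattern: str, m: int, N: int) -> np.ndarray:
    """Law of one daughter's size after a cell of size ``m`` grows one
    unit and divides.

    The mother's post-growth size is ``m + 1``; each daughter has at
    least one unit, so the daughter size ``n`` is supported on ``1..m``
    and the sibling has size ``m + 1 - n``.

    Parameters
    ----------
    pattern
        Division-pattern identifier: ``binomial`` (all prospective septa
        equiprobable), ``middle`` (cleavage at the centre), ``inverse_binomial``
        (cleavage biased towards the poles), or ``uniform``.
    m
        Pre-growth mother size, ``1 <= m <= N``.
    N
        Maximal size; only used for validation of ``m``.

    Returns
    -------
    numpy.ndarray
        Length-``m`` probability vector; entry ``n - 1`` is the
        probability of a daughter of size ``n``.
    """
    validate_pattern(pattern)
    if not 1 <= m <= N:
        raise DomainError(f"mother size m={m} outside [1, {N}]")
    m = int(m)
    n = np.arange(1, m + 1)
    if pattern == "binomial":
        # choosing n-1 of the m-1 inter-unit septa positions, all equiprobable
        pmf = binom.pmf(n - 1, m - 1, 0.5)
    elif pattern == "uniform":
        pmf = np.full(m, 1.0 / m)
    elif pattern == "inverse_binomial":
        if m == 1:
            pmf = np.array([1.0])
        else:
            pmf = (1.0 - binom.pmf(n - 1, m - 1, 0.5)) / (m - 1)
    else:  # middle
        pmf = np.zeros(m)
        if m % 2 == 1:
            pmf[(m + 1) // 2 - 1] = 1.0
        else:
            pmf[m // 2 - 1] = 0.5
            pmf[(m + 2) // 2 - 1] = 0.5
    return pmf


def _kernel_column(pattern: str, m: int, N: int) -> np.ndarray:
    """Division kernel embedded in a length-``N`` state vector."""
    col = np.zeros(N)
    col[:m] = division_kernel(pattern, m, N)
    return col


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic transition matrix of the growth/division chain.

    ``P[n-1, m-1]`` is the probability of obtaining a cell of size ``n``
    at the next step given that the cell (or its mother) had size ``m``.
    """

    P: np.ndarray
    params: ModelParams

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        N = self.params.N
        if P.shape != (N, N):
            raise DomainError(f"matrix shape {P.shape} does not match N={N}")
        colsums = P.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-12):
            raise NumericalError(
                f"columns not stochastic; max |sum-1| = {np.abs(colsums - 1).max():.3e}"
            )
        object.__setattr__(self, "P", P)

    @property
    def N(self) -> int:
        return self.params.N


@dataclass(frozen=True)
class SizeDistribution:
    """Probability vector over sizes 1..N.

    ``kind`` distinguishes the stationary size law ``stationary_p``, the
    per-step newborn law ``newborn_pi`` (sums to less than one: the
    remainder is the fraction of growing cells), and the birth-size law
    ``birth_pi_star``.
    """

    probs: np.ndarray
    kind: str
    params: ModelParams

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (self.params.N,):
            raise DomainError("distribution length does not match N")
        if probs.min() < -1e-12:
            raise NumericalError(f"negative probability {probs.min():.3e}")
        total = probs.sum()
        if self.kind in ("stationary_p", "birth_pi_star"):
            if abs(total - 1.0) > 1e-10:
                raise NumericalError(f"{self.kind} sums to {total}, expected 1")
        elif self.kind == "newborn_pi":
            if total > 1.0 + 1e-10:
                raise NumericalError(f"newborn_pi sums to {total} > 1")
        else:
            raise DomainError(f"unknown distribution kind {self.kind!r}")
        object.__setattr__(self, "probs", probs)

    @property
    def states(self) -> np.ndarray:
        return np.arange(1, self.params.N + 1)

    def mean(self) -> float:
        """Mean size, computed on the normalized distribution."""
        total = self.probs.sum()
        return float(self.states @ self.probs / total)


def build_transition_matrix(params: ModelParams) -> TransitionMatrix:
    """Assemble the full transition matrix for the given parameters.

    Interior columns ``m < N`` are
    ``(1 - alpha) * delta_{n, m+1} + alpha * kernel(m)``; the boundary
    column ``m = N`` is the division kernel at ``m = N`` alone (division
    probability forced to one, the ``n = N`` entry standing for "remain").
    """
    N, alpha, pattern = params.N, params.alpha, params.pattern
    P = np.zeros((N, N))
    for m in range(1, N):
        P[:, m - 1] = alpha * _kernel_column(pattern, m, N)
        P[m, m - 1] += 1.0 - alpha
    P[:, N - 1] = _kernel_column(pattern, N, N)
    return TransitionMatrix(P=P, params=params)


def division_channel(T: TransitionMatrix) -> np.ndarray:
    """The newborn-producing part of the transition matrix.

    For interior columns this is ``alpha * kernel(m)``; the boundary
    column is taken whole, since every outcome there is a division (or
    the degenerate "remain", which the kernel itself encodes).
    Used by the newborn-size law.
    """
    params = T.params
    N, alpha, pattern = params.N, params.alpha, params.pattern
    D = np.zeros((N, N))
    for m in range(1, N):
        D[:, m - 1] = alpha * _kernel_column(pattern, m, N)
    D[:, N - 1] = _kernel_column(pattern, N, N)
    return D


def stationary_distribution(T: TransitionMatrix, tol: float = 1e-10) -> SizeDistribution:
    """Solve ``(I - P) p = 0`` with the normalization ``sum(p) = 1``.

    One equation of the singular system is replaced by the normalization
    constraint, which is robust also for reducible chains (e.g. division
    by the middle at ``alpha = 1``, where high states are transient and
    carry zero stationary mass).  Entries in ``[-1e-12, 0)`` are clipped
    to zero and the vector renormalized.
    """
    P = T.P
    N = T.N
    A = np.eye(N) - P
    A[-1, :] = 1.0
    b = np.zeros(N)
    b[-1] = 1.0
    try:
        p = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        p, *_ = np.linalg.lstsq(A, b, rcond=None)
    p[(p < 0) & (p >= -1e-12)] = 0.0
    total = p.sum()
    if total <= 0 or p.min() < 0:
        raise NumericalError(
            f"no nonnegative normalized stationary solution (min entry {p.min():.3e})"
        )
    p /= total
    residual = np.abs(P @ p - p).max()
    if residual > tol:
        raise NumericalError(f"stationary residual {residual:.3e} exceeds {tol:.1e}")
    return SizeDistribution(probs=p, kind="stationary_p", params=T.params)
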