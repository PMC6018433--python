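"""Closed-form statistics of the stationary growth/division chain.

Quantities derived from the stationary size distribution ``p_st``:

* ``pi`` — per-step probability that a *newly born* cell has size ``n``
  (sums to less than one; the remainder is the growing-cell fraction);
* the reconstruction identity expressing ``p_st`` back in terms of
  ``pi`` via uninterrupted growth runs;
* ``pi_star`` — the birth-size law (probability that a cell was born
  with size ``n``), the model counterpart of an experimental
  size-at-birth histogram;
* the joint law of birth size ``m`` and size increment ``n`` at the next
  division, whose conditional mean gives the adder statistics: the mean
  increment ``<n>_m = (1 - (1-alpha)^(N-m)) / alpha`` is independent of
  the division pattern, tends to ``1/alpha`` for ``N >> 1``, and its
  slope in ``m`` at the origin tends to zero — the adder correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .markov import SizeDistribution, TransitionMatrix, build_transition_matrix, division_channel
from .params import ModelParams

__all__ = [
    "IncrementJoint",
    "AdderSummary",
    "newborn_distribution",
    "growing_fraction",
    "reconstruct_pst",
    "birth_size_distribution",
    "increment_joint",
    "mean_increment",
    "mean_increment_limit",
    "adder_slope",
    "adder_slope_limit",
    "adder_summary",
]


def _check_match(dist: SizeDistribution, params: ModelParams) -> None:
    if dist.params.N != params.N:
        raise DomainError(
            f"distribution built for N={dist.params.N}, expected N={params.N}"
        )


def newborn_distribution(p_st: SizeDistribution, params: ModelParams) -> SizeDistribution:
    """Per-step probability ``pi_n`` of observing a newborn of size ``n``.

    Sums the stationary flux through the division channel: the
    ``alpha``-weighted kernel for interior mothers and the whole boundary
    column for ``m = N``.  The total is below one; ``1 - sum(pi)`` is the
    fraction of cells that merely grew during the step.
    """
    _check_match(p_st, params)
    T = build_transition_matrix(params)
    D = division_channel(T)
    pi = D @ p_st.probs
    return SizeDistribution(probs=pi, kind="newborn_pi", params=params)


def growing_fraction(pi: SizeDistribution) -> float:
    """Fraction of cells that are growing (not newborn) at a given step."""
    return float(1.0 - pi.probs.sum())


def _growth_run_products(T: TransitionMatrix) -> np.ndarray:
    """``G[a, b] = prod_{k=a..b} P_{(k+1)k}`` for 1 <= a <= b <= N-1.

    Probability of growing uninterrupted from size ``a`` to ``b + 1``.
    Returned as an (N-1)x(N-1) array indexed ``[a-1, b-1]``; entries with
    ``b < a`` are 1 (empty product).
    """
    N = T.N
    sub = np.array([T.P[k, k - 1] for k in range(1, N)])  # P_{(k+1)k}, k=1..N-1
    G = np.ones((N - 1, N - 1))
    for a in range(1, N):
        for b in range(a, N):
            G[a - 1, b - 1] = G[a - 1, b - 2] * sub[b - 1] if b > a else sub[a - 1]
    return G


def reconstruct_pst(pi: SizeDistribution, T: TransitionMatrix) -> SizeDistribution:
    """Rebuild the stationary size law from the newborn law.

    A cell of size ``n`` is either a newborn of size ``n`` or was born at
    some ``m < n`` and grew ``n - m`` consecutive steps without dividing:
    ``p_n = pi_n + sum_{m<n} pi_m prod_{k=m..n-1} P_{(k+1)k}``.
    Serves as a consistency identity against the linear-system solution.
    """
    _check_match(pi, T.params)
    N = T.N
    G = _growth_run_products(T)
    p = pi.probs.copy()
    for n in range(2, N + 1):
        for m in range(1, n):
            p[n - 1] += pi.probs[m - 1] * G[m - 1, n - 2]
    return SizeDistribution(probs=p, kind="stationary_p", params=T.params)


def birth_size_distribution(pi: SizeDistribution, T: TransitionMatrix) -> SizeDistribution:
    """Birth-size law ``pi*_n``: probability that a cell was born at size ``n``.

    Collects newborns of size ``n`` together with all later steps at
    which they have grown but not yet divided,
    ``pi*_n = pi_n (1 + sum_{m>n} prod_{k=n..m-1} P_{(k+1)k})``,
    then normalizes across ``n`` — the normalized vector is the model
    counterpart of an experimental size-at-birth histogram.
    """
    _check_match(pi, T.params)
    N = T.N
    G = _growth_run_products(T)
    raw = pi.probs.copy()
    for n in range(1, N):
        raw[n - 1] *= 1.0 + sum(G[n - 1, m - 2] for m in range(n + 1, N + 1))
    total = raw.sum()
    if total <= 0:
        raise DomainError("newborn law has zero total mass")
    return SizeDistribution(probs=raw / total, kind="birth_pi_star", params=T.params)


@dataclass(frozen=True)
class IncrementJoint:
    """Joint law of birth size ``m`` and increment ``n`` at division.

    ``pstar[m-1, n-1]`` is the probability that a cell is born with size
    ``m`` and divides after adding exactly ``n`` units.  Not normalized:
    row and column sums are below one because not every step is a birth.
    """

    pstar: np.ndarray
    params: ModelParams

    def mean_increment_given_birth(self, m: int) -> float:
        """Empirical conditional mean ``<n>_m`` from the joint table."""
        row = self.pstar[m - 1]
        total = row.sum()
        if total == 0:
            raise DomainError(f"no division mass for birth size m={m}")
        n = np.arange(1, self.params.N + 1)
        return float(n @ row / total)


def increment_joint(pi: SizeDistribution, params: ModelParams) -> IncrementJoint:
    """Assemble the joint birth-size/increment table.

    ``p*_{m,n} = (alpha + delta_{n,N-m}(1-alpha)) pi_m (1-alpha)^{n-1}``
    supported on ``m < N`` and ``n <= N - m``; the boundary term collects
    cells that reach the maximal size and are then forced to divide.
    """
    _check_match(pi, params)
    N, alpha = params.N, params.alpha
    pstar = np.zeros((N, N))
    for m in range(1, N):  # theta(N - m): no mass for m = N
        for n in range(1, N - m + 1):  # theta(N - m + 1 - n)
            coef = alpha + (1.0 - alpha) * (n == N - m)
            pstar[m - 1, n - 1] = coef * pi.probs[m - 1] * (1.0 - alpha) ** (n - 1)
    return IncrementJoint(pstar=pstar, params=params)


def mean_increment(m: float, params: ModelParams) -> float:
    """Mean size increment ``<n>_m`` of a cell born with size ``m``.

    Closed form ``(1 - (1-alpha)^(N-m)) / alpha``; independent of the
    division pattern.  Non-integer ``m`` is accepted as the analytic
    continuation (useful for derivative checks).
    """
    alpha, N = params.alpha, params.N
    if alpha == 0:
        raise DomainError(
            f"mean increment undefined at alpha=0 (deterministic limit is N - m = {N - m})"
        )
    if not 0 < m < N:
        raise DomainError(f"birth size m={m} outside (0, N={N})")
    return (1.0 - (1.0 - alpha) ** (N - m)) / alpha


def mean_increment_limit(alpha: float) -> float:
    """``N -> infinity`` limit of the mean increment: ``1/alpha``."""
    if not 0 < alpha <= 1:
        raise DomainError(f"alpha must be in (0, 1], got {alpha}")
    return 1.0 / alpha


def adder_slope(params: ModelParams) -> float:
    """Slope of ``<n>_m`` in ``m`` at the smallest birth size,
    ``(1-alpha)^(N-1) ln(1-alpha) / alpha``.

    Negative for finite ``N`` and vanishing as ``N -> infinity``: the mean
    increment becomes independent of birth size, the adder correlation.
    """
    alpha, N = params.alpha, params.N
    if alpha <= 0 or alpha >= 1:
        raise DomainError(
            "adder slope defined for 0 < alpha < 1 "
            "(one-sided limits: 0 as alpha -> 1, -(N-1)/1 scaling as alpha -> 0)"
        )
    return (1.0 - alpha) ** (N - 1) * np.log(1.0 - alpha) / alpha


def adder_slope_limit(alpha: float) -> float:
    """``N -> infinity`` limit of the adder slope: exactly zero."""
    if alpha <= 0 or alpha >= 1:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    return 0.0


@dataclass(frozen=True)
class AdderSummary:
    """Mean increment per birth size plus the adder diagnostics."""

    mean_increment_by_birth: np.ndarray  # <n>_m for m = 1..N-1
    slope_at_origin: float
    limit_increment: float
    params: ModelParams


def adder_summary(params: ModelParams) -> AdderSummary:
    """Evaluate the adder statistics for all birth sizes ``m = 1..N-1``."""
    means = np.array([mean_increment(m, params) for m in range(1, params.N)])
    return AdderSummary(
        mean_increment_by_birth=means,
        slope_at_origin=adder_slope(params),
        limit_increment=mean_increment_limit(params.alpha),
        params=params,
    )
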