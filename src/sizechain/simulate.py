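"""Seeded single-lineage Monte Carlo of the growth/division chain.

Each growth step a cell of size ``m < N`` grows one unit; with
probability ``alpha`` the step ends in a division and the followed cell's
new size is drawn from the division kernel (equivalent to following one
daughter chosen by the kernel's own law, which is exactly the dynamics
the population recursion propagates).  At the maximal size ``N`` the
boundary column applies: the cell divides according to the kernel at
``m = N`` — a drawn outcome of ``N`` means it remains at the maximal
size.  The chain is ergodic, so a single long trajectory yields the
steady-state size statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, EmptyStatisticsError
from .markov import division_kernel
from .params import ModelParams

__all__ = [
    "Trajectory",
    "EmpiricalStats",
    "simulate_lineage",
    "collect_statistics",
    "convergence_experiment",
]


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered record of one simulated lineage.

    ``sizes[t]`` is the cell size after step ``t`` (``sizes[0]`` is the
    initial size).  Division events are stored columnwise: the step at
    which each division occurred, the dividing cell's size at birth, the
    size increment it had accumulated (division size minus birth size),
    the followed daughter's size, the post-growth mother size, and the
    division ratio (daughter over post-growth mother).
    """

    sizes: np.ndarray
    event_steps: np.ndarray
    event_birth_sizes: np.ndarray
    event_increments: np.ndarray
    event_daughters: np.ndarray
    event_division_sizes: np.ndarray
    event_ratios: np.ndarray
    burn_in: int
    seed: int
    params: ModelParams

    @property
    def n_events(self) -> int:
        return len(self.event_steps)

    def post_burn_in_mask(self) -> np.ndarray:
        return self.event_steps >= self.burn_in


@dataclass(frozen=True)
class EmpiricalStats:
    """Empirical steady-state summaries of a trajectory.

    ``pi_star_hat`` is a per-step census of the live cell's size at
    birth, the empirical counterpart of the birth-size law: cells that
    grow longer before dividing are represented at every step they are
    alive, exactly as in a population snapshot.
    """

    p_hat: np.ndarray  # state frequencies over post-burn-in steps
    pi_star_hat: np.ndarray  # per-step birth-size census over post-burn-in steps
    mean_increment_by_birth: dict  # m -> (mean, sd, se, count)
    ratios: np.ndarray
    n_steps: int
    n_events: int


def _kernel_cdfs(params: ModelParams) -> list[np.ndarray]:
    """Cumulative division kernels for every mother size 1..N."""
    return [np.cumsum(division_kernel(params.pattern, m, params.N)) for m in range(1, params.N + 1)]


def simulate_lineage(
    params: ModelParams,
    steps: int,
    burn_in: int | None = None,
    seed: int = 0,
    initial_size: int = 1,
) -> Trajectory:
    """Simulate one lineage for a fixed number of growth steps.

    Parameters
    ----------
    params
        Chain parameters.
    steps
        Number of growth steps.
    burn_in
        Steps discarded when computing steady-state statistics; defaults
        to ``steps // 3`` (a third of the run).
    seed
        Seed of the per-lineage random stream; identical inputs give
        identical trajectories.
    initial_size
        Size of the founding cell, ``1 <= initial_size <= N``.
    """
    if burn_in is None:
        burn_in = steps // 3
    if not steps > burn_in >= 0:
        raise DomainError(f"need steps > burn_in >= 0, got steps={steps}, burn_in={burn_in}")
    if not 1 <= initial_size <= params.N:
        raise DomainError(f"initial size {initial_size} outside [1, {params.N}]")

    N, alpha = params.N, params.alpha
    cdfs = _kernel_cdfs(params)
    rng = np.random.default_rng(seed)
    u_div = rng.random(steps)  # division decision at interior states
    u_kern = rng.random(steps)  # daughter-size draw

    sizes = np.empty(steps + 1, dtype=np.int64)
    sizes[0] = initial_size
    ev_step: list[int] = []
    ev_birth: list[int] = []
    ev_incr: list[int] = []
    ev_daughter: list[int] = []
    ev_divsize: list[int] = []

    size = initial_size
    birth_size = initial_size
    for t in range(steps):
        if size < N:
            if u_div[t] < alpha:
                post = size + 1
                daughter = int(np.searchsorted(cdfs[size - 1], u_kern[t], side="right")) + 1
                ev_step.append(t)
                ev_birth.append(birth_size)
                ev_incr.append(post - birth_size)
                ev_daughter.append(daughter)
                ev_divsize.append(post)
                size = daughter
                birth_size = daughter
            else:
                size += 1
        else:
            outcome = int(np.searchsorted(cdfs[N - 1], u_kern[t], side="right")) + 1
            if outcome < N:
                # boundary division: daughters sum to N
                ev_step.append(t)
                ev_birth.append(birth_size)
                ev_incr.append(N - birth_size)
                ev_daughter.append(outcome)
                ev_divsize.append(N)
                size = outcome
                birth_size = outcome
            # outcome == N: remain at the maximal size
        sizes[t + 1] = size

    ev_step_a = np.array(ev_step, dtype=np.int64)
    ev_divsize_a = np.array(ev_divsize, dtype=np.int64)
    ev_daughter_a = np.array(ev_daughter, dtype=np.int64)
    return Trajectory(
        sizes=sizes,
        event_steps=ev_step_a,
        event_birth_sizes=np.array(ev_birth, dtype=np.int64),
        event_increments=np.array(ev_incr, dtype=np.int64),
        event_daughters=ev_daughter_a,
        event_division_sizes=ev_divsize_a,
        event_ratios=ev_daughter_a / np.maximum(ev_divsize_a, 1),
        burn_in=burn_in,
        seed=seed,
        params=params,
    )


def collect_statistics(traj: Trajectory) -> EmpiricalStats:
    """Empirical steady-state statistics over the post-burn-in window."""
    mask = traj.post_burn_in_mask()
    if not mask.any():
        raise EmptyStatisticsError("no division events after burn-in")
    N = traj.params.N
    post_sizes = traj.sizes[traj.burn_in + 1 :]
    p_hat = np.bincount(post_sizes, minlength=N + 1)[1:].astype(float)
    p_hat /= p_hat.sum()

    # per-step census: the birth size of the cell alive after step u is
    # the followed daughter of the latest division at a step <= u - 1
    # (the founder's size stands in before the first division); a step
    # spent "remaining" at the maximal size counts as a rebirth at N,
    # matching the boundary column's n = N entry in the newborn law
    u = np.arange(traj.burn_in + 1, len(traj.sizes))
    j = np.searchsorted(traj.event_steps, u - 1, side="right")
    birth_census = np.where(
        j > 0, traj.event_daughters[np.maximum(j - 1, 0)], traj.sizes[0]
    )
    remained_at_top = (traj.sizes[u] == N) & (traj.sizes[u - 1] == N)
    birth_census = np.where(remained_at_top, N, birth_census)
    pi_star_hat = np.bincount(birth_census, minlength=N + 1)[1:].astype(float)
    pi_star_hat /= pi_star_hat.sum()

    by_birth: dict[int, tuple[float, float, float, int]] = {}
    bs = traj.event_birth_sizes[mask]
    incr = traj.event_increments[mask]
    for m in np.unique(bs):
        vals = incr[bs == m].astype(float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        by_birth[int(m)] = (
            float(vals.mean()),
            sd,
            sd / np.sqrt(len(vals)) if len(vals) > 1 else np.inf,
            int(len(vals)),
        )
    return EmpiricalStats(
        p_hat=p_hat,
        pi_star_hat=pi_star_hat,
        mean_increment_by_birth=by_birth,
        ratios=traj.event_ratios[mask],
        n_steps=len(post_sizes),
        n_events=int(mask.sum()),
    )


def convergence_experiment(
    params: ModelParams,
    n_lineages: int,
    generations: int,
    initial_size: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Birth size per generation for a bundle of independent lineages.

    Follows each lineage until it has divided ``generations`` times;
    lineage ``i`` uses seed ``seed + i``.  Returns an array of shape
    ``(n_lineages, generations + 1)`` whose column ``g`` holds the birth
    size at generation ``g`` (column 0 is the initial size) together with
    the cross-lineage mean per generation.  Starting from either one unit
    or many, the mean converges to ``1/alpha`` within a few generations.
    """
    if n_lineages < 1:
        raise DomainError("need at least one lineage")
    if not 1 <= initial_size <= params.N:
        raise DomainError(f"initial size {initial_size} outside [1, {params.N}]")
    N, alpha = params.N, params.alpha
    cdfs = _kernel_cdfs(params)
    births = np.empty((n_lineages, generations + 1), dtype=np.int64)
    births[:, 0] = initial_size
    for i in range(n_lineages):
        rng = np.random.default_rng(seed + i)
        size = initial_size
        g = 0
        while g < generations:
            if size < N:
                if rng.random() < alpha:
                    daughter = int(np.searchsorted(cdfs[size - 1], rng.random(), side="right")) + 1
                    g += 1
                    births[i, g] = daughter
                    size = daughter
                else:
                    size += 1
            else:
                outcome = int(np.searchsorted(cdfs[N - 1], rng.random(), side="right")) + 1
                if outcome < N:
                    g += 1
                    births[i, g] = outcome
                    size = outcome
    return births, births.mean(axis=0)
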