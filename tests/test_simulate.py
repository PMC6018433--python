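"""Lineage Monte Carlo: determinism, ergodic agreement, convergence."""

import numpy as np
import pytest

import sizechain as sc
from sizechain.errors import DomainError, EmptyStatisticsError
from sizechain.simulate import Trajectory

from conftest import batch_se


def test_seed_determinism():
    params = sc.ModelParams(0.3, 20, "uniform")
    a = sc.simulate_lineage(params, 5000, 1000, seed=7)
    b = sc.simulate_lineage(params, 5000, 1000, seed=7)
    np.testing.assert_array_equal(a.sizes, b.sizes)
    np.testing.assert_array_equal(a.event_daughters, b.event_daughters)
    c = sc.simulate_lineage(params, 5000, 1000, seed=8)
    assert not np.array_equal(a.sizes, c.sizes)


def test_alpha_one_binomial_from_unit_cell():
    # the only possible history: grow 1 -> 2, split into 1 + 1, repeat
    params = sc.ModelParams(1.0, 20, "binomial")
    traj = sc.simulate_lineage(params, 2000, 100, seed=0, initial_size=1)
    assert (traj.sizes == 1).all()
    assert (traj.event_daughters == 1).all()
    assert (traj.event_increments == 1).all()
    assert (traj.event_ratios == 0.5).all()


def test_step_bookkeeping_and_mass_conservation():
    params = sc.ModelParams(0.2, 20, "inverse_binomial")
    traj = sc.simulate_lineage(params, 50_000, 5000, seed=3)
    # consecutive sizes either grow by one or jump to a kernel daughter
    diffs = np.diff(traj.sizes)
    growth = diffs == 1
    stay_at_top = (diffs == 0) & (traj.sizes[:-1] == params.N)
    divided = np.zeros(len(diffs), dtype=bool)
    divided[traj.event_steps] = True
    assert (growth | stay_at_top | divided).all()
    # daughter plus implied sibling reconstruct the post-growth mother
    sibling = traj.event_division_sizes - traj.event_daughters
    assert (sibling >= 1).all() or params.alpha == 1.0
    assert (traj.event_daughters >= 1).all()
    assert (traj.event_increments >= 1).all()


@pytest.mark.parametrize("pattern", sc.PATTERNS)
def test_empirical_state_frequencies_match_stationary(pattern, filamentous_trajectories):
    traj = filamentous_trajectories[pattern]
    stats = sc.collect_statistics(traj)
    T = sc.build_transition_matrix(traj.params)
    pst = sc.stationary_distribution(T)
    se = batch_se(traj.sizes[traj.burn_in + 1 :], traj.params.N)
    tol = np.maximum(3 * se, 1e-4)
    assert (np.abs(stats.p_hat - pst.probs) < tol).all()


@pytest.mark.parametrize("pattern", sc.PATTERNS)
def test_empirical_birth_sizes_match_birth_law(pattern, filamentous_trajectories):
    traj = filamentous_trajectories[pattern]
    stats = sc.collect_statistics(traj)
    params = traj.params
    T = sc.build_transition_matrix(params)
    pst = sc.stationary_distribution(T)
    pi = sc.newborn_distribution(pst, params)
    pistar = sc.birth_size_distribution(pi, T)
    n_births = stats.n_events
    se = np.sqrt(pistar.probs * (1 - pistar.probs) / n_births)
    tol = np.maximum(4 * se, 5e-4)
    assert (np.abs(stats.pi_star_hat - pistar.probs) < tol).all()


@pytest.mark.parametrize("pattern", sc.PATTERNS)
def test_mean_increment_matches_closed_form(pattern, filamentous_trajectories):
    # <n>_m is pattern independent and equals (1-(1-a)^(N-m))/a
    traj = filamentous_trajectories[pattern]
    stats = sc.collect_statistics(traj)
    params = traj.params
    checked = 0
    for m, (mean, sd, se, count) in stats.mean_increment_by_birth.items():
        if count < 50 or m >= params.N:
            continue
        assert abs(mean - sc.mean_increment(m, params)) < max(3 * se, 0.05), f"m={m}"
        checked += 1
    assert checked >= 5


def test_collect_statistics_arithmetic():
    # two completed cells born at size 1 with increments 1 and 3 -> mean 2
    params = sc.ModelParams(0.5, 10, "binomial")
    traj = Trajectory(
        sizes=np.array([1, 2, 1, 2, 3, 4, 1]),
        event_steps=np.array([1, 5]),
        event_birth_sizes=np.array([1, 1]),
        event_increments=np.array([1, 3]),
        event_daughters=np.array([1, 1]),
        event_division_sizes=np.array([2, 4]),
        event_ratios=np.array([0.5, 0.25]),
        burn_in=0,
        seed=0,
        params=params,
    )
    stats = sc.collect_statistics(traj)
    assert stats.mean_increment_by_birth[1][0] == pytest.approx(2.0)
    assert stats.n_events == 2


def test_middle_pattern_ratios_are_half_up_to_discreteness():
    params = sc.ModelParams(0.87, 20, "middle")
    traj = sc.simulate_lineage(params, 50_000, 5000, seed=11)
    stats = sc.collect_statistics(traj)
    # odd post-growth sizes cannot split exactly in half; never beyond one unit off
    assert (np.abs(stats.ratios - 0.5) <= 0.5 / 3 + 1e-12).all()
    assert np.median(np.abs(stats.ratios - 0.5)) < 0.1


def test_no_events_raises():
    params = sc.ModelParams(0.0, 50, "binomial")
    traj = sc.simulate_lineage(params, 20, 10, seed=0, initial_size=1)
    with pytest.raises(EmptyStatisticsError):
        sc.collect_statistics(traj)


def test_invalid_simulation_arguments():
    params = sc.ModelParams(0.5, 10)
    with pytest.raises(DomainError):
        sc.simulate_lineage(params, 100, 100, seed=0)
    with pytest.raises(DomainError):
        sc.simulate_lineage(params, 100, 10, seed=0, initial_size=11)


class TestConvergence:
    def test_alpha_one_mean_birth_size_is_one(self):
        params = sc.ModelParams(1.0, 20, "binomial")
        births, mean = sc.convergence_experiment(params, 20, 10, initial_size=1, seed=0)
        np.testing.assert_allclose(mean[1:], 1.0)

    @pytest.mark.parametrize("initial_size", [20, 1])
    def test_converges_to_inverse_alpha_from_both_sides(self, initial_size):
        params = sc.ModelParams(0.1, 100, "binomial")
        births, mean = sc.convergence_experiment(
            params, 150, 40, initial_size=initial_size, seed=5
        )
        tail = mean[-10:]
        se = births[:, -10:].mean(axis=1).std(ddof=1) / np.sqrt(150)
        assert abs(tail.mean() - 10.0) < max(4 * se, 0.5)

    def test_lineages_use_distinct_streams(self):
        params = sc.ModelParams(0.5, 20, "uniform")
        births, _ = sc.convergence_experiment(params, 5, 20, initial_size=5, seed=1)
        assert len({tuple(row) for row in births}) > 1
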