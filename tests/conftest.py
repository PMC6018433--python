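import numpy as np
import pytest

import sizechain as sc


@pytest.fixture(scope="session")
def wildtype_population() -> sc.PopulationSample:
    """Synthetic wild-type population at the default study conditions
    (alpha = 0.87, l0 = 3.6 um, delta_l0 = 0.5 um, binomial, 3000 cells)."""
    return sc.generate_population(sc.GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def wildtype_histograms(wildtype_population):
    """Binned size and size-at-birth histograms of the wild-type sample."""
    pop = wildtype_population
    hp = sc.bin_lengths(pop.snapshot_lengths, 3.6)
    hpi = sc.bin_lengths(pop.birth_lengths, 3.6, source="size-at-birth")
    return hp, hpi


@pytest.fixture(scope="session")
def filamentous_trajectories():
    """One long lineage per pattern at alpha = 0.1, N = 20 (filamentous
    regime where the patterns differ)."""
    out = {}
    for i, pattern in enumerate(sc.PATTERNS):
        params = sc.ModelParams(alpha=0.1, N=20, pattern=pattern)
        out[pattern] = sc.simulate_lineage(params, steps=200_000, burn_in=20_000, seed=100 + i)
    return out


def batch_se(values: np.ndarray, n_states: int, n_batches: int = 30) -> np.ndarray:
    """Monte Carlo standard error of state frequencies from a correlated
    trajectory, via batch means."""
    values = np.asarray(values)
    usable = len(values) - len(values) % n_batches
    batches = values[:usable].reshape(n_batches, -1)
    freqs = np.stack(
        [np.bincount(b, minlength=n_states + 1)[1:n_states + 1] / batches.shape[1] for b in batches]
    )
    return freqs.std(axis=0, ddof=1) / np.sqrt(n_batches)
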