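"""Seeded generator of continuous-length single-cell data and
fluorescence profiles.

Emulates the data the estimation pipeline consumes: lineages are
simulated on the discrete chain and each discrete size ``s`` is mapped to
a continuous length ``s * l0`` plus Gaussian jitter of standard deviation
``delta_l0 * sqrt(s)`` (unit-scale noise accumulates with the number of
units), truncated to stay positive.  Division events carry both
daughters, whose discrete sizes sum to the post-growth mother size, so
the emitted mother length is the sum of the two jittered daughter
lengths.  Fluorescence profiles are sums of Gaussian peaks at the septum
spacing ``lambda`` with multiplicative noise, sampled at a fixed spatial
resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .params import ModelParams
from .simulate import simulate_lineage

__all__ = ["GeneratorConfig", "PopulationSample", "generate_population", "generate_profiles"]

#: default spatial sampling of fluorescence profiles (um per pixel)
PROFILE_RESOLUTION_UM = 0.065


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic single-cell data.

    Defaults match a wild-type population: division efficiency 0.87,
    unit size 3.6 um with spread 0.5 um, binomial division pattern, a
    state cap of 20 units, and a septum spacing of 8.3 um for the
    fluorescence profiles.
    """

    alpha: float = 0.87
    N: int = 20
    pattern: str = "binomial"
    l0: float = 3.6
    delta_l0: float = 0.5
    n_cells: int = 3000
    lambda_profile: float = 8.3
    profile_noise: float = 0.1
    seed: int = 0
    filament_fraction: float = 0.0  # optional contaminating long-birth fraction

    def __post_init__(self) -> None:
        if min(self.l0, self.lambda_profile) <= 0 or self.delta_l0 < 0:
            raise DomainError("l0 and lambda must be positive, delta_l0 nonnegative")
        if self.n_cells < 1:
            raise DomainError("need at least one cell")
        if not 0 <= self.filament_fraction < 1:
            raise DomainError("filament fraction must be in [0, 1)")
        if self.profile_noise < 0:
            raise DomainError("profile noise must be nonnegative")
        if self.delta_l0 / self.l0 > 0.3:
            warnings.warn(
                "delta_l0/l0 > 0.3: the binning scheme assumes small relative "
                "fluctuations around l0",
                stacklevel=2,
            )

    def model_params(self) -> ModelParams:
        return ModelParams(alpha=self.alpha, N=self.N, pattern=self.pattern, l0=self.l0)


@dataclass(frozen=True)
class PopulationSample:
    """Synthetic single-cell tables.

    ``cells`` is the lineage cell table (cell_id, mother_id,
    birth_length_um, division_length_um; the last followed cell has no
    recorded division); ``events`` lists division events with both
    daughters; ``snapshot_lengths`` are per-step cell lengths, the
    continuous counterpart of the stationary size distribution.
    """

    cells: pd.DataFrame
    events: pd.DataFrame
    snapshot_lengths: np.ndarray
    config: GeneratorConfig

    @property
    def birth_lengths(self) -> np.ndarray:
        return self.cells["birth_length_um"].to_numpy(float)


def _jitter(states: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Map discrete sizes to continuous lengths with truncated jitter."""
    states = np.asarray(states, dtype=float)
    lengths = states * cfg.l0 + rng.normal(0.0, 1.0, states.shape) * cfg.delta_l0 * np.sqrt(states)
    bad = lengths <= 0
    while bad.any():  # truncation: redraw the (rare) nonpositive lengths
        lengths[bad] = states[bad] * cfg.l0 + rng.normal(
            0.0, 1.0, int(bad.sum())
        ) * cfg.delta_l0 * np.sqrt(states[bad])
        bad = lengths <= 0
    return lengths


def generate_population(cfg: GeneratorConfig) -> PopulationSample:
    """Generate a continuous-length single-cell population.

    Simulates one lineage on the discrete chain until ``n_cells``
    post-burn-in division events are available, then assigns continuous
    lengths.  Each event records the followed daughter (which seeds the
    next cell) and its sibling; the mother's division length is the sum
    of the two jittered daughter lengths, so events are exactly
    mass-consistent.  Byte-identical output for identical configurations.
    """
    params = cfg.model_params()
    burn_in = 1000
    steps = burn_in + int(cfg.n_cells / max(cfg.alpha, 0.02) * 3) + 1000
    for _ in range(10):
        traj = simulate_lineage(params, steps=steps, burn_in=burn_in, seed=cfg.seed)
        if traj.post_burn_in_mask().sum() > cfg.n_cells:
            break
        steps *= 2
    mask = traj.post_burn_in_mask()
    idx = np.flatnonzero(mask)[: cfg.n_cells + 1]

    birth_states = traj.event_birth_sizes[idx]  # dividing cell's size at birth
    div_states = traj.event_division_sizes[idx]  # post-growth mother size
    d1_states = traj.event_daughters[idx]
    d2_states = div_states - d1_states  # sibling; zero only at the boundary "remain"

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**20]))
    first_birth = _jitter(birth_states[:1], cfg, rng)
    d1_lengths = _jitter(d1_states, cfg, rng)
    d2_lengths = _jitter(d2_states, cfg, rng)

    # lineage bookkeeping: event i divides cell i, whose followed daughter
    # is cell i+1; cell i's birth length must match how it was created.
    # Cells cannot shrink, so daughter jitters are redrawn (rarely) until
    # every division length exceeds the dividing cell's birth length.
    n_ev = len(idx)
    cell_birth = np.empty(n_ev)
    cell_birth[0] = first_birth[0]
    for _ in range(1000):
        cell_birth[1:] = d1_lengths[:-1]  # daughter length carried over as next birth
        bad = d1_lengths + d2_lengths <= cell_birth
        if not bad.any():
            break
        d1_lengths[bad] = _jitter(d1_states[bad], cfg, rng)
        d2_lengths[bad] = _jitter(d2_states[bad], cfg, rng)
    mother_lengths = d1_lengths + d2_lengths
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_ev),
            "mother_id": np.concatenate(([np.nan], np.arange(n_ev - 1))),
            "birth_length_um": cell_birth,
            "division_length_um": mother_lengths,
        }
    )
    # last followed daughter: born but division not observed
    tail = pd.DataFrame(
        {
            "cell_id": [n_ev],
            "mother_id": [float(n_ev - 1)],
            "birth_length_um": [d1_lengths[-1]],
            "division_length_um": [np.nan],
        }
    )
    cells = pd.concat([cells, tail], ignore_index=True)

    if cfg.filament_fraction > 0:
        k = int(round(cfg.filament_fraction * len(cells)))
        states = rng.integers(3, max(4, cfg.N // 2) + 1, size=k)
        contaminants = pd.DataFrame(
            {
                "cell_id": np.arange(len(cells), len(cells) + k),
                "mother_id": np.full(k, np.nan),
                "birth_length_um": _jitter(states, cfg, rng),
                "division_length_um": np.full(k, np.nan),
            }
        )
        cells = pd.concat([cells, contaminants], ignore_index=True)

    events = pd.DataFrame(
        {
            "mother_id": np.arange(n_ev),
            "mother_state": div_states,
            "mother_length": mother_lengths,
            "daughter1_length": d1_lengths,
            "daughter2_length": d2_lengths,
        }
    )
    events = events[d2_states > 0].reset_index(drop=True)  # drop boundary "remain" outcomes

    snapshot_states = traj.sizes[burn_in + 1 :]
    snapshot_lengths = _jitter(snapshot_states, cfg, rng)
    return PopulationSample(
        cells=cells, events=events, snapshot_lengths=snapshot_lengths, config=cfg
    )


def generate_profiles(
    cfg: GeneratorConfig,
    cell_lengths: np.ndarray,
    resolution_um: float = PROFILE_RESOLUTION_UM,
    peak_width: float | None = None,
) -> pd.DataFrame:
    """Synthesize axial fluorescence profiles with periodic ring signal.

    Each cell of length ``L >= lambda`` gets Gaussian intensity peaks at
    positions ``lambda/2 + k*lambda`` from the pole (peak width
    ``lambda/10`` by default), sampled every ``resolution_um``, with
    multiplicative Gaussian noise of relative standard deviation
    ``profile_noise``.  Cells shorter than one period are skipped with a
    warning.  Returns a long-format frame (cell_id, position_um,
    intensity).
    """
    lam = cfg.lambda_profile
    if peak_width is None:
        peak_width = lam / 10.0
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**21]))
    frames = []
    n_skipped = 0
    for cid, L in enumerate(np.asarray(cell_lengths, dtype=float)):
        if L < lam:
            n_skipped += 1
            continue
        x = np.arange(0.0, L, resolution_um)
        centers = np.arange(lam / 2.0, L, lam)
        intensity = np.exp(
            -0.5 * ((x[:, None] - centers[None, :]) / peak_width) ** 2
        ).sum(axis=1)
        if cfg.profile_noise > 0:
            intensity = np.clip(
                intensity * (1.0 + rng.normal(0.0, cfg.profile_noise, len(x))), 0.0, None
            )
        frames.append(pd.DataFrame({"cell_id": cid, "position_um": x, "intensity": intensity}))
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} cells shorter than one septum period", stacklevel=2
        )
    if not frames:
        raise DomainError("no cell is at least one septum period long")
    return pd.concat(frames, ignore_index=True)
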