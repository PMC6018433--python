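"""Estimation pipeline for continuous single-cell length data.

Turns measured lengths (micrometres) into the chain's dimensionless
quantities and back:

* three estimators of the unit size ``l0`` — the filtered size-at-birth
  mean, mother/daughter length differences, and the spectral septum
  spacing of fluorescence profiles (``l0 = lambda / 2``);
* binning of continuous lengths into ``l0`` states with boxes of unit
  width centred on integer multiples of ``l0``;
* the division-efficiency fit: a double regression of the binned size
  and size-at-birth histograms against the model's stationary and
  birth-size laws, minimizing
  ``eps^2 = (1/(N-1)) sum (pi*_exp - pi*_theo)^2 + (1/N) sum (p_exp - p_theo)^2``;
* the histogram-collapse estimate of ``l0`` for a second growth
  condition sharing the same ``alpha``; and the sensitivity analysis of
  the fitted ``alpha`` to the uncertainty in ``l0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .analytics import birth_size_distribution, newborn_distribution
from .errors import (
    DegenerateSampleError,
    DomainError,
    FitDegenerateError,
    PeakNotFoundError,
)
from .markov import build_transition_matrix, stationary_distribution
from .params import ModelParams, validate_pattern

__all__ = [
    "L0BirthEstimate",
    "MotherDaughterEstimate",
    "SpectralEstimate",
    "BinnedHistogram",
    "AlphaFit",
    "CollapseResult",
    "SensitivityResult",
    "estimate_l0_birth",
    "estimate_l0_mother_daughter",
    "estimate_l0_spectral",
    "bin_lengths",
    "ballpark_alpha",
    "theory_histograms",
    "fit_alpha",
    "bootstrap_alpha",
    "collapse_l0",
    "sensitivity_analysis",
]


# ---------------------------------------------------------------------------
# l0 estimators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class L0BirthEstimate:
    """Unit size from the filtered size-at-birth distribution."""

    l0: float
    spread: float
    cutoff: float
    n_total: int
    n_retained: int


def estimate_l0_birth(birth_lengths: Sequence[float]) -> L0BirthEstimate:
    """Estimate ``l0`` as the mean birth length of non-filamentous cells.

    Computes the mean and standard deviation of the full sample, discards
    cells with a Z-score above one (birth length beyond mean + sd, a
    single pass), and returns the mean and standard deviation of the
    retained subsample as ``l0`` and its spread ``delta_l0``.
    """
    lb = np.asarray(birth_lengths, dtype=float)
    if lb.size < 2:
        raise DegenerateSampleError("need at least two birth lengths")
    if (lb <= 0).any():
        raise DomainError("birth lengths must be positive")
    cutoff = lb.mean() + lb.std(ddof=1)
    kept = lb[lb <= cutoff]
    if kept.size == 0:
        raise DegenerateSampleError("no cells below the Z-score cutoff")
    spread = float(kept.std(ddof=1)) if kept.size > 1 else 0.0
    return L0BirthEstimate(
        l0=float(kept.mean()),
        spread=spread,
        cutoff=float(cutoff),
        n_total=int(lb.size),
        n_retained=int(kept.size),
    )


@dataclass(frozen=True)
class MotherDaughterEstimate:
    """Unit size from mother/daughter length statistics.

    The mean difference includes cells transitioning to filamentation and
    is an upper bound on ``l0``; the mode difference is less sensitive to
    the tail.
    """

    l0_mode_diff: float
    l0_mean_diff: float


def _histogram_mode(sample: np.ndarray) -> float:
    """Location of the histogram mode with Freedman-Diaconis bin width."""
    counts, edges = np.histogram(sample, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])
    top = np.flatnonzero(counts == counts.max())
    if len(top) > 1:
        warnings.warn(
            f"multimodal tie in mode estimation; candidates at {centers[top]}, using the first",
            stacklevel=3,
        )
    return float(centers[top[0]])


def estimate_l0_mother_daughter(
    mother_lengths: Sequence[float], daughter_lengths: Sequence[float]
) -> MotherDaughterEstimate:
    """Estimate ``l0`` from the mother and daughter length distributions,
    as the difference of their modes and the difference of their means."""
    lm = np.asarray(mother_lengths, dtype=float)
    ld = np.asarray(daughter_lengths, dtype=float)
    if lm.size == 0 or ld.size == 0:
        raise DegenerateSampleError("mother and daughter samples must be nonempty")
    return MotherDaughterEstimate(
        l0_mode_diff=_histogram_mode(lm) - _histogram_mode(ld),
        l0_mean_diff=float(lm.mean() - ld.mean()),
    )


@dataclass(frozen=True)
class SpectralEstimate:
    """Unit size from the periodicity of fluorescence profiles."""

    q_star: float  # dominant wavenumber, 1/um
    lam: float  # septum-septum spacing lambda = 1/q*, um
    l0: float  # lambda / 2 (septum spacing doubles relative to l0)
    q_grid: np.ndarray
    spectrum: np.ndarray


def _as_profile_list(
    profiles: pd.DataFrame | Iterable[tuple[np.ndarray, np.ndarray]],
) -> list[tuple[np.ndarray, np.ndarray]]:
    if isinstance(profiles, pd.DataFrame):
        return [
            (g["position_um"].to_numpy(float), g["intensity"].to_numpy(float))
            for _, g in profiles.groupby("cell_id", sort=True)
        ]
    return [(np.asarray(x, float), np.asarray(y, float)) for x, y in profiles]


def estimate_l0_spectral(
    profiles: pd.DataFrame | Iterable[tuple[np.ndarray, np.ndarray]],
    window: str = "none",
) -> SpectralEstimate:
    """Estimate ``l0`` from the averaged power spectrum of axial
    fluorescence profiles.

    Each profile is mean-subtracted, resampled to the finest sampling
    interval present, zero-padded to a common grid, and Fourier
    transformed; the spectrum moduli are averaged across cells.  The
    dominant interior peak at ``q* > 0`` gives the septum spacing
    ``lambda = 1/q*`` and ``l0 = lambda / 2`` (consecutive division rings
    sit two units apart in filamentous cells).  The peak location is
    refined by three-point parabolic interpolation.

    Parameters
    ----------
    profiles
        Either a DataFrame with columns ``cell_id, position_um,
        intensity`` or an iterable of ``(positions, intensities)`` pairs.
    window
        ``"none"`` (default) or ``"hann"`` taper applied before the FFT.
    """
    prof = _as_profile_list(profiles)
    if len(prof) == 0:
        raise DegenerateSampleError("need at least one profile")
    for x, y in prof:
        if len(x) < 16:
            raise DomainError("each profile needs at least 16 samples")
    dx = min(float(np.median(np.diff(x))) for x, _ in prof)
    if dx <= 0:
        raise DomainError("profile positions must be strictly increasing")

    resampled = []
    for x, y in prof:
        grid = np.arange(x[0], x[-1] + dx / 2, dx)
        resampled.append(np.interp(grid, x, y))
    n_common = max(len(r) for r in resampled)
    n_fft = 1 << int(np.ceil(np.log2(2 * n_common)))

    spec = np.zeros(n_fft // 2 + 1)
    for r in resampled:
        r = r - r.mean()
        if window == "hann":
            r = r * np.hanning(len(r))
        spec += np.abs(np.fft.rfft(r, n_fft))
    spec /= len(resampled)
    q = np.fft.rfftfreq(n_fft, d=dx)

    # interior local maxima, excluding the zero mode and the last point
    interior = (spec[1:-1] > spec[:-2]) & (spec[1:-1] >= spec[2:])
    idx = np.flatnonzero(interior) + 1
    idx = idx[spec[idx] > 0]
    if len(idx) == 0:
        raise PeakNotFoundError("no interior peak above the zero-mode shoulder")
    k = int(idx[np.argmax(spec[idx])])
    # parabolic refinement of the peak location
    y0, y1, y2 = spec[k - 1], spec[k], spec[k + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    q_star = float((k + shift) * q[1])
    lam = 1.0 / q_star
    return SpectralEstimate(q_star=q_star, lam=lam, l0=lam / 2.0, q_grid=q, spectrum=spec)


# ---------------------------------------------------------------------------
# binning and the alpha fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinnedHistogram:
    """Empirical state histogram after binning lengths by ``l0``.

    Bin ``n`` covers ``[l0 (n - 1/2), l0 (n + 1/2))``; lengths below
    ``l0/2`` are assigned to state 1.
    """

    counts: np.ndarray  # counts for states 1..len(counts)
    probs: np.ndarray
    l0: float
    source: str = "size"

    @property
    def states(self) -> np.ndarray:
        return np.arange(1, len(self.counts) + 1)

    def padded(self, N: int) -> np.ndarray:
        """Probability vector over states 1..N (zeros beyond the data);
        mass observed beyond state N, if any, is dropped without
        renormalizing."""
        out = np.zeros(N)
        k = min(N, len(self.probs))
        out[:k] = self.probs[:k]
        return out


def bin_lengths(lengths: Sequence[float], l0: float, source: str = "size") -> BinnedHistogram:
    """Assign each length to the state ``n = round(l / l0)`` (edges are
    left-closed) and return the normalized histogram."""
    if l0 <= 0:
        raise DomainError(f"l0 must be positive, got {l0}")
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise DegenerateSampleError("empty length sample")
    if (arr <= 0).any():
        raise DomainError("lengths must be positive")
    states = np.floor(arr / l0 + 0.5).astype(int)
    states[states < 1] = 1
    counts = np.bincount(states)[1:]
    return BinnedHistogram(
        counts=counts, probs=counts / counts.sum(), l0=float(l0), source=source
    )


def ballpark_alpha(l0: float, mean_birth_length: float) -> float:
    """First-pass division efficiency ``alpha = l0 / <l_b>``, clipped to
    ``(0, 1]`` with a warning when the ratio exceeds one."""
    if l0 <= 0 or mean_birth_length <= 0:
        raise DomainError("l0 and mean birth length must be positive")
    ratio = l0 / mean_birth_length
    if ratio > 1:
        warnings.warn(
            f"l0/<l_b> = {ratio:.3f} > 1 violates the model relation; clipping to 1",
            stacklevel=2,
        )
        return 1.0
    return ratio


def theory_histograms(alpha: float, pattern: str, N: int) -> tuple[np.ndarray, np.ndarray]:
    """Model stationary size law and normalized birth-size law for a
    candidate ``alpha`` — the regression targets of the fit."""
    params = ModelParams(alpha=alpha, N=N, pattern=pattern)
    T = build_transition_matrix(params)
    pst = stationary_distribution(T)
    pi = newborn_distribution(pst, params)
    pistar = birth_size_distribution(pi, T)
    return pst.probs, pistar.probs


def _eps2(
    p_vec: np.ndarray, pi_vec: np.ndarray, p_theo: np.ndarray, pi_theo: np.ndarray, N: int
) -> float:
    return float(
        ((pi_vec - pi_theo) ** 2).sum() / (N - 1) + ((p_vec - p_theo) ** 2).sum() / N
    )


@dataclass(frozen=True)
class AlphaFit:
    """Result of the double-regression fit of the division efficiency."""

    alpha_hat: float
    error: float
    alphas: np.ndarray  # diagnostic error-vs-alpha curve
    errors: np.ndarray


def fit_alpha(
    p_exp: BinnedHistogram,
    pi_star_exp: BinnedHistogram,
    pattern: str,
    N: int = 20,
) -> AlphaFit:
    """Fit ``alpha`` by simultaneously regressing the binned size and
    size-at-birth histograms on the model's stationary and birth-size laws.

    A coarse grid of step 0.01 over ``[0.01, 1]`` locates the minimum of
    the squared-error objective; a bounded golden-section refinement
    (tolerance 1e-4) polishes it.  States beyond the largest observed bin
    are compared against the theory as zeros up to ``N``.
    """
    validate_pattern(pattern)
    p_vec = p_exp.padded(N)
    pi_vec = pi_star_exp.padded(N)
    alphas = np.round(np.arange(0.01, 1.0 + 1e-9, 0.01), 10)
    errors = np.empty_like(alphas)
    for i, a in enumerate(alphas):
        p_theo, pi_theo = theory_histograms(a, pattern, N)
        errors[i] = _eps2(p_vec, pi_vec, p_theo, pi_theo, N)
    if errors.max() - errors.min() < 1e-14:
        raise FitDegenerateError("error curve is flat; data do not constrain alpha")
    i0 = int(np.argmin(errors))
    lo = alphas[max(i0 - 1, 0)]
    hi = alphas[min(i0 + 1, len(alphas) - 1)]

    def objective(a: float) -> float:
        p_theo, pi_theo = theory_histograms(a, pattern, N)
        return _eps2(p_vec, pi_vec, p_theo, pi_theo, N)

    if hi > lo:
        res = minimize_scalar(objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4})
        alpha_hat, err = float(res.x), float(res.fun)
        if errors[i0] < err:  # keep the grid point if refinement did not help
            alpha_hat, err = float(alphas[i0]), float(errors[i0])
    else:
        alpha_hat, err = float(alphas[i0]), float(errors[i0])
    return AlphaFit(alpha_hat=alpha_hat, error=err, alphas=alphas, errors=errors)


def bootstrap_alpha(
    lengths: Sequence[float],
    birth_lengths: Sequence[float],
    l0: float,
    pattern: str,
    N: int = 20,
    n_boot: int = 1000,
    seed: int = 0,
    grid_step: float = 0.005,
) -> np.ndarray:
    """Nonparametric bootstrap of the fitted ``alpha``.

    Resamples cells with replacement from both raw length samples,
    rebins, and refits on a fixed fine ``alpha`` grid (the model curves
    are computed once and reused).  Returns the bootstrap sample of
    ``alpha`` estimates; percentiles of it give confidence intervals.
    """
    lengths = np.asarray(lengths, dtype=float)
    births = np.asarray(birth_lengths, dtype=float)
    alphas = np.round(np.arange(grid_step, 1.0 + 1e-9, grid_step), 10)
    theo = [theory_histograms(a, pattern, N) for a in alphas]
    p_theo = np.array([t[0] for t in theo])
    pi_theo = np.array([t[1] for t in theo])
    rng = np.random.default_rng(seed)
    out = np.empty(n_boot)
    for b in range(n_boot):
        ls = rng.choice(lengths, size=len(lengths), replace=True)
        bs = rng.choice(births, size=len(births), replace=True)
        p_vec = bin_lengths(ls, l0).padded(N)
        pi_vec = bin_lengths(bs, l0, source="size-at-birth").padded(N)
        errs = ((pi_theo - pi_vec) ** 2).sum(axis=1) / (N - 1) + (
            (p_theo - p_vec) ** 2
        ).sum(axis=1) / N
        out[b] = alphas[int(np.argmin(errs))]
    return out


# ---------------------------------------------------------------------------
# histogram collapse and sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CollapseResult:
    """Unit size of a second condition found by histogram collapse."""

    l0_other: float
    collapse_error: float
    candidates: np.ndarray
    errors: np.ndarray


def collapse_l0(
    p_reference: BinnedHistogram,
    lengths_other: Sequence[float],
    grid_step: float = 0.05,
) -> CollapseResult:
    """Find the ``l0`` that collapses a second length sample onto a
    reference binned histogram.

    Scans candidate ``l0`` values in steps of ``grid_step`` over
    ``[0.5, 1.5] * l0_reference`` (the reference ``l0`` itself is always
    included), bins the sample at each candidate, and minimizes
    ``eps^2 = (1/N) sum (p_ref - p_other)^2``.  Two conditions with the
    same division efficiency collapse onto the same master curve.
    """
    lengths_other = np.asarray(lengths_other, dtype=float)
    if lengths_other.size == 0:
        raise DegenerateSampleError("empty sample for the second condition")
    l0_ref = p_reference.l0
    candidates = np.arange(0.5 * l0_ref, 1.5 * l0_ref + grid_step / 2, grid_step)
    candidates = np.unique(np.round(np.append(candidates, l0_ref), 12))
    errors = np.empty_like(candidates)
    for i, c in enumerate(candidates):
        h = bin_lengths(lengths_other, c)
        n_states = max(len(p_reference.probs), len(h.probs))
        diff = p_reference.padded(n_states) - h.padded(n_states)
        errors[i] = (diff**2).sum() / n_states
    i0 = int(np.argmin(errors))
    if i0 in (0, len(candidates) - 1):
        warnings.warn("collapse error minimized at the scan boundary", stacklevel=2)
    return CollapseResult(
        l0_other=float(candidates[i0]),
        collapse_error=float(errors[i0]),
        candidates=candidates,
        errors=errors,
    )


@dataclass(frozen=True)
class SensitivityResult:
    """Robustness of the fitted ``alpha`` to the uncertainty in ``l0``."""

    table: pd.DataFrame  # columns: l0, alpha_hat, error
    cv_l0: float
    cv_alpha: float
    robust: bool  # CV of the output below CV of the input


def sensitivity_analysis(
    raw_lengths: Sequence[float],
    raw_birth_lengths: Sequence[float],
    pattern: str,
    N: int,
    l0: float,
    delta_l0: float,
) -> SensitivityResult:
    """Refit ``alpha`` with the raw samples rebinned at ``l0 - delta``,
    ``l0``, and ``l0 + delta`` and compare coefficients of variation.

    The binning is robust when the variability of the output (the fitted
    ``alpha``) is below the variability of the input (``l0``).
    """
    if delta_l0 < 0 or delta_l0 >= l0:
        raise DomainError(f"delta_l0 must be in [0, l0), got {delta_l0} with l0={l0}")
    rows = []
    for cand in (l0 - delta_l0, l0, l0 + delta_l0):
        p = bin_lengths(raw_lengths, cand)
        pi = bin_lengths(raw_birth_lengths, cand, source="size-at-birth")
        fit = fit_alpha(p, pi, pattern, N)
        rows.append({"l0": cand, "alpha_hat": fit.alpha_hat, "error": fit.error})
    table = pd.DataFrame(rows)
    l0s = table["l0"].to_numpy()
    a = table["alpha_hat"].to_numpy()
    cv_l0 = float(l0s.std(ddof=1) / l0s.mean()) if delta_l0 > 0 else 0.0
    cv_alpha = float(a.std(ddof=1) / a.mean())
    return SensitivityResult(
        table=table, cv_l0=cv_l0, cv_alpha=cv_alpha, robust=bool(cv_alpha < cv_l0)
    )
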