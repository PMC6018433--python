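"""Model parameters for the discrete size-control chain.

A cell's length is counted in units of the characteristic size ``l0`` set
by the division machinery, so the state space is the integers 1..N.  Each
time step a cell grows one unit; with probability ``alpha`` (the division
efficiency) the step also ends in a division.  The division pattern names
the law of the daughter's size given the mother's post-growth size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError, DomainError

#: Valid division-pattern identifiers.
PATTERNS = ("binomial", "uniform", "inverse_binomial", "middle")


def validate_pattern(pattern: str) -> str:
    if pattern not in PATTERNS:
        raise ConfigurationError(
            f"unknown division pattern {pattern!r}; expected one of {PATTERNS}"
        )
    return pattern


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the growth/division chain.

    Parameters
    ----------
    alpha
        Probability of a division event per unit-length growth step,
        ``0 <= alpha <= 1``.
    N
        Maximal cell size in ``l0`` units (``N >= 2``).  A cell at the
        maximal size cannot grow further: it either remains there or
        divides.
    pattern
        Division-pattern identifier, one of :data:`PATTERNS`.
    l0
        Unit cell length in micrometres.  Only the estimation pipeline
        uses physical units; the chain itself is dimensionless.
    t0
        Time to grow one ``l0`` unit.  Metadata only: the stationary
        size statistics do not depend on it.
    """

    alpha: float
    N: int
    pattern: str = "binomial"
    l0: float = 1.0
    t0: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise DomainError(f"alpha must be in [0, 1], got {self.alpha}")
        if int(self.N) != self.N or self.N < 2:
            raise DomainError(f"N must be an integer >= 2, got {self.N}")
        object.__setattr__(self, "N", int(self.N))
        validate_pattern(self.pattern)
        if self.l0 <= 0:
            raise DomainError(f"l0 must be positive, got {self.l0}")
        if self.t0 <= 0:
            raise DomainError(f"t0 must be positive, got {self.t0}")
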