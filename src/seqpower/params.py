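"""Shared parameter containers and error types.

The negative binomial is parameterized throughout by its mean ``mu`` and
dispersion ``phi``, with variance ``mu + phi * mu**2`` (size parameter
``1/phi``; ``sqrt(phi)`` is the biological coefficient of variation).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

#: Dispersions below this are treated as the Poisson limit so that the
#: NB never degenerates numerically (Gamma(1/phi) overflow).
PHI_FLOOR = 1e-8


class SeqPowerError(Exception):
    """Base class for all seqpower errors."""


class InvalidParameterError(SeqPowerError, ValueError):
    """A scalar input is outside its declared domain."""


class InsufficientDesignError(SeqPowerError, RuntimeError):
    """The target power is unreachable within the sample-size cap."""

    def __init__(self, message: str, n_max: int | None = None,
                 power_at_max: float | None = None):
        super().__init__(message)
        self.n_max = n_max
        self.power_at_max = power_at_max


class ResourceLimitError(SeqPowerError, RuntimeError):
    """A computation would exceed the configured enumeration caps."""


class ConvergenceError(SeqPowerError, RuntimeError):
    """An iterative scheme failed to converge."""


class MonotonicityError(SeqPowerError, RuntimeError):
    """An asserted monotonicity (power vs n) was violated numerically."""


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidParameterError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class GeneParams:
    """One gene's control-group mean read count and dispersion.

    Parameters
    ----------
    mu : float
        Average read count per sample in the control group (>= 0).
    phi : float
        NB dispersion; variance = mu + phi * mu**2 (>= 0).
    """

    mu: float
    phi: float

    def __post_init__(self):
        mu = _check_finite("mu", self.mu)
        phi = _check_finite("phi", self.phi)
        if mu < 0:
            raise InvalidParameterError(f"mu must be >= 0, got {mu}")
        if phi < 0:
            raise InvalidParameterError(f"phi must be >= 0, got {phi}")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "phi", phi)


@dataclass(frozen=True)
class DesignSpec:
    """Two-group design: per-group sizes, fold change and normalization ratio.

    ``rho`` is the fold change between groups under the alternative;
    ``omega`` the geometric mean of normalization factors between groups
    (scales the treatment group's expected pseudo counts).  A balanced
    design has ``n0 == n1``.
    """

    n0: int
    n1: int
    rho: float
    omega: float = 1.0

    def __post_init__(self):
        for name in ("n0", "n1"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise InvalidParameterError(f"{name} must be a positive integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        rho = _check_finite("rho", self.rho)
        omega = _check_finite("omega", self.omega)
        if rho <= 0:
            raise InvalidParameterError(f"rho must be > 0, got {rho}")
        if omega <= 0:
            raise InvalidParameterError(f"omega must be > 0, got {omega}")
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "omega", omega)

    @classmethod
    def balanced(cls, n: int, rho: float, omega: float = 1.0) -> "DesignSpec":
        return cls(n0=n, n1=n, rho=rho, omega=omega)


@dataclass(frozen=True)
class FDRSpec:
    """Design-time multiple-testing assumptions.

    ``fdr`` is the target false discovery rate, ``m`` the total number of
    genes tested and ``m1`` the number of truly differentially expressed
    ("prognostic") genes assumed at design time.  The derived marginal
    type I error alpha* is computed by :mod:`seqpower.fdr`.
    """

    fdr: float = 0.05
    m: int = 10000
    m1: int = 100

    def __post_init__(self):
        f = _check_finite("fdr", self.fdr)
        if not 0 < f < 1:
            raise InvalidParameterError(f"fdr must be in (0, 1), got {f}")
        object.__setattr__(self, "fdr", f)
        for name in ("m", "m1"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise InvalidParameterError(f"{name} must be a positive integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if not self.m1 < self.m:
            raise InvalidParameterError(f"m1 must be < m, got m1={self.m1}, m={self.m}")
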