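"""Sample-size search, power curves over allocation ratios, power matrices.

The single-value ("conservative") mode represents every gene in the
experiment by one pair: a minimal average read count and a maximal
dispersion.  The smallest per-group n whose exact-test power reaches the
target is found by exponential doubling followed by integer bisection,
relying on the monotonicity of power in n (spot-checked during the search;
a violation aborts rather than returning a wrong n).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fdr import alpha_star_plugin
from .nbexact import single_gene_power
from .params import (
    DesignSpec,
    FDRSpec,
    GeneParams,
    InsufficientDesignError,
    InvalidParameterError,
    MonotonicityError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SampleSizeResult",
    "solve_sample_size",
    "required_sample_size",
    "power_curve",
    "power_matrix",
]

#: Numerical slack for the monotonicity assertion: power may jitter by this
#: much between evaluation paths without being treated as a violation.
_MONO_TOL = 1e-2


@dataclass(frozen=True)
class SampleSizeResult:
    """Bracketing certificate for a sample-size solve.

    ``power_below`` is the power at ``n - 1`` (None when ``n == 1``); a
    valid solve has ``power_below < target_power <= power_at_n``.
    """

    n: int
    alpha_star: float
    target_power: float
    power_at_n: float
    power_below: float | None


def _power_fn(gene, rho, omega, alpha, power_kwargs):
    cache: dict[int, float] = {}

    def fn(n: int) -> float:
        if n not in cache:
            cache[n] = single_gene_power(
                gene, DesignSpec.balanced(n, rho, omega), alpha, **power_kwargs)
        return cache[n]

    return fn


def solve_sample_size(gene, rho: float, fdr: FDRSpec, target_power: float, *,
                      omega: float = 1.0, n_max: int = 2000,
                      **power_kwargs) -> SampleSizeResult:
    """Smallest per-group n with exact-test power >= ``target_power``.

    alpha* is the plug-in adjustment at the target power (held fixed over
    the search).  Raises :class:`InsufficientDesignError`, carrying the
    power at ``n_max``, when the target is unreachable.
    """
    if not isinstance(gene, GeneParams):
        gene = GeneParams(*gene)
    if not 0.0 < target_power < 1.0:
        raise InvalidParameterError(f"target_power must be in (0, 1), got {target_power}")
    if n_max < 1:
        raise InvalidParameterError(f"n_max must be >= 1, got {n_max}")
    alpha = alpha_star_plugin(fdr.fdr, fdr.m, fdr.m1, target_power)
    power = _power_fn(gene, rho, omega, alpha, power_kwargs)

    # exponential doubling to bracket, with monotonicity spot checks
    n, prev = 1, None
    while power(n) < target_power:
        if prev is not None and power(n) < power(prev) - _MONO_TOL:
            raise MonotonicityError(
                f"power decreased from {power(prev):.4f} at n={prev} "
                f"to {power(n):.4f} at n={n}")
        if n >= n_max:
            raise InsufficientDesignError(
                f"power {power(n_max):.4f} at n_max={n_max} is below the "
                f"target {target_power}", n_max=n_max, power_at_max=power(n_max))
        prev, n = n, min(2 * n, n_max)
    lo = prev if prev is not None else 0   # power(lo) < target (or lo == 0)
    hi = n                                  # power(hi) >= target
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    below = power(hi - 1) if hi > 1 else None
    logger.info("solved n=%d (alpha*=%.4g, power=%.4f, power at n-1=%s)",
                hi, alpha, power(hi), f"{below:.4f}" if below is not None else "-")
    return SampleSizeResult(n=hi, alpha_star=alpha, target_power=target_power,
                            power_at_n=power(hi), power_below=below)


def required_sample_size(gene, rho: float, fdr: FDRSpec, target_power: float, *,
                         omega: float = 1.0, n_max: int = 2000,
                         **power_kwargs) -> int:
    """Per-group sample size; thin wrapper over :func:`solve_sample_size`."""
    return solve_sample_size(gene, rho, fdr, target_power, omega=omega,
                             n_max=n_max, **power_kwargs).n


def _parse_allocation(alloc) -> tuple[int, int]:
    if isinstance(alloc, str):
        parts = alloc.split(":")
        if len(parts) != 2:
            raise InvalidParameterError(f"allocation must look like '2:1', got {alloc!r}")
        k0, k1 = (int(p) for p in parts)
    else:
        k0, k1 = (int(v) for v in alloc)
    if k0 < 1 or k1 < 1:
        raise InvalidParameterError(f"allocation parts must be >= 1, got {alloc!r}")
    return k0, k1


def power_curve(gene, fdr: FDRSpec, rho: float, *, omega: float = 1.0,
                totals: Iterable[int],
                allocations: Sequence = ("1:1", "2:1", "3:1"),
                target_power: float = 0.8, alpha: float | None = None,
                **power_kwargs) -> pd.DataFrame:
    """Power against total sample count for several allocation ratios.

    Each total is split ``k0:k1`` between control and treatment; totals not
    divisible into a ratio with both groups >= 1 are skipped (logged).
    alpha* is held fixed across the curve (plug-in at ``target_power``)
    unless ``alpha`` is given, so that rows are comparable.
    """
    if not isinstance(gene, GeneParams):
        gene = GeneParams(*gene)
    if alpha is None:
        alpha = alpha_star_plugin(fdr.fdr, fdr.m, fdr.m1, target_power)
    rows = []
    for alloc in allocations:
        k0, k1 = _parse_allocation(alloc)
        label = f"{k0}:{k1}"
        for total in totals:
            total = int(total)
            if total % (k0 + k1) != 0:
                logger.info("skipping total=%d for allocation %s (not divisible)",
                            total, label)
                continue
            unit = total // (k0 + k1)
            n0, n1 = k0 * unit, k1 * unit
            pw = single_gene_power(gene, DesignSpec(n0, n1, rho, omega), alpha,
                                   **power_kwargs)
            rows.append((total, label, n0, n1, pw))
    if not rows:
        raise InvalidParameterError("no admissible (total, allocation) combinations")
    df = pd.DataFrame(rows, columns=["total_samples", "allocation", "n0", "n1", "power"])
    df.attrs["alpha_star"] = alpha
    return df.sort_values(["allocation", "total_samples"], ignore_index=True)


def power_matrix(phi: float, rho: float, fdr: FDRSpec, *, omega: float = 1.0,
                 n_grid: Iterable[int], count_grid: Iterable[float],
                 target_power: float = 0.8, alpha: float | None = None,
                 **power_kwargs) -> pd.DataFrame:
    """Power over a (per-group n) x (average read count) grid.

    Rows are per-group sample sizes, columns average read counts; all other
    parameters fixed, alpha* fixed across cells (plug-in at
    ``target_power``).  Entries are nondecreasing along both axes.
    """
    n_grid = [int(n) for n in n_grid]
    count_grid = [float(c) for c in count_grid]
    if not n_grid or not count_grid:
        raise InvalidParameterError("n_grid and count_grid must be nonempty")
    if alpha is None:
        alpha = alpha_star_plugin(fdr.fdr, fdr.m, fdr.m1, target_power)
    mat = np.empty((len(n_grid), len(count_grid)))
    for i, n in enumerate(n_grid):
        for j, mu in enumerate(count_grid):
            mat[i, j] = single_gene_power(
                GeneParams(mu, phi), DesignSpec.balanced(n, rho, omega), alpha,
                **power_kwargs)
    df = pd.DataFrame(mat, index=pd.Index(n_grid, name="n_per_group"),
                      columns=pd.Index(count_grid, name="read_count"))
    df.attrs["alpha_star"] = alpha
    return df
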