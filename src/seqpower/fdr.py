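"""Marginal type I error under FDR control.

Rejecting each of ``m`` gene-level tests at a marginal level ``alpha``
yields on average ``(m - m1) * alpha`` false rejections and
``m1 * power`` true rejections.  Setting the expected proportion of false
discoveries equal to the target FDR ``f`` and solving gives the plug-in
adjustment

    alpha* = f * m1 * power / ((1 - f) * (m - m1)).

When solving for a sample size at a user-chosen target power the plug-in
form with ``power = target`` is used.  When evaluating power at a fixed n
the achieved power is unknown a priori, so a self-consistent fixed point
of the same identity is iterated instead.
"""
from __future__ import annotations

import warnings
from typing import Callable, Tuple

from .params import ConvergenceError, FDRSpec, InvalidParameterError, _check_finite

__all__ = ["alpha_star_plugin", "alpha_star_fixedpoint"]


def _validate(f: float, m: int, m1: int) -> FDRSpec:
    return FDRSpec(fdr=f, m=m, m1=m1)  # runs the range checks


def alpha_star_plugin(f: float, m: int, m1: int, anticipated_power: float) -> float:
    """Marginal type I error equating the expected FDR to ``f``.

    ``anticipated_power`` is the per-gene power expected for the ``m1``
    truly differential genes; ``alpha* = f*m1*power / ((1-f)*(m-m1))``.
    """
    _validate(f, m, m1)
    p = _check_finite("anticipated_power", anticipated_power)
    if not 0.0 <= p <= 1.0:
        raise InvalidParameterError(f"anticipated_power must be in [0, 1], got {p}")
    if p == 0.0:
        warnings.warn("anticipated_power is 0: no true rejections expected, alpha*=0",
                      stacklevel=2)
        return 0.0
    alpha = f * m1 * p / ((1.0 - f) * (m - m1))
    if alpha >= 1.0:
        raise InvalidParameterError(
            f"derived alpha* = {alpha:.4g} >= 1; the FDR specification is degenerate")
    return alpha


def alpha_star_fixedpoint(f: float, m: int, m1: int,
                          power_at: Callable[[float], float], *,
                          tol: float = 1e-8, max_iter: int = 50) -> Tuple[float, float]:
    """Self-consistent alpha*: iterate the plug-in map with achieved power.

    ``power_at(alpha)`` must be nondecreasing in alpha (average power of
    the exact test is).  Iterates ``alpha <- f*m1*power_at(alpha) /
    ((1-f)(m-m1))`` from the plug-in value at power 1 until successive
    iterates differ by less than ``tol``.  Returns ``(alpha, power)``.
    """
    _validate(f, m, m1)
    scale = f * m1 / ((1.0 - f) * (m - m1))
    alpha = alpha_star_plugin(f, m, m1, 1.0)
    power = 0.0
    for _ in range(max_iter):
        power = float(power_at(alpha))
        if not 0.0 <= power <= 1.0:
            raise InvalidParameterError(f"power_at returned {power!r}, outside [0, 1]")
        nxt = scale * power
        if abs(nxt - alpha) < tol:
            return nxt, power
        alpha = nxt
    raise ConvergenceError(
        f"alpha* fixed point did not converge in {max_iter} iterations; "
        f"last bracket [{min(alpha, nxt):.3e}, {max(alpha, nxt):.3e}]")
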