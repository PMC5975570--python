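"""Negative-binomial exact test on pseudo counts and single-gene power.

Model
-----
Each of the ``n_i`` samples in group ``i`` contributes an independent
NB(mu_i, phi) read count.  The group total ("pseudo count") is then itself
negative binomial: the sum of n iid NB(mu, phi) variables is
NB(n * mu, phi / n).  Under the alternative the two pseudo counts are

    y0 ~ NB(n0 * mu,            phi / n0)          (control)
    y1 ~ NB(n1 * omega * rho * mu, phi / n1)       (treatment)

Differential expression is assessed with the conditional exact test
(Robinson & Smyth style): given the total ``s = y0 + y1``, the two-sided
p-value sums the null-conditional probabilities of all splits of ``s`` that
are no more probable than the observed one (ties included).  A gene's power
at marginal type I error ``alpha`` is the alternative-measure mass of the
rejection region ``{(y0, y1): p(y1, y0) < alpha}`` (strict inequality),
accumulated total-by-total with each marginal sum truncated at its
``1 - trunc_tol`` NB quantile.

A useful identity drives the implementation: conditional on ``s``, the null
law of the control split ``a`` is proportional to

    exp(c[a] + d[s - a] + a * delta(s))

where ``c`` and ``d`` collect the gamma-function terms of the two null
pmfs (1-D tables, computed once) and the tilt ``delta(s)`` carries the
whole dependence on the common null mean estimate
``muhat = s / (n0 + n1 * omega)``.  When ``omega = 1`` the tilt vanishes:
the balanced-normalization exact test is independent of how the null mean
is estimated, and the conditional law is the beta-binomial
BB(s, n0/phi, n1/phi).

At very large pseudo counts exhaustive enumeration is infeasible; the
rejection boundary is then computed exactly on a subsampled grid of totals,
interpolated monotonically in between, and power is accumulated through NB
tail probabilities (see :func:`single_gene_power`, ``method`` parameter).
"""
from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .params import (
    PHI_FLOOR,
    DesignSpec,
    GeneParams,
    InvalidParameterError,
    ResourceLimitError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "nb_pmf",
    "nb_logpmf",
    "nb_quantile",
    "exact_test_pvalue",
    "exact_test_pvalues_pseudo",
    "single_gene_power",
]

#: Half-width, in conditional standard deviations, of the window that is
#: guaranteed to hold all but ~1e-14 of the null conditional mass.
_Z_WINDOW = 8.5
_MIN_HALF_WIDTH = 6.0

#: Relative slack in the "at most as probable" comparison, so that
#: mathematically tied splits are never separated by floating-point
#: rounding (the same convention as R's binom.test).
_TIE_REL = 1e-7

#: Default caps: largest admissible total count and largest exact-path
#: enumeration workload (pairs visited).  The defaults accommodate average
#: read counts up to 2000 at realistic group sizes.
_MAX_TOTAL = 5_000_000
_MAX_WORKLOAD = 2.5e8


def _validate_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if not np.issubdtype(y.dtype, np.number):
        raise InvalidParameterError("counts must be numeric")
    if np.any(~np.isfinite(np.asarray(y, dtype=float))) or np.any(y < 0):
        raise InvalidParameterError("counts must be finite and >= 0")
    if np.any(np.mod(y, 1) != 0):
        raise InvalidParameterError("counts must be integers")
    return y.astype(np.int64)


def _lgamma_ratio(y: np.ndarray, r: float) -> np.ndarray:
    """log Gamma(y + r) - log Gamma(r) for integer y >= 0.

    For very large r the direct difference of gammaln values loses ~r*eps
    absolute precision; the telescoping sum log prod_{k<y} (r + k) is then
    exact to rounding.
    """
    if r < 1e6:
        return gammaln(y + r) - gammaln(r)
    top = int(y.max()) if y.size else 0
    table = np.zeros(top + 1)
    if top:
        table[1:] = np.cumsum(np.log(r + np.arange(top, dtype=np.float64)))
    return table[y]


def nb_logpmf(y, mu: float, phi: float) -> np.ndarray:
    """Log pmf of NB(mean=mu, dispersion=phi), Poisson limit below PHI_FLOOR."""
    y = _validate_counts(y)
    if not math.isfinite(mu) or mu <= 0:
        raise InvalidParameterError(f"mu must be positive and finite, got {mu!r}")
    if not math.isfinite(phi) or phi < 0:
        raise InvalidParameterError(f"phi must be >= 0 and finite, got {phi!r}")
    if phi < PHI_FLOOR:
        return stats.poisson.logpmf(y, mu)
    r = 1.0 / phi
    x = phi * mu
    return (
        _lgamma_ratio(y, r)
        - gammaln(y + 1.0)
        - r * math.log1p(x)
        + y * (math.log(x) - math.log1p(x))
    )


def nb_pmf(y, mu: float, phi: float):
    """Pmf of NB(mean=mu, dispersion=phi); computed in log space."""
    out = np.exp(nb_logpmf(y, mu, phi))
    return float(out) if np.isscalar(y) or np.ndim(y) == 0 else out


def nb_quantile(q: float, mu: float, phi: float) -> int:
    """Smallest integer y with P(Y <= y) >= q for Y ~ NB(mu, phi)."""
    if mu == 0:
        return 0
    if phi < PHI_FLOOR:
        return int(stats.poisson.ppf(q, mu))
    r = 1.0 / phi
    return int(stats.nbinom.ppf(q, r, r / (r + mu)))


def exact_test_pvalue(y0: int, y1: int, null_mean0: float, null_mean1: float,
                      disp0: float, disp1: float) -> float:
    """Two-sided conditional exact-test p-value for a pair of pseudo counts.

    Conditional on ``s = y0 + y1``, sums the null probabilities
    ``P0(a, s - a)`` of all splits at most as probable as the observed one
    (ties included), normalized by the total mass of splits of ``s``.
    ``P0`` is the product of NB(null_mean0, disp0) and NB(null_mean1, disp1)
    pmfs.  ``s = 0`` carries no information and returns 1.
    """
    (y0,) = _validate_counts([y0])
    (y1,) = _validate_counts([y1])
    s = int(y0 + y1)
    if s == 0:
        return 1.0
    a = np.arange(s + 1)
    lq = nb_logpmf(a, null_mean0, disp0) + nb_logpmf(s - a, null_mean1, disp1)
    q = np.exp(lq - lq.max())
    sq = np.sort(q)
    cs = np.cumsum(sq)
    idx = np.searchsorted(sq, q[y0] * (1.0 + _TIE_REL), side="right")
    return float(min(1.0, cs[idx - 1] / cs[-1]))


class _ConditionalNull:
    """Null conditional law of the control split ``a`` given total ``s``.

    Precomputes the 1-D gamma-term tables up to ``smax`` so that per-total
    work is a handful of vector operations.  ``pvalues(s, a)`` returns the
    two-sided exact-test p-values of the requested splits.
    """

    def __init__(self, n0: int, n1: int, phi: float, omega: float, smax: int):
        self.n0, self.n1, self.phi, self.omega = n0, n1, phi, omega
        A = np.arange(smax + 2, dtype=np.float64)
        gl1 = gammaln(A + 1.0)
        if phi < PHI_FLOOR:
            # Poisson limit: conditional law is Binomial(s, n0/(n0+n1*omega))
            self._c = -gl1
            self._d = -gl1
            self._poisson = True
            self._r0 = self._r1 = math.inf
            self.log_concave = True
        else:
            r0 = n0 / phi
            r1 = n1 / phi
            idx = np.arange(smax + 2)
            self._c = _lgamma_ratio(idx, r0) - gl1
            self._d = _lgamma_ratio(idx, r1) - gl1
            self._poisson = False
            self._r0, self._r1 = r0, r1
            # both NB pmfs log-concave iff their size parameters are >= 1
            self.log_concave = r0 >= 1.0 and r1 >= 1.0

    def _tilt(self, s: int) -> float:
        """Slope of the linear term in the conditional log-law at total s.

        The common per-sample null mean muhat = s / (n0 + n1*omega) enters
        only here; it cancels entirely when omega = 1, making the balanced
        exact test independent of how the null mean is estimated.
        """
        n0, n1, omega = self.n0, self.n1, self.omega
        if self._poisson:
            return math.log(n0 / (n1 * omega))
        if omega == 1.0:
            return 0.0
        x = self.phi * s / (n0 + n1 * omega)
        return math.log1p(omega * x) - math.log(omega) - math.log1p(x)

    def moments(self, s):
        """Approximate mean and variance of the conditional law at total s."""
        s = np.asarray(s, dtype=np.float64)
        n0, n1, phi, omega = self.n0, self.n1, self.phi, self.omega
        if self.phi < PHI_FLOOR:
            p = n0 / (n0 + n1 * omega)
            return s * p, s * p * (1.0 - p)
        if omega == 1.0:
            # exact beta-binomial BB(s, r0, r1) moments
            rt = self._r0 + self._r1
            p = self._r0 / rt
            return s * p, s * p * (1.0 - p) * (rt + s) / (rt + 1.0)
        muhat = s / (n0 + n1 * omega)
        m0 = n0 * muhat
        v0 = m0 * (1.0 + phi * muhat)
        v1 = (s - m0) * (1.0 + phi * omega * muhat)
        # normal heuristic for the tilted law; inflated for window safety
        var = np.where(v0 + v1 > 0, v0 * v1 / np.maximum(v0 + v1, 1e-300), 0.0)
        return m0, 1.5 * var

    def _window(self, s: int, lo_req: int, hi_req: int) -> tuple[int, int]:
        mean, var = self.moments(s)
        hw = _Z_WINDOW * math.sqrt(float(var)) + _MIN_HALF_WIDTH
        lo = min(lo_req, int(mean - hw))
        hi = max(hi_req, int(mean + hw) + 1)
        return max(0, lo), min(s, hi)

    def pvalues(self, s: int, a) -> np.ndarray:
        """Two-sided exact p-values of splits ``a`` of total ``s``.

        Splits outside the central null window (mass < ~1e-14 per tail)
        are handled implicitly: the window always contains the query
        points, and neglected mass cannot move a p-value by more than the
        truncated tail mass.
        """
        a = np.asarray(a, dtype=np.int64)
        if s == 0:
            return np.ones(a.shape)
        lo, hi = self._window(s, int(a.min()), int(a.max()))
        lq = self._c[lo:hi + 1] + self._d[s - hi:s - lo + 1][::-1]
        delta = self._tilt(s)
        if delta != 0.0:
            lq = lq + np.arange(lo, hi + 1) * delta
        q = np.exp(lq - lq.max())
        if self.log_concave:
            # q is unimodal: concatenating the two monotone tails gives two
            # sorted runs, which a stable (tim)sort merges in linear time.
            k = int(np.argmax(q))
            sq = np.sort(np.concatenate((q[:k + 1], q[k + 1:][::-1])), kind="stable")
        else:
            sq = np.sort(q)
        cs = np.cumsum(sq)
        idx = np.searchsorted(sq, q[a - lo] * (1.0 + _TIE_REL), side="right")
        return np.minimum(1.0, cs[idx - 1] / cs[-1])


def exact_test_pvalues_pseudo(y0, y1, n0: int, n1: int, phi: float,
                              omega: float = 1.0) -> np.ndarray:
    """Vectorized exact-test p-values for pseudo-count pairs of one design.

    Equivalent to calling :func:`exact_test_pvalue` with the common-mean
    null convention (null means ``n0 * muhat`` and ``n1 * omega * muhat``
    with ``muhat = (y0 + y1) / (n0 + n1 * omega)``); pairs are grouped by
    total so the conditional law is built once per distinct total.
    """
    y0 = _validate_counts(y0)
    y1 = _validate_counts(y1)
    s = y0 + y1
    out = np.ones(s.shape, dtype=np.float64)
    if s.size == 0:
        return out
    cond = _ConditionalNull(n0, n1, phi, omega, int(s.max()))
    order = np.argsort(s, kind="stable")
    ss = s[order]
    bounds = np.flatnonzero(np.r_[True, np.diff(ss) != 0])
    for start, stop in zip(bounds, np.r_[bounds[1:], ss.size]):
        tot = int(ss[start])
        if tot == 0:
            continue
        sel = order[start:stop]
        out[sel] = cond.pvalues(tot, y0[sel])
    return out


def _alt_bounds(mean: float, disp: float, tol: float) -> tuple[int, int]:
    lo = nb_quantile(tol, mean, disp)
    hi = nb_quantile(1.0 - tol, mean, disp)
    return lo, hi


def _power_exact(mu, phi, n0, n1, rho, omega, alpha, trunc_tol) -> float:
    m0a = n0 * mu
    m1a = n1 * omega * rho * mu
    d0 = phi / n0
    d1 = phi / n1
    y0lo, y0hi = _alt_bounds(m0a, d0, trunc_tol)
    y1lo, y1hi = _alt_bounds(m1a, d1, trunc_tol)
    f0 = np.exp(nb_logpmf(np.arange(y0lo, y0hi + 1), m0a, d0))
    f1 = np.exp(nb_logpmf(np.arange(y1lo, y1hi + 1), m1a, d1))
    cond = _ConditionalNull(n0, n1, phi, omega, y0hi + y1hi)
    power = 0.0
    for s in range(max(1, y0lo + y1lo), y0hi + y1hi + 1):
        alo = max(y0lo, s - y1hi)
        ahi = min(y0hi, s - y1lo)
        if alo > ahi:
            continue
        a = np.arange(alo, ahi + 1)
        pv = cond.pvalues(s, a)
        rej = pv < alpha
        if rej.any():
            w = f0[alo - y0lo:ahi - y0lo + 1] * f1[s - ahi - y1lo:s - alo - y1lo + 1][::-1]
            power += float(w[rej].sum())
    neglected = 4.0 * trunc_tol  # two truncated tails per marginal
    logger.debug("exact power: truncation error bound %.3g", neglected)
    return min(1.0, power)


def _boundary_at(cond: _ConditionalNull, s: int, alpha: float) -> tuple[int, int]:
    """Exact conditional rejection boundary at one total.

    Returns ``(lo, hi)``: splits with ``a <= lo`` or ``a >= hi`` are
    rejected at level alpha (the rejection set of the unimodal conditional
    law is a pair of tail blocks).
    """
    mean, var = cond.moments(s)
    hw = 1.5 * _Z_WINDOW * math.sqrt(float(var)) + _MIN_HALF_WIDTH
    lo_w = max(0, int(mean - hw))
    hi_w = min(s, int(mean + hw) + 1)
    a = np.arange(lo_w, hi_w + 1)
    keep = cond.pvalues(s, a) >= alpha
    if not keep.any():          # everything rejected (alpha ~ 1)
        return s, 0
    first = int(np.argmax(keep))
    last = keep.size - 1 - int(np.argmax(keep[::-1]))
    return int(a[first]) - 1, int(a[last]) + 1


def _power_boundary(mu, phi, n0, n1, rho, omega, alpha, trunc_tol,
                    max_boundary_pairs: float = 4e7) -> float:
    """High-count regime: exact boundary on a subsampled grid of totals.

    The conditional rejection boundary (lo(s), hi(s)) is computed exactly
    on a grid of totals and interpolated monotonically in between (it is a
    nondecreasing integer staircase, so interpolation errs by at most a
    cell or two near step edges).  Power then reduces to a single pass
    over the control pseudo count with NB tail probabilities of the
    treatment pseudo count.  Selected only when pseudo counts are large,
    where the relative effect of the interpolated cells is negligible.
    """
    m0a = n0 * mu
    m1a = n1 * omega * rho * mu
    d0 = phi / n0
    d1 = phi / n1
    y0lo, y0hi = _alt_bounds(m0a, d0, trunc_tol)
    y1lo, y1hi = _alt_bounds(m1a, d1, trunc_tol)
    smin = max(1, y0lo + y1lo)
    smax = y0hi + y1hi
    cond = _ConditionalNull(n0, n1, phi, omega, smax)
    _, var_mid = cond.moments((smin + smax) // 2)
    width = 2.0 * 1.5 * _Z_WINDOW * math.sqrt(float(var_mid)) + 1.0
    n_grid = int(np.clip(max_boundary_pairs / width, 33, 257))
    grid = np.unique(np.linspace(smin, smax, n_grid).astype(np.int64))
    cuts = np.array([_boundary_at(cond, int(sg), alpha) for sg in grid], dtype=float)
    s = np.arange(smin, smax + 1, dtype=np.float64)
    lo_cut = np.maximum.accumulate(np.floor(np.interp(s, grid, cuts[:, 0])))
    hi_cut = np.maximum.accumulate(np.ceil(np.interp(s, grid, cuts[:, 1])))

    a = np.arange(y0lo, y0hi + 1, dtype=np.float64)
    # smallest total with lo_cut >= a -> reject when y1 >= s_low(a) - a
    ix = np.searchsorted(lo_cut, a, side="left")
    s_low = np.where(ix < s.size, smin + ix, np.inf)
    b_hi = np.maximum(s_low - a, 0.0)
    # largest total with hi_cut <= a -> reject when y1 <= s_high(a) - a
    ix2 = np.searchsorted(hi_cut, a, side="right") - 1
    s_high = np.where(ix2 >= 0, smin + ix2, -np.inf)
    b_lo = s_high - a

    if phi < PHI_FLOOR:
        upper = stats.poisson.sf(b_hi - 1.0, m1a)
        lower = np.where(b_lo >= 0, stats.poisson.cdf(np.maximum(b_lo, 0.0), m1a), 0.0)
    else:
        r1 = 1.0 / d1
        p1 = r1 / (r1 + m1a)
        upper = stats.nbinom.sf(b_hi - 1.0, r1, p1)
        lower = np.where(b_lo >= 0, stats.nbinom.cdf(np.maximum(b_lo, 0.0), r1, p1), 0.0)
    f0 = np.exp(nb_logpmf(np.arange(y0lo, y0hi + 1), m0a, d0))
    return float(min(1.0, np.sum(f0 * np.minimum(1.0, upper + lower))))


def _estimate_workload(y0lo, y0hi, y1lo, y1hi, cond: _ConditionalNull) -> float:
    s = np.arange(max(1, y0lo + y1lo), y0hi + y1hi + 1, dtype=np.float64)
    if s.size == 0:
        return 0.0
    alo = np.maximum(y0lo, s - y1hi)
    ahi = np.minimum(y0hi, s - y1lo)
    mean, var = cond.moments(s)
    hw = _Z_WINDOW * np.sqrt(var) + _MIN_HALF_WIDTH
    lo = np.minimum(alo, np.maximum(0.0, mean - hw))
    hi = np.maximum(ahi, np.minimum(s, mean + hw))
    return float(np.sum(np.maximum(hi - lo + 1.0, 0.0)))


def single_gene_power(gene, design, alpha: float, *, trunc_tol: float = 1e-12,
                      max_total: int = _MAX_TOTAL,
                      max_workload: float = _MAX_WORKLOAD,
                      method: str = "auto") -> float:
    """Analytic power of the exact test for one gene at level ``alpha``.

    Parameters
    ----------
    gene : GeneParams or (mu, phi)
        Control-group mean read count and dispersion.
    design : DesignSpec or (n0, n1, rho[, omega])
        Two-group design.
    alpha : float
        Marginal type I error; the rejection indicator is the strict
        inequality ``p < alpha``.
    trunc_tol : float
        Each marginal alternative sum is truncated at its ``trunc_tol`` and
        ``1 - trunc_tol`` NB quantiles; the neglected mass (< 4 *
        trunc_tol) bounds the power error and is logged at DEBUG level.
    max_total, max_workload :
        Resource caps.  Totals beyond ``max_total`` raise
        :class:`ResourceLimitError` rather than silently truncating;
        enumeration workloads beyond ``max_workload`` switch to the
        high-count approximation (``method='auto'``).
    method : {'auto', 'exact', 'approx'}
        Force a path, or let the estimated workload decide.
    """
    if not isinstance(gene, GeneParams):
        gene = GeneParams(*gene)
    if not isinstance(design, DesignSpec):
        design = DesignSpec(*design)
    alpha = float(alpha)
    if not 0.0 <= alpha <= 1.0 or not math.isfinite(alpha):
        raise InvalidParameterError(f"alpha must be in [0, 1], got {alpha!r}")
    if method not in ("auto", "exact", "approx"):
        raise InvalidParameterError(f"unknown method {method!r}")
    if alpha == 0.0 or gene.mu == 0.0:
        # p-values are strictly positive, so I(p < 0) never fires
        return 0.0
    mu, phi = gene.mu, gene.phi
    n0, n1, rho, omega = design.n0, design.n1, design.rho, design.omega
    d0 = phi / n0
    d1 = phi / n1
    y0lo, y0hi = _alt_bounds(n0 * mu, d0, trunc_tol)
    y1lo, y1hi = _alt_bounds(n1 * omega * rho * mu, d1, trunc_tol)
    if y0hi + y1hi > max_total:
        raise ResourceLimitError(
            f"largest admissible total {y0hi + y1hi} exceeds max_total={max_total}; "
            "raise max_total explicitly to proceed")
    if method == "auto":
        cond = _ConditionalNull(n0, n1, phi, omega, 0)
        work = _estimate_workload(y0lo, y0hi, y1lo, y1hi, cond)
        method = "exact" if work <= max_workload else "approx"
        logger.debug("power path %s (estimated workload %.3g)", method, work)
    if method == "exact":
        return _power_exact(mu, phi, n0, n1, rho, omega, alpha, trunc_tol)
    return _power_boundary(mu, phi, n0, n1, rho, omega, alpha, trunc_tol)
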