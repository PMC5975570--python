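"""Negative-binomial pmf, conditional exact test and single-gene power."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from seqpower import (
    DesignSpec,
    GeneParams,
    InvalidParameterError,
    ResourceLimitError,
    exact_test_pvalue,
    exact_test_pvalues_pseudo,
    nb_logpmf,
    nb_pmf,
    nb_quantile,
    single_gene_power,
)


def brute_force_pvalue(y0, y1, m0, m1, d0, d1):
    """Independent enumeration oracle over all splits of the total."""
    s = y0 + y1
    if s == 0:
        return 1.0
    a = np.arange(s + 1)

    def pmf(y, mu, disp):
        if disp < 1e-8:
            return stats.poisson.pmf(y, mu)
        r = 1.0 / disp
        return stats.nbinom.pmf(y, r, r / (r + mu))

    q = pmf(a, m0, d0) * pmf(s - a, m1, d1)
    # ties included, with the customary relative slack against rounding
    return float(q[q <= q[y0] * (1 + 1e-7)].sum() / q.sum())


class TestNbPmf:
    def test_closed_form_value(self):
        # (1/(1+phi*mu))**(1/phi) at y=0: (1/2)**2
        assert nb_pmf(0, 2.0, 0.5) == pytest.approx(0.25, abs=1e-12)

    def test_poisson_limit(self):
        assert nb_pmf(3, 3.0, 1e-12) == pytest.approx(math.exp(-3) * 27 / 6, abs=1e-6)

    def test_normalizes_over_truncated_support(self):
        hi = nb_quantile(1 - 1e-12, 50.0, 0.4)
        total = nb_pmf(np.arange(hi + 1), 50.0, 0.4).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("mu,phi", [(3.0, 0.7), (40.0, 0.05), (1.5, 2.5)])
    def test_matches_scipy_parameterization(self, mu, phi):
        y = np.arange(0, 60)
        r = 1.0 / phi
        np.testing.assert_allclose(
            nb_pmf(y, mu, phi), stats.nbinom.pmf(y, r, r / (r + mu)), rtol=1e-12)

    @pytest.mark.parametrize("bad", [dict(y=-1, mu=2, phi=1), dict(y=2, mu=np.inf, phi=1),
                                     dict(y=2, mu=2, phi=np.nan), dict(y=1.5, mu=2, phi=1)])
    def test_domain_errors(self, bad):
        with pytest.raises(InvalidParameterError):
            nb_logpmf(bad["y"], bad["mu"], bad["phi"])


class TestExactTest:
    def test_modal_pair_has_pvalue_one(self):
        assert exact_test_pvalue(7, 7, 10.0, 10.0, 0.3, 0.3) == 1.0

    def test_zero_total_is_uninformative(self):
        assert exact_test_pvalue(0, 0, 5.0, 5.0, 0.2, 0.2) == 1.0

    def test_poisson_conditional_is_binomial(self):
        # null means equal, dispersion 0: conditional law Binomial(4, 1/2),
        # extreme splits 0 and 4 each carry 1/16
        assert exact_test_pvalue(0, 4, 1.0, 1.0, 0.0, 0.0) == pytest.approx(0.125)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            exact_test_pvalue(-1, 3, 1.0, 1.0, 0.1, 0.1)

    @given(
        y0=st.integers(0, 25),
        y1=st.integers(0, 25),
        m0=st.floats(0.3, 15.0),
        ratio=st.floats(0.2, 5.0),
        d0=st.floats(0.0, 2.5),
        d1=st.floats(0.0, 2.5),
    )
    def test_matches_enumeration_oracle(self, y0, y1, m0, ratio, d0, d1):
        mine = exact_test_pvalue(y0, y1, m0, m0 * ratio, d0, d1)
        oracle = brute_force_pvalue(y0, y1, m0, m0 * ratio, d0, d1)
        assert mine == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_batch_agrees_with_single_pair_common_mean(self, rng):
        n0, n1, phi, omega = 7, 5, 0.6, 1.3
        y0 = rng.integers(0, 120, 40)
        y1 = rng.integers(0, 160, 40)
        batch = exact_test_pvalues_pseudo(y0, y1, n0, n1, phi, omega)
        for i in range(40):
            muhat = (y0[i] + y1[i]) / (n0 + n1 * omega)
            if muhat == 0:
                continue
            single = exact_test_pvalue(int(y0[i]), int(y1[i]),
                                       n0 * muhat, n1 * omega * muhat,
                                       phi / n0, phi / n1)
            assert batch[i] == pytest.approx(single, rel=1e-9)


class TestSingleGenePower:
    def test_alpha_zero_gives_zero_power(self):
        assert single_gene_power((5, 0.5), (10, 10, 2.0, 1.0), 0.0) == 0.0

    def test_null_power_bounded_by_alpha(self):
        # under rho=1 the power is the size of a conservative discrete test
        for alpha in (0.01, 0.05, 0.2):
            size = single_gene_power((5, 0.5), (5, 5, 1.0, 1.0), alpha)
            assert 0.0 <= size <= alpha

    def test_matches_naive_per_pair_enumeration(self):
        from seqpower.nbexact import nb_quantile as q

        mu, phi, n, rho, alpha = 3.0, 0.5, 4, 2.0, 0.05
        m0, m1 = n * mu, n * rho * mu
        d = phi / n
        y0hi, y1hi = q(1 - 1e-12, m0, d), q(1 - 1e-12, m1, d)
        f0 = nb_pmf(np.arange(y0hi + 1), m0, d)
        f1 = nb_pmf(np.arange(y1hi + 1), m1, d)
        naive = 0.0
        for y0 in range(y0hi + 1):
            for y1 in range(y1hi + 1):
                if y0 + y1 == 0:
                    continue
                muhat = (y0 + y1) / (2 * n)
                if exact_test_pvalue(y0, y1, n * muhat, n * muhat, d, d) < alpha:
                    naive += f0[y0] * f1[y1]
        engine = single_gene_power((mu, phi), (n, n, rho, 1.0), alpha)
        assert engine == pytest.approx(naive, abs=1e-12)

    def test_monotone_in_design_parameters(self):
        alpha = 0.01
        base = dict(mu=8.0, phi=0.5, n=8, rho=2.0)

        def power(mu=None, phi=None, n=None, rho=None):
            p = {**base, **{k: v for k, v in dict(mu=mu, phi=phi, n=n, rho=rho).items()
                            if v is not None}}
            return single_gene_power((p["mu"], p["phi"]),
                                     (p["n"], p["n"], p["rho"], 1.0), alpha)

        assert power() <= power(n=16) <= power(n=32)            # more samples
        assert power() <= power(mu=16.0) <= power(mu=32.0)       # deeper counts
        assert power() >= power(phi=1.0) >= power(phi=2.0)       # noisier genes
        assert power(rho=1.0) <= power(rho=1.5) <= power()       # larger effect

    def test_unbalanced_reduces_to_balanced(self):
        alpha = 0.01
        pb = single_gene_power(GeneParams(6, 0.4), DesignSpec.balanced(6, 2.0), alpha)
        pu = single_gene_power(GeneParams(6, 0.4), DesignSpec(6, 6, 2.0), alpha)
        assert pb == pu

    def test_boundary_path_close_to_exact(self):
        alpha = 4.253e-4
        pe = single_gene_power((150, 0.4), (30, 30, 2.0, 1.0), alpha,
                               method="exact", max_workload=1e10)
        pb = single_gene_power((150, 0.4), (30, 30, 2.0, 1.0), alpha,
                               method="approx")
        assert pb == pytest.approx(pe, abs=2e-3)

    def test_resource_cap_raises_not_truncates(self):
        with pytest.raises(ResourceLimitError):
            single_gene_power((2000, 2.0), (200, 200, 2.0, 1.0), 0.01,
                              max_total=10_000)

    def test_alpha_domain_error(self):
        with pytest.raises(InvalidParameterError):
            single_gene_power((5, 0.5), (5, 5, 2.0, 1.0), 1.5)
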