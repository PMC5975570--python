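"""Distribution estimation, gene-set filtering and resampled power."""
import math

import numpy as np
import pandas as pd
import pytest

from seqpower import (
    FDRSpec,
    GeneDistribution,
    InvalidParameterError,
    ResamplingConfig,
    SimScenario,
    estimate_distribution,
    filter_genes,
    generate_counts,
    generate_distribution,
    required_sample_size,
    required_sample_size_empirical,
    resampled_power,
    single_gene_power,
)

FDR = FDRSpec(fdr=0.05, m=1000, m1=50)


def make_dist(rows: dict) -> GeneDistribution:
    return GeneDistribution(table=pd.DataFrame(rows, index=["mu", "phi"]).T)


class TestEstimateDistribution:
    def test_identical_columns_give_zero_dispersion(self):
        counts = pd.DataFrame(np.tile([[4], [9], [30]], (1, 8)),
                              index=["g1", "g2", "g3"])
        dist = estimate_distribution(counts)
        assert (dist.table.phi <= 1e-6).all()
        assert dist.table.mu.to_numpy() == pytest.approx([4, 9, 30])

    def test_depth_change_absorbed_by_normalization(self):
        sc = SimScenario(n_genes=300, n_control=50, libsize_log_sd=0.0, seed=21)
        counts, _, _ = generate_counts(sc)
        doubled = counts.copy()
        doubled.iloc[:, 0] = doubled.iloc[:, 0] * 2
        mu_a = estimate_distribution(counts).table.mu
        mu_b = estimate_distribution(doubled).table.mu
        common = mu_a.index.intersection(mu_b.index)
        ratio = (mu_b[common] / mu_a[common]).to_numpy()
        assert np.abs(ratio - 1).max() < 0.02

    def test_single_sample_rejected(self):
        counts = pd.DataFrame({"s1": [3, 5]}, index=["g1", "g2"])
        with pytest.raises(InvalidParameterError):
            estimate_distribution(counts)

    def test_all_genes_filtered_is_an_error(self):
        counts = pd.DataFrame(np.zeros((3, 4), dtype=int) + [[1], [0], [1]],
                              index=["a", "b", "c"])
        with pytest.raises(InvalidParameterError):
            estimate_distribution(counts, min_mean=100.0)

    def test_group_labels_restrict_to_control(self):
        sc = SimScenario(n_genes=200, n_control=40, n_treatment=40, m1=50,
                         rho=4.0, libsize_log_sd=0.0, seed=33)
        counts, truth, groups = generate_counts(sc)
        ctrl_only = estimate_distribution(counts, groups=groups)
        pooled = estimate_distribution(counts)
        de = truth.index[truth.de].intersection(ctrl_only.table.index)
        de = de.intersection(pooled.table.index)
        # pooling both groups inflates DE-gene means; restriction does not
        assert pooled.table.mu[de].median() > 1.2 * ctrl_only.table.mu[de].median()

    def test_provenance_determines_distribution(self):
        sc = SimScenario(n_genes=100, n_control=20, seed=8)
        counts, _, _ = generate_counts(sc)
        d1 = estimate_distribution(counts)
        d2 = estimate_distribution(counts)
        assert d1.table.equals(d2.table)
        assert d1.provenance == d2.provenance


class TestFilterGenes:
    def test_identity_on_full_set(self):
        dist = make_dist({"a": (5, 0.2), "b": (9, 0.4)})
        out = filter_genes(dist, ["a", "b"])
        assert out.table.equals(dist.table)

    def test_single_gene_reduces_to_single_gene_power(self):
        dist = make_dist({"a": (5, 0.2), "b": (9, 0.4)})
        sub = filter_genes(dist, ["b"])
        cfg = ResamplingConfig(m1=1, reps=5, seed=0)
        pd_ = resampled_power(sub, 6, 2.0, FDR, cfg, target_power=0.8)
        direct = single_gene_power((9, 0.4), (6, 6, 2.0, 1.0), pd_.alpha_star)
        assert pd_.summary == pytest.approx(direct, abs=1e-12)

    def test_disjoint_set_raises(self):
        dist = make_dist({"a": (5, 0.2)})
        with pytest.raises(InvalidParameterError):
            filter_genes(dist, ["zzz"])

    def test_duplicates_warn(self):
        dist = make_dist({"a": (5, 0.2), "b": (9, 0.4)})
        with pytest.warns(UserWarning):
            filter_genes(dist, ["a", "a"])


class TestResampledPower:
    def test_degenerate_distribution_equals_single_gene(self):
        dist = make_dist({f"g{i}": (10, 0.5) for i in range(20)})
        cfg = ResamplingConfig(m1=5, reps=50, seed=3)
        out = resampled_power(dist, 8, 2.0, FDR, cfg, target_power=0.8)
        direct = single_gene_power((10, 0.5), (8, 8, 2.0, 1.0), out.alpha_star)
        assert out.rep_powers == pytest.approx(np.full(50, direct))
        assert out.summary == pytest.approx(direct)

    def test_two_point_distribution_exact_average(self):
        dist = make_dist({"a": (4, 0.3), "b": (20, 0.6)})
        cfg = ResamplingConfig(m1=2, reps=25, seed=1)
        out = resampled_power(dist, 6, 2.0, FDR, cfg, target_power=0.8)
        pa = single_gene_power((4, 0.3), (6, 6, 2.0, 1.0), out.alpha_star)
        pb = single_gene_power((20, 0.6), (6, 6, 2.0, 1.0), out.alpha_star)
        assert out.summary == pytest.approx((pa + pb) / 2, abs=1e-12)

    def test_seeded_reproducibility_is_bitwise(self):
        dist = generate_distribution(SimScenario(n_genes=30, seed=2))
        cfg = ResamplingConfig(m1=10, reps=40, seed=77)
        a = resampled_power(dist, 5, 2.0, FDR, cfg, target_power=0.8)
        b = resampled_power(dist, 5, 2.0, FDR, cfg, target_power=0.8)
        assert (a.rep_powers == b.rep_powers).all()
        assert a.summary == b.summary

    def test_oversampling_without_replacement_rejected(self):
        dist = make_dist({"a": (5, 0.2)})
        cfg = ResamplingConfig(m1=3, reps=5, seed=0)
        with pytest.raises(InvalidParameterError, match="replace"):
            resampled_power(dist, 5, 2.0, FDR, cfg, target_power=0.8)

    def test_fixedpoint_alpha_when_no_target(self):
        dist = make_dist({"a": (10, 0.4), "b": (15, 0.3)})
        cfg = ResamplingConfig(m1=2, reps=10, seed=0)
        out = resampled_power(dist, 10, 2.0, FDR, cfg)
        scale = FDR.fdr * FDR.m1 / ((1 - FDR.fdr) * (FDR.m - FDR.m1))
        mean_power = float(out.gene_powers.mean())
        assert out.alpha_star == pytest.approx(scale * mean_power, abs=1e-6)

    def test_pathway_contrast_high_count_low_dispersion_wins(self):
        # high-count/low-dispersion gene sets yield strictly higher power
        # than low-count/high-dispersion ones at the same n
        favorable = make_dist({f"p{i}": (80 + i, 0.1) for i in range(10)})
        unfavorable = make_dist({f"c{i}": (2 + 0.1 * i, 1.5) for i in range(10)})
        cfg = ResamplingConfig(m1=5, reps=30, seed=5)
        hi = resampled_power(favorable, 8, 2.0, FDR, cfg, target_power=0.8)
        lo = resampled_power(unfavorable, 8, 2.0, FDR, cfg, target_power=0.8)
        assert hi.summary > lo.summary


class TestEmpiricalSampleSize:
    def test_degenerate_distribution_matches_single_value_solver(self):
        dist = make_dist({"a": (8, 0.6)})
        cfg = ResamplingConfig(m1=1, reps=10, seed=0)
        res = required_sample_size_empirical(dist, 2.0, FDR, 0.7, cfg)
        n_direct = required_sample_size((8, 0.6), 2.0, FDR, 0.7)
        assert res.n == n_direct

    def test_stochastic_dominance_in_gene_quality(self):
        worse = make_dist({f"g{i}": (4 + 0.2 * i, 1.0) for i in range(12)})
        better = make_dist({f"g{i}": (8 + 0.4 * i, 0.5) for i in range(12)})
        cfg = ResamplingConfig(m1=6, reps=15, seed=9)
        n_worse = required_sample_size_empirical(worse, 2.0, FDR, 0.7, cfg).n
        n_better = required_sample_size_empirical(better, 2.0, FDR, 0.7, cfg).n
        assert n_better <= n_worse

    def test_fixed_seed_gives_stable_n(self):
        dist = generate_distribution(SimScenario(n_genes=40, mu_log_sd=0.5, seed=6))
        cfg = ResamplingConfig(m1=15, reps=10, seed=123)
        a = required_sample_size_empirical(dist, 2.0, FDR, 0.7, cfg)
        b = required_sample_size_empirical(dist, 2.0, FDR, 0.7, cfg)
        assert a.n == b.n and a.summary_at_n == b.summary_at_n
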