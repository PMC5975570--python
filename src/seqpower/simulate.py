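"""Synthetic NB count matrices and gene-parameter distributions with known truth.

Emulates the salient features of a bulk RNA-seq reference matrix: gene
mean read counts spread over orders of magnitude (log-normal law),
dispersions tied to expression through a decreasing trend
``phi(mu) = a / mu + b`` with log-normal gene-level noise, per-sample
library-size factors, and (optionally) a treatment group in which a chosen
number of genes is differentially expressed at a common fold change.
Batch structure and gene-gene correlation are deliberately not modelled.

Every draw is reproducible from the scenario seed, and the ground-truth
(mu, phi, DE flag) table is emitted alongside the counts so estimation and
resampling code can be tested against known truth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import PHI_FLOOR, InvalidParameterError

__all__ = ["SimScenario", "generate_truth", "generate_counts", "generate_distribution"]


@dataclass(frozen=True)
class SimScenario:
    """Generator settings; defaults sketch a moderate bulk RNA-seq study."""

    n_genes: int = 2000
    n_control: int = 100
    n_treatment: int = 0          # 0 -> single-group reference matrix
    mu_log_mean: float = math.log(10.0)
    mu_log_sd: float = 1.2
    trend_a: float = 0.5          # phi(mu) = trend_a / mu + trend_b
    trend_b: float = 0.2
    phi_log_sd: float = 0.2       # log-normal gene-level noise around the trend
    m1: int = 0                   # number of DE genes (treatment group only)
    rho: float = 2.0              # fold change applied to DE genes
    libsize_log_sd: float = 0.15
    seed: int = 0
    max_mean: float = 1e7         # overflow guard for extreme draws

    def __post_init__(self):
        if self.n_genes < 1 or self.n_control < 1 or self.n_treatment < 0:
            raise InvalidParameterError("n_genes, n_control must be >= 1; n_treatment >= 0")
        if not 0 <= self.m1 <= self.n_genes:
            raise InvalidParameterError("m1 must be in [0, n_genes]")
        if self.m1 > 0 and self.n_treatment == 0:
            raise InvalidParameterError("DE genes require a treatment group")
        if self.rho <= 0 or self.mu_log_sd < 0 or self.phi_log_sd < 0:
            raise InvalidParameterError("rho must be > 0 and spreads >= 0")
        if self.trend_a < 0 or self.trend_b < 0:
            raise InvalidParameterError("trend coefficients must be >= 0")


def _rng(sc: SimScenario, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(sc.seed), stream]))


def generate_truth(sc: SimScenario) -> pd.DataFrame:
    """Ground-truth table: gene id, mu, phi, DE flag and fold change."""
    rng = _rng(sc, 0)
    width = max(4, len(str(sc.n_genes)))
    genes = [f"G{i + 1:0{width}d}" for i in range(sc.n_genes)]
    mu = np.minimum(
        np.exp(rng.normal(sc.mu_log_mean, sc.mu_log_sd, size=sc.n_genes)),
        sc.max_mean)
    trend = sc.trend_a / np.maximum(mu, 1e-12) + sc.trend_b
    phi = trend * np.exp(rng.normal(0.0, sc.phi_log_sd, size=sc.n_genes))
    de = np.zeros(sc.n_genes, dtype=bool)
    if sc.m1:
        de[rng.choice(sc.n_genes, size=sc.m1, replace=False)] = True
    return pd.DataFrame(
        {"mu": mu, "phi": phi, "de": de, "rho": np.where(de, sc.rho, 1.0)},
        index=pd.Index(genes, name="gene"))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi < PHI_FLOOR
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        lam = rng.gamma(shape=r, scale=mean[nb] / r)
        out[nb] = rng.poisson(lam)
    return out


def generate_counts(sc: SimScenario):
    """Draw a count matrix (genes x samples) plus truth table and group labels.

    Returns ``(counts, truth, groups)``: counts is an integer DataFrame,
    groups a Series mapping sample id to 'control'/'treatment'.  Entry
    (g, j) is NB with mean ``sizefactor_j * mu_g * (rho if DE and j
    treated)`` and dispersion ``phi_g``.
    """
    truth = generate_truth(sc)
    rng = _rng(sc, 1)
    n_samples = sc.n_control + sc.n_treatment
    factors = np.exp(rng.normal(0.0, sc.libsize_log_sd, size=n_samples))
    labels = ["control"] * sc.n_control + ["treatment"] * sc.n_treatment
    samples = [f"S{j + 1:03d}" for j in range(n_samples)]
    mu = truth["mu"].to_numpy()
    phi = truth["phi"].to_numpy()
    fold = truth["rho"].to_numpy()
    counts = np.empty((sc.n_genes, n_samples), dtype=np.int64)
    for j in range(n_samples):
        mean_j = factors[j] * mu * (fold if labels[j] == "treatment" else 1.0)
        counts[:, j] = _nb_draw(rng, np.minimum(mean_j, sc.max_mean), phi)
    counts = pd.DataFrame(counts, index=truth.index, columns=samples)
    groups = pd.Series(labels, index=counts.columns, name="group")
    return counts, truth, groups


def generate_distribution(sc: SimScenario):
    """Ground-truth GeneDistribution (bypasses estimation entirely)."""
    from .empirical import GeneDistribution

    truth = generate_truth(sc)
    table = truth[["mu", "phi"]].copy()
    provenance = {
        "source": "synthetic",
        "scenario": {k: getattr(sc, k) for k in sc.__dataclass_fields__},
    }
    return GeneDistribution(table=table, provenance=provenance)
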