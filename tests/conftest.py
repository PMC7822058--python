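"""Shared fixtures: small simulated panels and one full-scale power run.

Everything is generated programmatically with fixed seeds; the expensive
hide-a-causal-SNP experiment at the full panel size is session-scoped so
the power and acceptance checks share a single run.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import cholesky

from rhmap import (
    DesignLayout,
    PowerConfig,
    SimConfig,
    TraitTruth,
    run_power_experiment,
    simulate_genotypes,
    simulate_phenotypes,
)
from rhmap.grm import vanraden_grm


def grm_chol(geno):
    G = vanraden_grm(geno).matrix
    return cholesky(G + 1e-6 * np.mean(np.diag(G)) * np.eye(G.shape[0]), lower=True)


def background_pheno_generator(geno, h2=0.57, fixed_effect_sd=0.5):
    """Closure drawing background-only traits, amortizing the GRM factor."""
    Gc = grm_chol(geno)
    truth = TraitTruth(h2_background=h2, residual_variance=max(1.0 - h2, 1e-6),
                       fixed_effect_sd=fixed_effect_sd)

    def gen(seed):
        return simulate_phenotypes(geno, truth, DesignLayout(), seed=seed, grm_chol=Gc)[0]

    return gen


@pytest.fixture(scope="session")
def small_geno():
    """200 clones, 2 chromosomes x 250 SNPs, default LD."""
    return simulate_genotypes(SimConfig(n_clones=200, n_chromosomes=2,
                                        snps_per_chromosome=250, seed=42))


@pytest.fixture(scope="session")
def midsize_geno():
    """150 clones, 3 chromosomes x 300 SNPs — enough windows for batteries."""
    return simulate_genotypes(SimConfig(n_clones=150, n_chromosomes=3,
                                        snps_per_chromosome=300, seed=7))


@pytest.fixture(scope="session")
def full_geno():
    """The study-scale panel: 451 clones, 18 chromosomes."""
    return simulate_genotypes(SimConfig(seed=1))


@pytest.fixture(scope="session")
def power_full(full_geno):
    """72-test hide-a-causal-SNP run at the study scale (shared)."""
    gen = background_pheno_generator(full_geno)
    cfg = PowerConfig(variance_fraction=0.10, repetitions=4, seed=2)
    return run_power_experiment(full_geno, gen, cfg)


@pytest.fixture(scope="session")
def power_full_battery(full_geno):
    """Factory for reduced-repetition power runs on the study-scale panel."""
    gen = background_pheno_generator(full_geno)

    def run(variance_fraction, repetitions=1, seed=5):
        cfg = PowerConfig(variance_fraction=variance_fraction,
                          repetitions=repetitions, seed=seed)
        return run_power_experiment(full_geno, gen, cfg)

    return run


@pytest.fixture(scope="session")
def power_small_battery(midsize_geno):
    """Factory for quick power runs on the midsize panel."""
    gen = background_pheno_generator(midsize_geno)

    def run(variance_fraction, repetitions=6, seed=5):
        cfg = PowerConfig(variance_fraction=variance_fraction,
                          repetitions=repetitions, seed=seed)
        return run_power_experiment(midsize_geno, gen, cfg)

    return run
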