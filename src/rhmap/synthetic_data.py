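"""Synthetic genotypes, phenotypes, and gene models for a clonal crop panel.

The generator emulates the statistical structure the scan assumes: a panel
of a few hundred clones genotyped at dense biallelic SNPs with tunable
adjacent-marker linkage disequilibrium, a trait with a polygenic background
drawn from the panel's own genomic relationship matrix (so the background
kernel is correctly specified under the null), optional segment QTLs of a
stated phenotypic-variance fraction, and plot-level records from an
augmented trial design with trial-within-year-within-location fixed
effects.

LD model: a first-order haplotype copying chain.  Within a chromosome each
haplotype either repeats its own allele at the previous marker (probability
``ld_rho``) or draws a fresh allele at the population frequency.  This is
the simplest process with a single dial for adjacent-marker r2; it has no
long-range structure, recombination hotspots, or allele-frequency/LD
coupling.

Defaults mirror the study conditions: 451 clones, 18 chromosomes,
whole-genome heritability around 0.57, and a QTL variance fraction of 0.10
where one is injected.  The SNP count per chromosome (300) is a desk-scale
density; real genotyping-by-sequencing panels are ~30x denser.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cholesky

from .grm import vanraden_grm
from .io_formats import (
    GeneAnnotation,
    GenotypeMatrix,
    PhenotypeTable,
    genotype_matrix_from_dosages,
)

import pandas as pd

__all__ = [
    "SimConfig",
    "DesignLayout",
    "TraitTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_gene_annotation",
]


@dataclass
class SimConfig:
    """Genotype-simulation settings (defaults are the study conditions)."""

    n_clones: int = 451
    n_chromosomes: int = 18
    snps_per_chromosome: int = 300
    maf_min: float = 0.05
    ld_rho: float = 0.7
    chrom_length_bp: int = 30_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_clones, self.n_chromosomes, self.snps_per_chromosome) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 < self.maf_min <= 0.5:
            raise ValueError(f"maf_min must be in (0, 0.5], got {self.maf_min}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if self.chrom_length_bp < self.snps_per_chromosome:
            raise ValueError("chrom_length_bp too small for the requested SNP count")


@dataclass
class DesignLayout:
    """Balanced augmented-trial layout: trials nested in year in location."""

    n_locations: int = 3
    n_years: int = 2
    trials_per_cell: int = 2
    plots_per_clone: int = 1


@dataclass
class TraitTruth:
    """Ground truth for a simulated trait.

    ``h2_background`` and each QTL fraction are fractions of the total
    phenotypic variance (which the generator sets to
    residual_variance / (1 - h2_background - sum of QTL fractions)).
    ``true_clone_values`` and ``qtl_betas`` are filled by
    :func:`simulate_phenotypes`.
    """

    h2_background: float = 0.57
    qtl_list: list = field(default_factory=list)  # [(marker_id, variance fraction), ...]
    fixed_effect_sd: float = 0.0
    residual_variance: float = 1.0
    true_clone_values: dict = field(default_factory=dict)
    qtl_betas: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fr = self.h2_background + sum(f for _, f in self.qtl_list)
        if fr > 1.0 + 1e-12:
            raise ValueError(f"h2_background + QTL fractions = {fr:.3f} exceeds 1")
        if self.residual_variance < 0:
            raise ValueError("residual_variance must be >= 0")

    @property
    def total_phenotypic_variance(self) -> float:
        fr = self.h2_background + sum(f for _, f in self.qtl_list)
        if fr >= 1.0:
            raise ValueError("genetic fractions sum to 1; total variance undefined with residual > 0")
        return self.residual_variance / (1.0 - fr)


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw dosages from the haplotype copying chain and filter on MAF.

    Markers whose realized minor-allele frequency falls below
    ``cfg.maf_min`` are removed; marker IDs follow ``S{chrom}_{pos}`` with
    strictly increasing positions per chromosome.
    """
    rng = np.random.default_rng(cfg.seed)
    n_hap = 2 * cfg.n_clones
    all_ids: list[str] = []
    all_cols: list[np.ndarray] = []
    for chrom in range(1, cfg.n_chromosomes + 1):
        m = cfg.snps_per_chromosome
        pos = np.sort(rng.choice(cfg.chrom_length_bp, size=m, replace=False)) + 1
        p = rng.uniform(cfg.maf_min, 1.0 - cfg.maf_min, size=m)
        H = np.empty((n_hap, m), dtype=np.int8)
        H[:, 0] = rng.random(n_hap) < p[0]
        for j in range(1, m):
            copy = rng.random(n_hap) < cfg.ld_rho
            fresh = rng.random(n_hap) < p[j]
            H[:, j] = np.where(copy, H[:, j - 1], fresh)
        D = H[0::2] + H[1::2]
        maf = np.minimum(D.mean(axis=0) / 2.0, 1.0 - D.mean(axis=0) / 2.0)
        keep = maf >= cfg.maf_min
        ids = [f"S{chrom}_{q}" for q in pos[keep]]
        all_ids.extend(ids)
        all_cols.append(D[:, keep])
    if not all_ids:
        raise ValueError(
            f"no markers survived the MAF >= {cfg.maf_min} filter; "
            "lower maf_min or increase the panel size"
        )
    dosages = np.concatenate(all_cols, axis=1)
    clones = [f"clone{i:04d}" for i in range(cfg.n_clones)]
    return genotype_matrix_from_dosages(clones, all_ids, dosages)


def _background_values(geno: GenotypeMatrix, rng, grm_chol=None) -> np.ndarray:
    """Unit draws with covariance proportional to the whole-genome GRM."""
    if grm_chol is None:
        G = vanraden_grm(geno).matrix
        G = G + 1e-6 * np.mean(np.diag(G)) * np.eye(G.shape[0])
        grm_chol = cholesky(G, lower=True)
    return grm_chol @ rng.standard_normal(grm_chol.shape[0])


def simulate_phenotypes(
    geno: GenotypeMatrix,
    truth: TraitTruth,
    design: DesignLayout | None = None,
    seed: int = 0,
    grand_mean: float = 0.0,
    grm_chol=None,
) -> tuple[PhenotypeTable, TraitTruth]:
    """Simulate plot-level phenotypes for the clones in ``geno``.

    y = grand mean + trial effect + sum_q beta_q dosage_q + polygenic
    background + residual.  The background is drawn with covariance
    proportional to the whole-genome GRM and rescaled so its in-sample
    variance equals ``h2_background`` of the total phenotypic variance;
    QTL effects are sized against the realized dosage variance, with a
    random sign.  Pass ``grm_chol`` (a lower-triangular factor of the
    GRM) to amortize the factorization across repeated calls.

    Returns the phenotype table and a copy of ``truth`` with
    ``true_clone_values`` and ``qtl_betas`` filled.
    """
    design = design or DesignLayout()
    rng = np.random.default_rng(seed)
    n = geno.n_clones
    vp = truth.total_phenotypic_variance

    g = np.zeros(n)
    if truth.h2_background > 0:
        g0 = _background_values(geno, rng, grm_chol)
        sd0 = g0.std()
        if sd0 > 0:
            g = g0 * np.sqrt(truth.h2_background * vp) / sd0

    betas: dict[str, float] = {}
    qtl_part = np.zeros(n)
    for marker, frac in truth.qtl_list:
        j = geno.marker_indices([marker])[0]
        x = geno.dosages[:, j].astype(float)
        vx = x.var()
        if vx == 0:
            raise ValueError(f"QTL marker {marker!r} is monomorphic")
        beta = float(rng.choice([-1.0, 1.0]) * np.sqrt(frac * vp / vx))
        betas[marker] = beta
        qtl_part += beta * (x - x.mean())

    genetic = g + qtl_part

    # plot layout: each plot assigned to a uniformly random trial cell
    cells = [
        (f"loc{i + 1}", f"year{j + 1}", f"trial{k + 1}")
        for i in range(design.n_locations)
        for j in range(design.n_years)
        for k in range(design.trials_per_cell)
    ]
    trial_fx = rng.normal(0.0, truth.fixed_effect_sd, size=len(cells))
    rows = []
    for rep in range(design.plots_per_clone):
        cell_idx = rng.integers(0, len(cells), size=n)
        e = rng.normal(0.0, np.sqrt(truth.residual_variance), size=n)
        for i, c in enumerate(geno.clone_ids):
            loc, yr, tr = cells[cell_idx[i]]
            rows.append(
                (c, loc, yr, tr, grand_mean + trial_fx[cell_idx[i]] + genetic[i] + e[i])
            )
    df = pd.DataFrame(rows, columns=["clone", "location", "year", "trial", "value"])
    out_truth = replace(
        truth,
        true_clone_values={c: float(v) for c, v in zip(geno.clone_ids, genetic)},
        qtl_betas=betas,
    )
    return PhenotypeTable(df), out_truth


def simulate_gene_annotation(
    geno: GenotypeMatrix,
    n_genes: int = 100,
    mean_gene_length: int = 3000,
    seed: int = 0,
) -> GeneAnnotation:
    """Place genes uniformly on the chromosomes spanned by ``geno``.

    Gene lengths are exponential with the given mean (floored at 200 bp);
    intervals are 0-based half-open, within-chromosome, with unique IDs.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = geno.chromosomes()
    # chromosome extent taken from the outermost marker, padded
    extents = {
        c: int(geno.markers.loc[geno.markers["chrom"] == c, "pos"].max()) + 10_000
        for c in chroms
    }
    rows = []
    for i in range(n_genes):
        c = chroms[rng.integers(len(chroms))]
        length = max(200, int(rng.exponential(mean_gene_length)))
        if length >= extents[c]:
            raise ValueError(
                f"drawn gene length {length} exceeds chromosome {c} extent {extents[c]}"
            )
        start = int(rng.integers(0, extents[c] - length))
        rows.append(
            {
                "gene_id": f"gene{i + 1:05d}",
                "chrom": c,
                "start": start,
                "end": start + length,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    df = pd.DataFrame(rows).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return GeneAnnotation(df)
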