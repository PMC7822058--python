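"""Kernel-partitioned GBLUP cross-validation of candidate SNP sets.

A candidate set (SNPs flanking a gene list, or within a span of scan hits)
splits the genome into two kernels.  Model 2,

    y = X beta + Z s + Z g + e,   s ~ N(0, sigma2_s K_s),  g ~ N(0, sigma2_g K_g),

attributes genetic variance jointly to the candidate kernel K_s and the
rest-of-genome kernel K_g.  Five-fold cross-validation (10 repeats)
predicts held-out clones' candidate effects s_hat through the candidate
kernel's train-test cross-covariance, and accuracy is the correlation of
the pooled held-out s_hat with the clone values u_hat from Model 3 — a
single-kernel fit with identity covariance (clones treated as unrelated)
on all data.  A candidate set that truly tags trait variation beats a
size-matched random control; the whole-genome kernel is the ceiling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.model_selection import KFold

from .grm import vanraden_grm
from .io_formats import GeneAnnotation, GenotypeMatrix, PhenotypeTable
from .varcomp import ModelDesign, VarCompFit, fit_reml

log = logging.getLogger(__name__)

__all__ = [
    "SnpSetPartition",
    "CvAccuracy",
    "extract_flank_snps",
    "extract_region_snps",
    "sample_control_genes",
    "fit_model3",
    "cross_validate",
    "enrichment",
]


@dataclass
class SnpSetPartition:
    """Candidate SNPs vs the remaining genome, with provenance."""

    label: str
    candidate_snp_ids: list[str]
    background_snp_ids: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        cand, bg = set(self.candidate_snp_ids), set(self.background_snp_ids)
        if cand & bg:
            raise ValueError(f"{len(cand & bg)} SNP(s) appear in both candidate and background sets")

    @property
    def n_candidates(self) -> int:
        return len(self.candidate_snp_ids)

    def write_tsv(self, path) -> None:
        rows = [(s, "candidate") for s in self.candidate_snp_ids] + [
            (s, "background") for s in self.background_snp_ids
        ]
        pd.DataFrame(rows, columns=["snp_id", "set"]).to_csv(path, sep="\t", index=False)


@dataclass
class CvAccuracy:
    """Prediction accuracies across cross-validation repeat cycles."""

    label: str
    per_repeat: np.ndarray
    n_folds: int
    n_repeats: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_repeat))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.per_repeat, ddof=1)) if len(self.per_repeat) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "label": self.label,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "per_repeat": [float(a) for a in self.per_repeat],
        }


def _partition(label: str, geno: GenotypeMatrix, candidate_ids, provenance: str) -> SnpSetPartition:
    cand = list(dict.fromkeys(candidate_ids))
    cand_set = set(cand)
    background = [m for m in geno.marker_ids if m not in cand_set]
    return SnpSetPartition(label, cand, background, provenance)


def extract_flank_snps(
    genes: GeneAnnotation,
    geno: GenotypeMatrix,
    flank_bp: int = 2500,
    label: str = "candidates",
) -> SnpSetPartition:
    """Candidate set: SNPs within ``flank_bp`` of any listed gene model.

    Gene intervals are 0-based half-open; a SNP at position exactly
    ``end + flank_bp`` is outside (half-open convention).  Duplicates from
    overlapping genes collapse to one occurrence.
    """
    if len(genes) == 0:
        raise ValueError("empty gene list: nothing to extract flanking SNPs for")
    markers = geno.markers
    hits: list[str] = []
    for chrom, sub in genes.df.groupby("chrom", sort=False):
        mk = markers[markers["chrom"] == chrom]
        if mk.empty:
            continue
        pos = mk["pos"].to_numpy()
        ids = mk["marker_id"].to_numpy()
        keep = np.zeros(len(mk), dtype=bool)
        for _, g in sub.iterrows():
            lo = max(0, int(g["start"]) - flank_bp)
            hi = int(g["end"]) + flank_bp
            keep |= (pos >= lo) & (pos < hi)
        hits.extend(ids[keep])
    order = {m: i for i, m in enumerate(geno.marker_ids)}
    hits = sorted(set(hits), key=order.__getitem__)
    return _partition(label, geno, hits, f"{len(genes)} genes, flank {flank_bp} bp")


def extract_region_snps(
    hit_positions,
    geno: GenotypeMatrix,
    span_bp: int = 1_000_000,
    label: str = "region",
) -> SnpSetPartition:
    """Candidate set: SNPs within a span centered on each hit position.

    ``hit_positions`` is a list of (chromosome, position); the window is
    the closed interval position +/- span_bp / 2, clipped at zero.
    """
    hits = list(hit_positions)
    if not hits:
        raise ValueError("no hit positions supplied")
    half = span_bp // 2
    markers = geno.markers
    keep = np.zeros(len(markers), dtype=bool)
    pos = markers["pos"].to_numpy()
    chrom = markers["chrom"].to_numpy()
    for c, x in hits:
        keep |= (chrom == c) & (pos >= max(0, x - half)) & (pos <= x + half)
    ids = [m for m, k in zip(geno.marker_ids, keep) if k]
    return _partition(label, geno, ids, f"{len(hits)} hits, span {span_bp} bp")


def sample_control_genes(
    annotation: GeneAnnotation,
    n: int,
    exclude_regions=None,
    restrict_regions=None,
    seed: int = 0,
) -> GeneAnnotation:
    """Uniform sample of genes without replacement, reproducible by seed.

    ``exclude_regions`` / ``restrict_regions`` are lists of
    (chromosome, start, end) half-open intervals; a gene counts as inside
    a region when it overlaps it.
    """

    def overlaps(g, regions) -> bool:
        return any(
            g["chrom"] == c and g["start"] < e and g["end"] > s for c, s, e in regions
        )

    df = annotation.df
    mask = np.ones(len(df), dtype=bool)
    if exclude_regions:
        mask &= ~df.apply(lambda g: overlaps(g, exclude_regions), axis=1).to_numpy()
    if restrict_regions:
        mask &= df.apply(lambda g: overlaps(g, restrict_regions), axis=1).to_numpy()
    pool = df[mask]
    if n > len(pool):
        raise ValueError(f"requested {n} control genes but only {len(pool)} are available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return GeneAnnotation(pool.iloc[np.sort(idx)].reset_index(drop=True))


def fit_model3(
    pheno: PhenotypeTable,
    kernel: np.ndarray | None = None,
    clone_ids: list[str] | None = None,
) -> tuple[np.ndarray, VarCompFit, list[str]]:
    """Single-kernel clone-value fit: y = X beta + Z u + e.

    With ``kernel=None`` the clones are treated as unrelated
    (u ~ N(0, sigma2_u I)); pass a GRM to get the whole-genome GBLUP
    variant.  Returns (u_hat per clone, fit, clone order).
    """
    clones = clone_ids if clone_ids is not None else pheno.clones
    ph = pheno.subset_clones(clones)
    design = ModelDesign(ph.y, ph.design_X(), ph.incidence_Z(clones), [("u", kernel)])
    fit = fit_reml(design)
    return fit.blups["u"], fit, list(clones)


def cross_validate(
    pheno: PhenotypeTable,
    partition: SnpSetPartition,
    geno: GenotypeMatrix,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    reference_uhat: np.ndarray | None = None,
) -> CvAccuracy:
    """Cross-validated prediction accuracy of a candidate SNP set.

    Per repeat, clones are split into ``folds`` folds.  For each fold,
    Model 2 is fitted on the training clones' plots and the held-out
    clones' candidate effects are predicted through the candidate
    kernel's train-test cross-covariance at the training REML estimates.
    Accuracy per repeat is the correlation of the pooled held-out
    predictions with the Model 3 clone values fitted once on all data
    (pass ``reference_uhat`` to amortize that reference fit).
    """
    clones = [c for c in geno.clone_ids if c in set(pheno.clones)]
    n = len(clones)
    if n < folds:
        raise ValueError(f"{n} clones cannot be split into {folds} folds")
    if not partition.candidate_snp_ids:
        raise ValueError("partition has an empty candidate set")
    ridx = geno.clone_index(clones)
    K_s = vanraden_grm(geno, partition.candidate_snp_ids).matrix[np.ix_(ridx, ridx)]
    K_g = None
    if partition.background_snp_ids:
        K_g = vanraden_grm(geno, partition.background_snp_ids).matrix[np.ix_(ridx, ridx)]

    if reference_uhat is None:
        reference_uhat, _, _ = fit_model3(pheno, None, clones)

    rng = np.random.default_rng(seed)
    accuracies = []
    clones_arr = np.array(clones)
    for rep in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
        s_hat = np.full(n, np.nan)
        for train_idx, test_idx in kf.split(clones_arr):
            if len(test_idx) < 2:
                raise ValueError("a cross-validation fold has fewer than 2 clones")
            train_clones = clones_arr[train_idx].tolist()
            ph_tr = pheno.subset_clones(train_clones)
            y_tr = ph_tr.y
            X_tr = ph_tr.design_X()
            Z_tr = ph_tr.incidence_Z(train_clones)
            kernels = [("s", K_s[np.ix_(train_idx, train_idx)])]
            if K_g is not None:
                kernels.append(("g", K_g[np.ix_(train_idx, train_idx)]))
            fit = fit_reml(ModelDesign(y_tr, X_tr, Z_tr, kernels))
            # w = Z' V^-1 (y - X beta) on the training block
            V = fit.variance_components["residual"] * np.eye(len(y_tr))
            V += fit.variance_components["s"] * (Z_tr @ K_s[np.ix_(train_idx, train_idx)] @ Z_tr.T)
            if K_g is not None:
                V += fit.variance_components["g"] * (
                    Z_tr @ K_g[np.ix_(train_idx, train_idx)] @ Z_tr.T
                )
            cf = cho_factor(V, lower=True)
            r = y_tr - X_tr @ fit.beta_hat
            w = Z_tr.T @ cho_solve(cf, r)
            s_hat[test_idx] = fit.variance_components["s"] * (
                K_s[np.ix_(test_idx, train_idx)] @ w
            )
        acc = stats.pearsonr(s_hat, reference_uhat)[0]
        accuracies.append(acc)
    return CvAccuracy(partition.label, np.array(accuracies), folds, repeats)


def enrichment(
    n_region_genes: int,
    n_pathway_genes: int,
    n_genome_genes: int,
    n_observed: int,
    method: str = "poisson",
) -> tuple[float, float]:
    """Pathway-overlap expectation and probability of the observed count.

    expectation = region x pathway / genome.  ``method="poisson"``
    evaluates the Poisson point mass at the observed count with that mean;
    ``method="hypergeometric"`` uses the exact draw-without-replacement
    pmf.
    """
    if min(n_region_genes, n_pathway_genes, n_genome_genes, n_observed) < 0:
        raise ValueError("gene counts must be non-negative")
    if n_genome_genes == 0:
        raise ValueError("genome gene count must be positive")
    if max(n_region_genes, n_pathway_genes) > n_genome_genes:
        raise ValueError("region/pathway counts exceed the genome total")
    expectation = n_region_genes * n_pathway_genes / n_genome_genes
    if method == "poisson":
        prob = float(stats.poisson.pmf(n_observed, expectation))
    elif method == "hypergeometric":
        prob = float(stats.hypergeom.pmf(n_observed, n_genome_genes, n_pathway_genes, n_region_genes))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(expectation), prob
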