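"""Candidate extraction, Model-2/3 cross-validation, and enrichment."""

import numpy as np
import pandas as pd
import pytest

from rhmap.io_formats import GeneAnnotation, PhenotypeTable, genotype_matrix_from_dosages
from rhmap.synthetic_data import TraitTruth, simulate_gene_annotation, simulate_phenotypes
from rhmap.validation import (
    cross_validate,
    enrichment,
    extract_flank_snps,
    extract_region_snps,
    fit_model3,
    sample_control_genes,
)


def _geno_line(positions, n_clones=6, chrom=1, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"S{chrom}_{p}" for p in positions]
    d = rng.integers(0, 3, size=(n_clones, len(ids)))
    return genotype_matrix_from_dosages([f"c{i}" for i in range(n_clones)], ids, d)


class TestExtractFlankSnps:
    def test_boundary_at_end_plus_flank_is_half_open(self):
        geno = _geno_line([3400, 3500, 3501])
        genes = GeneAnnotation(pd.DataFrame(
            [{"gene_id": "g", "chrom": 1, "start": 0, "end": 1000, "strand": "+"}]))
        part = extract_flank_snps(genes, geno, flank_bp=2500)
        assert part.candidate_snp_ids == ["S1_3400"]
        assert "S1_3501" in part.background_snp_ids

    def test_overlapping_genes_count_snp_once(self):
        geno = _geno_line([100, 200, 900])
        genes = GeneAnnotation(pd.DataFrame([
            {"gene_id": "a", "chrom": 1, "start": 50, "end": 250, "strand": "+"},
            {"gene_id": "b", "chrom": 1, "start": 150, "end": 300, "strand": "-"},
        ]))
        part = extract_flank_snps(genes, geno, flank_bp=0)
        assert part.candidate_snp_ids == ["S1_100", "S1_200"]

    def test_zero_flank_includes_gene_body_snp(self):
        geno = _geno_line([500])
        genes = GeneAnnotation(pd.DataFrame(
            [{"gene_id": "g", "chrom": 1, "start": 400, "end": 600, "strand": "+"}]))
        part = extract_flank_snps(genes, geno, flank_bp=0)
        assert part.candidate_snp_ids == ["S1_500"]

    def test_empty_gene_list_rejected(self):
        geno = _geno_line([100])
        with pytest.raises(ValueError, match="empty gene list"):
            extract_flank_snps(GeneAnnotation(pd.DataFrame(columns=GeneAnnotation.COLUMNS)),
                               geno)

    def test_partition_is_complete_and_disjoint(self, small_geno):
        genes = simulate_gene_annotation(small_geno, n_genes=40, seed=5)
        part = extract_flank_snps(genes, small_geno, flank_bp=2500)
        assert set(part.candidate_snp_ids) | set(part.background_snp_ids) == set(
            small_geno.marker_ids
        )
        assert not set(part.candidate_snp_ids) & set(part.background_snp_ids)


class TestExtractRegionSnps:
    def test_megabase_window_inclusive(self):
        geno = _geno_line([4_500_000, 5_000_000, 5_500_000, 5_500_001])
        part = extract_region_snps([(1, 5_000_000)], geno, span_bp=1_000_000)
        assert part.candidate_snp_ids == ["S1_4500000", "S1_5000000", "S1_5500000"]

    def test_union_of_close_hits_without_double_count(self):
        geno = _geno_line([100_000, 200_000, 300_000])
        part = extract_region_snps([(1, 150_000), (1, 250_000)], geno, span_bp=200_000)
        assert part.candidate_snp_ids == ["S1_100000", "S1_200000", "S1_300000"]

    def test_window_clipped_at_chromosome_start(self):
        geno = _geno_line([10, 600_000])
        part = extract_region_snps([(1, 100)], geno, span_bp=1_000_000)
        assert part.candidate_snp_ids == ["S1_10"]


class TestSampleControlGenes:
    @pytest.fixture(scope="class")
    def genes(self, small_geno):
        return simulate_gene_annotation(small_geno, n_genes=60, seed=8)

    def test_full_sample_returns_all(self, genes):
        out = sample_control_genes(genes, n=60, seed=1)
        assert set(out.df["gene_id"]) == set(genes.df["gene_id"])

    def test_reproducible_by_seed(self, genes):
        a = sample_control_genes(genes, n=10, seed=2)
        b = sample_control_genes(genes, n=10, seed=2)
        assert a.df.equals(b.df)

    def test_total_exclusion_rejected(self, genes):
        regions = [(c, 0, 10**9) for c in genes.df["chrom"].unique()]
        with pytest.raises(ValueError, match="available"):
            sample_control_genes(genes, n=5, exclude_regions=regions, seed=3)


class TestFitModel3:
    def test_identity_fit_shrinks_adjusted_clone_means(self):
        """With r plots per clone, u_hat is the clone mean deviation shrunken
        by sigma2_u / (sigma2_u + sigma2_e / r)."""
        rng = np.random.default_rng(12)
        clones = [f"c{i}" for i in range(5)]
        r = 4
        u = rng.normal(0, 2.0, size=5)
        rows = []
        for i, c in enumerate(clones):
            for _ in range(r):
                rows.append({"clone": c, "location": "L", "year": 1, "trial": "T",
                             "value": 10.0 + u[i] + rng.normal(0, 0.5)})
        pheno = PhenotypeTable(pd.DataFrame(rows))
        uhat, fit, order = fit_model3(pheno)
        s2u = fit.variance_components["u"]
        s2e = fit.variance_components["residual"]
        means = pheno.df.groupby("clone", sort=False)["value"].mean().to_numpy()
        shrink = s2u / (s2u + s2e / r)
        expected = shrink * (means - means.mean())
        assert np.allclose(uhat, expected, atol=1e-6)

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        clones = [f"c{i}" for i in range(8)]
        vals = rng.normal(size=16)
        df = pd.DataFrame({"clone": clones * 2, "location": "L", "year": 1,
                           "trial": "T", "value": vals})
        pheno = PhenotypeTable(df)
        u1, _, order1 = fit_model3(pheno, clone_ids=clones)
        perm = clones[::-1]
        u2, _, order2 = fit_model3(pheno, clone_ids=perm)
        assert np.allclose(u1, u2[::-1], atol=1e-8)


@pytest.fixture(scope="module")
def signal_bundle(small_geno):
    """Trait where a contiguous candidate block carries half the genetic variance."""
    block = small_geno.marker_ids[60:140]  # 80 SNPs on chromosome 1
    qtl_ids = block[10:60:10]  # 5 QTLs inside the block
    truth = TraitTruth(
        h2_background=0.25,
        qtl_list=[(q, 0.05) for q in qtl_ids],
        residual_variance=0.5,
        fixed_effect_sd=0.3,
    )
    pheno, out = simulate_phenotypes(small_geno, truth, seed=71)
    uhat, _, _ = fit_model3(pheno, clone_ids=small_geno.clone_ids)
    return pheno, block, uhat


class TestCrossValidate:
    def test_causal_candidates_beat_random_control(self, small_geno, signal_bundle):
        """The Table-2 ordering as an inequality: candidate set > size-matched
        random control in nearly every paired repeat, and the whole-genome
        set tops both."""
        pheno, block, uhat = signal_bundle
        from rhmap.validation import SnpSetPartition

        cand = SnpSetPartition(
            "candidates", block,
            [m for m in small_geno.marker_ids if m not in set(block)])
        rng = np.random.default_rng(72)
        non_block = [m for m in small_geno.marker_ids if m not in set(block)]
        rand_ids = list(rng.choice(non_block, size=len(block), replace=False))
        ctrl = SnpSetPartition(
            "control", rand_ids,
            [m for m in small_geno.marker_ids if m not in set(rand_ids)])
        whole = SnpSetPartition("whole_genome", list(small_geno.marker_ids), [])

        acc_c = cross_validate(pheno, cand, small_geno, seed=1, reference_uhat=uhat)
        acc_r = cross_validate(pheno, ctrl, small_geno, seed=1, reference_uhat=uhat)
        acc_w = cross_validate(pheno, whole, small_geno, seed=1, reference_uhat=uhat)

        wins = np.sum(acc_c.per_repeat > acc_r.per_repeat)
        assert wins >= 9
        assert acc_w.mean_accuracy > acc_r.mean_accuracy

    def test_whole_genome_tops_subsets_on_polygenic_trait(self, small_geno):
        """When the signal is diffuse, no proper SNP subset beats the
        whole-genome kernel."""
        truth = TraitTruth(h2_background=0.5, residual_variance=0.5,
                           fixed_effect_sd=0.3)
        pheno, _ = simulate_phenotypes(small_geno, truth, seed=74)
        uhat, _, _ = fit_model3(pheno, clone_ids=small_geno.clone_ids)
        from rhmap.validation import SnpSetPartition

        chrom1 = small_geno.markers[small_geno.markers["chrom"] == 1][
            "marker_id"].tolist()
        subset = SnpSetPartition(
            "chrom1", chrom1,
            [m for m in small_geno.marker_ids if m not in set(chrom1)])
        whole = SnpSetPartition("whole_genome", list(small_geno.marker_ids), [])
        acc_s = cross_validate(pheno, subset, small_geno, seed=3, reference_uhat=uhat)
        acc_w = cross_validate(pheno, whole, small_geno, seed=3, reference_uhat=uhat)
        assert acc_w.mean_accuracy > acc_s.mean_accuracy

    def test_null_candidate_accuracy_near_zero(self, small_geno):
        """Candidates untouched by the signal predict ~nothing."""
        truth = TraitTruth(h2_background=0.0,
                           qtl_list=[(small_geno.marker_ids[10], 0.2),
                                     (small_geno.marker_ids[30], 0.2)],
                           residual_variance=0.6, fixed_effect_sd=0.0)
        pheno, _ = simulate_phenotypes(small_geno, truth, seed=73)
        # candidates from the other chromosome, far from both QTLs
        chrom2 = small_geno.markers[small_geno.markers["chrom"] == 2]
        ids = chrom2["marker_id"].tolist()[:80]
        from rhmap.validation import SnpSetPartition

        part = SnpSetPartition("null", ids,
                               [m for m in small_geno.marker_ids if m not in set(ids)])
        acc = cross_validate(pheno, part, small_geno, seed=2)
        assert abs(acc.mean_accuracy) <= 0.1

    def test_fold_count_exceeding_clones_rejected(self, small_geno, signal_bundle):
        pheno, block, uhat = signal_bundle
        from rhmap.validation import SnpSetPartition

        part = SnpSetPartition("x", block,
                               [m for m in small_geno.marker_ids if m not in set(block)])
        with pytest.raises(ValueError, match="folds"):
            cross_validate(pheno, part, small_geno, folds=10**4)


class TestEnrichment:
    def test_degenerate_region_gives_certain_zero(self):
        expectation, prob = enrichment(0, 123, 33030, 0)
        assert expectation == 0.0
        assert prob == pytest.approx(1.0)

    def test_hypergeometric_variant(self):
        _, p_pois = enrichment(650, 123, 33030, 3)
        _, p_hyp = enrichment(650, 123, 33030, 3, method="hypergeometric")
        assert p_hyp == pytest.approx(p_pois, abs=0.02)

    def test_zero_genome_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            enrichment(1, 1, 0, 0)
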