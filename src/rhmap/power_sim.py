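"""Hide-a-causal-SNP power simulation for the regional heritability scan.

Each test: pick five adjacent scan windows on a chromosome, add an effect
at a random SNP in the middle window sized to inflate the phenotypic
variance by a stated fraction (default 10%), mask that SNP out of the
causal window's relationship matrix (optionally also out of the
background kernel), fit the two-kernel model for each of the five
windows, and call the test detected when any window's LRT p-value falls
below the significance threshold (default 0.00024, the empirical p-value
at an LFDR of 0.05).  Because adjacent windows overlap, a flanking window
may legitimately retain the masked SNP; adjacent-segment capture — a
flanking window significant while the causal window's p is higher — is
tallied to gauge how far from the causal window the signal is picked up.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .grm import center_markers, vanraden_grm
from .io_formats import GenotypeMatrix, PhenotypeTable
from .rhm_scan import Segment, make_windows
from .varcomp import ModelDesign, fit_reml, lrt

log = logging.getLogger(__name__)

__all__ = ["PowerConfig", "PowerResult", "inject_causal_snp", "run_power_experiment", "pvalue_at_lfdr"]


@dataclass
class PowerConfig:
    """Settings for the hide-a-causal-SNP experiment.

    ``repetitions`` batteries are run per chromosome, so the number of
    tests is repetitions x chromosomes (12 x 18 = 216 at full scale).
    """

    variance_fraction: float = 0.10
    n_adjacent_segments: int = 5
    causal_segment_index: int = 3  # 1-based within the battery
    repetitions: int = 12
    p_threshold: float = 0.00024
    window: int = 100
    step: int = 50
    seed: int = 0
    exclude_causal_from_background: bool = False
    post_injection_share: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.causal_segment_index <= self.n_adjacent_segments:
            raise ValueError("causal_segment_index must lie within the battery")
        if not 0.0 <= self.variance_fraction < 1.0:
            raise ValueError("variance_fraction must be in [0, 1)")


@dataclass
class PowerResult:
    """Tallies and per-test records from one power experiment."""

    n_tests: int
    n_detected: int
    n_causal_segment_hits: int
    n_adjacent_only_hits: int
    records: pd.DataFrame
    config: PowerConfig
    seed: int

    @property
    def power(self) -> float:
        return self.n_detected / self.n_tests if self.n_tests else float("nan")

    @property
    def adjacent_capture_rate(self) -> float:
        return self.n_adjacent_only_hits / self.n_tests if self.n_tests else float("nan")

    def summary(self) -> dict:
        return {
            "n_tests": self.n_tests,
            "n_detected": self.n_detected,
            "power": self.power,
            "n_causal_segment_hits": self.n_causal_segment_hits,
            "n_adjacent_only_hits": self.n_adjacent_only_hits,
            "adjacent_capture_rate": self.adjacent_capture_rate,
            "adjacent_only_vs_causal_hits": (
                self.n_adjacent_only_hits / self.n_causal_segment_hits
                if self.n_causal_segment_hits
                else None
            ),
            "seed": self.seed,
            "config": asdict(self.config),
        }

    def write(self, json_path=None, tsv_path=None) -> None:
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.summary(), fh, indent=2)
                fh.write("\n")
        if tsv_path is not None:
            self.records.to_csv(tsv_path, sep="\t", index=False, float_format="%.12g")


def inject_causal_snp(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    snp_id: str,
    variance_fraction: float,
    seed: int = 0,
    post_injection_share: bool = False,
) -> tuple[PhenotypeTable, float]:
    """Add an allele-substitution effect at one SNP to the phenotypes.

    beta = sign * sqrt(f * Var(y_pre) / Var(dosage)), so the added term
    contributes fraction ``f`` of the pre-injection phenotypic variance
    ("inflating" it by f).  With ``post_injection_share`` the effect is
    sized so the QTL holds fraction f of the post-injection variance
    instead (f -> f / (1 - f) of the pre-injection variance).
    """
    rng = np.random.default_rng(seed)
    sign = float(rng.choice([-1.0, 1.0]))
    j = geno.marker_indices([snp_id])[0]
    x_clone = geno.dosages[:, j].astype(float)
    lookup = dict(zip(geno.clone_ids, x_clone))
    x = np.array([lookup[c] for c in pheno.df["clone"]])
    vx = float(x.var())
    if vx == 0.0:
        raise ValueError(f"SNP {snp_id!r} is monomorphic; cannot carry a causal effect")
    f = variance_fraction
    if post_injection_share:
        f = f / (1.0 - f)
    if f == 0.0:
        return pheno, 0.0
    beta = sign * float(np.sqrt(f * pheno.y.var() / vx))
    return pheno.with_values(pheno.y + beta * (x - x.mean())), beta


def run_power_experiment(
    geno: GenotypeMatrix,
    pheno_generator,
    cfg: PowerConfig,
) -> PowerResult:
    """Run the full battery-of-five experiment over chromosomes x repetitions.

    ``pheno_generator(seed)`` must return a PhenotypeTable for the clones
    of ``geno`` (typically a background-only simulated trait).  Fully
    reproducible from ``cfg.seed``; chromosomes with fewer than
    ``n_adjacent_segments`` windows are skipped with a log message and the
    test denominator adjusted.
    """
    rng = np.random.default_rng(cfg.seed)
    windows = make_windows(geno, window=cfg.window, step=cfg.step)
    by_chrom: dict = {}
    for w in windows:
        by_chrom.setdefault(w.chromosome, []).append(w)

    # full-genome centered markers once; single-SNP exclusion is a rank-1
    # downdate of the numerator and a scalar downdate of the denominator
    M, kept_ids, p_all, _ = center_markers(geno)
    Gnum = M @ M.T
    denom_full = 2.0 * float(np.sum(p_all * (1.0 - p_all)))
    col_of = {s: i for i, s in enumerate(kept_ids)}

    k_causal = cfg.causal_segment_index - 1
    records = []
    for rep in range(cfg.repetitions):
        for chrom, wins in by_chrom.items():
            if len(wins) < cfg.n_adjacent_segments:
                log.warning("chromosome %s has only %d windows; skipping", chrom, len(wins))
                continue
            start = int(rng.integers(0, len(wins) - cfg.n_adjacent_segments + 1))
            battery: list[Segment] = wins[start : start + cfg.n_adjacent_segments]
            causal_seg = battery[k_causal]
            poly = [s for s in causal_seg.snp_ids if s in col_of]
            snp = poly[int(rng.integers(len(poly)))]
            pheno = pheno_generator(int(rng.integers(2**31)))
            pheno_q, beta = inject_causal_snp(
                geno, pheno, snp, cfg.variance_fraction,
                seed=int(rng.integers(2**31)),
                post_injection_share=cfg.post_injection_share,
            )

            clones = [c for c in geno.clone_ids if c in set(pheno_q.clones)]
            ph = pheno_q.subset_clones(clones)
            y, X, Z = ph.y, ph.design_X(), ph.incidence_Z(clones)
            ridx = geno.clone_index(clones)

            if cfg.exclude_causal_from_background:
                jc = col_of[snp]
                pq = p_all[jc] * (1.0 - p_all[jc])
                G_bg = (Gnum - np.outer(M[:, jc], M[:, jc])) / (denom_full - 2.0 * pq)
            else:
                G_bg = Gnum / denom_full
            G_bg = G_bg[np.ix_(ridx, ridx)]

            null_fit = fit_reml(ModelDesign(y, X, Z, [("background", G_bg)]))
            # start each alt fit at the null optimum (near-zero segment)
            warm = {
                "segment": 1e-4 * float(np.var(y)),
                "background": null_fit.variance_components["background"],
                "residual": null_fit.variance_components["residual"],
            }
            pvals = []
            mask_ok = True
            for k_idx, seg in enumerate(battery):
                # the pseudocausal SNP is excluded from the causal segment's
                # GRM only; overlapping flank windows legitimately keep it
                if k_idx == k_causal:
                    ids = [s for s in seg.snp_ids if s != snp]
                    mask_ok = mask_ok and (snp not in ids)
                else:
                    ids = list(seg.snp_ids)
                G_seg = vanraden_grm(geno, ids).matrix[np.ix_(ridx, ridx)]
                alt = fit_reml(
                    ModelDesign(y, X, Z, [("segment", G_seg), ("background", G_bg)]),
                    init=warm, ai_burn_in=1,
                )
                pvals.append(lrt(alt, null_fit, df=1).p_value)
            pvals = np.array(pvals)
            detected = bool(np.any(pvals < cfg.p_threshold))
            causal_hit = bool(pvals[k_causal] < cfg.p_threshold)
            flanks = [i for i in (0, cfg.n_adjacent_segments - 1) if i != k_causal]
            adjacent_only = any(
                pvals[i] < cfg.p_threshold and pvals[k_causal] > pvals[i] for i in flanks
            )
            rec = {
                "repetition": rep,
                "chrom": chrom,
                "battery_start": start,
                "causal_snp": snp,
                "beta": beta,
                "detected": detected,
                "causal_segment_hit": causal_hit,
                "adjacent_only_hit": bool(adjacent_only),
                "causal_snp_masked": bool(mask_ok),
            }
            for i, pv in enumerate(pvals, start=1):
                rec[f"p_segment_{i}"] = pv
            records.append(rec)

    df = pd.DataFrame(records)
    n_tests = len(df)
    return PowerResult(
        n_tests=n_tests,
        n_detected=int(df["detected"].sum()) if n_tests else 0,
        n_causal_segment_hits=int(df["causal_segment_hit"].sum()) if n_tests else 0,
        n_adjacent_only_hits=int(df["adjacent_only_hit"].sum()) if n_tests else 0,
        records=df,
        config=cfg,
        seed=cfg.seed,
    )


def pvalue_at_lfdr(scan_result, lfdr_cutoff: float = 0.05):
    """Largest p among segments at or below the LFDR cutoff (None if empty).

    This is the scan's empirical significance threshold on the p scale,
    the quantity used as ``p_threshold`` in the power experiment.
    """
    from .multiple_testing import significant_segments

    _, p_threshold = significant_segments(scan_result, lfdr_cutoff)
    return p_threshold
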