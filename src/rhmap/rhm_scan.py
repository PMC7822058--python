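"""Genome-wide regional heritability scan.

Chromosomes are cut into sliding windows of ``window`` SNPs advancing by
``step`` (defaults 100/50, i.e. adjacent windows share half their SNPs).
For each window the two-kernel model

    y = X beta + Z u_seg + Z u_bg + e

is fitted, with u_seg covarying by the window's GRM and u_bg by the
whole-genome GRM (which doubles as the population-structure control).  The
window's genomic heritability is

    h2_seg = sigma2_seg / (sigma2_seg + sigma2_bg + sigma2_e)

and its significance comes from a likelihood-ratio test against the
background-only null, which is shared across windows and therefore fitted
once per scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm import vanraden_grm
from .io_formats import SCAN_COLUMNS, GenotypeMatrix, PhenotypeTable
from .varcomp import ModelDesign, fit_reml, lrt

log = logging.getLogger(__name__)

__all__ = ["Segment", "ScanResult", "make_windows", "segment_h2", "scan"]


@dataclass
class Segment:
    """One scan window: a run of consecutive SNPs on a chromosome."""

    chromosome: int
    snp_index_range: tuple[int, int]  # half-open over the chromosome's marker order
    snp_ids: list[str]
    span_bp: tuple[int, int]  # position of first and last SNP

    @property
    def n_snps(self) -> int:
        return self.snp_index_range[1] - self.snp_index_range[0]

    @property
    def tag_snp(self) -> str:
        """The window's last SNP, used as its identifier in result tables."""
        return self.snp_ids[-1]


@dataclass
class ScanResult:
    """Per-segment scan records plus scan metadata."""

    df: pd.DataFrame
    segments: list[Segment] = field(default_factory=list)
    window: int = 100
    step: int = 50
    n_clones: int = 0
    background_h2: float = float("nan")

    def with_columns(self, **cols) -> "ScanResult":
        df = self.df.copy()
        for name, values in cols.items():
            df[name] = values
        return ScanResult(df, self.segments, self.window, self.step, self.n_clones,
                          self.background_h2)


def make_windows(geno: GenotypeMatrix, window: int = 100, step: int = 50) -> list[Segment]:
    """Enumerate sliding windows per chromosome.

    Starts advance by ``step``; the final window is truncated at the
    chromosome end and merged into the previous one if it would hold
    ``step`` or fewer SNPs (a short terminal window would make a
    degenerate kernel).  Chromosomes with fewer than ``window`` SNPs
    become a single whole-chromosome window.
    """
    if not window > step > 0:
        raise ValueError(f"require window > step > 0, got window={window}, step={step}")
    segments: list[Segment] = []
    markers = geno.markers
    for chrom in geno.chromosomes():
        sub = markers[markers["chrom"] == chrom]
        ids = sub["marker_id"].tolist()
        pos = sub["pos"].tolist()
        m = len(ids)
        if m < window:
            log.warning("chromosome %s has %d < %d SNPs; using one whole-chromosome window",
                        chrom, m, window)
            segments.append(Segment(chrom, (0, m), ids, (pos[0], pos[-1])))
            continue
        bounds = []
        start = 0
        while True:
            end = min(start + window, m)
            bounds.append((start, end))
            if end >= m:
                break
            start += step
        if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] <= step:
            last = bounds.pop()
            prev = bounds.pop()
            bounds.append((prev[0], last[1]))
        for s, e in bounds:
            segments.append(Segment(chrom, (s, e), ids[s:e], (pos[s], pos[e - 1])))
    return segments


def segment_h2(sigma_seg: float, sigma_bg: float, sigma_e: float) -> float:
    """Genomic heritability of one segment: its share of total variance."""
    if min(sigma_seg, sigma_bg, sigma_e) < 0:
        raise ValueError("variance components must be non-negative")
    total = sigma_seg + sigma_bg + sigma_e
    if total == 0:
        raise ValueError("all variance components are zero; h2 undefined")
    return sigma_seg / total


def scan(
    pheno: PhenotypeTable,
    geno: GenotypeMatrix,
    windows: list[Segment] | None = None,
    window: int = 100,
    step: int = 50,
    exclude_segment_from_background: bool = False,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> ScanResult:
    """Run the regional heritability scan.

    The background kernel uses all genome SNPs (including each segment's
    own, unless ``exclude_segment_from_background``); the background-only
    null fit is shared across segments when the background kernel is
    shared.  Non-converged segment fits are flagged per row, not fatal.
    The scan itself is deterministic given its inputs.
    """
    if windows is None:
        windows = make_windows(geno, window=window, step=step)
    if len(windows) < 2:
        raise ValueError("need at least 2 windows to scan")
    clones = [c for c in geno.clone_ids if c in set(pheno.clones)]
    if not clones:
        raise ValueError("no clones shared between phenotypes and genotypes")
    ph = pheno.subset_clones(clones)
    y = ph.y
    X = ph.design_X()
    Z = ph.incidence_Z(clones)
    rows_idx = geno.clone_index(clones)

    G_bg_full = vanraden_grm(geno).matrix[np.ix_(rows_idx, rows_idx)]
    null_fit = None
    if not exclude_segment_from_background:
        null_fit = fit_reml(ModelDesign(y, X, Z, [("background", G_bg_full)]),
                            tol=tol, max_iter=max_iter)
    records = []
    warm = None
    for seg in windows:
        G_seg = vanraden_grm(geno, seg.snp_ids).matrix[np.ix_(rows_idx, rows_idx)]
        if exclude_segment_from_background:
            bg_ids = [m for m in geno.marker_ids if m not in set(seg.snp_ids)]
            G_bg = vanraden_grm(geno, bg_ids).matrix[np.ix_(rows_idx, rows_idx)]
            nf = fit_reml(ModelDesign(y, X, Z, [("background", G_bg)]),
                          tol=tol, max_iter=max_iter)
        else:
            G_bg, nf = G_bg_full, null_fit
        if warm is None:
            # start at the null optimum with a near-zero segment component:
            # the alt likelihood then starts at the null's and EM/AI only
            # climbs, so LRT statistics cannot go materially negative
            warm = {
                "segment": 1e-4 * np.var(y),
                "background": nf.variance_components["background"],
                "residual": nf.variance_components["residual"],
            }
        alt = fit_reml(
            ModelDesign(y, X, Z, [("segment", G_seg), ("background", G_bg)]),
            tol=tol, max_iter=max_iter, init=warm, ai_burn_in=1,
        )
        test = lrt(alt, nf, df=1)
        s_seg = alt.variance_components["segment"]
        s_bg = alt.variance_components["background"]
        s_e = alt.variance_components["residual"]
        records.append(
            {
                "chrom": seg.chromosome,
                "start_index": seg.snp_index_range[0],
                "end_index": seg.snp_index_range[1],
                "n_snps": seg.n_snps,
                "span_start": seg.span_bp[0],
                "span_end": seg.span_bp[1],
                "tag_snp": seg.tag_snp,
                "sigma2_seg": s_seg,
                "sigma2_bg": s_bg,
                "sigma2_e": s_e,
                "h2_seg": segment_h2(s_seg, s_bg, s_e),
                "lrt": test.statistic,
                "p_value": test.p_value,
                "q_value": np.nan,
                "lfdr": np.nan,
                "converged": bool(alt.converged),
            }
        )
        if not alt.converged:
            log.warning("segment %s:%s did not converge in %d iterations",
                        seg.chromosome, seg.tag_snp, alt.n_iterations)
    df = pd.DataFrame(records, columns=SCAN_COLUMNS)
    bg_h2 = float("nan")
    if null_fit is not None:
        bg_h2 = null_fit.h2("background")
    return ScanResult(df, list(windows), window, step, len(clones), bg_h2)


def manhattan_plot(scan_result: ScanResult, path, column: str = "lfdr") -> None:
    """Optional presentation helper: -log10 of a scan column along the genome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = scan_result.df
    x = np.arange(len(df))
    vals = -np.log10(np.clip(df[column].to_numpy(dtype=float), 1e-300, None))
    fig, ax = plt.subplots(figsize=(10, 3))
    for i, (_, sub) in enumerate(df.groupby("chrom", sort=False)):
        ax.scatter(x[sub.index], vals[sub.index], s=8,
                   color="C0" if i % 2 == 0 else "C1")
    ax.set_xlabel("segment (genome order)")
    ax.set_ylabel(f"-log10({column})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
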