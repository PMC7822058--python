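"""Storey-style pi0, q-values, and local false discovery rates.

Re-implements the estimator family behind the classic qvalue approach:
pi0 from the tail counts #{p > lambda} smoothed across a lambda grid with
a cubic polynomial, step-up q-values, and a local FDR from a kernel
density estimate of the p-values on the probit scale.

The scan's overlapping windows make the per-segment tests positively
dependent; the estimators are applied to the full set regardless (no
effective-number-of-tests correction), which is conservative for pi0 and
standard practice for window scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["FdrResult", "estimate_pi0", "qvalues", "local_fdr", "attach_fdr", "significant_segments"]

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)


@dataclass
class FdrResult:
    pi0: float
    q_values: np.ndarray
    lfdr: np.ndarray
    lambda_grid: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDA_GRID.copy())


def _check_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def estimate_pi0(pvals, lambda_grid=None) -> float:
    """Estimate the null proportion pi0 by the smoother method.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the
    grid, smoothed by a cubic polynomial in lambda, and read off at the
    largest lambda; the result is clamped to (0, 1].  With fewer tests
    than grid points the estimator falls back to the single point
    lambda = 0.5 (logged).
    """
    p = _check_pvals(pvals)
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    m = p.size
    if m < grid.size:
        log.info("only %d tests for a %d-point lambda grid; using fixed lambda = 0.5", m, grid.size)
        pi0 = np.mean(p > 0.5) / 0.5
        return float(min(max(pi0, 1.0 / m), 1.0))
    pi0_lam = np.array([np.mean(p > lam) / (1.0 - lam) for lam in grid])
    coef = np.polyfit(grid, pi0_lam, deg=3)
    pi0 = float(np.polyval(coef, grid.max()))
    return float(min(max(pi0, 1.0 / m), 1.0))


def qvalues(pvals, pi0: float | None = None) -> np.ndarray:
    """Step-up q-values: q(p_(i)) = min_{j>=i} pi0 * m * p_(j) / j."""
    p = _check_pvals(pvals)
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def local_fdr(pvals, pi0: float | None = None, min_tests: int = 50) -> np.ndarray:
    """Local FDR: lfdr(p) = pi0 / f(p), density estimated on the probit scale.

    p-values are mapped to z = Phi^-1(p); a Gaussian KDE (Silverman
    bandwidth) of z gives the p-value density through the change of
    variables f_p(p) = f_z(z) / phi(z).  The density is forced monotone
    non-increasing in p before the ratio, and the result clamped to
    [0, 1].  Requires at least ``min_tests`` tests.
    """
    p = _check_pvals(pvals)
    if p.size < min_tests:
        raise ValueError(
            f"{p.size} tests is too few for local-FDR density estimation "
            f"(need >= {min_tests}); use q-values instead"
        )
    if pi0 is None:
        pi0 = estimate_pi0(p)
    eps = 1e-15  # keep extreme p-values inside the probit transform's range
    pc = np.clip(p, eps, 1.0 - eps)
    z = stats.norm.ppf(pc)
    kde = stats.gaussian_kde(z, bw_method="silverman")
    f_p = kde(z) / stats.norm.pdf(z)
    # enforce a non-increasing density in p (signal mass sits at small p)
    order = np.argsort(pc, kind="stable")
    f_sorted = np.minimum.accumulate(f_p[order])
    dens = np.empty_like(f_p)
    dens[order] = np.maximum(f_sorted, 1e-12)
    return np.clip(pi0 / dens, 0.0, 1.0)


def attach_fdr(scan_result, lambda_grid=None, min_tests: int = 50):
    """Compute pi0/q/lfdr for a ScanResult and return an augmented copy."""
    p = scan_result.df["p_value"].to_numpy(dtype=float)
    pi0 = estimate_pi0(p, lambda_grid)
    q = qvalues(p, pi0)
    if p.size >= min_tests:
        lf = local_fdr(p, pi0, min_tests=min_tests)
    else:
        log.warning("only %d segments; lfdr column left as q-values fallback NaN", p.size)
        lf = np.full(p.size, np.nan)
    out = scan_result.with_columns(q_value=q, lfdr=lf)
    out.pi0 = pi0
    return out


def significant_segments(scan_result, lfdr_cutoff: float = 0.05):
    """Rows at or below the LFDR cutoff, plus the empirical p threshold.

    Returns (filtered ScanResult-like frame, p_threshold).  The threshold
    is the largest p-value among significant rows — the scan's empirical
    significance boundary on the p scale — or None when nothing passes.
    """
    df = scan_result.df if hasattr(scan_result, "df") else scan_result
    if df["lfdr"].isna().all():
        raise ValueError("lfdr column not computed; run attach_fdr first")
    sig = df[df["lfdr"] <= lfdr_cutoff]
    p_threshold = float(sig["p_value"].max()) if len(sig) else None
    return sig, p_threshold
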