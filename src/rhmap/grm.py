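"""VanRaden genomic relationship matrices from arbitrary SNP subsets.

G = M Mt / (2 * sum_j p_j (1 - p_j))

where M is the column-centered dosage matrix and p the per-marker allele
frequency.  The denominator scales G so its average diagonal is near 1 for
a population in Hardy-Weinberg proportions, which puts the attached
variance component on the additive-genetic scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = ["GRM", "center_markers", "vanraden_grm", "write_grm", "read_grm"]


@dataclass
class GRM:
    """A relationship matrix plus the provenance needed to rebuild it."""

    clone_ids: list[str]
    matrix: np.ndarray
    snp_ids: list[str]
    denominator: float
    centering: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_dropped_monomorphic: int = 0

    def __post_init__(self) -> None:
        G = np.asarray(self.matrix, dtype=float)
        n = len(self.clone_ids)
        if G.shape != (n, n):
            raise ValueError(f"GRM shape {G.shape} does not match {n} clones")
        if not np.allclose(G, G.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")
        self.matrix = (G + G.T) / 2.0

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])


def center_markers(geno: GenotypeMatrix, snp_subset=None, coding: str = "freq"):
    """Column-center the dosage matrix over a SNP subset.

    With ``coding="freq"`` each column becomes dosage − 2p̄ (p̄ the observed
    alternate-dosage mean / 2), so columns sum to zero.  ``coding="raw"``
    keeps the literal −1/0/1 coding (dosage − 1) without frequency
    centering.  Monomorphic columns are dropped with a logged count.

    Returns (M, kept_snp_ids, p_kept, offsets).
    """
    if snp_subset is None:
        snp_subset = geno.marker_ids
    snp_subset = list(snp_subset)
    if not snp_subset:
        raise ValueError("empty SNP subset for marker centering")
    idx = geno.marker_indices(snp_subset)
    D = geno.dosages[:, idx].astype(float)
    p = D.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    n_drop = int((~poly).sum())
    if n_drop:
        log.info("dropping %d monomorphic SNP(s) from GRM subset", n_drop)
    if not poly.any():
        raise ValueError(
            f"all {len(snp_subset)} SNPs in subset are monomorphic; cannot build a GRM"
        )
    D = D[:, poly]
    p = p[poly]
    kept = [s for s, keep in zip(snp_subset, poly) if keep]
    if coding == "freq":
        offsets = 2.0 * p
    elif coding == "raw":
        offsets = np.ones(D.shape[1])
    else:
        raise ValueError(f"unknown coding {coding!r}; expected 'freq' or 'raw'")
    M = D - offsets
    return M, kept, p, offsets


def vanraden_grm(
    geno: GenotypeMatrix,
    snp_subset=None,
    coding: str = "freq",
    ridge: float = 0.0,
) -> GRM:
    """Build G = M Mt / 2Σp(1−p) over a SNP subset.

    ``ridge`` adds a small multiple of the identity to the diagonal for
    near-singular downstream solves (off by default).
    """
    M, kept, p, offsets = center_markers(geno, snp_subset, coding=coding)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = (M @ M.T) / denom
    if ridge:
        G = G + ridge * np.eye(G.shape[0])
    return GRM(
        clone_ids=list(geno.clone_ids),
        matrix=G,
        snp_ids=kept,
        denominator=denom,
        centering=offsets,
        n_dropped_monomorphic=len(list(snp_subset or geno.marker_ids)) - len(kept),
    )


def write_grm(grm: GRM, path) -> None:
    df = pd.DataFrame(grm.matrix, columns=grm.clone_ids)
    df.insert(0, "clone", grm.clone_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_grm(path) -> GRM:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    clones = df["clone"].tolist()
    G = df[df.columns[1:]].to_numpy(dtype=float)
    return GRM(clone_ids=clones, matrix=G, snp_ids=[], denominator=float("nan"))
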