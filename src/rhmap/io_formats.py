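"""On-disk formats and in-memory containers for the mapping pipeline.

Dosage matrices travel as TSV (clone rows, marker columns, values 0/1/2),
phenotypes as CSV with the augmented-design factors, gene models as GFF3 or
BED, and scan results as TSV.  Readers validate strictly and refuse to
coerce malformed input: the upstream data are assumed imputed to
completeness, so a missing or out-of-range dosage is a pipeline error, not
something to paper over.

Coordinates are 0-based half-open internally.  GFF3 (1-based inclusive) is
shifted on the way in and out; BED passes through unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "GeneAnnotation",
    "parse_snp_id",
    "read_dosage",
    "write_dosage",
    "read_phenotypes",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_bed",
    "write_bed",
    "write_scan_results",
    "read_scan_results",
]

_SNP_ID_RE = re.compile(r"^S(\d+)_(\d+)$")

#: Stable column order for the per-segment results table.
SCAN_COLUMNS = [
    "chrom",
    "start_index",
    "end_index",
    "n_snps",
    "span_start",
    "span_end",
    "tag_snp",
    "sigma2_seg",
    "sigma2_bg",
    "sigma2_e",
    "h2_seg",
    "lrt",
    "p_value",
    "q_value",
    "lfdr",
    "converged",
]


def parse_snp_id(marker_id: str) -> tuple[int, int]:
    """Split a ``S{chrom}_{pos}`` marker ID into (chromosome, position).

    The marker IDs encode the assembly coordinate of each SNP, e.g.
    ``S1_3416180`` is chromosome 1, position 3,416,180 bp.
    """
    m = _SNP_ID_RE.match(str(marker_id))
    if m is None:
        raise ValueError(f"malformed SNP identifier {marker_id!r}: expected S<chrom>_<pos>")
    return int(m.group(1)), int(m.group(2))


@dataclass
class GenotypeMatrix:
    """Clones x markers dosage matrix with a marker map.

    Parameters
    ----------
    clone_ids
        Ordered unique clone identifiers (rows of ``dosages``).
    markers
        DataFrame with columns ``marker_id``, ``chrom``, ``pos``, ``freq``
        (alternate-allele dosage frequency, i.e. mean dosage / 2) and
        ``major_freq`` (major-allele frequency, in [0.5, 1)).
    dosages
        int8 array of shape (n_clones, n_markers) with values in {0, 1, 2}.
    """

    clone_ids: list[str]
    markers: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.clone_ids = [str(c) for c in self.clone_ids]
        if len(set(self.clone_ids)) != len(self.clone_ids):
            raise ValueError("duplicate clone IDs in genotype matrix")
        ids = self.markers["marker_id"].tolist()
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker IDs in genotype matrix")
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.clone_ids), len(ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.clone_ids)} clones x {len(ids)} markers"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage value {self.dosages[r, c]!r} at clone "
                f"{self.clone_ids[r]!r}, marker {ids[c]!r} is not in {{0,1,2}}"
            )
        self.dosages = self.dosages.astype(np.int8)
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"marker positions not strictly increasing on chromosome {chrom}")
        self._recompute_freqs()
        self._index = {m: i for i, m in enumerate(ids)}

    def _recompute_freqs(self) -> None:
        freq = self.dosages.mean(axis=0) / 2.0
        self.markers = self.markers.copy()
        self.markers["freq"] = freq
        self.markers["major_freq"] = np.maximum(freq, 1.0 - freq)

    # -- basic accessors -------------------------------------------------
    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return self.markers["marker_id"].tolist()

    def marker_indices(self, marker_ids) -> np.ndarray:
        try:
            return np.array([self._index[m] for m in marker_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"marker {exc.args[0]!r} not present in genotype matrix") from None

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.markers["chrom"]))

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        idx = self.marker_indices(marker_ids)
        return GenotypeMatrix(
            clone_ids=list(self.clone_ids),
            markers=self.markers.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def clone_index(self, clone_ids) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.clone_ids)}
        try:
            return np.array([lookup[c] for c in clone_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"clone {exc.args[0]!r} not present in genotype matrix") from None


def _markers_from_ids(marker_ids) -> pd.DataFrame:
    chrom_pos = [parse_snp_id(m) for m in marker_ids]
    return pd.DataFrame(
        {
            "marker_id": list(marker_ids),
            "chrom": [cp[0] for cp in chrom_pos],
            "pos": [cp[1] for cp in chrom_pos],
        }
    )


def genotype_matrix_from_dosages(clone_ids, marker_ids, dosages) -> GenotypeMatrix:
    """Build a GenotypeMatrix taking chromosome/position from the marker IDs."""
    return GenotypeMatrix(list(clone_ids), _markers_from_ids(marker_ids), dosages)


def read_dosage(path) -> GenotypeMatrix:
    """Read a dosage TSV: first column clone ID, header row of marker IDs."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    clone_col = df.columns[0]
    marker_ids = list(df.columns[1:])
    body = df[marker_ids]
    vals = body.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        bad = body.stack()[lambda s: pd.to_numeric(s, errors="coerce").isna()]
        row, col = bad.index[0]
        raise ValueError(f"non-numeric dosage {bad.iloc[0]!r} at clone {df[clone_col][row]!r}, marker {col!r}")
    if np.isnan(vals).any():
        r, c = np.argwhere(np.isnan(vals))[0]
        raise ValueError(
            f"missing dosage at clone {df[clone_col][r]!r}, marker {marker_ids[c]!r}: "
            "inputs must be imputed to completeness"
        )
    bad = ~np.isin(vals, (0, 1, 2))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"dosage {vals[r, c]!r} at clone {df[clone_col][r]!r}, marker {marker_ids[c]!r} is not in {{0,1,2}}")
    return genotype_matrix_from_dosages(df[clone_col].tolist(), marker_ids, vals.astype(np.int8))


def write_dosage(geno: GenotypeMatrix, path) -> None:
    out = pd.DataFrame(geno.dosages, columns=geno.marker_ids)
    out.insert(0, "clone", geno.clone_ids)
    out.to_csv(path, sep="\t", index=False)


PHENO_COLUMNS = ["clone", "location", "year", "trial", "value"]


class PhenotypeTable:
    """Plot-level phenotype records for an augmented trial design.

    One row per plot: (clone, location, year, trial, value).  Duplicate
    (clone, trial) rows are legitimate plot-level replicates.  The fixed
    design is a grand mean plus trial-within-year-within-location one-hot
    cells with the first cell dropped as the reference level.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in PHENO_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing required column(s): {missing}")
        self.df = df[PHENO_COLUMNS].reset_index(drop=True).copy()
        self.df["clone"] = self.df["clone"].astype(str)
        if not np.issubdtype(self.df["value"].dtype, np.number):
            raise ValueError("phenotype 'value' column must be numeric")
        if self.df["value"].isna().any():
            raise ValueError("phenotype 'value' column contains missing entries")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def y(self) -> np.ndarray:
        return self.df["value"].to_numpy(dtype=float)

    @property
    def clones(self) -> list[str]:
        """Unique phenotyped clones in first-appearance order."""
        return list(dict.fromkeys(self.df["clone"]))

    def cell_labels(self) -> pd.Series:
        d = self.df
        return (
            d["location"].astype(str) + ":" + d["year"].astype(str) + ":" + d["trial"].astype(str)
        )

    def design_X(self) -> np.ndarray:
        """Grand mean + nested trial-cell dummies (reference cell dropped)."""
        cells = self.cell_labels()
        levels = list(dict.fromkeys(cells))
        X = [np.ones(len(self.df))]
        for lv in levels[1:]:
            X.append((cells == lv).to_numpy(dtype=float))
        X = np.column_stack(X)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient after reference dropping")
        return X

    def incidence_Z(self, clone_ids) -> np.ndarray:
        """Plot -> clone incidence matrix for the given clone ordering."""
        lookup = {c: j for j, c in enumerate(clone_ids)}
        Z = np.zeros((len(self.df), len(clone_ids)))
        for i, c in enumerate(self.df["clone"]):
            if c not in lookup:
                raise KeyError(f"phenotyped clone {c!r} absent from the supplied clone list")
            Z[i, lookup[c]] = 1.0
        return Z

    def subset_clones(self, clone_set) -> "PhenotypeTable":
        keep = self.df["clone"].isin(set(map(str, clone_set)))
        return PhenotypeTable(self.df[keep])

    def with_values(self, values) -> "PhenotypeTable":
        df = self.df.copy()
        df["value"] = np.asarray(values, dtype=float)
        return PhenotypeTable(df)

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path))


@dataclass
class GeneAnnotation:
    """Gene records with 0-based half-open coordinates."""

    df: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"gene annotation missing column(s): {missing}")
        self.df = self.df[self.COLUMNS].reset_index(drop=True).copy()
        bad = self.df["start"] >= self.df["end"]
        if bad.any():
            g = self.df[bad].iloc[0]
            raise ValueError(f"gene {g['gene_id']!r} has inverted or empty interval ({g['start']}, {g['end']})")
        if self.df["start"].lt(0).any():
            raise ValueError("gene interval with negative start")
        if self.df["gene_id"].duplicated().any():
            dup = self.df[self.df["gene_id"].duplicated()]["gene_id"].iloc[0]
            raise ValueError(f"duplicate gene ID {dup!r}")

    def __len__(self) -> int:
        return len(self.df)


def read_gff3_genes(path) -> GeneAnnotation:
    """Read gene features from GFF3 (1-based inclusive -> 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.end < feat.start:
            raise ValueError(f"gene {feat.id!r} has end < start in GFF3")
        rows.append(
            {
                "gene_id": feat.id,
                "chrom": _chrom_token(feat.seqid),
                "start": feat.start - 1,
                "end": feat.end,
                "strand": feat.strand if feat.strand in "+-" else ".",
            }
        )
    return GeneAnnotation(pd.DataFrame(rows, columns=GeneAnnotation.COLUMNS))


def _chrom_token(seqid):
    """Normalize a sequence name to the integer chromosome used in marker IDs."""
    s = str(seqid)
    m = re.match(r"^(?:chr|chromosome_?)?(\d+)$", s, flags=re.IGNORECASE)
    return int(m.group(1)) if m else s


def write_gff3_genes(genes: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.df.iterrows():
            fh.write(
                f"{g['chrom']}\trhmap\tgene\t{int(g['start']) + 1}\t{int(g['end'])}\t.\t"
                f"{g['strand']}\t.\tID={g['gene_id']}\n"
            )


def read_bed(path) -> GeneAnnotation:
    """Read a 4-column BED (already 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("BED file must have at least 4 columns (chrom, start, end, name)")
    out = pd.DataFrame(
        {
            "gene_id": df[3].astype(str),
            "chrom": [_chrom_token(c) for c in df[0]],
            "start": df[1].astype(int),
            "end": df[2].astype(int),
            "strand": df[5].astype(str) if df.shape[1] > 5 else ".",
        }
    )
    return GeneAnnotation(out)


def write_bed(genes: GeneAnnotation, path) -> None:
    genes.df[["chrom", "start", "end", "gene_id"]].to_csv(path, sep="\t", header=False, index=False)


def write_scan_results(scan, path) -> None:
    """Write a ScanResult table as TSV with a stable column order.

    Floats carry 12 significant digits so that a round trip preserves
    p-values and variance components for downstream thresholding.
    """
    df = scan.df if hasattr(scan, "df") else scan
    df = df.reindex(columns=SCAN_COLUMNS)
    df = df.sort_values(["chrom", "span_start"], kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_scan_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
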