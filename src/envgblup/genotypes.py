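"""Genotype handling: HapMap I/O, marker QC, numeric encoding, GRM, PCA.

Genotypes for an inbred-line panel are read from tab-delimited HapMap files,
quality-filtered on missingness, minor-allele frequency and heterozygosity,
and encoded on the {0, 0.5, 1} scale (major homozygote, heterozygote, minor
homozygote).  The genomic relationship matrix is the cross-product of the
centred, standardised marker matrix divided by the number of markers,
G = X X' / p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HapMapRecord",
    "MarkerMatrix",
    "GenomicRelationship",
    "PCAResult",
    "HapMapFormatError",
    "GenotypeDataError",
    "parse_hapmap",
    "write_hapmap",
    "marker_stats",
    "filter_markers",
    "encode_numeric",
    "impute_and_standardize",
    "compute_grm",
    "pca_scores",
]

#: the 11 fixed metadata columns of a HapMap file, in order
HAPMAP_COLUMNS = (
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
)

#: IUPAC single-letter heterozygote codes
IUPAC_HET = {
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
}

MISSING_CODES = {"NN", "N", "-", "--", "./.", "", "NA"}


class HapMapFormatError(ValueError):
    """Raised when a HapMap file does not follow the expected layout."""


class GenotypeDataError(ValueError):
    """Raised for inconsistent genotype content (duplicates, triallelic calls)."""


@dataclass
class HapMapRecord:
    """One SNP row of a HapMap file.

    ``calls`` holds one genotype code per panel line, either diploid pairs
    ("AA", "AG") or IUPAC single letters ("A", "R"); missing data is ``None``.
    """

    marker_id: str
    alleles: tuple[str, str]
    chromosome: str
    position: int
    calls: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        a, b = self.alleles
        if a == b or not {a, b} <= set("ACGT"):
            raise GenotypeDataError(
                f"marker {self.marker_id!r}: alleles must be two distinct "
                f"nucleotides, got {self.alleles}"
            )
        if self.position <= 0:
            raise GenotypeDataError(f"marker {self.marker_id!r}: position must be > 0")


@dataclass
class MarkerMatrix:
    """Lines x markers genotypes on the {0, 0.5, 1} scale; NaN marks missing."""

    line_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.line_ids)) != len(self.line_ids):
            raise GenotypeDataError("duplicate line ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise GenotypeDataError("duplicate marker ids")
        if self.values.shape != (len(self.line_ids), len(self.marker_ids)):
            raise GenotypeDataError("values shape does not match id lists")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.marker_ids)


@dataclass
class GenomicRelationship:
    """Genomic relationship matrix G = XX'/p over the panel lines."""

    line_ids: list[str]
    G: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.G, index=self.line_ids, columns=self.line_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "GenomicRelationship":
        df = pd.read_csv(path, index_col=0)
        return cls(line_ids=list(df.index), G=df.to_numpy(dtype=float))


@dataclass
class PCAResult:
    scores: np.ndarray  # lines x components
    explained_variance_fraction: np.ndarray


def _decode_call(call: str, alleles: frozenset[str], marker_id: str) -> str | None:
    """Normalise one genotype code to a two-letter pair, or None if missing."""
    call = call.strip()
    if call in MISSING_CODES:
        return None
    if len(call) == 1:
        if call in IUPAC_HET:
            pair = IUPAC_HET[call]
            if not pair <= alleles:
                raise GenotypeDataError(
                    f"marker {marker_id!r}: call {call!r} implies alleles {sorted(pair)} "
                    f"outside {sorted(alleles)}"
                )
            a, b = sorted(pair)
            return a + b
        if call in "ACGT":
            return call + call
        return None
    if len(call) == 2 and set(call) <= set("ACGT"):
        return call
    return None


def parse_hapmap(path) -> tuple[list[HapMapRecord], list[str]]:
    """Read a HapMap genotype file.

    Returns the SNP records and the ordered panel line ids.  Both diploid-pair
    and IUPAC single-letter heterozygote dialects are accepted; "NN", "N" and
    "-" map to missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in HAPMAP_COLUMNS:
        if col not in df.columns[: len(HAPMAP_COLUMNS)]:
            raise HapMapFormatError(f"missing required HapMap column {col!r}")
    line_ids = list(df.columns[len(HAPMAP_COLUMNS):])
    if not line_ids:
        raise HapMapFormatError("no sample columns after the 11 header columns")
    seen: set[str] = set()
    records: list[HapMapRecord] = []
    for row in df.itertuples(index=False):
        marker_id = row[0]
        if marker_id in seen:
            raise GenotypeDataError(f"duplicate marker id {marker_id!r}")
        seen.add(marker_id)
        allele_field = row[1].replace("/", "")
        if len(allele_field) != 2:
            raise HapMapFormatError(
                f"marker {marker_id!r}: cannot parse alleles field {row[1]!r}"
            )
        alleles = (allele_field[0], allele_field[1])
        allele_set = frozenset(alleles)
        calls = [
            _decode_call(c, allele_set, marker_id)
            for c in row[len(HAPMAP_COLUMNS):]
        ]
        records.append(
            HapMapRecord(
                marker_id=marker_id,
                alleles=alleles,
                chromosome=str(row[2]),
                position=int(row[3]),
                calls=calls,
            )
        )
    return records, line_ids


def write_hapmap(records: list[HapMapRecord], line_ids: list[str], path) -> None:
    """Write records back to the tab-delimited HapMap layout (diploid pairs)."""
    rows = []
    for rec in records:
        if len(rec.calls) != len(line_ids):
            raise GenotypeDataError(
                f"marker {rec.marker_id!r}: {len(rec.calls)} calls for "
                f"{len(line_ids)} lines"
            )
        row = {
            "rs#": rec.marker_id,
            "alleles": f"{rec.alleles[0]}/{rec.alleles[1]}",
            "chrom": rec.chromosome,
            "pos": rec.position,
            "strand": "+",
            "assembly#": "NA", "center": "NA", "protLSID": "NA",
            "assayLSID": "NA", "panelLSID": "NA", "QCcode": "NA",
        }
        for lid, call in zip(line_ids, rec.calls):
            row[lid] = "NN" if call is None else call
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _record_counts(rec: HapMapRecord) -> tuple[int, int, dict[str, int]]:
    """(n_total, n_missing, allele counts over non-missing calls)."""
    n_missing = sum(c is None for c in rec.calls)
    counts: dict[str, int] = {a: 0 for a in rec.alleles}
    for c in rec.calls:
        if c is None:
            continue
        for letter in c:
            if letter not in counts:
                raise GenotypeDataError(
                    f"marker {rec.marker_id!r}: allele {letter!r} not in "
                    f"declared pair {rec.alleles}"
                )
            counts[letter] += 1
    return len(rec.calls), n_missing, counts


def marker_stats(records: list[HapMapRecord]) -> pd.DataFrame:
    """Per-marker missing fraction, minor-allele frequency and het fraction.

    MAF and heterozygosity are computed over non-missing calls only.
    """
    rows = []
    for rec in records:
        n, n_missing, counts = _record_counts(rec)
        n_called = n - n_missing
        if n_called == 0:
            maf = 0.0
            het = 0.0
        else:
            total_alleles = sum(counts.values())
            freq = min(counts.values()) / total_alleles if total_alleles else 0.0
            maf = freq
            het = sum(c is not None and c[0] != c[1] for c in rec.calls) / n_called
        rows.append(
            {
                "marker_id": rec.marker_id,
                "missing_fraction": n_missing / n if n else 0.0,
                "maf": maf,
                "het_fraction": het,
            }
        )
    return pd.DataFrame(rows).set_index("marker_id")


def filter_markers(
    records: list[HapMapRecord],
    max_missing: float = 0.20,
    min_maf: float = 0.05,
    max_het: float = 0.10,
) -> tuple[list[HapMapRecord], pd.DataFrame]:
    """Apply the three marker QC filters jointly.

    A marker is removed if missingness exceeds ``max_missing``, MAF is below
    ``min_maf``, or heterozygosity exceeds ``max_het`` (all strict, as the
    thresholds are phrased).  Statistics are computed once on the input so the
    outcome does not depend on removal order; the retained set keeps the input
    order.
    """
    if not records:
        warnings.warn("filter_markers called with no records", stacklevel=2)
        return [], pd.DataFrame(
            columns=["missing_fraction", "maf", "het_fraction", "retained"]
        )
    stats = marker_stats(records)
    keep = (
        (stats["missing_fraction"] <= max_missing)
        & (stats["maf"] >= min_maf)
        & (stats["het_fraction"] <= max_het)
    )
    stats["retained"] = keep
    retained = [rec for rec in records if keep.loc[rec.marker_id]]
    return retained, stats


def encode_numeric(records: list[HapMapRecord], line_ids: list[str]) -> MarkerMatrix:
    """Encode calls numerically: major homozygote 0, het 0.5, minor homozygote 1.

    The panel-major allele (higher frequency over non-missing calls; ties
    broken by the declared allele order) defines the 0 state.  Orientation is
    immaterial downstream: the GRM of the centred matrix is invariant to it.
    """
    values = np.full((len(line_ids), len(records)), np.nan)
    marker_ids = []
    for j, rec in enumerate(records):
        _, _, counts = _record_counts(rec)
        # ties resolve to the first declared allele
        major = max(rec.alleles, key=lambda a: counts[a])
        for i, call in enumerate(rec.calls):
            if call is None:
                continue
            n_major = call.count(major)
            values[i, j] = {2: 0.0, 1: 0.5, 0: 1.0}[n_major]
        marker_ids.append(rec.marker_id)
    return MarkerMatrix(line_ids=list(line_ids), marker_ids=marker_ids, values=values)


def impute_and_standardize(m: MarkerMatrix) -> np.ndarray:
    """Mean-impute missing genotypes per marker, then centre and scale.

    Returns the lines x markers matrix X with column mean 0 and sample
    standard deviation (n-1 denominator) 1, as used in G = XX'/p.
    """
    values = m.values.copy()
    col_means = np.nanmean(values, axis=0)
    idx = np.where(np.isnan(values))
    values[idx] = np.take(col_means, idx[1])
    centered = values - values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [m.marker_ids[j] for j in np.where(sd == 0)[0]]
        raise GenotypeDataError(f"zero-variance (monomorphic) markers: {bad}")
    return centered / sd


def compute_grm(X: np.ndarray, line_ids: list[str] | None = None) -> GenomicRelationship:
    """Genomic relationship matrix G = XX'/p from centred standardised markers."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise GenotypeDataError("GRM needs at least 2 lines")
    if p < 1:
        raise GenotypeDataError("GRM needs at least 1 marker")
    G = X @ X.T / p
    G = (G + G.T) / 2.0  # enforce exact symmetry
    if line_ids is None:
        line_ids = [f"L{i}" for i in range(n)]
    return GenomicRelationship(line_ids=list(line_ids), G=G)


def pca_scores(X: np.ndarray, n_components: int) -> PCAResult:
    """Principal-component scores of the centred standardised marker matrix.

    Scores are U * S from the thin SVD of X; explained-variance fractions are
    the squared singular values over their total.
    """
    X = np.asarray(X, dtype=float)
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds min(n_lines, n_markers)")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    frac = s**2 / np.sum(s**2)
    return PCAResult(
        scores=U[:, :n_components] * s[:n_components],
        explained_variance_fraction=frac[:n_components],
    )
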