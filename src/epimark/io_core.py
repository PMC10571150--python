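"""Readers, writers and validated in-memory containers for the formats the
pipeline touches.

All genomic coordinates are handled 0-based half-open internally (BED
convention); any conversion from 1-based annotation happens in loaders, never
downstream.  Chromosome names are opaque strings — no "chr" normalisation is
attempted.  Output files are tab-separated, LF-terminated and deterministically
ordered, so identical inputs always round-trip to identical bytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open 0-based interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name is empty")
        if self.start < 0:
            raise ValidationError(f"interval start {self.start} < 0")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PeakSet:
    """Ordered collection of intervals with stable names and optional scores.

    Input order is preserved on read; sorting is an explicit operation.
    Scores are kept as raw strings so a canonical BED6 file round-trips
    byte-identically.
    """

    intervals: list[GenomicInterval]
    names: list[str]
    scores: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.names) != len(self.intervals):
            raise ValidationError("names/intervals length mismatch")
        if self.scores is not None and len(self.scores) != len(self.intervals):
            raise ValidationError("scores/intervals length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("duplicate peak names")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(zip(self.names, self.intervals))

    def sorted(self) -> "PeakSet":
        order = sorted(
            range(len(self)),
            key=lambda i: (
                self.intervals[i].chrom,
                self.intervals[i].start,
                self.intervals[i].end,
            ),
        )
        return PeakSet(
            intervals=[self.intervals[i] for i in order],
            names=[self.names[i] for i in order],
            scores=None if self.scores is None else [self.scores[i] for i in order],
        )


@dataclass(frozen=True)
class InteractionRecord:
    """One promoter-anchored distal contact, as produced by promoter-capture
    Hi-C: the promoter-side anchor carries the gene id(s), the distal anchor
    is the candidate regulatory region."""

    promoter_anchor: GenomicInterval
    gene_ids: tuple[str, ...]
    distal_anchor: GenomicInterval

    def __post_init__(self) -> None:
        if self.promoter_anchor == self.distal_anchor:
            raise ValidationError("promoter and distal anchors are identical")
        if not self.gene_ids:
            raise ValidationError("interaction record without gene ids")


@dataclass
class InteractionMap:
    records: list[InteractionRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


class CountMatrix:
    """Non-negative integer counts, features x samples.

    Thin wrapper over a pandas DataFrame that enforces unique ids, integer
    dtype and non-negativity at construction.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if data.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if data.isna().any().any():
            raise ValidationError("count matrix contains missing values")
        arr = data.to_numpy()
        if not (arr == arr.astype(int)).all():
            raise ValidationError("counts must be integers")
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        self.data = data.astype("int64")
        self.data.index.name = "feature_id"

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self):
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        return CountMatrix(self.data[list(sample_ids)])

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", lineterminator="\n")


SAMPLE_SHEET_COLUMNS = ["sample_id", "condition", "replicate", "assay"]


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    sheet = sheet[SAMPLE_SHEET_COLUMNS].copy()
    if sheet["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample sheet")
    rep = pd.to_numeric(sheet["replicate"], errors="coerce")
    if rep.isna().any() or (rep < 1).any() or (rep != rep.astype(int)).any():
        raise ValidationError("replicate must be a positive integer")
    sheet["replicate"] = rep.astype(int)
    return sheet


def read_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t", dtype=str))


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


GENE_TABLE_COLUMNS = ["gene_id", "gene_name", "chrom", "tss", "strand"]


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_TABLE_COLUMNS if c not in genes.columns]
    if missing:
        raise FormatError(f"gene table missing columns: {missing}")
    genes = genes[GENE_TABLE_COLUMNS].copy()
    if genes["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene_id in gene table")
    tss = pd.to_numeric(genes["tss"], errors="coerce")
    if tss.isna().any() or (tss < 0).any():
        raise ValidationError("tss must be a non-negative integer")
    genes["tss"] = tss.astype(int)
    bad = ~genes["strand"].isin(["+", "-"])
    if bad.any():
        raise ValidationError(
            f"gene strand must be + or -: {genes.loc[bad, 'gene_id'].tolist()[:5]}"
        )
    return genes


def read_gene_table(path) -> pd.DataFrame:
    """Read a TSS table (gene_id, gene_name, chrom, tss, strand); tss is
    0-based.  Converting from 1-based GTF coordinates is the caller's job."""
    return validate_gene_table(pd.read_csv(path, sep="\t", dtype=str))


def write_gene_table(genes: pd.DataFrame, path) -> None:
    validate_gene_table(genes).to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# BED / BEDPE / counts / bedGraph parsing


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_bed(path) -> PeakSet:
    """Read BED3+ into a PeakSet.  Names are auto-generated (peak_000001 ...)
    when column 4 is absent; input order is preserved."""
    intervals: list[GenomicInterval] = []
    names: list[str] = []
    scores: list[str] = []
    any_score = False
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 3:
            raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        strand = cols[5] if len(cols) >= 6 else "."
        try:
            iv = GenomicInterval(cols[0], start, end, strand)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        intervals.append(iv)
        names.append(cols[3] if len(cols) >= 4 else f"peak_{len(intervals):06d}")
        if len(cols) >= 5:
            any_score = True
            scores.append(cols[4])
        else:
            scores.append("0")
    return PeakSet(intervals, names, scores if any_score else None)


def write_bed(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for i, (name, iv) in enumerate(peaks):
            fields = [iv.chrom, str(iv.start), str(iv.end), name]
            if peaks.scores is not None or iv.strand != ".":
                fields.append(peaks.scores[i] if peaks.scores is not None else "0")
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def read_bedpe_interactions(path, gene_table: pd.DataFrame) -> InteractionMap:
    """Read promoter-distal interactions (BEDPE plus a gene-id column 7,
    comma-separated list allowed).  Gene ids are resolved against the gene
    table; records with no resolvable gene are dropped with a warning."""
    known = set(gene_table["gene_id"])
    records: list[InteractionRecord] = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 7:
            raise FormatError(
                f"{path}:{lineno}: expected 6 coordinate columns plus a gene column"
            )
        try:
            prom = GenomicInterval(cols[0], int(cols[1]), int(cols[2]))
            dist = GenomicInterval(cols[3], int(cols[4]), int(cols[5]))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad anchor coordinates: {exc}") from exc
        genes = tuple(g for g in cols[6].split(",") if g in known)
        if not genes:
            logger.warning(
                "%s:%d: no resolvable gene id in %r; record dropped",
                path, lineno, cols[6],
            )
            continue
        records.append(InteractionRecord(prom, genes, dist))
    return InteractionMap(records)


def write_bedpe_interactions(imap: InteractionMap, path) -> None:
    with open(path, "w") as fh:
        for rec in imap:
            p, d = rec.promoter_anchor, rec.distal_anchor
            fh.write(
                "\t".join(
                    [p.chrom, str(p.start), str(p.end),
                     d.chrom, str(d.start), str(d.end),
                     ",".join(rec.gene_ids)]
                )
                + "\n"
            )


def read_counts(path, sample_sheet: pd.DataFrame | None = None) -> CountMatrix:
    """Read a counts TSV (first column feature_id, remaining columns samples).

    When a sample sheet is given, columns are restricted to and reordered by
    the sheet; a sheet sample absent from the file is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    cm = CountMatrix(df)
    if sample_sheet is not None:
        wanted = list(sample_sheet["sample_id"])
        missing = [s for s in wanted if s not in df.columns]
        if missing:
            raise ValidationError(
                f"sample sheet samples missing from {path}: {missing}"
            )
        cm = cm.subset_samples(wanted)
    return cm


def read_bedgraph(path) -> pd.DataFrame:
    """Read binned coverage (chrom, start, end, value) with an optional
    header line."""
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    has_header = str(first.iloc[0, 0]) == "chrom"
    df = pd.read_csv(
        path, sep="\t",
        header=0 if has_header else None,
        names=["chrom", "start", "end", "value"],
    )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["value"] = df["value"].astype(float)
    if (df["end"] <= df["start"]).any():
        raise ValidationError(f"{path}: bin end must exceed start")
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    out = df[["chrom", "start", "end", "value"]].copy()
    out["value"] = out["value"].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
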