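"""Readers and writers for the on-disk artifacts of the atlas pipeline.

Everything is plain text: BED intervals (0-based half-open), a tab-separated
sample sheet mirroring the atlas metadata/mapping-statistics tables, labeled
numeric matrices, and FASTA sequences. All genomic coordinates are kept in
BED convention (0-based, half-open) throughout the package; any 1-based
dialect must be converted at this boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class ParseError(ValueError):
    """A malformed line or field in an input file."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


# --------------------------------------------------------------------------
# Genomic intervals
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``[start, end)``.

    The unit of both peaks and sequenced fragments. ``name``, ``score`` and
    ``strand`` are optional BED6 extras.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def read_bed(path: str | Path, min_fields: int = 3) -> list[GenomicInterval]:
    """Read a BED file into a list of :class:`GenomicInterval` in file order.

    Lines starting with ``#``, ``track`` or ``browser`` and blank lines are
    skipped. ``min_fields`` (>= 3) is the minimum number of tab-separated
    fields each data line must carry.
    """
    if min_fields < 3:
        raise ValueError("min_fields must be >= 3")
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {min_fields} fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] else None
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name, score, strand)
                )
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3/BED6 (six columns as soon as any extra is set)."""
    intervals = list(intervals)
    six = any(
        iv.name is not None or iv.score is not None or iv.strand is not None
        for iv in intervals
    )
    with Path(path).open("w") as fh:
        for iv in intervals:
            if six:
                score = "." if iv.score is None else format_number(iv.score)
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score}\t{iv.strand or '.'}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def format_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


# --------------------------------------------------------------------------
# Sample sheet
# --------------------------------------------------------------------------

SHEET_REQUIRED_COLUMNS = (
    "sample_id",
    "strain",
    "serial",
    "gender",
    "tissue",
    "replicate",
    "total_reads",
    "mapped_reads",
    "chrm_reads",
    "usable_reads",
)
SHEET_METRIC_COLUMNS = ("tss_enrichment", "reproducible_peaks")


@dataclass
class SampleRecord:
    """Metadata, read accounting and QC metrics for one ATAC-seq library.

    ``usable_reads`` is the number of mapped reads left after removing
    low-mapping-quality, duplicate and mitochondrial reads; it is the RPM
    denominator downstream. ``tss_enrichment`` and ``reproducible_peaks``
    may be missing (``None``) until the QC / peak stages have run.
    """

    sample_id: str
    strain: str
    serial: int
    gender: str
    tissue: str
    replicate: int
    total_reads: int
    mapped_reads: int
    chrm_reads: int
    usable_reads: int
    tss_enrichment: float | None = None
    reproducible_peaks: int | None = None

    def __post_init__(self) -> None:
        if self.replicate not in (1, 2):
            raise ValidationError(
                f"{self.sample_id}: replicate must be 1 or 2, got {self.replicate}"
            )
        if self.gender not in ("Male", "Female"):
            raise ValidationError(
                f"{self.sample_id}: gender must be Male or Female, got {self.gender!r}"
            )
        if not (self.usable_reads <= self.mapped_reads <= self.total_reads):
            raise ValidationError(
                f"{self.sample_id}: require usable <= mapped <= total reads"
            )
        if self.chrm_reads > self.mapped_reads:
            raise ValidationError(f"{self.sample_id}: chrM reads exceed mapped reads")


def _parse_count(value: str | int | float, column: str, sample: str) -> int:
    """Parse an integer count, tolerating thousands separators."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if float(value) != int(value):
            raise ParseError(f"{sample}: non-integer {column} {value!r}")
        return int(value)
    text = str(value).replace(",", "").strip()
    if not text.lstrip("-").isdigit():
        raise ParseError(f"{sample}: non-integer {column} {value!r}")
    return int(text)


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read the tab-separated sample sheet into :class:`SampleRecord` objects.

    The sheet must carry a header with at least the metadata and
    read-accounting columns; QC metric columns are optional. Count columns
    may use comma thousands separators, as the printed tables do. Extra
    columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SHEET_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sample sheet missing required columns: {missing}")
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        if sid in seen:
            raise ValidationError(f"duplicate sample_id {sid!r}")
        seen.add(sid)
        tss = None
        if "tss_enrichment" in df.columns and not _is_missing(row["tss_enrichment"]):
            tss = float(row["tss_enrichment"])
        peaks = None
        if "reproducible_peaks" in df.columns and not _is_missing(
            row["reproducible_peaks"]
        ):
            peaks = _parse_count(row["reproducible_peaks"], "reproducible_peaks", sid)
        records.append(
            SampleRecord(
                sample_id=sid,
                strain=str(row["strain"]),
                serial=_parse_count(row["serial"], "serial", sid),
                gender=str(row["gender"]),
                tissue=str(row["tissue"]),
                replicate=_parse_count(row["replicate"], "replicate", sid),
                total_reads=_parse_count(row["total_reads"], "total_reads", sid),
                mapped_reads=_parse_count(row["mapped_reads"], "mapped_reads", sid),
                chrm_reads=_parse_count(row["chrm_reads"], "chrm_reads", sid),
                usable_reads=_parse_count(row["usable_reads"], "usable_reads", sid),
                tss_enrichment=tss,
                reproducible_peaks=peaks,
            )
        )
    return records


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value).strip() in ("", "NA", "nan", "None")


def write_sample_sheet(records: Sequence[SampleRecord], path: str | Path) -> None:
    cols = list(SHEET_REQUIRED_COLUMNS) + list(SHEET_METRIC_COLUMNS)
    rows = []
    for r in records:
        d = {c: getattr(r, c) for c in SHEET_REQUIRED_COLUMNS}
        d["tss_enrichment"] = "NA" if r.tss_enrichment is None else r.tss_enrichment
        d["reproducible_peaks"] = (
            "NA" if r.reproducible_peaks is None else r.reproducible_peaks
        )
        rows.append(d)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Labeled matrices
# --------------------------------------------------------------------------

NA_SENTINEL = "NA"


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled numeric matrix as TSV with a leading row-label column.

    NaN cells are written as the sentinel ``NA`` and restored on read.
    Values round-trip exactly because floats are serialized with ``repr``
    precision. Duplicate row/column labels and empty matrices are rejected.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValidationError("refusing to write an empty matrix")
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise ValidationError("matrix labels must be unique")
    with Path(path).open("w") as fh:
        fh.write("\t".join(["row_id", *map(str, matrix.columns)]) + "\n")
        for label, row in matrix.iterrows():
            cells = [
                NA_SENTINEL if pd.isna(v) else format_number(v) for v in row.to_numpy()
            ]
            fh.write("\t".join([str(label), *cells]) + "\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[NA_SENTINEL], keep_default_na=False
    )
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValidationError("matrix labels must be unique")
    return df


# --------------------------------------------------------------------------
# FASTA and motif tables (inputs to the motif-summary stage)
# --------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` mapping."""
    seqs: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                if name in seqs:
                    raise ValidationError(f"duplicate FASTA record {name!r}")
                chunks = []
            else:
                if name is None:
                    raise ParseError(f"{path}: sequence before first header")
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
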