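"""Readers and writers for the external formats the pipeline touches.

BED flavors (BED3/BED6/narrowPeak/broadPeak), a gene annotation TSV, a
JASPAR-style motif file, a raw count TSV, and indexed FASTA access. All
parsing converts to 0-based half-open coordinates at this boundary; the
annotation TSS (1-based, as annotation exports conventionally are) is
converted here and nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "GeneRecord",
    "GeneAnnotationTable",
    "MotifModel",
    "CountMatrix",
    "read_bed",
    "write_bed",
    "read_gene_annotation",
    "read_motifs",
    "read_counts",
    "fetch_sequence",
]

_BASES = "ACGT"

_DIALECT_COLUMNS = {"bed3": 3, "bed6": 6, "broadPeak": 9, "narrowPeak": 10}


class BedParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int  # 0-based position
    exonic_length: int
    description: str = ""


class GeneAnnotationTable:
    """Per-gene annotation: symbol, chromosome, strand, TSS, exonic length."""

    def __init__(self, records: Iterable[GeneRecord]):
        self._by_id: dict[str, GeneRecord] = {}
        for rec in records:
            if rec.gene_id in self._by_id:
                raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
            if rec.exonic_length <= 0:
                raise ValueError(
                    f"gene {rec.gene_id!r}: exonic_length must be > 0"
                )
            if rec.tss < 0:
                raise ValueError(f"gene {rec.gene_id!r}: tss must be >= 0")
            if rec.strand not in {"+", "-", "."}:
                raise ValueError(
                    f"gene {rec.gene_id!r}: invalid strand {rec.strand!r}"
                )
            self._by_id[rec.gene_id] = rec
        self._by_symbol: dict[str, GeneRecord] = {}
        for rec in self._by_id.values():
            self._by_symbol.setdefault(rec.symbol, rec)

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def get_by_symbol(self, symbol: str) -> GeneRecord | None:
        return self._by_symbol.get(symbol)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._by_id)

    def records(self) -> list[GeneRecord]:
        return list(self._by_id.values())


@dataclass
class MotifModel:
    """Per-TF position probability matrix.

    ``matrix`` is L x 4 (columns A, C, G, T), each row summing to 1 with
    strictly positive entries after pseudocounting. Dimer motifs carry the
    constituent gene symbols (name split on ".." or "::").
    """

    tf_name: str
    matrix: np.ndarray
    constituents: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("motif matrix must be L x 4")
        if self.matrix.shape[0] < 1:
            raise ValueError("motif length must be >= 1")
        if not np.all(self.matrix > 0):
            raise ValueError(f"motif {self.tf_name!r}: entries must be > 0")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"motif {self.tf_name!r}: rows must sum to 1")
        if not self.constituents:
            self.constituents = re.split(r"\.\.|::", self.tf_name)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


@dataclass
class CountMatrix:
    """Raw RNA-seq counts, genes x samples, with a sample -> group mapping."""

    genes: list[str]
    samples: list[str]
    counts: np.ndarray
    sample_groups: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts shape does not match gene/sample lists")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")
        missing = [s for s in self.samples if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.sample_groups[s], None)
        return list(seen)

    def group_columns(self, group: str) -> list[int]:
        cols = [j for j, s in enumerate(self.samples) if self.sample_groups[s] == group]
        if not cols:
            raise ValueError(f"unknown group label {group!r}")
        return cols

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)


def _infer_dialect(n_cols: int) -> str:
    for name, cols in _DIALECT_COLUMNS.items():
        if n_cols == cols:
            return name
    if n_cols > 10:
        return "narrowPeak"
    if 6 < n_cols < 9:
        return "bed6"
    if 3 < n_cols < 6:
        return "bed3"
    raise BedParseError(f"cannot infer BED dialect from {n_cols} columns")


def read_bed(
    path: str | Path,
    dialect: str = "auto",
    group: str = "",
    assay: str = "",
) -> PeakSet:
    """Read a BED3/BED6/narrowPeak/broadPeak file into a sorted PeakSet.

    ``dialect="auto"`` infers the flavor from the column count of the
    first data line. narrowPeak summit offsets (column 10) are retained on
    each interval. Track and comment lines are skipped.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    inferred: str | None = None if dialect == "auto" else dialect
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if inferred is None:
                inferred = _infer_dialect(len(fields))
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in {".", ""}:
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "."
            summit: int | None = None
            if inferred == "narrowPeak" and len(fields) >= 10:
                s = int(fields[9])
                summit = s if s >= 0 else None
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name, score, strand, summit)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(intervals, group=group, assay=assay, source_path=str(path))


def write_bed(peaks: PeakSet | Iterable[GenomicInterval], path: str | Path) -> None:
    intervals = peaks.intervals if isinstance(peaks, PeakSet) else list(peaks)
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields.append(iv.name if iv.name is not None else ".")
                fields.append(f"{iv.score:g}" if iv.score is not None else "0")
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


_ANNOT_COLUMNS = {"gene_id", "symbol", "chrom", "strand", "tss", "length"}


def read_gene_annotation(path: str | Path) -> GeneAnnotationTable:
    """Read the gene annotation TSV.

    Required header columns: gene_id, symbol, chrom, strand, tss, length.
    ``tss`` is 1-based in the file and converted to 0-based here. An
    optional ``description`` column is carried through.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = _ANNOT_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            GeneRecord(
                gene_id=row.gene_id,
                symbol=row.symbol,
                chrom=row.chrom,
                strand=row.strand,
                tss=int(row.tss) - 1,
                exonic_length=int(row.length),
                description=getattr(row, "description", "") or "",
            )
        )
    return GeneAnnotationTable(records)


def read_motifs(path: str | Path, pseudocount: float = 0.01) -> list[MotifModel]:
    """Parse a JASPAR-style motif file into MotifModels.

    Each block is ``>name`` followed by four base rows (A, C, G, T) of
    counts or frequencies, optionally in the ``A [ 1 2 3 ]`` style. The
    pseudocount is added to every count before column-wise normalization,
    guaranteeing strictly positive probabilities.
    """
    motifs: list[MotifModel] = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal name, rows
        if name is None:
            return
        if len(rows) != 4:
            raise ValueError(f"motif {name!r}: expected 4 base rows, got {len(rows)}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"motif {name!r}: ragged rows {sorted(lengths)}")
        counts = np.array(rows, dtype=float).T  # L x 4, file rows are A,C,G,T
        counts = counts + pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        motifs.append(MotifModel(name, probs))
        name, rows = None, []

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                rows = []
            else:
                nums = re.findall(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?", line)
                # drop a leading base letter such as "A [ ... ]"
                if not nums:
                    raise ValueError(f"unparseable motif row: {line!r}")
                rows.append([float(x) for x in nums])
    flush()
    if not motifs:
        raise ValueError(f"{path}: no motifs found")
    return motifs


def read_counts(path: str | Path, groups: Mapping[str, str]) -> CountMatrix:
    """Read a raw count TSV (first column gene_id, one column per sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    unmapped = [s for s in df.columns if s not in groups]
    if unmapped:
        raise ValueError(f"samples missing from group map: {unmapped}")
    counts = df.to_numpy()
    if np.any(counts < 0):
        raise ValueError("negative counts present")
    return CountMatrix(
        genes=list(df.index.astype(str)),
        samples=list(df.columns.astype(str)),
        counts=counts.astype(np.int64),
        sample_groups={s: groups[s] for s in df.columns},
    )


def fetch_sequence(genome: Fasta, interval: GenomicInterval) -> str:
    """Fetch the uppercase sequence for a half-open interval.

    Raises for chromosomes absent from the FASTA or intervals extending
    past the chromosome end; ambiguous bases are preserved as N.
    """
    if interval.chrom not in genome:
        raise KeyError(f"chromosome {interval.chrom!r} not in FASTA")
    chrom_len = len(genome[interval.chrom])
    if interval.end > chrom_len:
        raise ValueError(
            f"{interval.chrom}:{interval.start}-{interval.end} exceeds "
            f"chromosome length {chrom_len}"
        )
    return str(genome[interval.chrom][interval.start : interval.end]).upper()
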