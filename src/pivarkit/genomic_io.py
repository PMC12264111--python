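"""Tabular genomic I/O, read filtering, interval overlap and cluster counting.

All coordinates are 0-based half-open internally.  BED-style files are read
and written as-is; strand is one of ``+``, ``-`` or ``.`` (unstranded).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "AlignmentRecord",
    "SmallRNARead",
    "CountMatrix",
    "SampleTable",
    "read_intervals",
    "write_intervals",
    "read_alignments",
    "write_alignments",
    "read_fastq",
    "filter_reads",
    "count_reads_in_clusters",
    "interval_overlap",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_table",
    "write_sample_table",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-annotated genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."
    extra: tuple = ()

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) for {self.name}"
            )
        if self.strand not in STRANDS and self.strand != "both":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap(self, other: "GenomicInterval") -> int | None:
        """Edge-to-edge gap in bp; 0 when overlapping, None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped small-RNA read.

    ``n_hits`` is the number of genomic loci the read maps to;
    ``n_hits == 1`` means uniquely mapping.
    """

    read_id: str
    sample_id: str
    chrom: str
    start: int
    end: int
    strand: str
    n_hits: int = 1

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("alignment end must exceed start")
        if self.n_hits < 1:
            raise ValueError("n_hits must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"alignment strand must be + or -, got {self.strand!r}")

    @property
    def read_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SmallRNARead:
    read_id: str
    sequence: str
    qualities: tuple

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities must have equal length")


@dataclass
class CountMatrix:
    """Clusters x samples matrix of non-negative integer read counts."""

    cluster_ids: list
    sample_ids: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cluster_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.cluster_ids)) != len(self.cluster_ids):
            raise ValueError("cluster ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.cluster_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())


@dataclass
class SampleTable:
    """Per-sample metadata: strain, tissue, batch and optional pedigree link."""

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "strain", "tissue", "batch")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValueError(f"sample table missing column {col!r}")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("sample_id values must be unique")
        if "individual_id" not in self.frame.columns:
            self.frame = self.frame.assign(individual_id=pd.NA)

    def strains(self) -> list:
        return sorted(self.frame["strain"].unique())

    def samples_for(self, strain, tissue=None) -> list:
        mask = self.frame["strain"] == strain
        if tissue is not None:
            mask &= self.frame["tissue"] == tissue
        return list(self.frame.loc[mask, "sample_id"])


# ---------------------------------------------------------------------------
# readers / writers


def _parse_bed6_line(line: str, lineno: int) -> GenomicInterval:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 6:
        raise ValueError(f"line {lineno}: expected >= 6 BED fields, got {len(parts)}")
    chrom, start, end, name, score, strand = parts[:6]
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinates") from exc
    if end_i <= start_i:
        raise ValueError(f"line {lineno}: end <= start ({start_i}, {end_i})")
    return GenomicInterval(chrom, start_i, end_i, name, strand, tuple(parts[6:]))


def read_intervals(path, format: str = "BED6") -> list[GenomicInterval]:
    """Read intervals from BED6 or a TEV-style TSV (BED6 + extra columns)."""
    if format not in ("BED6", "TEV-TSV"):
        raise ValueError(f"unknown interval format {format!r}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track ")):
                continue
            out.append(_parse_bed6_line(line, lineno))
    return out


def write_intervals(path, intervals: Iterable[GenomicInterval], score: str = "0") -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.name, score, iv.strand]
            fields.extend(str(x) for x in iv.extra)
            fh.write("\t".join(fields) + "\n")


ALIGNMENT_COLUMNS = ["read_id", "sample_id", "chrom", "start", "end", "strand", "n_hits"]


def read_alignments(path) -> pd.DataFrame:
    """Read the alignment TSV dialect into a typed DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "read_id": str, "sample_id": str})
    missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"alignment table missing columns: {missing}")
    if (df["end"] <= df["start"]).any():
        bad = df.index[df["end"] <= df["start"]][0]
        raise ValueError(f"alignment row {bad}: end <= start")
    if (df["n_hits"] < 1).any():
        raise ValueError("n_hits must be >= 1")
    return df


def write_alignments(path, alignments: pd.DataFrame) -> None:
    alignments[ALIGNMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_fastq(path) -> list[SmallRNARead]:
    """Read a FASTQ file (Phred+33) into SmallRNARead records."""
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError("malformed FASTQ record")
            reads.append(
                SmallRNARead(header[1:].split()[0], seq, tuple(ord(c) - 33 for c in qual))
            )
    return reads


def read_count_matrix(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix.from_frame(df)


def write_count_matrix(path, cm: CountMatrix) -> None:
    df = cm.to_frame()
    df.index.name = "cluster_id"
    df.to_csv(path, sep="\t")


def read_sample_table(path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str}))


def write_sample_table(path, table: SampleTable) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# read-level filters


def filter_reads(
    reads: Sequence[SmallRNARead],
    min_len: int = 19,
    max_len: int = 36,
    min_q: int = 30,
    min_frac: float = 0.9,
) -> list[SmallRNARead]:
    """Length and quality filter for small-RNA reads.

    Retains reads with ``min_len <= length <= max_len`` and with at least
    ``min_frac`` of bases at quality >= ``min_q``.  Order is preserved.
    """
    kept = []
    for read in reads:
        n = len(read.sequence)
        if n < min_len or n > max_len:
            continue
        good = sum(1 for q in read.qualities if q >= min_q)
        if good / n >= min_frac:
            kept.append(read)
    return kept


# ---------------------------------------------------------------------------
# interval machinery


def interval_overlap(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    max_gap: int = 0,
) -> list[tuple[int, int, int, int]]:
    """All (i, j, overlap_bp, gap_bp) pairs with edge-to-edge gap <= max_gap.

    Overlapping pairs are reported with their overlap length and gap 0.
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(b):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for lst in by_chrom.values():
        lst.sort()
    pairs = []
    for i, iv in enumerate(a):
        candidates = by_chrom.get(iv.chrom, ())
        for start, end, j in candidates:
            if start > iv.end + max_gap:
                break
            if end < iv.start - max_gap:
                continue
            ov = max(0, min(iv.end, end) - max(iv.start, start))
            gap = max(0, max(iv.start, start) - min(iv.end, end))
            if gap <= max_gap:
                pairs.append((i, j, ov, gap))
    return pairs


def _overlaps_any(df: pd.DataFrame, intervals: Sequence[GenomicInterval]) -> np.ndarray:
    """Boolean mask: does each alignment row overlap (>=1 bp) any interval."""
    mask = np.zeros(len(df), dtype=bool)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    chrom_codes = df["chrom"].to_numpy()
    for chrom, ivs in by_chrom.items():
        sel = np.flatnonzero(chrom_codes == chrom)
        if sel.size == 0:
            continue
        s, e = starts[sel], ends[sel]
        hit = np.zeros(sel.size, dtype=bool)
        for iv in ivs:
            hit |= (np.minimum(e, iv.end) - np.maximum(s, iv.start)) > 0
        mask[sel] |= hit
    return mask


def count_reads_in_clusters(
    alignments: pd.DataFrame,
    clusters: Sequence[GenomicInterval],
    min_overlap: int = 18,
    unique_only: bool = True,
    exclude_repeats: Sequence[GenomicInterval] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> CountMatrix:
    """Count reads overlapping each cluster by at least ``min_overlap`` bp.

    Counting is strand-agnostic.  With ``unique_only`` only reads with
    n_hits == 1 contribute; with ``exclude_repeats`` reads overlapping any
    repeat interval are dropped first.  A read overlapping several clusters
    at >= min_overlap contributes to each of them.
    """
    names = [iv.name for iv in clusters]
    if len(set(names)) != len(names):
        raise ValueError("cluster ids must be unique")
    if sample_ids is None:
        sample_ids = sorted(alignments["sample_id"].unique())
    sample_ids = list(sample_ids)

    df = alignments
    if unique_only:
        df = df[df["n_hits"] == 1]
    if exclude_repeats:
        df = df[~_overlaps_any(df, exclude_repeats)]

    counts = np.zeros((len(clusters), len(sample_ids)), dtype=np.int64)
    sample_index = {s: k for k, s in enumerate(sample_ids)}
    codes = df["sample_id"].map(sample_index).to_numpy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    chroms = df["chrom"].to_numpy()
    for i, iv in enumerate(clusters):
        sel = chroms == iv.chrom
        ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
        hit = sel & (ov >= min_overlap)
        if hit.any():
            counts[i] = np.bincount(codes[hit], minlength=len(sample_ids))
    return CountMatrix(names, sample_ids, counts)
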