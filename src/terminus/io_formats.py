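"""Readers and writers for the genomic formats the pipeline touches.

One coordinate convention is used throughout the package: 0-based, half-open
intervals, as in BED and bedGraph.  GTF (1-based, inclusive) is converted on
read and write.  A transcript "3' end" is stored as the 0-based coordinate of
the 3'-most transcribed nucleotide: the maximal genomic coordinate on the +
strand and the minimal one on the - strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "CoverageTrack",
    "UtrIsoform",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "read_bedgraph",
    "write_bedgraph",
    "read_ends_bed",
    "write_ends_bed",
    "three_prime_coord",
    "terminal_window_bounds",
]

PROVENANCE_CODES = {"ensembl": 0, "extended": 1, "novel": 2}
_CODES_PROVENANCE = {v: k for k, v in PROVENANCE_CODES.items()}


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be parsed; the message names the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded, 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """A transcript with its known 3' UTR isoform ends.

    Multiple annotated ends are kept on one model (one per known tandem
    isoform) rather than duplicating the transcript.  ``cds_end_3p`` is the
    0-based coordinate of the first 3' UTR nucleotide (adjacent to the stop
    codon); ``annotated_ends`` hold 3'-most-base coordinates.
    """

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    cds_end_3p: int
    annotated_ends: list[int] = field(default_factory=list)
    has_utr: bool = True

    @property
    def strand(self) -> str:
        return self.interval.strand

    def utr_length_of(self, end: int) -> int:
        """3' UTR length in nt implied by an end coordinate."""
        if self.strand == "+":
            return end - self.cds_end_3p + 1
        return self.cds_end_3p - end + 1

    def end_of_utr_length(self, length: int) -> int:
        if self.strand == "+":
            return self.cds_end_3p + length - 1
        return self.cds_end_3p - length + 1

    @property
    def distal_annotated_end(self) -> int | None:
        if not self.annotated_ends:
            return None
        return max(self.annotated_ends) if self.strand == "+" else min(self.annotated_ends)


@dataclass
class UtrIsoform:
    """A single 3' UTR end (annotated, extended, or novel) of a transcript."""

    transcript_id: str
    end: int
    utr_length: int
    provenance: str
    chrom: str = "."
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCE_CODES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.utr_length <= 0:
            raise ValueError("utr_length must be positive")


@dataclass
class CoverageTrack:
    """Dense per-nucleotide stranded read depth on one reference sequence.

    ``values[i]`` is the depth at genomic position ``start + i``.  Positions
    outside ``[start, start + len(values))`` have depth zero.
    """

    chrom: str
    strand: str
    start: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("coverage depth must be non-negative")

    @property
    def end(self) -> int:
        return self.start + self.values.size

    def slice(self, start: int, end: int) -> np.ndarray:
        """Per-nt depth over genomic [start, end), zero-padded outside the span."""
        if end <= start:
            return np.zeros(0)
        out = np.zeros(end - start)
        lo = max(start, self.start)
        hi = min(end, self.end)
        if lo < hi:
            out[lo - start : hi - start] = self.values[lo - self.start : hi - self.start]
        return out

    def window_sum(self, start: int, end: int) -> float:
        return float(self.slice(start, end).sum())

    def __add__(self, other: "CoverageTrack") -> "CoverageTrack":
        if (self.chrom, self.strand) != (other.chrom, other.strand):
            raise ValueError("cannot add tracks from different chrom/strand")
        lo = min(self.start, other.start)
        hi = max(self.end, other.end)
        vals = np.zeros(hi - lo)
        vals[self.start - lo : self.end - lo] += self.values
        vals[other.start - lo : other.end - lo] += other.values
        return CoverageTrack(self.chrom, self.strand, lo, vals)


def three_prime_coord(start: int, end: int, strand: str) -> int:
    """3'-most base of a half-open interval in transcript orientation."""
    return end - 1 if strand == "+" else start


def terminal_window_bounds(end: int, window: int, strand: str) -> tuple[int, int]:
    """Half-open genomic bounds of the ``window`` nt ending at base ``end``."""
    if strand == "+":
        return end + 1 - window, end + 1
    return end, end + window


# ---------------------------------------------------------------------------
# GTF


def _parse_gtf_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise GtfParseError(f"malformed attribute {chunk!r} on GTF line {lineno}")
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse an Ensembl-dialect GTF into transcript models.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    ``three_prime_utr`` features supply the annotated isoform ends (several
    per transcript are allowed); transcripts without any are flagged
    ``has_utr=False`` rather than dropped, with the 3' transcript end used
    as a degenerate UTR anchor.
    """
    feats: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise GtfParseError(f"expected 9 columns on GTF line {lineno}")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attr_text = cols
            if strand not in ("+", "-"):
                warnings.warn(f"GTF line {lineno}: unknown strand {strand!r}; record rejected")
                continue
            try:
                start = int(start1) - 1
                end = int(end1)
            except ValueError as exc:
                raise GtfParseError(f"non-integer coordinate on GTF line {lineno}") from exc
            attrs = _parse_gtf_attributes(attr_text, lineno)
            tid = attrs.get("transcript_id")
            if tid is None:
                continue  # gene-level line
            rec = feats.setdefault(
                tid,
                {
                    "gene_id": attrs.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "span": [start, end],
                    "utr": [],
                    "cds": [],
                    "has_transcript_line": False,
                },
            )
            rec["span"][0] = min(rec["span"][0], start)
            rec["span"][1] = max(rec["span"][1], end)
            if feature == "transcript":
                rec["has_transcript_line"] = True
            elif feature == "three_prime_utr":
                rec["utr"].append((start, end))
            elif feature == "CDS":
                rec["cds"].append((start, end))

    models: list[TranscriptModel] = []
    for tid, rec in feats.items():
        strand = rec["strand"]
        interval = GenomicInterval(rec["chrom"], rec["span"][0], rec["span"][1], strand)
        utrs = rec["utr"]
        if utrs:
            has_utr = True
            if strand == "+":
                cds_end_3p = min(s for s, _ in utrs)
                ends = sorted({e - 1 for _, e in utrs})
            else:
                cds_end_3p = max(e for _, e in utrs) - 1
                ends = sorted({s for s, _ in utrs}, reverse=True)
        else:
            has_utr = False
            if rec["cds"]:
                if strand == "+":
                    cds_end_3p = max(e for _, e in rec["cds"])
                else:
                    cds_end_3p = min(s for s, _ in rec["cds"]) - 1
            else:
                cds_end_3p = three_prime_coord(interval.start, interval.end, strand)
            ends = [three_prime_coord(interval.start, interval.end, strand)]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                interval=interval,
                cds_end_3p=cds_end_3p,
                annotated_ends=ends,
                has_utr=has_utr,
            )
        )
    return models


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as Ensembl-dialect GTF (inverse of read_gtf)."""
    with open(path, "w") as fh:
        for t in transcripts:
            iv = t.interval
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'

            def line(feature: str, s0: int, e0: int) -> str:
                return (
                    f"{iv.chrom}\tterminus\t{feature}\t{s0 + 1}\t{e0}\t.\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )

            fh.write(line("transcript", iv.start, iv.end))
            fh.write(line("exon", iv.start, iv.end))
            if t.has_utr:
                for end in t.annotated_ends:
                    if iv.strand == "+":
                        fh.write(line("three_prime_utr", t.cds_end_3p, end + 1))
                    else:
                        fh.write(line("three_prime_utr", end, t.cds_end_3p + 1))


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path, strand: str, chrom: str | None = None) -> CoverageTrack:
    """Read a single-chromosome bedGraph into a dense coverage track.

    Intervals must be 0-based half-open and non-overlapping; positions absent
    from the file get depth 0.  ``chrom`` selects a chromosome when the file
    contains several.
    """
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "depth"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "depth": np.float64},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "depth"])
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    elif df["chrom"].nunique() > 1:
        raise ValueError(
            f"bedGraph {path} covers multiple chromosomes; pass chrom= to select one"
        )
    if df.empty:
        return CoverageTrack(chrom or ".", strand, 0, np.zeros(0))
    if (df["depth"] < 0).any():
        raise ValueError(f"negative depth in bedGraph {path}")
    df = df.sort_values(["start", "end"], kind="mergesort").reset_index(drop=True)
    if (df["start"].values[1:] < df["end"].values[:-1]).any():
        raise ValueError(f"overlapping intervals in bedGraph {path}")
    lo = int(df["start"].iloc[0])
    hi = int(df["end"].iloc[-1])
    vals = np.zeros(hi - lo)
    for s, e, d in zip(df["start"], df["end"], df["depth"]):
        vals[s - lo : e - lo] = d
    return CoverageTrack(str(df["chrom"].iloc[0]), strand, lo, vals)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Run-length encode a track as bedGraph; zero-depth runs are omitted."""
    vals = track.values
    with open(path, "w") as fh:
        if vals.size == 0:
            return
        change = np.flatnonzero(np.diff(vals)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [vals.size]))
        for s, e in zip(starts, ends):
            d = vals[s]
            if d == 0:
                continue
            d_out = int(d) if float(d).is_integer() else float(d)
            fh.write(f"{track.chrom}\t{track.start + s}\t{track.start + e}\t{d_out}\n")


# ---------------------------------------------------------------------------
# BED6 isoform ends


def write_ends_bed(isoforms: Iterable[UtrIsoform], path: str | Path) -> None:
    """BED6 of single-nucleotide 3'-end positions; score encodes provenance."""
    with open(path, "w") as fh:
        for iso in isoforms:
            name = f"{iso.transcript_id}|{iso.utr_length}"
            fh.write(
                f"{iso.chrom}\t{iso.end}\t{iso.end + 1}\t{name}\t"
                f"{PROVENANCE_CODES[iso.provenance]}\t{iso.strand}\n"
            )


def read_ends_bed(path: str | Path) -> list[UtrIsoform]:
    isoforms: list[UtrIsoform] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, _end, name, score, strand = line.rstrip("\n").split("\t")
            tid, length = name.rsplit("|", 1)
            isoforms.append(
                UtrIsoform(
                    transcript_id=tid,
                    end=int(start),
                    utr_length=int(length),
                    provenance=_CODES_PROVENANCE[int(score)],
                    chrom=chrom,
                    strand=strand,
                )
            )
    return isoforms
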