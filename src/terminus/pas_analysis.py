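"""Poly(A)-signal hexamer scanning, enrichment, and atlas recovery.

The 3'-end-proximal sequence (-100..+50 nt around each annotated or novel
end) is scanned for the twelve canonical and non-canonical PAS hexamers; per
motif enrichment between two isoform classes uses Fisher's exact test with
BH correction, and novel ends are benchmarked against a reference poly(A)
site set by nearest same-strand distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .differential_apa import bh_fdr, fisher_exact_2x2
from .io_formats import UtrIsoform

__all__ = [
    "PAS_MOTIFS",
    "PasHit",
    "RecoveryCurve",
    "scan_pas_motifs",
    "pas_enrichment",
    "reference_recovery_curve",
]

#: Canonical (AATAAA, ATTAAA) and non-canonical PAS hexamers.
PAS_MOTIFS = (
    "AATACA",
    "ATTAAA",
    "TATAAA",
    "AATATA",
    "AATAGA",
    "AGTAAA",
    "AATGAA",
    "ACTAAA",
    "CATAAA",
    "GATAAA",
    "AAGAAA",
    "AATAAA",
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PasHit:
    transcript_id: str
    end: int
    motif: str
    offset: int  # motif start relative to the 3' end; negative = upstream


@dataclass
class RecoveryCurve:
    thresholds: list[int]
    fraction_recovered: list[float]

    def __post_init__(self) -> None:
        if any(b < a for a, b in zip(self.fraction_recovered, self.fraction_recovered[1:])):
            raise ValueError("recovery fraction must be non-decreasing with threshold")


class SequenceUnavailableError(KeyError):
    pass


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Plus-strand sequence over half-open [start, end); genome is a pyfaidx
    Fasta or any mapping of chromosome name -> string."""
    try:
        ref = genome[chrom]
    except KeyError as exc:
        raise SequenceUnavailableError(f"no sequence for contig {chrom!r}") from exc
    seq = ref[max(start, 0) : end]
    return str(seq).upper()


def scan_pas_motifs(
    genome,
    isoform: UtrIsoform,
    upstream: int = 100,
    downstream: int = 50,
    motifs: Sequence[str] = PAS_MOTIFS,
) -> list[PasHit]:
    """All exact PAS hexamer matches on the sense strand around a 3' end.

    The window spans ``upstream`` nt before through ``downstream`` nt after
    the end in transcript orientation (clipped at chromosome bounds);
    overlapping matches are all reported.  Offsets are motif start positions
    relative to the end (0 = the 3'-most base).
    """
    if isoform.strand == "+":
        lo = isoform.end - upstream
        hi = isoform.end + downstream + 1
        clip_left = max(0, -lo)
        seq = _fetch(genome, isoform.chrom, lo, hi)
        origin = -upstream + clip_left
    else:
        lo = isoform.end - downstream
        hi = isoform.end + upstream + 1
        seq = _fetch(genome, isoform.chrom, lo, hi)
        tail_clip = (hi - max(lo, 0)) - len(seq)
        seq = reverse_complement(seq)
        origin = -upstream + max(tail_clip, 0)
    hits: list[PasHit] = []
    for motif in motifs:
        start = seq.find(motif)
        while start != -1:
            hits.append(PasHit(isoform.transcript_id, isoform.end, motif, origin + start))
            start = seq.find(motif, start + 1)
    hits.sort(key=lambda h: (h.offset, h.motif))
    return hits


def pas_enrichment(
    hits_a: Iterable[PasHit],
    class_a: Sequence[UtrIsoform],
    hits_b: Iterable[PasHit],
    class_b: Sequence[UtrIsoform],
    motifs: Sequence[str] = PAS_MOTIFS,
) -> pd.DataFrame:
    """Per-motif enrichment between two disjoint isoform classes.

    The unit is the isoform (has at least one occurrence of the motif or
    not); each motif gets a 2x2 Fisher test and odds ratio (Haldane 0.5
    correction when any cell is zero), BH-corrected across the dictionary.
    """
    if not class_a or not class_b:
        raise ValueError("both isoform classes must be non-empty")
    keys_a = {(i.transcript_id, i.end) for i in class_a}
    keys_b = {(i.transcript_id, i.end) for i in class_b}
    if keys_a & keys_b:
        raise ValueError("isoform classes must be disjoint")

    def with_motif(hits: Iterable[PasHit], motif: str) -> set:
        return {(h.transcript_id, h.end) for h in hits if h.motif == motif}

    hits_a, hits_b = list(hits_a), list(hits_b)
    rows = []
    for motif in motifs:
        a1 = len(with_motif(hits_a, motif) & keys_a)
        a0 = len(keys_a) - a1
        b1 = len(with_motif(hits_b, motif) & keys_b)
        b0 = len(keys_b) - b1
        p = fisher_exact_2x2([[a1, a0], [b1, b0]])
        if 0 in (a1, a0, b1, b0):
            odds = ((a1 + 0.5) * (b0 + 0.5)) / ((a0 + 0.5) * (b1 + 0.5))
        else:
            odds = (a1 * b0) / (a0 * b1)
        rows.append(
            {
                "motif": motif,
                "n_with_a": a1,
                "n_without_a": a0,
                "n_with_b": b1,
                "n_without_b": b0,
                "odds_ratio": odds,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    return df


def reference_recovery_curve(
    novel_ends: Sequence[UtrIsoform],
    reference_ends: pd.DataFrame,
    thresholds: Sequence[int] = (10, 50, 100, 500),
) -> RecoveryCurve:
    """Fraction of novel ends within each distance of a reference poly(A) site.

    ``reference_ends`` is a BED-like frame with columns chrom/start/strand
    (single-nucleotide sites).  Distances are nearest same-strand,
    same-chromosome reference positions; duplicates in the reference do not
    change the curve.
    """
    if reference_ends.empty:
        raise ValueError("reference poly(A) site set is empty")
    ref_by_key: dict[tuple[str, str], np.ndarray] = {}
    for (chrom, strand), sub in reference_ends.groupby(["chrom", "strand"]):
        ref_by_key[(chrom, strand)] = np.sort(sub["start"].unique())
    dists = []
    for iso in novel_ends:
        ref = ref_by_key.get((iso.chrom, iso.strand))
        if ref is None or ref.size == 0:
            dists.append(np.inf)
            continue
        idx = np.searchsorted(ref, iso.end)
        best = np.inf
        if idx < ref.size:
            best = min(best, abs(int(ref[idx]) - iso.end))
        if idx > 0:
            best = min(best, abs(int(ref[idx - 1]) - iso.end))
        dists.append(best)
    d = np.asarray(dists)
    thresholds = sorted(int(t) for t in thresholds)
    fractions = [float((d <= t).mean()) for t in thresholds]
    return RecoveryCurve(thresholds, fractions)
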