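"""Differential proximal/distal poly(A)-site usage between compartments.

For every transcript with at least two called 3' UTR isoforms the outermost
called pair (most proximal, most distal) forms a tandem pair.  Usage shifts
between cell body (CB) and axon are scored by

    S1 = log2(I_prox / I_dist)_CB - log2(I_prox / I_dist)_axon
    S2 = (I_prox / (I_prox + I_dist))_CB - (I_prox / (I_prox + I_dist))_axon

with significance from Fisher's exact test on the summed raw counts and
Benjamini-Hochberg FDR control.  A proximal shift in axons requires
S1 <= -1, S2 <= -0.15 and FDR < 0.01; a distal shift mirrors the signs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .isoform_quant import ExpressionCall, IsoformCounts

__all__ = [
    "TandemPair",
    "TandemPairResult",
    "build_tandem_pairs",
    "compute_shift_scores",
    "fisher_exact_2x2",
    "bh_fdr",
    "classify_shift",
    "stringent_axon_subset",
    "score_tandem_pairs",
    "UndefinedScoreError",
]


class UndefinedScoreError(ValueError):
    """Raised when both counts of a compartment are zero (S2 undefined)."""


@dataclass
class TandemPair:
    """Proximal/distal isoform pair with per-compartment summed counts."""

    transcript_id: str
    proximal_end: int
    distal_end: int
    counts: dict[str, tuple[float, float]]  # compartment -> (I_prox, I_dist)

    def table(self) -> list[list[int]]:
        p_cb, d_cb = self.counts["cell_body"]
        p_ax, d_ax = self.counts["axon"]
        return [[round(p_cb), round(d_cb)], [round(p_ax), round(d_ax)]]


@dataclass
class TandemPairResult:
    pair: TandemPair
    s1: float
    s2: float
    p: float
    fdr: float = np.nan
    shift: str = "none"
    axon_extreme: bool = False


def build_tandem_pairs(
    counts: Sequence[IsoformCounts],
    calls: Sequence[ExpressionCall],
    samples_by_compartment: dict[str, list[str]],
) -> tuple[list[TandemPair], list[str]]:
    """Outermost called isoform pair per transcript, counts summed by compartment.

    An isoform enters the called set if it is called in either compartment
    (union rule); transcripts with fewer than two called isoforms are skipped
    and returned in the log list.
    """
    called_ends: dict[str, set[int]] = {}
    for call in calls:
        if call.called:
            called_ends.setdefault(call.transcript_id, set()).add(call.end)
    by_key = {(c.transcript_id, c.end): c for c in counts}
    pairs: list[TandemPair] = []
    skipped: list[str] = []
    for tid, ends in sorted(called_ends.items()):
        if len(ends) < 2:
            skipped.append(tid)
            continue
        # proximal = shortest UTR in transcript orientation
        ranked = sorted(ends, key=lambda e: by_key[(tid, e)].utr_length)
        prox, dist = ranked[0], ranked[-1]
        rec_a, rec_b = by_key[(tid, prox)], by_key[(tid, dist)]
        comp_counts = {}
        for comp, samples in samples_by_compartment.items():
            comp_counts[comp] = (
                sum(rec_a.counts[s] for s in samples),
                sum(rec_b.counts[s] for s in samples),
            )
        pairs.append(TandemPair(tid, prox, dist, comp_counts))
    return pairs, skipped


def compute_shift_scores(pair: TandemPair, pseudocount: float = 0.5) -> tuple[float, float]:
    """S1 (log2-ratio difference) and S2 (proximal-fraction difference), CB - axon.

    The pseudocount is added to all four counts for S1 only when any count is
    zero; S2 always uses raw fractions and is undefined when a compartment
    has no reads at all.
    """
    p_cb, d_cb = pair.counts["cell_body"]
    p_ax, d_ax = pair.counts["axon"]
    if (p_cb + d_cb) == 0 or (p_ax + d_ax) == 0:
        raise UndefinedScoreError(
            f"{pair.transcript_id}: both counts zero in one compartment"
        )
    raw = (p_cb, d_cb, p_ax, d_ax)
    a, b, c, d = (v + pseudocount for v in raw) if 0 in raw else raw
    s1 = float(np.log2(a / b) - np.log2(c / d))
    s2 = float(p_cb / (p_cb + d_cb) - p_ax / (p_ax + d_ax))
    return s1, s2


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p: total hypergeometric probability of all
    tables with fixed margins no more likely than the observed one."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return 1.0
    return float(fisher_exact(t, alternative="two-sided")[1])


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def classify_shift(
    s1: float,
    s2: float,
    fdr: float,
    s1_threshold: float = 1.0,
    s2_threshold: float = 0.15,
    fdr_threshold: float = 0.01,
) -> str:
    """Shift class: S1/S2 boundaries inclusive, FDR strictly below threshold."""
    if s1 <= -s1_threshold and s2 <= -s2_threshold and fdr < fdr_threshold:
        return "proximal_in_axon"
    if s1 >= s1_threshold and s2 >= s2_threshold and fdr < fdr_threshold:
        return "distal_in_axon"
    return "none"


def stringent_axon_subset(
    results: Sequence[TandemPairResult],
    low: float = 0.2,
    high: float = 0.8,
) -> list[TandemPairResult]:
    """Flag pairs whose cell-body usage is extreme (near-exclusive detection
    of the shifted isoform in axons): CB proximal fraction <= 0.2 for
    proximal shifts, >= 0.8 for distal shifts."""
    for res in results:
        p_cb, d_cb = res.pair.counts["cell_body"]
        frac = p_cb / (p_cb + d_cb) if (p_cb + d_cb) > 0 else np.nan
        res.axon_extreme = bool(
            (res.shift == "proximal_in_axon" and frac <= low)
            or (res.shift == "distal_in_axon" and frac >= high)
        )
    return list(results)


def score_tandem_pairs(
    pairs: Sequence[TandemPair],
    pseudocount: float = 0.5,
    s1_threshold: float = 1.0,
    s2_threshold: float = 0.15,
    fdr_threshold: float = 0.01,
    stringent_low: float = 0.2,
    stringent_high: float = 0.8,
) -> list[TandemPairResult]:
    """Score, test, FDR-adjust and classify every tandem pair in one batch."""
    results: list[TandemPairResult] = []
    for pair in pairs:
        s1, s2 = compute_shift_scores(pair, pseudocount)
        p = fisher_exact_2x2(pair.table())
        results.append(TandemPairResult(pair, s1, s2, p))
    fdrs = bh_fdr([r.p for r in results])
    for res, fdr in zip(results, fdrs):
        res.fdr = float(fdr)
        res.shift = classify_shift(
            res.s1, res.s2, res.fdr, s1_threshold, s2_threshold, fdr_threshold
        )
    return stringent_axon_subset(results, stringent_low, stringent_high)


def results_frame(results: Sequence[TandemPairResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        p_cb, d_cb = r.pair.counts["cell_body"]
        p_ax, d_ax = r.pair.counts["axon"]
        rows.append(
            {
                "transcript_id": r.pair.transcript_id,
                "prox_end": r.pair.proximal_end,
                "dist_end": r.pair.distal_end,
                "I_prox_CB": p_cb,
                "I_dist_CB": d_cb,
                "I_prox_ax": p_ax,
                "I_dist_ax": d_ax,
                "S1": r.s1,
                "S2": r.s2,
                "p": r.p,
                "fdr": r.fdr,
                "shift": r.shift,
                "axon_extreme": r.axon_extreme,
            }
        )
    return pd.DataFrame(rows)
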