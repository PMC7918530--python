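"""De novo 3' UTR end annotation from 3'-biased coverage.

The stage mirrors the two-step logic of 3'-end re-annotation: (1) find the
longest expressed 3' UTR per transcript from continuously covered regions,
then (2) locate alternative 3' ends inside it as change-points of a
piecewise-constant negative-binomial model of the (running-median smoothed)
coverage.  Four segmentation runs — {cell body, axon} x {raw, log2 scale} —
are merged by 50-nt single-linkage clustering of candidate ends, keeping the
most promoter-distal member of each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .io_formats import CoverageTrack, GenomicInterval, TranscriptModel, UtrIsoform

__all__ = [
    "ExpressedRegion",
    "SegmentationResult",
    "sliding_window_regions",
    "merge_regions",
    "assign_to_transcript",
    "extend_longest_utr",
    "running_median",
    "nb_segment",
    "merge_end_candidates",
    "annotate_ends",
]


@dataclass
class ExpressedRegion:
    """A maximal run of nucleotides that pass the sliding-window rule."""

    interval: GenomicInterval
    mean_depth: float
    assigned_transcript: str | None = None


@dataclass
class SegmentationResult:
    """Optimal piecewise-constant segmentation of one 3' UTR coverage signal."""

    utr_id: str
    scale: str  # "raw" (negative binomial) or "log2" (Gaussian)
    sample: str
    changepoints: list[int]  # 3' UTR coordinates (nt from the UTR start)
    k: int
    segment_means: list[float]
    loglik: float
    loglik_by_k: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.k != len(self.changepoints) + 1:
            raise ValueError("K must equal len(changepoints) + 1")
        if any(b <= a for a, b in zip(self.changepoints, self.changepoints[1:])):
            raise ValueError("changepoints must be strictly increasing")


# ---------------------------------------------------------------------------
# Expressed regions


def sliding_window_regions(
    track: CoverageTrack,
    window: int = 100,
    min_depth: float = 7,
    min_positions: int = 80,
) -> list[ExpressedRegion]:
    """Continuously transcribed regions from a sliding-window coverage rule.

    A nucleotide is expressed iff it lies in at least one length-``window``
    window that contains strictly more than ``min_positions`` positions of
    depth >= ``min_depth``; maximal runs of expressed nucleotides form the
    regions.  When the track is shorter than the window a single truncated
    window is evaluated.
    """
    values = track.values
    n = values.size
    if n == 0:
        return []
    qual = (values >= min_depth).astype(np.int64)
    covered = np.zeros(n + 1, dtype=np.int64)
    if n <= window:
        if int(qual.sum()) > min_positions:
            covered[0] += 1
            covered[n] -= 1
    else:
        csum = np.concatenate(([0], np.cumsum(qual)))
        wsums = csum[window:] - csum[:-window]  # window starting at s
        good = np.flatnonzero(wsums > min_positions)
        np.add.at(covered, good, 1)
        np.add.at(covered, good + window, -1)
    mask = np.cumsum(covered[:-1]) > 0
    regions: list[ExpressedRegion] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for s, e in zip(edges[::2], edges[1::2]):
        regions.append(
            ExpressedRegion(
                GenomicInterval(track.chrom, track.start + s, track.start + e, track.strand),
                float(values[s:e].mean()),
            )
        )
    return regions


def merge_regions(
    regions: Sequence[ExpressedRegion],
    max_gap: int,
    track: CoverageTrack | None = None,
) -> list[ExpressedRegion]:
    """Union neighbouring regions separated by gaps <= ``max_gap`` nt.

    The merged mean depth is recomputed over the union span, from ``track``
    when given, otherwise treating gap positions as zero.
    """
    if not regions:
        return []
    regions = sorted(regions, key=lambda r: r.interval.start)
    merged: list[ExpressedRegion] = []
    cur = regions[0]
    cur_sum = cur.mean_depth * len(cur.interval)
    for nxt in regions[1:]:
        gap = nxt.interval.start - cur.interval.end
        if gap <= max_gap:
            union = GenomicInterval(
                cur.interval.chrom,
                cur.interval.start,
                max(cur.interval.end, nxt.interval.end),
                cur.interval.strand,
            )
            if track is not None:
                mean = track.window_sum(union.start, union.end) / len(union)
                cur_sum = mean * len(union)
            else:
                cur_sum += nxt.mean_depth * len(nxt.interval)
                mean = cur_sum / len(union)
            cur = ExpressedRegion(union, mean)
        else:
            merged.append(cur)
            cur = nxt
            cur_sum = cur.mean_depth * len(cur.interval)
    merged.append(cur)
    return merged


def _utr_span(t: TranscriptModel) -> GenomicInterval:
    """Annotated 3' UTR hull (stop codon to the most distal annotated end)."""
    distal = t.distal_annotated_end
    if distal is None:
        distal = t.cds_end_3p
    if t.strand == "+":
        lo, hi = t.cds_end_3p, distal + 1
    else:
        lo, hi = distal, t.cds_end_3p + 1
    hi = max(hi, lo + 1)
    return GenomicInterval(t.interval.chrom, lo, hi, t.strand)


def assign_to_transcript(
    region: ExpressedRegion,
    transcripts: Sequence[TranscriptModel],
    max_dist: int = 10_000,
) -> str | None:
    """Assign an expressed region to a transcript's 3' UTR.

    A region overlapping an annotated 3' UTR on the same strand is assigned
    to it (largest overlap wins).  An isolated region is assigned to the
    closest upstream transcript's 3' UTR iff the downstream gap is below
    ``max_dist`` and no other annotated transcript lies in between.
    """
    iv = region.interval
    best_tid, best_ov = None, 0
    for t in transcripts:
        if t.strand != iv.strand or t.interval.chrom != iv.chrom:
            continue
        span = _utr_span(t)
        ov = min(iv.end, span.end) - max(iv.start, span.start)
        if ov > best_ov:
            best_tid, best_ov = t.transcript_id, ov
    if best_tid is not None:
        return best_tid

    # isolated region: the region must lie downstream (3') of the UTR end
    best_tid, best_gap = None, max_dist
    for t in transcripts:
        if t.strand != iv.strand or t.interval.chrom != iv.chrom:
            continue
        if t.strand == "+":
            gap = iv.start - t.interval.end
            lo, hi = t.interval.end, iv.start
        else:
            gap = t.interval.start - iv.end
            lo, hi = iv.end, t.interval.start
        if 0 <= gap < best_gap:
            between = GenomicInterval(iv.chrom, lo, hi, iv.strand) if hi > lo else None
            if between is not None and any(
                o.transcript_id != t.transcript_id
                and o.interval.chrom == iv.chrom
                and o.interval.overlaps(between)
                for o in transcripts
            ):
                continue
            best_tid, best_gap = t.transcript_id, gap
    return best_tid


def extend_longest_utr(
    transcript: TranscriptModel, assigned_regions: Sequence[ExpressedRegion]
) -> UtrIsoform | None:
    """Longest 3' end supported by expression: the 3'-most expressed base.

    Provenance is ``extended`` when expression continues beyond every
    annotated end, else ``ensembl``.  Returns None when no region is
    assigned (transcript unexpressed).
    """
    if not assigned_regions:
        return None
    if transcript.strand == "+":
        end = max(r.interval.end for r in assigned_regions) - 1
    else:
        end = min(r.interval.start for r in assigned_regions)
    distal = transcript.distal_annotated_end
    if distal is None:
        beyond = True
    elif transcript.strand == "+":
        beyond = end > distal
    else:
        beyond = end < distal
    length = transcript.utr_length_of(end)
    if length <= 0:
        return None
    return UtrIsoform(
        transcript_id=transcript.transcript_id,
        end=end,
        utr_length=length,
        provenance="extended" if beyond else "ensembl",
        chrom=transcript.interval.chrom,
        strand=transcript.strand,
    )


# ---------------------------------------------------------------------------
# Smoothing and segmentation


def running_median(values: np.ndarray, width: int = 150) -> np.ndarray:
    """Running median with symmetric truncation at the boundaries.

    Even widths are incremented to the next odd value.  At position i the
    window is values[i-h : i+h+1] with h = min(width//2, i, n-1-i).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        return x.copy()
    if width % 2 == 0:
        width += 1
    half = width // 2
    out = np.empty(n)
    if n >= width:
        from numpy.lib.stride_tricks import sliding_window_view

        out[half : n - half] = np.median(sliding_window_view(x, width), axis=1)
        edge = half
    else:
        edge = n  # every position is boundary-truncated
    for i in range(min(edge, n)):
        h = min(half, i, n - 1 - i)
        out[i] = np.median(x[i - h : i + h + 1])
    for i in range(max(n - edge, 0), n):
        h = min(half, i, n - 1 - i)
        out[i] = np.median(x[i - h : i + h + 1])
    return out


def estimate_nb_dispersion(values: np.ndarray, floor: float = 1e-3) -> float:
    """Method-of-moments NB dispersion (var = m + a*m^2) of a raw track.

    The within-segment variance is estimated from successive differences
    (half the squared difference of neighbouring positions), which is robust
    to the segment-mean changes the segmentation is meant to find; a global
    variance would count those changes as noise and flatten the likelihood.
    The estimate is the median of the per-pair moment ratio.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        return floor
    m = 0.5 * (x[1:] + x[:-1])
    v = 0.5 * np.diff(x) ** 2
    ok = m >= 1.0
    if not ok.any():
        return floor
    alpha = np.median((v[ok] - m[ok]) / m[ok] ** 2)
    return max(float(alpha), floor)


def estimate_log_sigma(raw_values: np.ndarray, floor: float = 0.05) -> float:
    """Robust noise scale of log2(depth+1), from successive differences."""
    x = np.log2(np.asarray(raw_values, dtype=float) + 1.0)
    if x.size < 2:
        return floor
    mad = np.median(np.abs(np.diff(x)))
    return max(1.4826 * mad / np.sqrt(2.0), floor)


def _nb_cost_matrix(x: np.ndarray, r: float) -> np.ndarray:
    """C[i, j] = max log-likelihood of x[i..j] as one NB segment (size r)."""
    n = x.size
    cs = np.concatenate(([0.0], np.cumsum(x)))
    g = gammaln(x + r) - gammaln(x + 1.0)
    cg = np.concatenate(([0.0], np.cumsum(g)))
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    L = (j - i + 1).astype(float)
    S = cs[j + 1] - cs[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        m = S / L
        C = (
            (cg[j + 1] - cg[i])
            - L * gammaln(r)
            + L * r * (np.log(r) - np.log(r + m))
            + np.where(S > 0, S * (np.log(m) - np.log(m + r)), 0.0)
        )
    C[j < i] = -np.inf
    return C


def _gauss_cost_matrix(x: np.ndarray, sigma: float) -> np.ndarray:
    """C[i, j] = log-likelihood of x[i..j] as one Gaussian segment (fixed sigma)."""
    n = x.size
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cq = np.concatenate(([0.0], np.cumsum(x * x)))
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    L = (j - i + 1).astype(float)
    S = cs[j + 1] - cs[i]
    Q = cq[j + 1] - cq[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = np.maximum(Q - S * S / L, 0.0)
    C = -0.5 * L * np.log(2.0 * np.pi * sigma**2) - rss / (2.0 * sigma**2)
    C[j < i] = -np.inf
    return C


def nb_segment(
    values: np.ndarray,
    k_max: int = 10,
    scale: str = "raw",
    penalty_alpha: float = 1.0,
    dispersion: float | None = None,
    sigma: float | None = None,
    utr_id: str = "",
    sample: str = "",
    max_dp_length: int = 3000,
) -> SegmentationResult:
    """Exact optimal piecewise-constant segmentation by dynamic programming.

    The raw scale models counts as negative binomial with a per-UTR
    method-of-moments dispersion; the log2 scale models log2-transformed
    coverage as Gaussian with a robust fixed noise scale (a negative binomial
    is undefined on non-integers).  For each K <= ``k_max`` the DP maximizes
    the segment log-likelihood exactly; the reported K minimizes the
    penalized criterion -2*logL(K) + penalty_alpha*(2K-1)*log(n).  Exact
    likelihood ties are broken toward the earliest (most 5') boundary.
    Signals longer than ``max_dp_length`` are decimated before the DP and
    change-points are mapped back.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("cannot segment an empty signal")
    if scale not in ("raw", "log2"):
        raise ValueError(f"unknown scale {scale!r}")

    step = 1
    if n > max_dp_length:
        step = int(np.ceil(n / max_dp_length))
        x = x[::step]
        n = x.size

    if scale == "raw":
        x = np.rint(np.maximum(x, 0.0))
        if dispersion is None:
            dispersion = estimate_nb_dispersion(x)
        C = _nb_cost_matrix(x, 1.0 / max(dispersion, 1e-3))
    else:
        if sigma is None:
            sigma = estimate_log_sigma(np.maximum(np.exp2(x) - 1.0, 0.0))
        C = _gauss_cost_matrix(x, max(sigma, 1e-3))

    k_max = max(1, min(k_max, n))
    D = np.full((k_max + 1, n), -np.inf)
    B = np.zeros((k_max + 1, n), dtype=np.int64)
    D[1] = C[0]
    for k in range(2, k_max + 1):
        # segment k starts at i in [k-1, n); previous segments end at i-1
        A = D[k - 1, :-1][:, None] + C[1:, :]
        D[k] = A.max(axis=0)
        B[k] = A.argmax(axis=0) + 1  # argmax is the first max: earliest boundary

    loglik_by_k = [float(D[k, n - 1]) for k in range(1, k_max + 1)]
    crit = [-2.0 * ll + penalty_alpha * (2 * k - 1) * np.log(n) for k, ll in enumerate(loglik_by_k, start=1)]
    finite = [k for k, c in enumerate(crit, start=1) if np.isfinite(c)]
    k_best = min(finite, key=lambda k: (crit[k - 1], k))

    bounds = []
    j = n - 1
    for k in range(k_best, 1, -1):
        i = int(B[k, j])
        bounds.append(i)
        j = i - 1
    bounds.reverse()

    starts = [0] + bounds
    ends = bounds + [n]
    means = [float(x[s:e].mean()) for s, e in zip(starts, ends)]
    return SegmentationResult(
        utr_id=utr_id,
        scale=scale,
        sample=sample,
        changepoints=[b * step for b in bounds],
        k=k_best,
        segment_means=means,
        loglik=loglik_by_k[k_best - 1],
        loglik_by_k=loglik_by_k,
    )


def drop_changepoints(
    result: SegmentationResult, min_fold: float = 1.0, min_upstream_mean: float = 7.0
) -> list[int]:
    """Change-points where the segment mean drops 5'->3' (candidate 3' ends).

    A read pile-up ends at an isoform's poly(A) site, so a mean decrease
    marks a candidate end; a mean increase marks the pile-up start about one
    read length upstream and is not an end.  The upstream segment must reach
    ``min_upstream_mean`` (the expressed-region depth floor, on the raw
    scale) so that steps inside the background or jitter tail do not spawn
    ends.
    """
    floor = min_upstream_mean
    if result.scale == "log2":
        floor = np.log2(min_upstream_mean + 1.0)
    out = []
    for cp, a, b in zip(result.changepoints, result.segment_means, result.segment_means[1:]):
        if b < a and a >= floor and a >= min_fold * max(b, 1e-12):
            out.append(cp)
    return out


# ---------------------------------------------------------------------------
# Merging candidate ends across runs


def merge_end_candidates(
    ends: Iterable[int],
    transcript: TranscriptModel,
    cluster_dist: int = 50,
) -> list[UtrIsoform]:
    """Single-linkage clustering of candidate 3' ends from the four runs.

    Ends within ``cluster_dist`` nt link into one cluster represented by its
    most promoter-distal member (genomically largest on +, smallest on -).
    A representative within ``cluster_dist`` of an annotated end snaps to it
    (provenance ``ensembl``); one beyond the most distal annotated end is
    ``extended``; anything else is ``novel``.  Output is sorted proximal to
    distal.
    """
    ends = sorted(set(int(e) for e in ends))
    if not ends:
        return []
    clusters: list[list[int]] = [[ends[0]]]
    for e in ends[1:]:
        if e - clusters[-1][-1] <= cluster_dist:
            clusters[-1].append(e)
        else:
            clusters.append([e])
    plus = transcript.strand == "+"
    distal_ann = transcript.distal_annotated_end
    isoforms: list[UtrIsoform] = []
    for cluster in clusters:
        rep = max(cluster) if plus else min(cluster)
        provenance = "novel"
        if transcript.annotated_ends:
            nearest = min(transcript.annotated_ends, key=lambda a: abs(a - rep))
            if abs(nearest - rep) <= cluster_dist:
                rep, provenance = nearest, "ensembl"
            elif (plus and rep > distal_ann) or (not plus and rep < distal_ann):
                provenance = "extended"
        length = transcript.utr_length_of(rep)
        if length <= 0:
            continue
        isoforms.append(
            UtrIsoform(
                transcript_id=transcript.transcript_id,
                end=rep,
                utr_length=length,
                provenance=provenance,
                chrom=transcript.interval.chrom,
                strand=transcript.strand,
            )
        )
    isoforms.sort(key=lambda i: i.utr_length)
    # snapping can collapse neighbouring clusters onto one annotated end
    seen: dict[int, UtrIsoform] = {}
    for iso in isoforms:
        seen[iso.end] = iso
    return sorted(seen.values(), key=lambda i: i.utr_length)


# ---------------------------------------------------------------------------
# Stage orchestration


def _overlaps_foreign_gene_body(
    region: ExpressedRegion, transcripts: Sequence[TranscriptModel], tid: str
) -> bool:
    """True if the region overlaps a non-3'-UTR part of another transcript."""
    iv = region.interval
    for t in transcripts:
        if t.transcript_id == tid or t.interval.chrom != iv.chrom:
            continue
        if not t.interval.overlaps(iv):
            continue
        span = _utr_span(t)
        # overlap confined to the other transcript's own 3' UTR is tolerated
        if iv.start >= span.start and iv.end <= span.end:
            continue
        return True
    return False


def annotate_ends(
    tracks_by_compartment: dict[str, CoverageTrack],
    transcripts: Sequence[TranscriptModel],
    window: int = 100,
    min_depth: float = 7,
    min_positions: int = 80,
    max_gap: int = 150,
    max_assign_dist: int = 10_000,
    smooth_width: int = 150,
    k_max: int = 10,
    penalty_alpha: float = 1.0,
    cluster_dist: int = 50,
    min_drop_fold: float = 1.0,
) -> tuple[list[UtrIsoform], dict]:
    """Run the full end-annotation stage on pooled per-compartment coverage.

    Returns the merged isoform set over all transcripts plus a per-transcript
    log of longest ends, per-run segment counts and change-points.
    """
    by_tid = {t.transcript_id: t for t in transcripts}
    assigned: dict[str, list[ExpressedRegion]] = {}
    for comp, track in tracks_by_compartment.items():
        regions = merge_regions(
            sliding_window_regions(track, window, min_depth, min_positions),
            max_gap,
            track,
        )
        for region in regions:
            tid = assign_to_transcript(region, transcripts, max_assign_dist)
            if tid is None:
                continue
            if _overlaps_foreign_gene_body(region, transcripts, tid):
                continue
            region.assigned_transcript = tid
            assigned.setdefault(tid, []).append(region)

    isoforms: list[UtrIsoform] = []
    log: dict[str, dict] = {}
    for tid, regions in sorted(assigned.items()):
        t = by_tid[tid]
        longest = extend_longest_utr(t, regions)
        if longest is None:
            continue
        if t.strand == "+":
            dom_lo, dom_hi = t.cds_end_3p, longest.end + 1
        else:
            dom_lo, dom_hi = longest.end, t.cds_end_3p + 1
        candidates: list[int] = [longest.end]
        tlog = {"longest_end": longest.end, "runs": {}}
        for comp, track in tracks_by_compartment.items():
            raw = track.slice(dom_lo, dom_hi)
            if t.strand == "-":
                raw = raw[::-1]
            if raw.size < 2:
                continue
            dispersion = estimate_nb_dispersion(raw)
            sigma = estimate_log_sigma(raw)
            smooth = running_median(raw, smooth_width)
            for scale in ("raw", "log2"):
                signal = smooth if scale == "raw" else np.log2(smooth + 1.0)
                seg = nb_segment(
                    signal,
                    k_max=k_max,
                    scale=scale,
                    penalty_alpha=penalty_alpha,
                    dispersion=dispersion,
                    sigma=sigma,
                    utr_id=tid,
                    sample=comp,
                )
                drops = drop_changepoints(seg, min_drop_fold, min_upstream_mean=min_depth)
                # UTR coordinate c: the new segment starts at c, so the end
                # base of the upstream pile-up is c-1 in UTR coordinates
                for cp in drops:
                    if t.strand == "+":
                        candidates.append(dom_lo + cp - 1)
                    else:
                        candidates.append(dom_hi - 1 - cp + 1)
                tlog["runs"][f"{comp}:{scale}"] = {
                    "k": seg.k,
                    "changepoints": seg.changepoints,
                }
        merged = merge_end_candidates(candidates, t, cluster_dist)
        isoforms.extend(merged)
        tlog["n_isoforms"] = len(merged)
        log[tid] = tlog
    return isoforms, log
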