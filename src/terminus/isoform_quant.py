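"""3' UTR isoform quantification and expression calling.

Each isoform is quantified by the reads falling in the terminal 500 nt of
its 3' UTR.  Across all isoforms of a sample the log10 read density is
bimodal — a low-density background population and an expressed population —
and a two-component Gaussian mixture fitted by EM separates the two.  An
isoform is called expressed when every replicate has < 5% posterior
probability of background, or at least one replicate has > 10% posterior
probability of being expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, spearmanr

from .io_formats import CoverageTrack, TranscriptModel, UtrIsoform, terminal_window_bounds

__all__ = [
    "IsoformCounts",
    "MixtureModel",
    "ExpressionCall",
    "terminal_counts",
    "log_density",
    "fit_two_component_gaussian",
    "posterior_background",
    "call_expressed",
    "metagene_end_profile",
    "replicate_correlation",
    "quantify_isoforms",
    "call_expression_table",
    "DegenerateMixtureError",
]


class DegenerateMixtureError(ValueError):
    """Raised when the density data cannot support a two-component fit.

    Callers should fall back to a fixed density threshold in this case.
    """


@dataclass
class IsoformCounts:
    """Terminal-window read counts of one isoform across samples."""

    transcript_id: str
    end: int
    counts: dict[str, float] = field(default_factory=dict)  # sample -> reads
    window: int = 500
    log_density: dict[str, float] = field(default_factory=dict)
    utr_length: int = 0
    strand: str = "+"


@dataclass
class MixtureModel:
    """Two-component 1-D Gaussian mixture; component 0 is background."""

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    loglik: float
    n_iter: int

    def __post_init__(self) -> None:
        if not self.means[0] < self.means[1]:
            raise ValueError("background mean must be below expressed mean")


@dataclass
class ExpressionCall:
    transcript_id: str
    end: int
    compartment: str
    p_background: list[float]  # one per replicate
    p_expressed: list[float]
    called: bool


def terminal_counts(
    track: CoverageTrack,
    isoform: UtrIsoform,
    window: int = 500,
    read_length: int = 150,
    floor_coord: int | None = None,
) -> float:
    """Reads in the terminal ``window`` nt of an isoform's 3' UTR.

    The per-nt depth over the window is summed and divided by the read
    length to convert coverage to a read count.  The window is truncated at
    ``floor_coord`` — the UTR start or the next-proximal isoform end,
    whichever is 3'-most (pass the corresponding genomic coordinate of the
    first admissible base).
    """
    lo, hi = terminal_window_bounds(isoform.end, window, isoform.strand)
    if floor_coord is not None:
        if isoform.strand == "+":
            lo = max(lo, floor_coord)
        else:
            hi = min(hi, floor_coord + 1)
    if hi <= lo:
        return 0.0
    return track.window_sum(lo, hi) / read_length


def log_density(
    count: float, window: int, library_size: float, pseudocount: float = 0.01
) -> float:
    """log10 of the library-size-normalised per-nt read density."""
    per_million = max(library_size, 1.0) / 1e6
    return float(np.log10(count / window / per_million + pseudocount))


def fit_two_component_gaussian(
    values: Sequence[float],
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MixtureModel:
    """Fit a two-component Gaussian mixture by EM with deterministic init.

    Means start at the 25th/75th percentiles with the pooled sd and equal
    weights; EM runs to |delta logL| < ``tol`` or ``max_iter`` iterations.
    Components are ordered so the background (low-density) mean comes first.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise DegenerateMixtureError(
            f"need >= 10 finite densities to fit the mixture, got {x.size}; "
            "fall back to a fixed density threshold"
        )
    if np.allclose(x, x[0]):
        raise DegenerateMixtureError(
            "all densities identical; fall back to a fixed density threshold"
        )
    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    if mu[0] == mu[1]:
        mu[1] = mu[0] + x.std() + 1e-6
    sd = np.full(2, max(x.std(), 1e-6))
    w = np.array([0.5, 0.5])
    prev_ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        comp = np.stack(
            [np.log(w[k]) + norm.logpdf(x, mu[k], sd[k]) for k in range(2)]
        )
        m = comp.max(axis=0)
        lse = m + np.log(np.exp(comp - m).sum(axis=0))
        ll = float(lse.sum())
        resp = np.exp(comp - lse)
        nk = resp.sum(axis=1)
        w = nk / x.size
        mu = (resp @ x) / nk
        sd = np.sqrt(np.maximum((resp @ (x**2)) / nk - mu**2, 1e-12))
        if abs(ll - prev_ll) < tol:
            prev_ll = ll
            break
        prev_ll = ll
    order = np.argsort(mu)
    return MixtureModel(
        means=tuple(mu[order]),
        sds=tuple(sd[order]),
        weights=tuple(w[order]),
        loglik=prev_ll,
        n_iter=n_iter,
    )


def posterior_background(model: MixtureModel, value: float) -> float:
    """Posterior probability that one density value is background."""
    lp = np.array(
        [
            np.log(model.weights[k]) + norm.logpdf(value, model.means[k], model.sds[k])
            for k in range(2)
        ]
    )
    m = lp.max()
    p = np.exp(lp - m)
    return float(p[0] / p.sum())


def call_expressed(
    p_background: Sequence[float],
    p_expressed: Sequence[float] | None = None,
    bg_threshold: float = 0.05,
    expr_threshold: float = 0.10,
    strict: bool = False,
) -> bool:
    """Expression call from per-replicate posteriors.

    Called iff the background posterior is < 5% in every replicate, or (non
    strict mode) the expressed posterior is > 10% in at least one replicate.
    """
    p_bg = list(p_background)
    if not p_bg:
        raise ValueError("need at least one replicate")
    if all(p < bg_threshold for p in p_bg):
        return True
    if strict:
        return False
    p_ex = [1.0 - p for p in p_bg] if p_expressed is None else list(p_expressed)
    return any(p > expr_threshold for p in p_ex)


def metagene_end_profile(
    tracks: Sequence[CoverageTrack],
    transcripts: Sequence[TranscriptModel],
    length_range: tuple[int, int] = (2000, 3000),
) -> pd.DataFrame:
    """Mean read density aligned at the 3' end over length-matched transcripts.

    Each transcript's per-nt coverage over its terminal ``length_range[0]``
    nt is normalised by its total reads, then averaged; the x axis is the
    distance from the 3' end (0 at the end, negative upstream).
    """
    lo_len, hi_len = length_range
    chosen = [t for t in transcripts if lo_len <= len(t.interval) <= hi_len]
    if not chosen:
        raise ValueError("no transcript in the requested length range")
    width = lo_len
    acc = np.zeros(width)
    n_used = 0
    for t in chosen:
        for track in tracks:
            if track.chrom != t.interval.chrom:
                continue
            end = t.interval.end if t.strand == "+" else t.interval.start
            if t.strand == "+":
                vals = track.slice(end - width, end)
            else:
                vals = track.slice(end, end + width)[::-1]
            total = vals.sum()
            if total > 0:
                acc += vals / total
                n_used += 1
    if n_used == 0:
        raise ValueError("no coverage over the selected transcripts")
    return pd.DataFrame(
        {"distance_from_end": np.arange(-width + 1, 1), "density": acc / n_used}
    )


def replicate_correlation(
    counts: Sequence[IsoformCounts], sample_a: str, sample_b: str
) -> float:
    """Spearman rank correlation of log densities between two samples."""
    xs, ys = [], []
    for c in counts:
        if sample_a in c.log_density and sample_b in c.log_density:
            xs.append(c.log_density[sample_a])
            ys.append(c.log_density[sample_b])
    if len(xs) < 3:
        raise ValueError("need at least 3 shared isoforms")
    rho = spearmanr(xs, ys).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# Stage orchestration


def quantify_isoforms(
    isoforms: Sequence[UtrIsoform],
    tracks: dict[str, CoverageTrack],
    window: int = 500,
    read_length: int = 150,
    pseudocount: float = 0.01,
) -> list[IsoformCounts]:
    """Terminal counts and log densities for every isoform in every sample.

    ``tracks`` maps sample labels (e.g. ``cell_body_rep0``) to coverage.
    Windows are truncated at the next-proximal isoform end of the same
    transcript.
    """
    by_tid: dict[str, list[UtrIsoform]] = {}
    for iso in isoforms:
        by_tid.setdefault(iso.transcript_id, []).append(iso)
    out: list[IsoformCounts] = []
    for tid, group in sorted(by_tid.items()):
        group = sorted(group, key=lambda i: i.utr_length)
        for idx, iso in enumerate(group):
            if idx == 0:
                floor = None
            elif iso.strand == "+":
                floor = group[idx - 1].end + 1
            else:
                floor = group[idx - 1].end - 1
            rec = IsoformCounts(
                tid, iso.end, window=window, utr_length=iso.utr_length, strand=iso.strand
            )
            for sample, track in tracks.items():
                rec.counts[sample] = terminal_counts(
                    track, iso, window, read_length, floor_coord=floor
                )
            out.append(rec)
    library_sizes = {
        sample: sum(rec.counts[sample] for rec in out) for sample in tracks
    }
    for rec in out:
        for sample, count in rec.counts.items():
            rec.log_density[sample] = log_density(
                count, window, library_sizes[sample], pseudocount
            )
    return out


def call_expression_table(
    counts: Sequence[IsoformCounts],
    samples_by_compartment: dict[str, list[str]],
    strict: bool = False,
) -> tuple[list[ExpressionCall], dict[str, MixtureModel]]:
    """Fit one mixture per compartment (pooled replicates) and call isoforms."""
    calls: list[ExpressionCall] = []
    models: dict[str, MixtureModel] = {}
    for comp, samples in samples_by_compartment.items():
        pooled = [rec.log_density[s] for rec in counts for s in samples]
        models[comp] = fit_two_component_gaussian(pooled)
        for rec in counts:
            p_bg = [posterior_background(models[comp], rec.log_density[s]) for s in samples]
            p_ex = [1.0 - p for p in p_bg]
            calls.append(
                ExpressionCall(
                    transcript_id=rec.transcript_id,
                    end=rec.end,
                    compartment=comp,
                    p_background=p_bg,
                    p_expressed=p_ex,
                    called=call_expressed(p_bg, p_ex, strict=strict),
                )
            )
    return calls, models
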