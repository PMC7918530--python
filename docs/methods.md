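# Methods

## Coverage model and what the generator emulates

3′-end RNA-seq with two rounds of linear amplification concentrates reads in
the last ~read length of each transcript. The generator reproduces exactly
that geometry: for each isoform of a locus it draws a read count, places
each read's 3′ terminus at the isoform end plus rounded Gaussian jitter
(default sd 10 nt, clipped inside the 3′ UTR), and covers the `read_length`
(default 150 nt, matching 2×150 bp sequencing) nucleotides ending there,
truncated at the UTR start. Per-nucleotide Poisson background (rate 0.2) is
added over the locus span. Reads are modelled single-end at the 3′ terminus:
only 3′-proximal coverage carries signal for this pipeline, so mate
placement would add cost without information.

Counts are negative binomial with dispersion 0.2 (var = μ + 0.2 μ²),
realized as a gamma–Poisson: one Gamma(1/α, α) factor per (locus,
replicate) scales the Poisson rate of every isoform. The marginal of each
isoform count is exactly NB(μ, α), while the isoform *ratio* within a
replicate stays binomial-stable. This is deliberate and matters: replicate
overdispersion in RNA-seq acts mostly at the library/transcript level, not
on a transcript's internal isoform proportions, and the Fisher count test
downstream is calibrated for conditionally binomial ratios. If the two
isoform counts were independent NB draws at α = 0.2, the test would be
grossly anticonservative (measured empirical FDR ≈ 0.5 at the printed
thresholds) and no counting test could work; with the shared factor the
null is super-uniform, which the test suite verifies on 2,000 null pairs.

What the generator does not emulate: mappability structure, multi-mapping,
amplification sequence bias, fragment-length variation, internal priming.
Passing tests therefore demonstrate correctness of the algorithms under the
stated noise model, not robustness to every artifact of real libraries.

Determinism: every stream derives from `SeedSequence(seed, spawn_key)` keyed
by a CRC of the transcript id, the compartment index and the replicate, so
a (seed, locus, compartment, replicate) tuple always yields the same track
regardless of how many other loci are simulated.

## End annotation

**Expressed regions.** A nucleotide is expressed iff it lies in some 100-nt
window containing strictly more than 80 positions of depth ≥ 7; maximal
runs form regions, and neighbouring regions with gaps ≤ 150 nt (one read
length; the merge distance is not otherwise constrained by the protocol)
are unioned. Regions are assigned to an overlapping same-strand annotated
3′ UTR, or — if isolated — to the closest upstream transcript when the gap
is < 10 kb and no other annotation intervenes. Regions overlapping the
non-UTR body of another gene are discarded as likely intragenic
transcription or retained introns. The 3′-most expressed coordinate defines
the transcript's longest 3′ UTR (provenance `extended` when it passes every
annotated end).

**Segmentation.** Within each longest 3′ UTR, coverage is smoothed with a
150-nt running median (width forced odd; windows truncate symmetrically at
the boundaries) and segmented by exact dynamic programming over
piecewise-constant models, for every K up to 10. Two likelihoods are run
per compartment: negative binomial on (rounded) raw coverage, and Gaussian
with fixed σ on log2(coverage + 1), since an NB is undefined on
non-integers. Model size is chosen by the penalized criterion

    crit(K) = −2 logL(K) + α (2K − 1) log n,   α = 1 by default,

a BIC-style count of one mean per segment plus K − 1 boundaries. The cited
segmentation literature uses an oracle penalty with unstated constants;
this deterministic criterion is the package's own choice and α is exposed.

Noise parameters are estimated from the *unsmoothed* track — estimating
from the smoothed signal collapses the noise scale and overfits K. The NB
dispersion is the median of the per-pair moment ratio ((d²/2 − m)/m²) over
successive-difference pairs with local mean ≥ 1, floored at 1e−3; the
Gaussian σ is 1.4826·MAD(Δ log2)/√2, floored at 0.05. Both are
successive-difference estimators because they must ignore the segment-mean
jumps the DP is supposed to find.

Numerical details: exact likelihood ties break toward the earliest (most
5′) boundary, making output deterministic; constant or all-zero input gives
K = 1; signals longer than 3,000 nt are decimated to bound the O(n²K) DP
and change-points are mapped back (UTRs in the synthetic studies are
shorter, so the DP there is exact).

**Candidate ends and merging.** A change-point is a candidate 3′ end only
when the segment mean *drops* 5′→3′ — a rise marks the start of a read
pile-up one read length upstream of an end, not an end — and only when the
upstream mean reaches the expressed-region floor (7 reads; log2(8) on the
log scale), so steps inside the background or the jitter tail do not spawn
ends. Candidates from the four runs plus the longest end are single-linkage
clustered at 50 nt; each cluster is represented by its most promoter-distal
member (genomically smallest coordinate on the − strand). A representative
within 50 nt of an annotated end snaps to it (`ensembl`); beyond the most
distal annotation it is `extended`; otherwise `novel`. The distal-member
rule gives novel ends a small distal bias (≲ cluster radius), visible in
the worked example (469 recovered vs 451 planted).

**Separability limit.** Two tandem ends closer than one read length are
distinguishable only if the coverage levels flanking the inner end differ:
with equal levels the sole evidence is an overlap plateau of width
(read_length − separation), which the 150-nt median erases when that width
is below half the smoothing window. The IMPA1 fixture therefore plants the
short isoforms at twice the long form's abundance (expected terminal reads
200/200/100) — consistent with the short form's dominance in the tissue —
making the 120-nt-spaced pair resolvable.

## Quantification and expression calls

Isoform expression is the summed per-nt depth over the terminal 500 nt of
the 3′ UTR divided by the read length; the window truncates at the UTR
start or the next-proximal isoform end. Densities are
log10(count / window / (library/10⁶) + 0.01); the pseudocount and scale are
configuration keys. Per compartment (replicates pooled) a two-component
Gaussian mixture is fitted by EM with deterministic initialization (means
at the 25th/75th percentiles, pooled sd, equal weights) to |ΔlogL| < 1e−8
or 1,000 iterations; the lower-mean component is background. Degenerate
input (< 10 finite values, or all equal) raises an error instructing a
fixed-threshold fallback rather than fitting nonsense.

The call rule is applied as printed: expressed iff background posterior
< 5% in *all* replicates, or expressed posterior > 10% in *any* replicate.
The second clause is much weaker than the first and admits almost anything
with non-negligible density; it may well have been intended as a
conjunction, but the disjunction is what the protocol states, so it is the
default and a `strict` flag applies clause 1 alone.

## Differential PAS usage

The tandem pair of a transcript is its most proximal and most distal
*called* isoform (union of compartments). Which pair constitutes "the"
tandem pair for ≥ 3 isoforms is not defined by the protocol; the outermost
pair maximizes the planted signal and skipped transcripts are logged so
adjacent-pair analyses can be compared. S1 adds a 0.5 pseudocount to all
four counts only when a zero is present; S2 uses raw fractions and is
undefined (error) when a compartment has no reads. Fisher's exact test
always uses raw integer counts summed over replicates; BH-FDR is computed
once over all tested pairs. Classification: S1/S2 boundaries inclusive,
FDR strictly below 0.01. Note the sign convention is S1 = cell body −
axon, so S1 ≤ −1 means *proximal* enrichment in axons.

## PAS scan, atlas recovery, cleavage histogram

The scan window is −100..+50 nt around the end in transcript orientation
(− strand features scanned on the reverse complement), exact matching of
the 12-hexamer dictionary, overlapping occurrences all reported.
Enrichment between two disjoint isoform classes counts isoforms (≥ 1
occurrence), one Fisher test per motif, BH across the 12, odds ratios with
Haldane 0.5 correction when a cell is zero. Atlas recovery is the fraction
of novel ends whose nearest same-strand reference site lies within each
threshold (10/50/100/500 nt by default); the reference is any user-supplied
BED — in the tests, the generator's truth table. Cleavage clones are binned
by signed offset from the predicted site in half-open 50-nt bins anchored
at the site ([k·50, (k+1)·50)); the sign is kept rather than folded since
the direction (upstream/downstream of the predicted site) is informative.

## Problem sizes in the checked studies

The test suite and acceptance script use: one IMPA1 locus (UTR 1,248 nt,
four samples, four segmentation runs) for end recovery; 200 two-isoform
transcripts with 40 planted shifts (expected |S1| = 3, terminal counts
~100 per replicate, 2 replicates) for recall/FDR; 1,000 random instances
(length ≤ 24, K ≤ 3) for DP-vs-enumeration; 1,000 random tables with
margins ≤ 30 for Fisher-vs-enumeration; 500 random tracks for the window
scan; 2,000 draws for mixture recovery and 2,000 null pairs for
calibration. These sizes give stable pass/fail behaviour at fixed seeds
while keeping the full suite under a minute of compute for the heavy parts.

## Known limitations

- Intronic and alternative-last-exon ends are out of scope; the only
  filtering of foreign transcription is the gene-body overlap discard.
- Terminal windows bleed: an unexpressed isoform's window picks up reads
  from a distal isoform when ends are closer than the read length, and from
  the proximal jitter tail. The expression caller absorbs this at realistic
  separations; quantification of ends < ~50 nt apart is unreliable.
- The segmentation penalty is not the oracle penalty of the cited
  segmentation method; K estimates can differ even where the optimal
  segmentations at each K agree (the DP itself is exact).
- Fisher's test presumes conditionally binomial ratio sampling; strong
  isoform-ratio overdispersion between replicates (not modelled by the
  generator's shared factor) would inflate discoveries.
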