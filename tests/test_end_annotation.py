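import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from terminus.end_annotation import (
    ExpressedRegion,
    assign_to_transcript,
    drop_changepoints,
    extend_longest_utr,
    merge_end_candidates,
    merge_regions,
    nb_segment,
    running_median,
    sliding_window_regions,
)
from terminus.io_formats import CoverageTrack, GenomicInterval, TranscriptModel


# ---------------------------------------------------------------------------
# oracles


def brute_force_regions(values, window, min_depth, min_positions):
    """Quadratic reference for the sliding-window rule."""
    n = len(values)
    mask = [False] * n
    if n <= window:
        if sum(v >= min_depth for v in values) > min_positions:
            mask = [True] * n
    else:
        for s in range(n - window + 1):
            if sum(v >= min_depth for v in values[s : s + window]) > min_positions:
                for i in range(s, s + window):
                    mask[i] = True
    runs, start = [], None
    for i, m in enumerate(mask + [False]):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    return runs


def nb_seg_loglik(x, r):
    """Log-likelihood of one NB segment at its fitted mean."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    if m == 0:
        return 0.0
    ll = (gammaln(x + r) - gammaln(r) - gammaln(x + 1)).sum()
    return float(ll + x.size * r * np.log(r / (r + m)) + x.sum() * np.log(m / (m + r)))


def exhaustive_best_loglik(x, k, r):
    """Enumerate all boundary placements for exactly k segments."""
    n = len(x)
    best = -np.inf
    for bounds in itertools.combinations(range(1, n), k - 1):
        edges = [0, *bounds, n]
        ll = sum(nb_seg_loglik(x[a:b], r) for a, b in zip(edges, edges[1:]))
        best = max(best, ll)
    return best


def _track(values, start=0):
    return CoverageTrack("chrT", "+", start, np.asarray(values, dtype=float))


def _transcript(tid="t", start=0, end=2000, strand="+", cds_end_3p=500, ends=(999,)):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=tid,
        interval=GenomicInterval("chrT", start, end, strand),
        cds_end_3p=cds_end_3p,
        annotated_ends=list(ends),
    )


# ---------------------------------------------------------------------------
# sliding windows


class TestSlidingWindowRegions:
    def test_all_zero_track(self):
        assert sliding_window_regions(_track(np.zeros(500))) == []

    def test_solid_span_detected_exactly(self):
        vals = np.zeros(1000)
        vals[200:500] = 10
        regions = sliding_window_regions(_track(vals))
        expected = brute_force_regions(vals, 100, 7, 80)
        assert [(r.interval.start, r.interval.end) for r in regions] == expected
        assert len(regions) == 1
        s, e = expected[0]
        assert s <= 200 and e >= 500  # covers the expressed span

    def test_exactly_80_positions_is_not_enough(self):
        vals = np.zeros(100)
        vals[:80] = 10  # exactly 80 qualifying positions: rule is strict >
        assert sliding_window_regions(_track(vals)) == []
        vals[80] = 10  # 81 qualifying
        assert len(sliding_window_regions(_track(vals))) == 1

    def test_short_track_single_window(self):
        vals = np.full(90, 10.0)
        regions = sliding_window_regions(_track(vals))
        assert [(r.interval.start, r.interval.end) for r in regions] == [(0, 90)]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 12), min_size=30, max_size=400), st.integers(0, 10_000))
    def test_matches_brute_force(self, values, seed):
        rng = np.random.default_rng(seed)
        vals = np.asarray(values, dtype=float)
        # salt with structured runs so regions actually appear
        if vals.size > 120:
            a = rng.integers(0, vals.size - 100)
            vals[a : a + 100] = 9
        got = sliding_window_regions(_track(vals), window=50, min_depth=7, min_positions=30)
        want = brute_force_regions(vals, 50, 7, 30)
        assert [(r.interval.start, r.interval.end) for r in got] == want


class TestMergeRegions:
    def _regions(self, spans, depth=10.0):
        return [
            ExpressedRegion(GenomicInterval("chrT", a, b, "+"), depth) for a, b in spans
        ]

    def test_gap_at_and_above_threshold(self):
        merged = merge_regions(self._regions([(0, 100), (110, 200)]), max_gap=150)
        assert len(merged) == 1
        not_merged = merge_regions(self._regions([(0, 100), (251, 300)]), max_gap=150)
        assert len(not_merged) == 2

    def test_boundary_gap_equal_max_gap_merges(self):
        merged = merge_regions(self._regions([(0, 100), (250, 300)]), max_gap=150)
        assert len(merged) == 1

    def test_idempotent(self):
        regions = self._regions([(0, 100), (120, 200), (600, 700)])
        once = merge_regions(regions, max_gap=150)
        twice = merge_regions(once, max_gap=150)
        assert [(r.interval.start, r.interval.end) for r in once] == [
            (r.interval.start, r.interval.end) for r in twice
        ]

    def test_mean_recomputed_over_union_from_track(self):
        vals = np.zeros(300)
        vals[0:100] = 10
        vals[200:300] = 30
        track = _track(vals)
        (merged,) = merge_regions(self._regions([(0, 100), (200, 300)]), 150, track)
        assert merged.mean_depth == pytest.approx((1000 + 3000) / 300)


class TestAssignToTranscript:
    def test_overlapping_utr_wins(self):
        t = _transcript()
        region = ExpressedRegion(GenomicInterval("chrT", 600, 900, "+"), 10.0)
        assert assign_to_transcript(region, [t]) == "t"

    def test_isolated_region_beyond_10kb_unassigned(self):
        t = _transcript(end=1000)
        region = ExpressedRegion(GenomicInterval("chrT", 13_000, 13_500, "+"), 10.0)
        assert assign_to_transcript(region, [t]) is None

    def test_isolated_region_within_10kb_assigned(self):
        t = _transcript(end=1000)
        region = ExpressedRegion(GenomicInterval("chrT", 6_000, 6_500, "+"), 10.0)
        assert assign_to_transcript(region, [t]) == "t"

    def test_intervening_annotation_blocks_assignment(self):
        # the region is 5 kb past t but another gene sits in between, and it
        # is itself more than 10 kb upstream of the region
        t = _transcript(end=1000)
        other = _transcript(tid="other", start=2000, end=3000, cds_end_3p=2500, ends=(2999,))
        region = ExpressedRegion(GenomicInterval("chrT", 13_500, 14_000, "+"), 10.0)
        assert assign_to_transcript(region, [t, other]) is None
        # without the intervening gene, t itself is still too far (>10 kb)
        near = ExpressedRegion(GenomicInterval("chrT", 6_000, 6_500, "+"), 10.0)
        assert assign_to_transcript(near, [t, other]) == "other"

    def test_strand_must_match(self):
        t = _transcript()
        region = ExpressedRegion(GenomicInterval("chrT", 600, 900, "-"), 10.0)
        assert assign_to_transcript(region, [t]) is None


class TestExtendLongestUtr:
    def test_no_regions_reports_unexpressed(self):
        assert extend_longest_utr(_transcript(), []) is None

    def test_expression_to_annotated_end_is_ensembl(self):
        t = _transcript(ends=(999,))
        region = ExpressedRegion(GenomicInterval("chrT", 600, 1000, "+"), 10.0)
        iso = extend_longest_utr(t, [region])
        assert iso.end == 999 and iso.provenance == "ensembl"

    def test_extension_beyond_annotation(self):
        t = _transcript(ends=(999,))
        region = ExpressedRegion(GenomicInterval("chrT", 600, 1500, "+"), 10.0)
        iso = extend_longest_utr(t, [region])
        assert iso.end == 1499 and iso.provenance == "extended"
        assert iso.utr_length == 1000

    def test_minus_strand_extension_decreases_coordinate(self):
        t = _transcript(strand="-", cds_end_3p=1500, ends=(1000,))
        region = ExpressedRegion(GenomicInterval("chrT", 400, 1501, "-"), 10.0)
        iso = extend_longest_utr(t, [region])
        assert iso.end == 400 and iso.provenance == "extended"
        assert iso.utr_length == 1101


class TestRunningMedian:
    def test_constant_input_unchanged(self):
        x = np.full(400, 7.0)
        assert running_median(x, 150).tolist() == x.tolist()

    def test_single_spike_suppressed(self):
        x = np.zeros(400)
        x[200] = 100
        assert running_median(x, 150).tolist() == [0.0] * 400

    def test_short_input_truncated_windows(self):
        x = np.array([1.0, 5.0, 9.0])
        out = running_median(x, 150)
        assert out.tolist() == [1.0, 5.0, 9.0]  # h = min(i, n-1-i)

    def test_even_width_promoted_to_odd(self):
        x = np.arange(20.0)
        assert running_median(x, 4).tolist() == running_median(x, 5).tolist()

    def test_empty_input(self):
        assert running_median(np.array([]), 150).size == 0


# ---------------------------------------------------------------------------
# segmentation


class TestNbSegment:
    def test_constant_coverage_one_segment(self):
        res = nb_segment(np.full(400, 20.0))
        assert res.k == 1 and res.changepoints == []

    def test_all_zero_one_segment(self):
        res = nb_segment(np.zeros(100))
        assert res.k == 1

    def test_two_level_nb_changepoint_within_15nt(self):
        r = 1.0 / 0.2
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = np.concatenate(
                [
                    rng.negative_binomial(r, r / (r + 50.0), size=500),
                    rng.negative_binomial(r, r / (r + 5.0), size=500),
                ]
            ).astype(float)
            res = nb_segment(x, dispersion=0.2)
            if any(abs(cp - 500) <= 15 for cp in res.changepoints):
                hits += 1
        assert hits == 5

    def test_dp_equals_exhaustive_enumeration_small(self):
        import itertools as it

        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(6, 20))
            x = rng.poisson(rng.uniform(1, 30), size=n).astype(float)
            disp = 0.25
            res = nb_segment(x, k_max=3, dispersion=disp)
            r = 1.0 / disp
            for k in (1, 2, 3):
                if k > n:
                    continue
                want = exhaustive_best_loglik(x, k, r)
                assert res.loglik_by_k[k - 1] == pytest.approx(want, abs=1e-8)

    def test_loglik_nondecreasing_in_k(self):
        rng = np.random.default_rng(3)
        x = rng.poisson(20, size=300).astype(float)
        res = nb_segment(x, k_max=6, dispersion=0.2)
        ll = res.loglik_by_k
        assert all(b >= a - 1e-9 for a, b in zip(ll, ll[1:]))

    def test_true_k_recovered_with_separated_means(self):
        # means ratio >= 5, segments >= 100 nt: the penalty should find K=3
        r = 1.0 / 0.1
        good = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            x = np.concatenate(
                [
                    rng.negative_binomial(r, r / (r + 100.0), size=150),
                    rng.negative_binomial(r, r / (r + 20.0), size=150),
                    rng.negative_binomial(r, r / (r + 4.0), size=150),
                ]
            ).astype(float)
            res = nb_segment(x, dispersion=0.1)
            good += res.k == 3
        assert good >= 9

    def test_log2_scale_on_gaussian_steps(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(8, 0.3, 300), rng.normal(2, 0.3, 300)])
        res = nb_segment(x, scale="log2", sigma=0.3)
        assert res.k == 2
        assert abs(res.changepoints[0] - 300) <= 5

    def test_long_signal_decimated_changepoints_mapped_back(self):
        x = np.concatenate([np.full(4000, 50.0), np.full(4000, 5.0)])
        res = nb_segment(x, dispersion=0.2, max_dp_length=2000)
        assert len(res.changepoints) == 1
        assert abs(res.changepoints[0] - 4000) <= 8


class TestDropChangepoints:
    def _result(self, cps, means):
        from terminus.end_annotation import SegmentationResult

        return SegmentationResult("u", "raw", "s", cps, len(cps) + 1, means, 0.0)

    def test_only_drops_are_candidates(self):
        res = self._result([100, 250], [10.0, 300.0, 20.0])
        assert drop_changepoints(res) == [250]

    def test_background_level_drops_excluded(self):
        res = self._result([100], [3.0, 0.2])
        assert drop_changepoints(res, min_upstream_mean=7.0) == []


class TestMergeEndCandidates:
    def test_single_linkage_hand_example(self):
        # transcript-orientation offsets 100/130/220 from a UTR at 1000
        t = _transcript(cds_end_3p=1000, ends=(1700,), end=2000)
        isoforms = merge_end_candidates([1100, 1130, 1220], t, cluster_dist=50)
        assert [i.end for i in isoforms] == [1130, 1220]  # most distal per cluster
        assert all(i.provenance == "novel" for i in isoforms)

    def test_single_end_is_itself(self):
        t = _transcript(cds_end_3p=1000, ends=(1700,), end=2000)
        (iso,) = merge_end_candidates([1300], t)
        assert iso.end == 1300

    def test_snap_to_annotated_end_within_50(self):
        t = _transcript(cds_end_3p=1000, ends=(1700,), end=2000)
        (iso,) = merge_end_candidates([1680], t)
        assert iso.end == 1700 and iso.provenance == "ensembl"

    def test_beyond_distal_annotation_is_extended(self):
        t = _transcript(cds_end_3p=1000, ends=(1400,), end=2000)
        isoforms = merge_end_candidates([1800], t)
        assert isoforms[0].provenance == "extended"

    def test_minus_strand_promoter_distal_is_genomically_smallest(self):
        t = _transcript(strand="-", cds_end_3p=1900, ends=(1000,), start=500, end=2000)
        (iso,) = merge_end_candidates([1205, 1230], t)
        assert iso.end == 1205

    def test_cluster_invariants(self):
        rng = np.random.default_rng(11)
        t = _transcript(cds_end_3p=1000, ends=(5000,), end=6000)
        ends = sorted(rng.integers(1100, 4000, size=40).tolist())
        isoforms = merge_end_candidates(ends, t, cluster_dist=50)
        assert len(isoforms) <= len(set(ends))
        # every input end is within cluster_dist * (cluster span) of a representative
        reps = [i.end for i in isoforms]
        for e in ends:
            assert min(abs(e - rp) for rp in reps) <= 50 * len(ends)


def test_impa1_end_to_end_recovery(impa1_annotation):
    """All three planted IMPA1 ends are recovered within 50 nt."""
    isoforms, _log = impa1_annotation
    lengths = sorted(i.utr_length for i in isoforms)
    assert len(lengths) == 3
    for got, want in zip(lengths, (451, 1128, 1248)):
        assert abs(got - want) <= 50
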