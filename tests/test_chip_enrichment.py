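import numpy as np
import pytest

from parspipe.chip_enrichment import (
    CoverageTrack, EnrichmentProfile,
    annotate_peaks, call_peaks, coverage_from_reads, enrichment, smooth,
    spreading_extent,
)
from parspipe.motif_scan import MotifHit
from parspipe.synthetic_data import (
    SpreadingModel, SpreadingSite, expected_fold_profile, gen_chip_reads, gen_genome,
)


def oracle_coverage(intervals, L):
    counts = np.zeros(L)
    for s, e in intervals:
        for i in range(s, e):
            counts[i % L] += 1
    return counts


def oracle_smooth(counts, window):
    if window % 2 == 0:
        window += 1
    half = window // 2
    L = len(counts)
    out = np.empty(L)
    for i in range(L):
        out[i] = np.mean([counts[(i + d) % L] for d in range(-half, half + 1)])
    return out


def oracle_peaks(fold, threshold, min_width=1, merge_gap=0):
    """Scan-and-merge over the linearized profile with circular closure."""
    L = len(fold)
    above = [f >= threshold for f in fold]
    runs, start = [], None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, L))
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == L:
        s, _ = runs.pop()
        _, e = runs.pop(0)
        runs.append((s, L + e))
    if merge_gap > 0:
        merged = []
        for s, e in sorted(runs):
            if merged and s - merged[-1][1] < merge_gap:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        if len(merged) > 1 and (merged[0][0] + L) - merged[-1][1] < merge_gap:
            s, _ = merged.pop()
            _, e = merged.pop(0)
            merged.append((s, L + e))
        runs = merged
    return sorted((s, e) for s, e in runs if e - s >= min_width)


class TestCoverage:
    def test_single_read_mass(self):
        t = coverage_from_reads([(10, 60)], 100)
        assert t.counts.sum() == 50 and t.total_reads == 1
        assert t.counts[10] == 1 and t.counts[59] == 1 and t.counts[60] == 0

    def test_linearity_in_duplicate_reads(self):
        one = coverage_from_reads([(10, 60)], 100)
        two = coverage_from_reads([(10, 60), (10, 60)], 100)
        assert np.array_equal(two.counts, 2 * one.counts)

    def test_circular_wrap(self):
        t = coverage_from_reads([(95, 105)], 100)
        assert t.counts[95:].sum() == 5 and t.counts[:5].sum() == 5

    def test_matches_per_base_overlap_loop(self, rng):
        L = 10_000
        starts = rng.integers(0, L, size=1000)
        lengths = rng.integers(1, 300, size=1000)
        intervals = np.column_stack([starts, starts + lengths])
        got = coverage_from_reads(intervals, L).counts
        assert np.array_equal(got, oracle_coverage(intervals.tolist(), L))

    def test_five_prime_extension(self):
        t = coverage_from_reads([(100, 1), (300, -1)], 1000, fragment_length=50)
        assert t.counts[100:150].sum() == 50    # + read extends rightward
        assert t.counts[251:301].sum() == 50    # - read extends leftward

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            coverage_from_reads([], 100)


class TestSmooth:
    def test_constant_track_unchanged(self):
        t = CoverageTrack(np.full(500, 3.0), total_reads=10)
        assert np.allclose(smooth(t, 99).counts, 3.0)

    def test_unit_impulse_closed_form(self):
        counts = np.zeros(100)
        counts[50] = 1.0
        sm = smooth(CoverageTrack(counts, 1), 5).counts
        assert np.allclose(sm[48:53], 0.2)
        assert np.allclose(sm[:48], 0) and np.allclose(sm[53:], 0)

    def test_mass_conserved_and_not_idempotent(self, rng):
        counts = np.zeros(1000)
        counts[123] = 7.0
        t = CoverageTrack(counts, 7)
        once = smooth(t, 201)
        assert np.isclose(once.counts.sum(), 7.0)
        twice = smooth(once, 201)
        assert not np.allclose(once.counts, twice.counts)

    def test_matches_naive_windowed_mean(self, rng):
        counts = rng.poisson(5, size=777).astype(float)
        got = smooth(CoverageTrack(counts, 100), 201).counts
        assert np.allclose(got, oracle_smooth(counts, 201))

    def test_even_window_bumped_to_odd(self, rng):
        counts = rng.poisson(5, size=300).astype(float)
        assert np.allclose(smooth(CoverageTrack(counts, 1), 200).counts,
                           smooth(CoverageTrack(counts, 1), 201).counts)

    def test_window_longer_than_track_rejected(self):
        with pytest.raises(ValueError):
            smooth(CoverageTrack(np.ones(10), 1), 11)


class TestEnrichment:
    def test_identical_tracks_give_unit_fold(self, rng):
        counts = rng.poisson(20, size=1000).astype(float)
        ip = CoverageTrack(counts, 100, "IP")
        inp = CoverageTrack(counts.copy(), 100, "IN")
        assert np.allclose(enrichment(ip, inp).fold, 1.0)

    def test_depth_invariance(self, rng):
        counts = rng.poisson(20, size=1000).astype(float) + 1
        ip = CoverageTrack(counts, 100, "IP")
        inp = CoverageTrack(rng.poisson(20, size=1000).astype(float) + 1, 200, "IN")
        base = enrichment(ip, inp, pseudocount=0.0).fold
        scaled = enrichment(CoverageTrack(counts * 3, 300, "IP"), inp,
                            pseudocount=0.0).fold
        assert np.allclose(base, scaled)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            enrichment(CoverageTrack(np.ones(10), 1), CoverageTrack(np.ones(11), 1))

    def test_fold_finite_at_zero_input_bases(self):
        ip = CoverageTrack(np.ones(600), 10, "IP")
        inp = CoverageTrack(np.zeros(600), 10, "IN")
        fold = enrichment(ip, inp).fold
        assert np.all(np.isfinite(fold))


class TestPeaks:
    def test_flat_profile_no_peaks(self):
        p = EnrichmentProfile(np.ones(1000))
        assert call_peaks(p, 10) == []

    def test_step_profile_exact_boundaries(self):
        fold = np.ones(5000)
        fold[1000:3000] = 12.0
        peaks = call_peaks(EnrichmentProfile(fold), 10)
        assert [(p.start, p.end) for p in peaks] == [(1000, 3000)]
        assert peaks[0].max_fold == 12.0

    def test_matches_oracle_on_random_profiles(self, rng):
        for _ in range(200):
            L = int(rng.integers(20, 300))
            fold = rng.choice([0.5, 5.0, 20.0], size=L, p=[0.5, 0.3, 0.2])
            threshold = float(rng.choice([2.0, 10.0]))
            min_w = int(rng.integers(1, 4))
            gap = int(rng.integers(0, 4))
            peaks = call_peaks(EnrichmentProfile(fold), threshold,
                               min_width_bp=min_w, merge_gap_bp=gap)
            got = sorted((p.start, p.end) for p in peaks)
            assert got == oracle_peaks(fold, threshold, min_w, gap)

    def test_origin_crossing_run_reported_once(self):
        fold = np.ones(1000)
        fold[:100] = 15.0
        fold[900:] = 15.0
        peaks = call_peaks(EnrichmentProfile(fold), 10)
        assert len(peaks) == 1
        assert (peaks[0].start, peaks[0].end) == (900, 1100)


class TestSpreadingExtent:
    def test_anchor_inside_step_reports_step_width(self):
        fold = np.ones(5000)
        fold[1000:3000] = 12.0
        res = spreading_extent(EnrichmentProfile(fold), [2000], 10)
        assert res[0].width_bp == 2000

    def test_subthreshold_anchor_warns_width_zero(self):
        fold = np.ones(5000)
        fold[1000:3000] = 12.0
        with pytest.warns(UserWarning):
            res = spreading_extent(EnrichmentProfile(fold), [500], 10)
        assert res[0].width_bp == 0

    def test_anchors_sharing_region_report_same_width(self):
        fold = np.ones(5000)
        fold[1000:3000] = 12.0
        res = spreading_extent(EnrichmentProfile(fold), [1500, 2500], 10)
        assert res[0].region == res[1].region and res[0].width_bp == res[1].width_bp

    def test_width_monotone_in_decay_scale(self):
        # a lower threshold keeps the run visible even at large decay
        # scales, where normalization depresses the absolute fold
        genome, _ = gen_genome(200_000, seed=3)
        widths = []
        for lam in (1000, 2000, 5000, 10_000):
            model = SpreadingModel(sites=[SpreadingSite(100_000, 30.0, lam)])
            ip, inp = gen_chip_reads(genome, model, 50_000, 100_000, seed=4)
            prof = enrichment(coverage_from_reads(ip, len(genome), label="IP"),
                              coverage_from_reads(inp, len(genome), label="IN"))
            res = spreading_extent(prof, [100_000], 3.0)
            widths.append(res[0].width_bp)
        assert widths == sorted(widths) and widths[0] > 0


class TestAnnotate:
    def _peak(self, start, end):
        from parspipe.chip_enrichment import Peak
        return Peak(start=start, end=end, max_fold=20.0, mean_fold=15.0)

    def test_hit_inside_peak_flags_pars(self):
        hit = MotifHit(2000, 2016, "+", 0, "A" * 16, 2000)
        peaks = annotate_peaks([self._peak(1000, 3000)], [hit])
        assert peaks[0].contains_parS and peaks[0].classification == "spreading"

    def test_narrow_peak_without_hit_is_point(self):
        peaks = annotate_peaks([self._peak(1000, 1300)], [])
        assert not peaks[0].contains_parS and peaks[0].classification == "point"

    def test_wrapped_peak_overlap(self):
        hit = MotifHit(10, 26, "+", 0, "A" * 16, 10)
        peaks = annotate_peaks([self._peak(990, 1030)], [hit], genome_length=1000)
        assert peaks[0].contains_parS


class TestEndToEndRecovery:
    def test_planted_sites_recovered_and_classified(self):
        """2 spreading + 2 point anchors on 600 kb; all recovered, labels right."""
        L = 600_000
        genome, _ = gen_genome(L, seed=21)
        spread_pos = [150_000, 450_000]
        point_pos = [300_000, 500_000]
        sites = [SpreadingSite(p, 30.0, 4000.0) for p in spread_pos] + \
                [SpreadingSite(p, 60.0, 250.0) for p in point_pos]
        model = SpreadingModel(sites=sites, fragment_length=500)
        ip, inp = gen_chip_reads(genome, model, 100_000, 400_000, seed=22)
        prof = enrichment(coverage_from_reads(ip, L, label="IP"),
                          coverage_from_reads(inp, L, label="IN"))
        peaks = call_peaks(prof, 10.0, genome=genome)
        hits = [MotifHit(p, p + 16, "+", 0, "N" * 16, p) for p in spread_pos]
        annotate_peaks(peaks, hits, genome_length=L)

        def peak_at(pos):
            for p in peaks:
                if p.start <= pos < p.end or (p.end > L and pos < p.end - L):
                    return p
            return None

        for pos in spread_pos:
            pk = peak_at(pos)
            assert pk is not None and pk.classification == "spreading" and pk.contains_parS
        for pos in point_pos:
            pk = peak_at(pos)
            assert pk is not None and pk.classification == "point" and not pk.contains_parS

        # fold at each anchor within 3 SE of the closed-form expectation
        exp = expected_fold_profile(L, model)
        ip_cov = coverage_from_reads(ip, L, label="IP")
        in_cov = coverage_from_reads(inp, L, label="IN")
        for pos in spread_pos + point_pos:
            se_rel = np.sqrt(1.0 / max(ip_cov.counts[pos], 1.0)
                             + 1.0 / max(in_cov.counts[pos], 1.0))
            assert abs(prof.fold[pos] - exp[pos]) <= 3 * se_rel * exp[pos]

    def test_spreading_width_tracks_planted_truth(self):
        """At deep coverage the measured super-threshold width around each
        anchor matches the width of the expected-fold profile to within
        twice the smoothing window."""
        L = 500_000
        genome, _ = gen_genome(L, seed=31)
        anchors = [120_000, 370_000]
        model = SpreadingModel(sites=[SpreadingSite(p, 30.0, 4000.0) for p in anchors],
                               fragment_length=500)
        ip, inp = gen_chip_reads(genome, model, 1_000_000, 2_000_000, seed=32)
        prof = enrichment(coverage_from_reads(ip, L, label="IP"),
                          coverage_from_reads(inp, L, label="IN"))
        exp = expected_fold_profile(L, model)

        def truth_width(p):
            above = exp >= 10.0
            l = r = p
            while above[l - 1]:
                l -= 1
            while above[(r + 1) % L]:
                r += 1
            return r - l + 1

        for res in spreading_extent(prof, anchors, 10.0):
            assert abs(res.width_bp - truth_width(res.anchor)) <= 2 * prof.window_bp
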