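"""Binning, smoothing, aggregation, correlation and region classification."""

import numpy as np
import pytest

from ccseq import (
    BreakMap,
    Locus,
    NormalizedTrack,
    aggregate,
    autocorrelate,
    bin_positions,
    call_peaks,
    classify_igrs,
    density_smooth,
    hann_smooth,
    hann_window,
    quantify_vs_covariate,
    region_density,
    strand_cross_correlation,
    stratify,
)
from ccseq.breakmap import WATSON, CRICK


def track_from(watson=None, crick=None, contig="chr1"):
    t = NormalizedTrack(total_mapped_pairs=1_000_000)
    if watson:
        t.values[(contig, WATSON)] = dict(watson)
    if crick:
        t.values[(contig, CRICK)] = dict(crick)
    return t


class TestBinning:
    def test_bin_assignment_convention(self):
        # 1-based position p maps to bin floor((p-1)/width)
        assert bin_positions({49: 1.0}, 50)[0] == 1.0
        out = bin_positions({50: 1.0, 51: 2.0}, 50)
        assert out[0] == 1.0 and out[1] == 2.0

    def test_conserves_total(self):
        rng = np.random.default_rng(2)
        vals = {int(p) + 1: float(v) for p, v in zip(rng.choice(5000, 300, replace=False), rng.random(300))}
        assert bin_positions(vals, 37).sum() == pytest.approx(sum(vals.values()))

    def test_empty_is_all_zero(self):
        assert np.all(bin_positions({}, 10) == 0)


class TestHannSmoothing:
    def test_window_one_is_identity(self):
        x = np.array([1.0, 5.0, 2.0])
        assert np.allclose(hann_smooth(x, 1), x)

    def test_constant_input_unchanged(self):
        x = np.full(50, 3.3)
        assert np.allclose(hann_smooth(x, 10), x)

    def test_impulse_reproduces_kernel(self):
        x = np.zeros(51)
        x[25] = 1.0
        out = hann_smooth(x, 9)
        kern = hann_window(9)
        assert np.allclose(out[21:30], kern)

    def test_mass_conserved_for_interior_signal(self):
        x = np.zeros(100)
        x[40:45] = [1, 2, 7, 2, 1]
        assert hann_smooth(x, 10).sum() == pytest.approx(x.sum())

    def test_symmetric_input_symmetric_output(self):
        x = np.array([0, 1, 3, 9, 3, 1, 0], dtype=float)
        out = hann_smooth(x, 5)
        assert np.allclose(out, out[::-1])


class TestDensitySmooth:
    def test_mass_conserved(self):
        vals = {100: 5.0, 102: 3.0, 500: 1.0}
        _xs, out = density_smooth(vals)
        assert out.sum() == pytest.approx(9.0)

    def test_isolated_hit_smoothed_more_than_dense_cluster(self):
        vals = {100: 1.0}
        for p in range(500, 520):
            vals[p] = 1.0
        xs, out = density_smooth(vals, b0=5.0)
        iso_peak = out[xs == 100][0]
        dense_peak = out[(xs >= 500) & (xs < 520)].max()
        assert iso_peak < dense_peak  # broader kernel flattens the isolated hit

    def test_empty_track_is_error(self):
        with pytest.raises(ValueError):
            density_smooth({})


class TestAggregate:
    def test_single_plus_locus_equals_local_window(self):
        t = track_from(watson={98: 1.0, 100: 2.0, 103: 4.0})
        prof = aggregate(t, [Locus("chr1", 100, "+")], flank=5)
        assert prof.watson_mean[prof.offsets.tolist().index(0)] == 2.0
        assert prof.watson_mean[prof.offsets.tolist().index(-2)] == 1.0
        assert prof.watson_mean[prof.offsets.tolist().index(3)] == 4.0

    def test_minus_locus_mirrors_and_swaps_strands(self):
        t = track_from(watson={103: 4.0}, crick={98: 1.0})
        prof = aggregate(t, [Locus("chr1", 100, "-")], flank=5)
        # watson@+3 appears at offset -3 on the crick accumulator
        assert prof.crick_mean[prof.offsets.tolist().index(-3)] == 4.0
        assert prof.watson_mean[prof.offsets.tolist().index(2)] == 1.0

    def test_matches_naive_per_locus_loop(self):
        rng = np.random.default_rng(8)
        w = {int(p) + 1: float(v) for p, v in zip(rng.choice(2000, 150, replace=False), rng.integers(1, 9, 150))}
        c = {int(p) + 1: float(v) for p, v in zip(rng.choice(2000, 150, replace=False), rng.integers(1, 9, 150))}
        t = track_from(watson=w, crick=c)
        loci = [Locus("chr1", int(p), "+") for p in rng.integers(100, 1900, 20)]
        flank = 50
        prof = aggregate(t, loci, flank, orient=False)
        naive_w = np.zeros(2 * flank + 1)
        for locus in loci:
            for i, off in enumerate(range(-flank, flank + 1)):
                naive_w[i] += w.get(locus.position + off, 0.0)
        assert np.allclose(prof.watson_mean, naive_w / len(loci))

    def test_out_of_bounds_loci_dropped(self):
        t = track_from(watson={10: 1.0})
        prof = aggregate(t, [Locus("chr1", 3, "+"), Locus("chr1", 50, "+")], flank=5)
        assert prof.n_loci == 1 and prof.n_dropped == 1

    def test_zero_track_zero_profile(self):
        prof = aggregate(track_from(), [Locus("chr1", 100, "+")], flank=10)
        assert np.all(prof.total_mean == 0)


class TestStratify:
    def test_even_split(self):
        loci = [Locus("chr1", i, covariate=float(i)) for i in range(1, 9)]
        groups = stratify(loci, 4)
        assert [len(g) for g in groups] == [2, 2, 2, 2]
        assert groups[0][0].covariate == 1.0 and groups[-1][-1].covariate == 8.0

    def test_constant_covariate_stable_order(self):
        loci = [Locus("chr1", i, covariate=1.0, name=str(i)) for i in range(6)]
        groups = stratify(loci, 3)
        assert [l.name for g in groups for l in g] == [str(i) for i in range(6)]

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(3)
        loci = [Locus("chr1", i + 1, covariate=float(v)) for i, v in enumerate(rng.random(37))]
        groups = stratify(loci, 4)
        oracle = sorted(loci, key=lambda l: l.covariate)
        flat = [l for g in groups for l in g]
        assert [l.covariate for l in flat] == [l.covariate for l in oracle]
        sizes = [len(g) for g in groups]
        assert max(sizes) - min(sizes) <= 1

    def test_missing_covariate_dropped(self):
        loci = [Locus("chr1", 1, covariate=None), Locus("chr1", 2, covariate=1.0)]
        groups = stratify(loci, 1)
        assert sum(len(g) for g in groups) == 1


class TestAutocorrelate:
    def test_zero_separation_is_unity(self):
        rng = np.random.default_rng(1)
        r = autocorrelate(rng.random(500), 5)
        assert r[0] == pytest.approx(1.0)

    def test_iid_noise_within_sampling_bound(self):
        rng = np.random.default_rng(4)
        r = autocorrelate(rng.random(4000), 10)
        assert np.all(np.abs(r[1:]) < 3 / np.sqrt(4000))

    def test_period_two_alternation(self):
        x = np.tile([1.0, -1.0], 100)
        r = autocorrelate(x, 2)
        assert r[1] == pytest.approx(-1.0)
        assert r[2] == pytest.approx(1.0)

    def test_zero_variance_flagged_nan(self):
        r = autocorrelate(np.full(50, 2.0), 3)
        assert np.all(np.isnan(r))


class TestStrandCrossCorrelation:
    def make_offset_map(self, offset, n=60, seed=5):
        rng = np.random.default_rng(seed)
        bmap = BreakMap()
        positions = np.sort(rng.choice(100_000, n, replace=False)) + 200
        for p in positions:
            amp = int(rng.integers(5, 200))
            w = amp + int(rng.integers(0, 5))
            c = amp + int(rng.integers(0, 5))
            bmap.add("chr1", WATSON, int(p), w)
            bmap.add("chr1", CRICK, int(p) + offset, c)
        bmap.total_mapped_pairs = bmap.total_count()
        return bmap

    @pytest.mark.parametrize("offset", [1, 3])
    def test_argmax_recovers_constructed_offset(self, offset):
        oc = strand_cross_correlation(self.make_offset_map(offset))
        assert oc.argmax_offsets() == [offset]

    def test_watson_only_map_undefined_everywhere(self):
        bmap = BreakMap()
        for p in (100, 200, 300):
            bmap.add("chr1", WATSON, p, 5)
        oc = strand_cross_correlation(bmap, (-5, 5))
        assert np.all(np.isnan(oc.r))

    def test_read_fraction_normalised(self):
        oc = strand_cross_correlation(self.make_offset_map(3), (-20, 20))
        defined = ~np.isnan(oc.read_fraction)
        assert oc.read_fraction[defined].sum() == pytest.approx(1.0)


class TestClassifyIgrs:
    GENES = [
        ("chr1", 100, 200, "-"),
        ("chr1", 300, 400, "+"),
        ("chr1", 500, 600, "+"),
        ("chr1", 700, 800, "-"),
    ]

    def test_gap_labels(self):
        regions = classify_igrs(self.GENES)
        labels = {(r.start, r.end): r.label for r in regions}
        assert labels[(201, 299)] == "IGR_divergent"   # <-gene gap gene->
        assert labels[(401, 499)] == "IGR_tandem"      # -> gap ->
        assert labels[(601, 699)] == "IGR_convergent"  # -> gap <-
        assert labels[(100, 200)] == "intragenic"

    def test_overlapping_genes_unioned(self):
        regions = classify_igrs(
            [("chr1", 100, 250, "+"), ("chr1", 200, 300, "+"), ("chr1", 400, 500, "-")]
        )
        intr = [r for r in regions if r.label == "intragenic"]
        assert (intr[0].start, intr[0].end) == (100, 300)

    def test_partition_covers_span_once(self):
        regions = classify_igrs(self.GENES)
        covered = np.zeros(801, dtype=int)
        for r in regions:
            covered[r.start : r.end + 1] += 1
        assert np.all(covered[100:801] == 1)
        assert np.all(covered[:100] == 0)


class TestRegionDensity:
    def test_uniform_track_equal_densities(self):
        t = track_from(watson={p: 1.0 for p in range(1, 1001)})
        regions = classify_igrs([("chr1", 1, 100, "+"), ("chr1", 201, 300, "+")])
        table, _ = region_density(t, regions)
        assert np.allclose(table["density"], 1.0)

    def test_peak_density(self):
        t = track_from(watson={150: 50.0})
        regions = classify_igrs([("chr1", 101, 200, "+"), ("chr1", 301, 400, "+")])
        table, _ = region_density(t, regions)
        row = table[(table.start == 101)].iloc[0]
        assert row.density == pytest.approx(0.5)

    def test_whiskers_match_tukey_oracle(self):
        rng = np.random.default_rng(9)
        genes = [("chr1", i * 200 + 1, i * 200 + 100, "+") for i in range(40)]
        vals = {}
        for i in range(40):
            for p in rng.integers(i * 200 + 1, i * 200 + 100, 5):
                vals[int(p)] = vals.get(int(p), 0) + float(rng.integers(1, 30))
        t = track_from(watson=vals)
        regions = [r for r in classify_igrs(genes) if r.label == "intragenic"]
        table, summary = region_density(t, regions)
        d = table["density"].to_numpy()
        q1, q3 = np.percentile(d, [25, 75])
        iqr = q3 - q1
        s = summary["intragenic"]
        assert s["whisker_low"] == d[d >= q1 - 1.5 * iqr].min()
        assert s["whisker_high"] == d[d <= q3 + 1.5 * iqr].max()


class TestCallPeaks:
    def test_all_below_threshold_empty(self):
        t = track_from(watson={10: 0.01})
        assert call_peaks(t, 0.05) == []

    def test_boundary_value_kept(self):
        t = track_from(watson={10: 0.05})
        assert [(c, p) for c, p, _v in call_peaks(t, 0.05)] == [("chr1", 10)]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(6)
        w = {int(p) + 1: float(v) for p, v in zip(rng.choice(1000, 100, replace=False), rng.random(100) * 0.2)}
        c = {int(p) + 1: float(v) for p, v in zip(rng.choice(1000, 100, replace=False), rng.random(100) * 0.2)}
        t = track_from(watson=w, crick=c)
        expected = sorted(
            p for p in set(w) | set(c) if w.get(p, 0) + c.get(p, 0) >= 0.05
        )
        assert [p for _c, p, _v in call_peaks(t, 0.05)] == expected


class TestQuantifyVsCovariate:
    def test_proportional_covariate_perfect_rank_correlation(self):
        rng = np.random.default_rng(7)
        loci = []
        w = {}
        for i in range(20):
            pos = 1000 + i * 500
            sig = float(i + 1)
            w[pos] = sig
            loci.append(Locus("chr1", pos, "+", covariate=sig * 2.5, name=str(i)))
        t = track_from(watson=w)
        r, rs, _table = quantify_vs_covariate(t, loci, (-10, 10))
        assert rs == pytest.approx(1.0)

    def test_monotone_nonlinear_covariate(self):
        loci = []
        w = {}
        for i in range(15):
            pos = 1000 + i * 500
            w[pos] = float(i + 1)
            loci.append(Locus("chr1", pos, "+", covariate=float(np.exp(i / 2)), name=str(i)))
        t = track_from(watson=w)
        r, rs, _ = quantify_vs_covariate(t, loci, (-10, 10), log_transform=False)
        assert rs == pytest.approx(1.0)
        assert r < 1.0

    def test_permuted_covariate_decorrelates(self):
        rng = np.random.default_rng(12)
        n = 200
        sig = rng.gamma(2, 10, n)
        perm = rng.permutation(sig)
        loci = []
        w = {}
        for i in range(n):
            pos = 1000 + i * 100
            w[pos] = float(sig[i])
            loci.append(Locus("chr1", pos, "+", covariate=float(perm[i]) + 0.1, name=str(i)))
        t = track_from(watson=w)
        r, rs, _ = quantify_vs_covariate(t, loci, (-5, 5))
        assert abs(rs) < 3 / np.sqrt(n)

    def test_nonpositive_covariate_dropped_under_log(self):
        loci = [Locus("chr1", 1000 + i * 100, "+", covariate=float(i - 1), name=str(i)) for i in range(6)]
        t = track_from(watson={l.position: 1.0 for l in loci})
        _r, _rs, table = quantify_vs_covariate(t, loci, (-5, 5))
        assert len(table) == 4  # covariates 0 and -1 dropped
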