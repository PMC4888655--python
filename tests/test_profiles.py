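"""Meta-profiles, tertiles, permutation Spearman, KS, peak overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hmcscan as h

from conftest import make_gene


def _uniform_table(step=100, count=10, n=2000, chrom="chr1"):
    pos = np.arange(0, n * step, step)
    return h.SiteTable(pd.DataFrame(
        {"chrom": chrom, "pos": pos, "strand": "+", "count": count}))


class TestTssProfile:
    def test_uniform_reads_give_flat_profile(self):
        table = _uniform_table()
        gene = make_gene(start=50_000, end=80_000, exons=[(50_000, 80_000)])
        prof = h.tss_profile(table, [gene], window=5000, bin_bp=50)
        enr = prof.pooled_enrichment()
        vals = enr[~np.isnan(enr)]
        assert np.allclose(vals, 10.0)

    def test_minus_strand_profile_equals_mirrored_plus_gene(self):
        """A minus-strand gene's profile matches the same data seen mirrored."""
        rng = np.random.default_rng(0)
        total = 200_001
        pos = np.sort(rng.choice(total, 3000, replace=False))
        counts = rng.integers(0, 100, 3000)
        table = h.SiteTable(pd.DataFrame(
            {"chrom": "chr1", "pos": pos, "strand": "+", "count": counts}))
        mirrored = h.SiteTable(pd.DataFrame(
            {"chrom": "chr1", "pos": total - 1 - pos, "strand": "+", "count": counts}))
        t = 100_000
        minus = make_gene(strand="-", start=t - 20_000, end=t + 1,
                          exons=[(t - 20_000, t + 1)])
        plus = make_gene(strand="+", start=total - 1 - t, end=total - 1 - t + 20_000,
                         exons=[(total - 1 - t, total - 1 - t + 20_000)])
        p_minus = h.tss_profile(table, [minus], 5000, 50)
        p_plus = h.tss_profile(mirrored, [plus], 5000, 50)
        assert np.array_equal(p_minus.ccgg[0], p_plus.ccgg[0])
        assert np.array_equal(p_minus.reads[0], p_plus.reads[0])

    def test_window_must_be_bin_multiple(self, bundle_small):
        with pytest.raises(ValueError, match="multiple"):
            h.tss_profile(bundle_small["rrhp"][("hESC", 1)],
                          bundle_small["genome"].genes, window=5025, bin_bp=50)

    def test_planted_tss_shape_reproduced(self, bundle_mid):
        """The generator plants peaks near TSS+/-350 bp and a dip at the TSS."""
        genes = bundle_mid["genome"].genes
        prof = h.tss_profile(bundle_mid["rrhp"][("hESC", 1)], genes, 5000, 50)
        enr = prof.pooled_enrichment()
        c = prof.bin_centers
        at = lambda x: np.nanmean(enr[np.abs(c - x) <= 75])
        assert at(-350) > at(0) and at(350) > at(0)   # dip at the TSS
        assert at(350) > at(3000)        # proximal peak above the body plateau

    def test_zero_ccgg_bins_flagged_missing(self):
        table = _uniform_table(step=5000)
        gene = make_gene(start=50_000, end=80_000, exons=[(50_000, 80_000)])
        prof = h.tss_profile(table, [gene], window=5000, bin_bp=50)
        enr = prof.pooled_enrichment()
        assert np.isnan(enr).any() and not np.all(np.isnan(enr))


class TestScaledRegionMatrix:
    def _track(self, values, bin_bp=10, chrom="chr1"):
        starts = np.arange(len(values)) * bin_bp
        return h.SignalTrack({chrom: (starts, starts + bin_bp, np.asarray(values, float))})

    def test_constant_track_fills_matrix(self):
        track = self._track([7.0] * 10_000)
        regions = pd.DataFrame({"chrom": "chr1", "start": [20_000, 41_000], "end": [30_000, 56_000]})
        m = h.scaled_region_matrix(track, regions, flank_bp=1000, n_body_bins=20)
        assert np.allclose(m.values, 7.0)

    def test_region_length_equal_to_bins_gives_single_bp_bins(self):
        vals = np.arange(100.0)
        track = self._track(vals, bin_bp=1)
        regions = pd.DataFrame({"chrom": "chr1", "start": [10], "end": [30]})
        m = h.scaled_region_matrix(track, regions, flank_bp=0 or 5, n_body_bins=20, flank_bin_bp=5)
        body = m.values[0, 1:-1]
        assert np.allclose(body, vals[10:30])

    def test_matches_naive_per_bin_mean_oracle(self, rng):
        vals = rng.gamma(2.0, 3.0, size=5000)
        track = self._track(vals, bin_bp=1)
        s, e = 1000, 1000 + 40 * 25  # body length divisible by bin count
        regions = pd.DataFrame({"chrom": "chr1", "start": [s], "end": [e]})
        m = h.scaled_region_matrix(track, regions, flank_bp=200, n_body_bins=40, flank_bin_bp=50)
        edges = np.concatenate([np.arange(s - 200, s, 50),
                                np.linspace(s, e, 41)[:-1],
                                np.arange(e, e + 200, 50), [e + 200]])
        expected = [vals[int(a):int(b)].mean() for a, b in zip(edges[:-1], edges[1:])]
        assert np.allclose(m.values[0], expected)

    def test_degenerate_region_rejected(self):
        track = self._track([1.0] * 100)
        bad = pd.DataFrame({"chrom": "chr1", "start": [50], "end": [50]})
        with pytest.raises(ValueError, match="degenerate"):
            h.scaled_region_matrix(track, bad)


class TestExpressionTertiles:
    def test_even_split(self):
        expr = pd.DataFrame({"gene_id": [f"g{i}" for i in range(9)],
                             "fpkm": np.arange(9.0)})
        t = h.expression_tertiles(expr)
        assert t.value_counts().tolist() == [3, 3, 3]
        assert t["g8"] == "high" and t["g0"] == "low"

    def test_all_equal_fpkm_deterministic(self):
        expr = pd.DataFrame({"gene_id": [f"g{i}" for i in range(6)], "fpkm": 2.0})
        t1 = h.expression_tertiles(expr)
        t2 = h.expression_tertiles(expr.sample(frac=1, random_state=3))
        pd.testing.assert_series_equal(t1.sort_index(), t2.sort_index())

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            h.expression_tertiles(pd.DataFrame({"gene_id": ["a"], "fpkm": [1.0]}))

    def test_planted_extremes_land_in_correct_tertiles(self, bundle_small):
        expr = bundle_small["expression"]["hESC"]
        t = h.expression_tertiles(expr)
        ranked = expr.sort_values("fpkm")
        assert t[ranked["gene_id"].iloc[0]] == "low"
        assert t[ranked["gene_id"].iloc[-1]] == "high"


class TestSpearmanPerm:
    def test_identity_rho_one(self):
        res = h.spearman_perm(np.arange(10.0), np.arange(10.0), n_perm=100, seed=0)
        assert res.rho == pytest.approx(1.0)

    def test_exact_enumeration_matches_brute_force(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 1, 4, 3])
        res = h.spearman_perm(x, y)
        assert res.exact and res.n_perm == 24
        rho_obs = stats.spearmanr(x, y).statistic
        assert res.rho == pytest.approx(rho_obs)
        hits = sum(
            abs(stats.spearmanr(x, np.array(p)).statistic) >= abs(rho_obs) - 1e-12
            for p in itertools.permutations(y))
        assert res.p == pytest.approx(hits / 24)

    def test_monte_carlo_p_has_plus_one_correction(self, rng):
        x = np.arange(20.0)
        res = h.spearman_perm(x, x, n_perm=999, seed=4)
        assert not res.exact
        assert res.p == pytest.approx(1 / 1000)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            h.spearman_perm([1.0, 1, 1, 1], [1.0, 2, 3, 4])

    def test_null_p_uniform(self, rng):
        pvals = [h.spearman_perm(rng.normal(size=25), rng.normal(size=25),
                                 n_perm=200, seed=i).p for i in range(80)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestKsTwoSample:
    def test_identical_samples_d_zero(self):
        a = np.arange(50.0)
        assert h.ks_two_sample(a, a).D == 0.0

    def test_disjoint_supports_d_one(self):
        assert h.ks_two_sample([1.0, 2, 3], [10.0, 11]).D == 1.0

    def test_matches_quadratic_ecdf_oracle(self, rng):
        for _ in range(10):
            a = rng.normal(size=rng.integers(3, 30))
            b = rng.normal(0.5, 1.2, size=rng.integers(3, 30))
            grid = np.concatenate([a, b])
            oracle = max(abs((a <= v).mean() - (b <= v).mean()) for v in grid)
            assert h.ks_two_sample(a, b).D == pytest.approx(oracle)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            h.ks_two_sample([], [1.0])


class TestOverlapFraction:
    def _background(self, pos, counts):
        return h.SiteTable(pd.DataFrame(
            {"chrom": "chr1", "pos": pos, "strand": "+", "count": counts}))

    def test_whole_genome_peaks(self):
        bg = self._background(np.arange(0, 10_000, 100), [10] * 100)
        pos = h.call_sites(bg, 5)  # subset positive (all counts 10 > 5)
        bg2 = self._background(list(np.arange(0, 10_000, 100)) + [10_500], [10] * 100 + [1])
        positive = h.call_sites(bg2, 5)
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000_000]})
        res = h.overlap_fraction(positive, peaks, bg2)
        assert res.fraction_in_peaks == 1.0
        assert res.enrichment == pytest.approx(1.0)

    def test_positives_only_inside_peaks_hand_ratio(self):
        # 10 positive sites in [0,1000); 40 unmodified: 10 inside, 30 outside
        pos_sites = list(range(0, 1000, 100))
        unmod_in = list(range(10, 1000, 100))
        unmod_out = list(range(2000, 5000, 100))
        bg = self._background(pos_sites + unmod_in + unmod_out,
                              [200] * 10 + [1] * len(unmod_in + unmod_out))
        positive = h.call_sites(bg, 100)
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        res = h.overlap_fraction(positive, peaks, bg)
        assert res.fraction_in_peaks == 1.0
        assert res.background_fraction == pytest.approx(10 / 40)
        assert res.enrichment == pytest.approx(4.0)

    def test_empty_background_rejected(self):
        positive = h.PositiveSiteSet(pd.DataFrame(
            {"chrom": [], "pos": [], "strand": [], "count": []}), cutoff=1)
        with pytest.raises(ValueError):
            h.overlap_fraction(positive, pd.DataFrame({"chrom": [], "start": [], "end": []}),
                               self._background([], []))
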