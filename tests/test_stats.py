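"""Window statistics, paired/one-sample tests, the permutation null,
correlations and overlap fractions, cross-checked against scipy."""

import numpy as np
import pytest
from scipy import stats as sps

from breakdomains.intervals import make_genes, make_sites, make_zones
from breakdomains.stats import (
    DegenerateTestError,
    expression_change_test,
    gene_signal,
    paired_site_test,
    peak_overlap_fraction,
    random_site_null,
    signal_ratio_correlation,
    stratified_compare,
    tss_window_test,
    window_mean_at_sites,
)
from breakdomains.tracks import ProbeTrack

from conftest import build_track


def track_1d(values, positions=None, chrom="chr1"):
    values = np.asarray(values, dtype=float)
    if positions is None:
        positions = np.arange(values.size) * 100
    return ProbeTrack.from_dict({chrom: (np.asarray(positions), values)})


class TestWindowMeans:
    def test_two_probe_average(self):
        t = track_1d([1.0, 3.0], positions=[990, 1010])
        out = window_mean_at_sites(t, make_sites(["chr1"], [1000]), 2000)
        assert out.iloc[0]["mean"] == 2.0
        assert out.iloc[0]["n_probes"] == 2

    def test_constant_track(self):
        t = track_1d(np.full(50, 7.0))
        sites = make_sites(["chr1"] * 3, [500, 2500, 4000])
        out = window_mean_at_sites(t, sites, 1000)
        assert (out["mean"] == 7.0).all()

    def test_closed_window_membership(self):
        # |pos - site| <= w/2 is closed: probes exactly at the edge count
        t = track_1d([1.0, 2.0, 3.0], positions=[0, 1000, 2000])
        out = window_mean_at_sites(t, make_sites(["chr1"], [1000]), 2000)
        assert out.iloc[0]["n_probes"] == 3
        assert out.iloc[0]["mean"] == 2.0

    def test_site_without_probes_flagged(self):
        t = track_1d([1.0], positions=[0])
        out = window_mean_at_sites(t, make_sites(["chr1"], [100_000]), 1000)
        assert out.iloc[0]["n_probes"] == 0
        assert np.isnan(out.iloc[0]["mean"])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(100_000, size=400, replace=False))
        vals = rng.normal(size=400)
        t = track_1d(vals, positions=pos)
        sites = make_sites(["chr1"] * 20, rng.integers(0, 100_000, 20))
        out = window_mean_at_sites(t, sites, 5000)
        for _, row in out.iterrows():
            sel = np.abs(pos - row["pos"]) <= 2500
            if sel.any():
                assert row["mean"] == pytest.approx(vals[sel].mean())
            else:
                assert row["n_probes"] == 0


class TestPairedTest:
    def test_identical_tracks_give_p_one(self, tiny_genome):
        a = build_track(tiny_genome, seed=1, sd=0.3)
        sites = make_sites(["chr1"] * 5, [10_000, 30_000, 50_000, 70_000, 90_000])
        res = paired_site_test(a, a, sites, 2000)
        assert res.t == 0.0 and res.p == 1.0 and res.df == 4

    def test_hand_computed_t(self):
        # paired means a=[1,2,3,4], b=[1.5,2.5,3.4,4.6]:
        # d = [.5,.5,.4,.6], t = mean(d) / (sd(d)/sqrt(4)) = 12.247...
        pos = [1000, 11_000, 21_000, 31_000]
        a = track_1d([1.0, 2.0, 3.0, 4.0], positions=pos)
        b = track_1d([1.5, 2.5, 3.4, 4.6], positions=pos)
        sites = make_sites(["chr1"] * 4, pos)
        res = paired_site_test(a, b, sites, 1000)
        assert res.t == pytest.approx(12.247448, abs=1e-5)
        assert res.df == 3
        ref = sps.ttest_rel([1.5, 2.5, 3.4, 4.6], [1.0, 2.0, 3.0, 4.0])
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_matches_scipy_on_random_cases(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            pos = np.arange(n) * 10_000 + 1000
            av = rng.normal(size=n)
            bv = rng.normal(size=n)
            a = track_1d(av, positions=pos)
            b = track_1d(bv, positions=pos)
            sites = make_sites(["chr1"] * n, pos)
            res = paired_site_test(a, b, sites, 1000)
            ref = sps.ttest_rel(bv, av)
            assert res.t == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_constant_nonzero_difference_is_degenerate(self):
        pos = [1000, 11_000, 21_000]
        a = track_1d([1.0, 2.0, 3.0], positions=pos)
        b = track_1d([1.5, 2.5, 3.5], positions=pos)
        sites = make_sites(["chr1"] * 3, pos)
        with pytest.raises(DegenerateTestError):
            paired_site_test(a, b, sites, 1000)

    def test_order_invariance(self, tiny_genome):
        a = build_track(tiny_genome, seed=3, sd=0.5)
        b = build_track(tiny_genome, seed=4, sd=0.5)
        positions = [5_000, 25_000, 45_000, 65_000, 85_000]
        fwd = make_sites(["chr1"] * 5, positions)
        rev = make_sites(["chr1"] * 5, positions[::-1])
        assert paired_site_test(a, b, fwd, 2000).p == \
            pytest.approx(paired_site_test(a, b, rev, 2000).p, abs=1e-14)


class TestRandomSiteNull:
    def test_identical_tracks_all_p_one(self, tiny_genome):
        a = build_track(tiny_genome, seed=1, sd=0.3)
        rep = random_site_null(a, a, tiny_genome, 20, 10, 2000, seed=0)
        assert (rep.p_values == 1.0).all()
        assert rep.fraction_below_alpha == 0.0

    def test_deterministic_given_seed(self, noise_track_pair, tiny_genome):
        a, b = noise_track_pair
        r1 = random_site_null(a, b, tiny_genome, 30, 8, 2000, seed=9)
        r2 = random_site_null(a, b, tiny_genome, 30, 8, 2000, seed=9)
        np.testing.assert_array_equal(r1.p_values, r2.p_values)
        assert r1.log10_p_quartiles == r2.log10_p_quartiles

    def test_report_shape(self, noise_track_pair, tiny_genome):
        a, b = noise_track_pair
        rep = random_site_null(a, b, tiny_genome, 25, 8, 2000, seed=2)
        assert rep.p_values.size == 25
        assert 0.0 <= rep.fraction_below_alpha <= 1.0
        q1, q2, q3 = rep.log10_p_quartiles
        assert q1 <= q2 <= q3 <= 0.0


class TestGeneSignal:
    def genes(self, entries):
        return make_genes([
            {"name": f"g{i}", "chrom": c, "strand": "+", "tx_start": s, "tx_end": e}
            for i, (c, s, e) in enumerate(entries)
        ])

    def test_simple_mean(self):
        t = track_1d([1.0, 3.0, 5.0, 100.0], positions=[100, 300, 500, 5000])
        out = gene_signal(t, self.genes([("chr1", 100, 501)]))
        assert out.iloc[0] == 3.0

    def test_half_open_gene_body(self):
        t = track_1d([1.0, 9.0], positions=[100, 500])
        out = gene_signal(t, self.genes([("chr1", 100, 500)]))
        assert out.iloc[0] == 1.0  # probe at tx_end excluded

    def test_gene_without_probes_nan(self):
        t = track_1d([1.0], positions=[0])
        out = gene_signal(t, self.genes([("chr1", 5000, 6000)]))
        assert np.isnan(out.iloc[0])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(50_000, 300, replace=False))
        vals = rng.normal(size=300)
        t = track_1d(vals, positions=pos)
        entries = []
        for _ in range(15):
            s = int(rng.integers(0, 45_000))
            entries.append(("chr1", s, s + int(rng.integers(500, 5000))))
        out = gene_signal(t, self.genes(entries))
        genes = self.genes(entries)
        for (_, g), got in zip(genes.iterrows(), out):
            sel = (pos >= g["tx_start"]) & (pos < g["tx_end"])
            if sel.any():
                assert got == pytest.approx(vals[sel].mean())
            else:
                assert np.isnan(got)


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p, n = signal_ratio_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == 0.0 and n == 10
        r, _, _ = signal_ratio_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_scipy_pearson(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 100))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            r, p, _ = signal_ratio_correlation(x, y)
            ref = sps.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_nan_pairs_dropped(self):
        x = np.array([1.0, 2, 3, np.nan, 5])
        y = np.array([1.0, 2, 3, 4, np.nan])
        r, p, n = signal_ratio_correlation(x, y)
        assert n == 3

    def test_generative_coupling_recovered(self):
        # known latent correlation r = 0.8 at n = 359
        devs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=359)
            y = 0.8 * x + np.sqrt(1 - 0.8 ** 2) * rng.normal(size=359)
            r, _, _ = signal_ratio_correlation(x, y)
            devs.append(abs(r - 0.8))
        assert max(devs) < 0.08


class TestTssWindowTest:
    def genes(self, entries):
        return make_genes([
            {"name": f"g{i}", "chrom": c, "strand": s, "tx_start": a, "tx_end": b}
            for i, (c, s, a, b) in enumerate(entries)
        ])

    def test_identical_tracks_p_one(self):
        t = track_1d(np.random.default_rng(0).normal(size=200))
        genes = self.genes([("chr1", "+", 3000, 6000), ("chr1", "-", 8000, 12_001),
                            ("chr1", "+", 15_000, 17_000)])
        res = tss_window_test(t, t, genes, (-200, 200))
        assert res.p == 1.0

    def test_uniform_shift_recovered(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 0.05, size=400)
        a = track_1d(vals)
        vb = vals.copy()
        genes = self.genes([("chr1", "+", 5000, 8000), ("chr1", "+", 15_000, 18_000),
                            ("chr1", "+", 25_000, 28_000), ("chr1", "+", 35_000, 38_000)])
        for tss in [5000, 15_000, 25_000, 35_000]:
            sel = (np.arange(400) * 100 >= tss - 200) & (np.arange(400) * 100 < tss + 200)
            vb[sel] += 0.5
        b = track_1d(vb)
        res = tss_window_test(a, b, genes, (-200, 200))
        assert res.mean_diff == pytest.approx(0.5, abs=0.05)
        assert res.p < 0.01

    def test_minus_strand_reads_mirrored_window(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=300)
        t = track_1d(vals)
        # minus gene, TSS at 10_000; same numbers from a plus gene at the
        # mirrored position on the reversed track
        minus = self.genes([("chr1", "-", 5000, 10_001)])
        rev = track_1d(vals[::-1])
        rev_tss = (300 - 1) * 100 - 10_000
        plus = self.genes([("chr1", "+", rev_tss, rev_tss + 5000)])
        from breakdomains.stats import _oriented_window_mean
        m1 = _oriented_window_mean(t, minus, -200, 200)
        m2 = _oriented_window_mean(rev, plus, -200, 200)
        assert m1[0] == pytest.approx(m2[0], abs=1e-12)


class TestStratified:
    def test_constructed_shift_recovered(self):
        rng = np.random.default_rng(4)
        ratio = np.concatenate([np.full(50, 0.9), np.full(50, 1.2)])
        cov = rng.normal(0, 0.1, 100)
        cov[50:] += 0.5
        out = stratified_compare(ratio, cov, low_cut=0.95, high_cut=1.1)
        assert out["high_mean"] - out["low_mean"] == pytest.approx(0.5, abs=0.1)
        assert out["p"] < 1e-6
        assert out["low_n"] == 50 and out["high_n"] == 50

    def test_identical_distributions(self):
        rng = np.random.default_rng(5)
        ratio = np.concatenate([np.full(200, 0.9), np.full(200, 1.2)])
        cov = rng.normal(size=400)
        out = stratified_compare(ratio, cov, 0.95, 1.1)
        assert abs(out["high_mean"] - out["low_mean"]) < 0.3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty comparison group"):
            stratified_compare(np.full(10, 1.0), np.ones(10), 0.95, 1.1)


class TestExpressionChange:
    def test_no_change_p_one(self):
        out = expression_change_test(np.ones((3, 5)))
        assert (out["t"] == 0.0).all()
        assert (out["p"] == 1.0).all()

    def test_hand_example_matches_scipy(self):
        fc = np.array([[0.8, 0.9, 0.85, 0.95, 0.9]])
        out = expression_change_test(fc)
        ref = sps.ttest_1samp(fc[0], popmean=1.0)
        assert out.iloc[0]["t"] == pytest.approx(ref.statistic, abs=1e-10)
        assert out.iloc[0]["p"] == pytest.approx(ref.pvalue, abs=1e-10)
        assert out.iloc[0]["df"] == 4
        # the replicate set is clearly below the no-change ratio
        assert out.iloc[0]["t"] < -4
        assert out.iloc[0]["p"] < 0.01

    def test_matches_scipy_random(self):
        rng = np.random.default_rng(6)
        fc = rng.lognormal(0, 0.2, size=(20, 4))
        out = expression_change_test(fc)
        for g in range(20):
            ref = sps.ttest_1samp(fc[g], popmean=1.0)
            assert out.iloc[g]["t"] == pytest.approx(ref.statistic, abs=1e-10)
            assert out.iloc[g]["p"] == pytest.approx(ref.pvalue, abs=1e-10)


class TestOverlapFraction:
    def zones(self, spans, chrom="chr1"):
        return make_zones([
            {"chrom": chrom, "start": s, "end": e, "n_probes": 1,
             "mean_score": 1.0, "label": "peak"} for s, e in spans
        ])

    def test_identical_sets(self):
        z = self.zones([(0, 100), (200, 300)])
        assert peak_overlap_fraction(z, z) == 1.0

    def test_disjoint_sets(self):
        a = self.zones([(0, 100), (200, 300)])
        b = self.zones([(100, 200), (300, 400)])
        assert peak_overlap_fraction(a, b) == 0.0

    def test_one_of_four(self):
        a = self.zones([(0, 10), (100, 110), (200, 210), (300, 310)])
        b = self.zones([(305, 320)])
        assert peak_overlap_fraction(a, b) == 0.25

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = self.zones(sorted_spans(rng, 15))
            b = self.zones(sorted_spans(rng, 10))
            expected = 0
            for _, za in a.iterrows():
                if any((zb["start"] < za["end"]) and (zb["end"] > za["start"])
                       for _, zb in b.iterrows()):
                    expected += 1
            assert peak_overlap_fraction(a, b) == pytest.approx(expected / len(a))


def sorted_spans(rng, k):
    starts = np.sort(rng.choice(10_000, size=k, replace=False))
    return [(int(s), int(s + rng.integers(10, 600))) for s in starts]
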