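"""Density summaries, Wilcoxon rank-sum conventions, the model object."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from asmirmask import (DensityRecord, MirnaSiteEnrichment, compare_regions,
                       site_density, summarize_densities, wilcoxon_rank_sum)


class TestSiteDensity:
    @pytest.mark.parametrize("n,L,per100", [
        (18704, 358663, 5.21),   # pooled pairing-region totals
        (111192, 1570606, 7.07),  # pooled non-pairing totals
    ])
    def test_aggregate_density_arithmetic(self, n, L, per100):
        d = site_density(n, L)
        assert d.per_100nt == pytest.approx(per100, abs=0.01)  # printed precision
        assert d.per_nt == n / L

    def test_zero_count(self):
        assert site_density(0, 1000) == (0.0, 0.0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            site_density(1, 0)


def _recs(densities, cls="pairing", L=1000):
    return [DensityRecord(f"p{i}", cls, int(round(d * L)), L)
            for i, d in enumerate(densities)]


class TestSummarizeDensities:
    def test_constant_densities(self):
        s = summarize_densities(_recs([0.05] * 10), "pairing")
        assert s.median == s.q1 == s.q3 == pytest.approx(0.05)

    def test_quartiles_match_linear_interpolation_oracle(self):
        # order statistics 1,2,3,4 (scaled): type-7 linear interpolation
        s = summarize_densities(_recs([0.001, 0.002, 0.003, 0.004]), "pairing")
        assert s.q1 == pytest.approx(0.00175)
        assert s.median == pytest.approx(0.0025)
        assert s.q3 == pytest.approx(0.00325)
        assert (s.min, s.max) == (0.001, 0.004)

    def test_aggregate_mean_diverges_from_median(self):
        recs = [DensityRecord("a", "pairing", 10, 100),
                DensityRecord("b", "pairing", 0, 900)]
        s = summarize_densities(recs, "pairing")
        assert s.mean_per_100nt == pytest.approx(1.0)  # 100 x 10/1000
        assert s.median == pytest.approx(0.05)

    def test_pooled_mean_is_totals_ratio(self):
        rng = np.random.default_rng(0)
        recs = [DensityRecord(f"p{i}", "pairing", int(rng.integers(0, 40)),
                              int(rng.integers(100, 900))) for i in range(30)]
        s = summarize_densities(recs, "pairing")
        total_n = sum(r.site_count for r in recs)
        total_L = sum(r.length_nt for r in recs)
        assert s.mean_per_100nt == 100 * total_n / total_L

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            summarize_densities(_recs([0.1]), "nonpairing")


def _enumeration_p(a, b):
    """Independent oracle: full enumeration over pooled value assignments."""
    pooled = list(a) + list(b)
    n = len(a)
    w_obs = sps.rankdata(pooled)[:n].sum()
    ws = []
    for idx in itertools.combinations(range(len(pooled)), n):
        ranks = sps.rankdata(pooled)
        ws.append(ranks[list(idx)].sum())
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxonRankSum:
    def test_exact_separated_triples(self):
        w, p, method = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert (w, p, method) == (6.0, 0.1, "exact")

    def test_identical_samples_give_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]).pvalue == 1.0

    def test_single_observations(self):
        assert wilcoxon_rank_sum([0.01], [0.09]).pvalue == 1.0

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for n in range(2, 8):
            a = rng.normal(size=n)
            b = rng.normal(0.8, size=n)
            mine = wilcoxon_rank_sum(a, b)
            assert mine.method == "exact"
            assert mine.pvalue == pytest.approx(_enumeration_p(a, b))

    def test_normal_path_matches_scipy(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=40)
        b = rng.normal(0.4, size=35)
        mine = wilcoxon_rank_sum(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert mine.method == "normal"
        assert mine.pvalue == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_exact_and_normal_paths_agree_at_n10(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.normal(size=10)
            b = rng.normal(rng.uniform(0, 1), size=10)
            exact = wilcoxon_rank_sum(a, b)
            w = exact.statistic
            n = m = 10
            N = n + m
            mu = n * (N + 1) / 2
            sigma = np.sqrt(n * m * (N + 1) / 12)
            z = (w - mu - 0.5 * np.sign(w - mu)) / sigma
            p_norm = min(1.0, 2 * sps.norm.sf(abs(z)))
            assert abs(exact.pvalue - p_norm) <= 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(5)
        rejections = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(size=50)
            b = rng.normal(size=50)
            if wilcoxon_rank_sum(a, b).pvalue < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.08


class TestEnrichmentModel:
    def _records(self, seed=0, n=40, rp=0.02, rn=0.05):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(n):
            lp = int(rng.integers(200, 800))
            ln = int(rng.integers(500, 2000))
            recs.append(DensityRecord(f"p{i}", "pairing", int(rng.poisson(rp * lp)), lp))
            recs.append(DensityRecord(f"p{i}", "nonpairing", int(rng.poisson(rn * ln)), ln))
        return recs

    def test_fit_detects_planted_depletion(self):
        res = compare_regions(self._records())
        assert res.direction == "nonpairing>pairing"
        assert res.pvalue < 1e-6
        assert res.pairing.median < res.nonpairing.median

    def test_scale_equivariance(self):
        recs = self._records(seed=1)
        k = 7
        scaled = [DensityRecord(r.pair_id, r.region_class, r.site_count * k,
                                r.length_nt * k) for r in recs]
        a, b = compare_regions(recs), compare_regions(scaled)
        assert a.pvalue == b.pvalue
        assert a.statistic == b.statistic
        assert a.pairing.median == pytest.approx(b.pairing.median)
        assert a.pairing.mean_per_100nt == pytest.approx(b.pairing.mean_per_100nt)

    def test_missing_class_for_one_pair_tolerated(self):
        recs = self._records(seed=2, n=10)
        recs.append(DensityRecord("lonely", "pairing", 3, 500))
        res = compare_regions(recs)
        assert res.pairing.n == 11 and res.nonpairing.n == 10

    def test_model_requires_both_classes(self):
        with pytest.raises(ValueError):
            MirnaSiteEnrichment(_recs([0.1, 0.2], cls="pairing"))

    def test_summary_and_to_dict(self):
        res = compare_regions(self._records(seed=3, n=12))
        text = res.summary()
        assert "Wilcoxon" in text and "nonpairing" in text
        d = res.to_dict()
        assert set(d) >= {"wilcoxon_W", "p_wilcoxon", "direction",
                          "pairing", "nonpairing"}
        assert d["pairing"]["n_pairs"] == 12

    def test_from_sites_builds_zero_count_records(self, small_set, small_partitions):
        from asmirmask import scan_regions

        sites = []
        for part in small_partitions[:6]:
            sites.extend(scan_regions(small_set.mirnas, part))
        model = MirnaSiteEnrichment.from_sites(sites, small_partitions[:6])
        assert len(model.records) == 12  # 6 pairs x 2 classes, zero counts kept
        lengths = {(r.pair_id, r.region_class): r.length_nt for r in model.records}
        truth = small_set.ground_truth.region_lengths
        for (pid, cls), L in lengths.items():
            assert L == truth[pid][cls]
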