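"""External-evidence statistics against exact oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crdomics import integrate
from crdomics.simulate import simulate_ld_genotypes


def _interactions(rows):
    return pd.DataFrame(rows, columns=["chromA", "startA", "endA",
                                       "chromB", "startB", "endB", "score"])


class TestPchicSupport:
    def _pair(self, s1, s2, width=1000, chrom="1"):
        return ((chrom, s1, s1 + width), (chrom, s2, s2 + width))

    def test_toy_fraction_matches_overlap_check(self):
        pairs = [self._pair(0, 100_000 + 5_000 * i) for i in range(10)]
        rows = [("1", 0, 1000, "1", 100_000 + 5_000 * i, 100_000 + 5_000 * i + 1000, 9.0)
                for i in range(3)]  # supports the first three pairs
        curve = integrate.pchic_support(pairs, _interactions(rows),
                                        bins=[20_000, 500_000])
        assert curve["n_pairs"].iloc[0] == 10
        assert curve["fraction"].iloc[0] == pytest.approx(0.3)

    def test_low_scores_support_nothing(self):
        pairs = [self._pair(0, 100_000)]
        rows = [("1", 0, 1000, "1", 100_000, 101_000, 4.9)]
        curve = integrate.pchic_support(pairs, _interactions(rows),
                                        bins=[20_000, 500_000])
        assert curve["n_supported"].sum() == 0

    def test_short_range_pairs_excluded(self):
        pairs = [self._pair(0, 15_000), self._pair(0, 60_000)]
        rows = [("1", 0, 1000, "1", 15_000, 16_000, 10.0),
                ("1", 0, 1000, "1", 60_000, 61_000, 10.0)]
        curve = integrate.pchic_support(pairs, _interactions(rows),
                                        bins=[20_000, 500_000])
        assert curve["n_pairs"].sum() == 1  # the 14 kb pair never enters

    def test_either_orientation_matches(self):
        pairs = [self._pair(200_000, 0)]
        rows = [("1", 0, 1000, "1", 200_000, 201_000, 7.0)]
        curve = integrate.pchic_support(pairs, _interactions(rows),
                                        bins=[20_000, 500_000])
        assert curve["n_supported"].sum() == 1

    def test_monotone_in_score_threshold(self):
        rng = np.random.default_rng(0)
        pairs = [self._pair(0, 50_000 + 10_000 * i) for i in range(20)]
        rows = [("1", 0, 1000, "1", 50_000 + 10_000 * i, 51_000 + 10_000 * i,
                 float(rng.uniform(0, 12))) for i in range(20)]
        ia = _interactions(rows)
        fracs = []
        for smin in (2.0, 5.0, 8.0, 11.0):
            c = integrate.pchic_support(pairs, ia, score_min=smin,
                                        bins=[20_000, 10_000_000])
            fracs.append(c["n_supported"].sum())
        assert fracs == sorted(fracs, reverse=True)

    def test_mean_aggregate(self):
        pairs = [self._pair(0, 100_000)]
        rows = [("1", 0, 1000, "1", 100_000, 101_000, 4.0),
                ("1", 0, 1000, "1", 100_000, 101_000, 8.0)]
        any_mode = integrate.pchic_support(pairs, _interactions(rows),
                                           bins=[20_000, 500_000], aggregate="any")
        mean_mode = integrate.pchic_support(pairs, _interactions(rows),
                                            bins=[20_000, 500_000], aggregate="mean")
        assert any_mode["n_supported"].sum() == 1   # max 8 >= 5
        assert mean_mode["n_supported"].sum() == 1  # mean 6 >= 5
        rows[1] = ("1", 0, 1000, "1", 100_000, 101_000, 5.5)
        mean2 = integrate.pchic_support(pairs, _interactions(rows),
                                        bins=[20_000, 500_000], aggregate="mean")
        assert mean2["n_supported"].sum() == 0      # mean 4.75 < 5

    def test_unsorted_bins_rejected(self):
        with pytest.raises(ValueError):
            integrate.pchic_support([], _interactions([("1", 0, 1, "1", 2, 3, 1.0)]),
                                    bins=[10, 5])


class TestTfbsEnrichment:
    def _setup(self, n11=10, n10=90, n01=5, n00=195):
        # lay variants on a line; TFBS covers the first (n11+n01) positions
        sig = {f"s{i}" for i in range(n11 + n10)}
        bg = sig | {f"b{i}" for i in range(n01 + n00)}
        pos_rows = []
        k = 1
        for i in range(n11):
            pos_rows.append({"variant_id": f"s{i}", "chrom": "1", "pos": k}); k += 1
        for i in range(n01):
            pos_rows.append({"variant_id": f"b{i}", "chrom": "1", "pos": k}); k += 1
        inside_end = k - 1
        for i in range(n11, n11 + n10):
            pos_rows.append({"variant_id": f"s{i}", "chrom": "1", "pos": k}); k += 1
        for i in range(n01, n01 + n00):
            pos_rows.append({"variant_id": f"b{i}", "chrom": "1", "pos": k}); k += 1
        tfbs = {"TF1": pd.DataFrame({"chrom": ["1"], "start": [0], "end": [inside_end]})}
        return sig, bg, tfbs, pd.DataFrame(pos_rows)

    def test_fisher_table_exact(self):
        sig, bg, tfbs, vp = self._setup()
        out = integrate.tfbs_enrichment(sig, bg, tfbs, vp)
        rec = out.iloc[0]
        assert (rec["n11"], rec["n10"], rec["n01"], rec["n00"]) == (10, 90, 5, 195)
        assert rec["odds_ratio"] == pytest.approx(10 * 195 / (90 * 5))
        _, p_ref = stats.fisher_exact([[10, 90], [5, 195]])
        assert rec["p"] == pytest.approx(p_ref, rel=1e-12)
        # hypergeometric tail oracle for the one-sided mass at the observed table
        assert stats.hypergeom.pmf(10, 300, 15, 100) <= p_ref

    def test_zero_cell_haldane(self):
        sig, bg, tfbs, vp = self._setup(n11=0, n10=50, n01=10, n00=100)
        out = integrate.tfbs_enrichment(sig, bg, tfbs, vp)
        orr = out["odds_ratio"].iloc[0]
        assert np.isfinite(orr) and orr < 1
        assert orr == pytest.approx((0.5 * 100.5) / (50.5 * 10.5))

    def test_top_k_ranking_by_crd_overlap(self):
        sig, bg, tfbs, vp = self._setup()
        tfbs["TF2"] = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [5]})
        tfbs["TF3"] = pd.DataFrame({"chrom": ["2"], "start": [0], "end": [5]})
        peaks = pd.DataFrame({"chrom": ["1"] * 3, "start": [0, 2, 4], "end": [1, 3, 5]})
        names = integrate.rank_tfbs_by_crd_overlap(tfbs, peaks, top_k=2)
        assert names[0] in ("TF1", "TF2") and "TF3" not in names


class TestLd:
    def test_duplicated_variant_r2_one(self):
        g = simulate_ld_genotypes(2, 100, block_size=1, rho=0.0, seed=1)
        g.dosages[1] = g.dosages[0]
        ld = integrate.ld_matrix(g)
        assert ld["r2"].iloc[0] == pytest.approx(1.0)

    def test_independent_variants_low_r2(self):
        g = simulate_ld_genotypes(30, 1000, block_size=1, rho=0.0, seed=2,
                                  spacing=10_000)
        ld = integrate.ld_matrix(g)
        assert ld["r2"].mean() < 0.01

    def test_window_exclusion(self):
        g = simulate_ld_genotypes(3, 50, block_size=1, rho=0.0, seed=3,
                                  spacing=251_000)
        ld = integrate.ld_matrix(g, window_bp=500_000)
        got = set(zip(ld["variant_a"], ld["variant_b"]))
        # adjacent pairs are 251 kb apart; the outer pair is 502 kb -> absent
        assert got == {("ld_0000", "ld_0001"), ("ld_0001", "ld_0002")}


class TestGwasOverlap:
    def _ld(self, rows):
        return pd.DataFrame(rows, columns=["variant_a", "variant_b", "r2"])

    def test_overlap_via_self(self):
        gwas = pd.DataFrame({"variant_id": ["v1"], "p": [1e-6]})
        out = integrate.gwas_overlap({"v1"}, gwas, self._ld([]))
        assert out.iloc[0]["proxy"] == "v1"

    def test_overlap_via_proxy_and_orientation_invariance(self):
        gwas = pd.DataFrame({"variant_id": ["v2"], "p": [1e-8]})
        for ld_rows in ([("v1", "v2", 0.95)], [("v2", "v1", 0.95)]):
            out = integrate.gwas_overlap({"v1"}, gwas, self._ld(ld_rows))
            assert list(out["proxy"]) == ["v2"]
        weak = integrate.gwas_overlap({"v1"}, gwas, self._ld([("v1", "v2", 0.5)]))
        assert len(weak) == 0

    def test_no_signal_empty(self):
        gwas = pd.DataFrame({"variant_id": ["v1", "v2"], "p": [0.2, 1e-4]})
        out = integrate.gwas_overlap({"v1"}, gwas, self._ld([("v1", "v2", 0.99)]))
        assert len(out) == 0

    def test_row_order_invariance(self):
        gwas = pd.DataFrame({"variant_id": ["v3", "v2", "v1"],
                             "p": [0.5, 1e-8, 0.9]})
        ld = self._ld([("v1", "v2", 0.95), ("v1", "v3", 0.99)])
        out1 = integrate.gwas_overlap({"v1"}, gwas, ld)
        out2 = integrate.gwas_overlap({"v1"}, gwas.iloc[::-1], ld)
        pd.testing.assert_frame_equal(out1, out2)


class TestInflation:
    def test_all_half_is_exactly_one(self):
        lam, _ = integrate.inflation_lambda(np.full(1000, 0.5))
        assert lam == pytest.approx(1.0, abs=1e-12)

    def test_null_near_one(self):
        rng = np.random.default_rng(4)
        lam, qq = integrate.inflation_lambda(rng.uniform(size=10_000))
        assert lam == pytest.approx(1.0, abs=0.05)
        assert len(qq) == 10_000

    def test_signal_inflates_and_matches_median_ratio(self):
        rng = np.random.default_rng(5)
        p = np.concatenate([rng.uniform(0, 1e-4, 2000), rng.uniform(size=8000)])
        lam, _ = integrate.inflation_lambda(p)
        manual = np.median(stats.chi2.isf(p, 1)) / stats.chi2.ppf(0.5, 1)
        assert lam == pytest.approx(manual, rel=1e-12)
        assert lam > 1.2

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            integrate.inflation_lambda(np.array([]))
        with pytest.raises(ValueError):
            integrate.inflation_lambda(np.array([0.0]))
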