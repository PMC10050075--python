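"""The cis association engine against closed-form and calibration oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crdomics import association as assoc
from crdomics.containers import CRD


def _features(values, pos=None, chrom="1"):
    values = np.asarray(values, dtype=float)
    f = values.shape[0]
    pos = np.asarray(pos if pos is not None else (np.arange(f) + 1) * 1000)
    return assoc.CisFeatures(
        np.array([f"f{i}" for i in range(f)], dtype=object),
        np.array([chrom] * f, dtype=object), pos, values,
    )


class TestActivity:
    def test_single_member_and_mean(self, make_matrix):
        m = make_matrix([[1.0, 3.0], [3.0, 5.0], [10.0, 20.0]])
        crds = [CRD("c0", "1", 0, 500, ["pk000"], 1.0),
                CRD("c1", "1", 0, 10500, ["pk000", "pk001"], 0.9)]
        act = assoc.crd_activity(m, crds)
        np.testing.assert_allclose(act.row("c0"), [1.0, 3.0])
        np.testing.assert_allclose(act.row("c1"), [2.0, 4.0])

    def test_matches_bruteforce_mean(self, make_matrix):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(10, 8)))
        members = [f"pk{i:03d}" for i in rng.choice(10, size=6, replace=False)]
        act = assoc.crd_activity(m, [CRD("c", "1", 0, 1000, members, 0.5)])
        manual = np.mean([m.row(x) for x in members], axis=0)
        np.testing.assert_allclose(act.values[0], manual)

    def test_missing_member_reported(self, make_matrix):
        m = make_matrix(np.zeros((2, 3)))
        with pytest.raises(KeyError, match="ghost"):
            assoc.crd_activity(m, [CRD("cX", "1", 0, 1, ["ghost"], 0.0)])


class TestCisScan:
    def test_matches_linregress(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=10)
        x = np.vstack([rng.normal(size=10) for _ in range(4)])
        hit = assoc.cis_scan(y, _features(x))
        best = min(range(4), key=lambda i: stats.linregress(x[i], y).pvalue)
        ref = stats.linregress(x[best], y)
        assert hit.feature_id == f"f{best}"
        assert hit.slope == pytest.approx(ref.slope, rel=1e-10)
        assert hit.nominal_p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_identical_feature_wins_hard(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=50)
        x = np.vstack([rng.normal(size=50), y])
        hit = assoc.cis_scan(y, _features(x))
        assert hit.feature_id == "f1"
        assert hit.nominal_p < 1e-30

    def test_window_boundary_one_megabase(self):
        feats = _features(np.random.default_rng(3).normal(size=(3, 5)),
                          pos=[900_000, 1_000_500, 1_000_501])
        # anchor interval [0, 500): positions up to end + 1 Mb = 1_000_500
        win = feats.in_window("1", 0, 500, 1_000_000)
        assert list(win.ids) == ["f0", "f1"]  # f2 is 1 bp beyond the window

    def test_empty_window_and_zero_variance(self):
        y = np.random.default_rng(4).normal(size=6)
        assert assoc.cis_scan(y, _features(np.empty((0, 6)))) is None
        only_flat = _features(np.ones((1, 6)))
        assert assoc.cis_scan(y, only_flat) is None


class TestPermutationAdjust:
    def test_floor_when_observed_beats_all(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=80)
        x = np.vstack([y + 0.01 * rng.normal(size=80)] +
                      [rng.normal(size=80) for _ in range(9)])
        adj = assoc.permutation_adjust(y, _features(x), n_perm=1000, seed=0)
        assert adj == pytest.approx(1 / 1001)

    def test_null_adjusted_pvalues_uniform(self):
        rng = np.random.default_rng(6)
        n, n_feat = 60, 20
        perms = assoc.make_permutations(n, 300, seed=1)
        adj = []
        for _ in range(150):
            y = rng.normal(size=n)
            x = rng.normal(size=(n_feat, n))
            adj.append(assoc.permutation_adjust(y, _features(x), perm_indices=perms))
        assert stats.kstest(adj, "uniform").pvalue > 0.01

    def test_adjusted_geq_nominal_best(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            y = rng.normal(size=40)
            x = rng.normal(size=(15, 40))
            feats = _features(x)
            hit = assoc.cis_scan(y, feats)
            adj = assoc.permutation_adjust(y, feats, n_perm=200, seed=2)
            assert adj >= 1 / 201
            assert adj >= hit.nominal_p / 20  # adjusted never wildly anti-conservative


class TestFdr:
    def test_all_ones_no_discoveries(self):
        q, sig, _ = assoc.fdr_qvalue(np.ones(100))
        assert not sig.any()

    def test_bh_stepup_toy(self):
        q, sig, pi0 = assoc.fdr_qvalue(np.array([0.01, 0.02, 0.03, 0.04]),
                                       method="bh", level=0.05)
        assert sig.all() and pi0 == 1.0

    def test_known_mixture_pi0(self):
        rng = np.random.default_rng(8)
        p = np.concatenate([rng.uniform(0, 1e-8, 3000), rng.uniform(0, 1, 7000)])
        _, _, pi0 = assoc.fdr_qvalue(p)
        assert 0.65 <= pi0 <= 0.75

    def test_storey_no_larger_than_bh(self):
        rng = np.random.default_rng(9)
        p = np.concatenate([rng.uniform(0, 1e-6, 300), rng.uniform(0, 1, 700)])
        q_s, _, pi0 = assoc.fdr_qvalue(p, method="storey")
        q_b, _, _ = assoc.fdr_qvalue(p, method="bh")
        assert pi0 < 1
        assert np.all(q_s <= q_b + 1e-12)

    def test_empty_and_invalid(self):
        q, sig, _ = assoc.fdr_qvalue(np.array([]))
        assert len(q) == 0 and len(sig) == 0
        with pytest.raises(ValueError):
            assoc.fdr_qvalue(np.array([1.5]))


class TestConditional:
    def test_two_independent_signals_recovered(self):
        rng = np.random.default_rng(10)
        n = 200
        f = rng.normal(size=(20, n))
        y = 0.5 * f[3] + 0.5 * f[11] + np.sqrt(0.5) * rng.normal(size=n)
        feats = _features(f)
        perms = assoc.make_permutations(n, 500, seed=3)
        hits = assoc.conditional_scan(y, feats, adjusted_p_threshold=0.01,
                                      perm_indices=perms)
        assert {h.feature_id for h in hits} == {"f3", "f11"}

    def test_single_signal_single_record(self):
        rng = np.random.default_rng(11)
        n = 150
        f = rng.normal(size=(10, n))
        y = 0.7 * f[2] + 0.6 * rng.normal(size=n)
        perms = assoc.make_permutations(n, 500, seed=4)
        hits = assoc.conditional_scan(y, _features(f), 0.01, perms)
        assert [h.feature_id for h in hits] == ["f2"]

    def test_null_yields_nothing(self):
        rng = np.random.default_rng(12)
        n = 100
        perms = assoc.make_permutations(n, 300, seed=5)
        hits = assoc.conditional_scan(rng.normal(size=n),
                                      _features(rng.normal(size=(10, n))),
                                      0.005, perms)
        assert hits == []


class TestMapCis:
    def _population(self, seed, n=120, n_phen=30, causal=0, h2=0.3):
        rng = np.random.default_rng(seed)
        from crdomics.containers import QuantificationMatrix

        dos = rng.binomial(2, 0.3, size=(n_phen, n)).astype(float)
        z = (dos - dos.mean(axis=1, keepdims=True)) / dos.std(axis=1, keepdims=True)
        values = rng.standard_normal((n_phen, n))
        for i in range(causal):
            values[i] = np.sqrt(h2) * z[i] + np.sqrt(1 - h2) * values[i]
        phen = QuantificationMatrix(
            np.array([f"p{i}" for i in range(n_phen)], dtype=object),
            np.array([str(1 + i // 10) for i in range(n_phen)], dtype=object),
            np.array([(i % 10) * 50_000 for i in range(n_phen)]),
            np.array([(i % 10) * 50_000 + 500 for i in range(n_phen)]),
            values, [f"S{j}" for j in range(n)], "peak")
        feats = assoc.CisFeatures(
            np.array([f"v{i}" for i in range(n_phen)], dtype=object),
            phen.chrom.copy(), phen.start + 250, dos)
        return phen, feats

    def test_planted_qtls_found_nulls_controlled(self):
        phen, feats = self._population(seed=13, causal=6)
        res = assoc.map_cis(phen, feats, n_perm=500, fdr=0.05, seed=6)
        sig = set(res[res["significant"]]["phenotype_id"])
        assert {f"p{i}" for i in range(6)} <= sig
        assert len(sig - {f"p{i}" for i in range(6)}) <= 2

    def test_seed_reproducibility(self):
        phen, feats = self._population(seed=14, causal=2)
        a = assoc.map_cis(phen, feats, n_perm=200, seed=7)
        b = assoc.map_cis(phen, feats, n_perm=200, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_conditional_rank_records(self):
        rng = np.random.default_rng(15)
        from crdomics.containers import QuantificationMatrix

        n = 200
        f = rng.normal(size=(15, n))
        y = 0.55 * f[2] + 0.55 * f[9] + 0.6 * rng.normal(size=n)
        phen = QuantificationMatrix(
            np.array(["p0"], dtype=object), np.array(["1"], dtype=object),
            np.array([0]), np.array([500]), y[None, :],
            [f"S{j}" for j in range(n)], "peak")
        feats = _features(f)
        res = assoc.map_cis(phen, feats, n_perm=300, fdr=0.05, seed=8,
                            conditional=True)
        assert (res["rank"] == 0).sum() == 1
        assert (res["rank"] == 1).sum() == 1
        assert set(res["feature_id"]) == {"f2", "f9"}


class TestCoexpression:
    def test_duplicated_gene_significant(self, make_matrix):
        rng = np.random.default_rng(16)
        base = rng.normal(size=80)
        rows = np.vstack([base, base] + [rng.normal(size=80) for _ in range(40)])
        expr = make_matrix(rows, phenotype_class="gene",
                           ids=[f"g{i}" for i in range(42)])
        pairs = assoc.coexpression_pairs(expr, max_distance_bp=2_000_000)
        top = pairs[(pairs["gene_a"] == "g0") & (pairs["gene_b"] == "g1")]
        assert top["r"].iloc[0] == pytest.approx(1.0)
        assert bool(top["significant"].iloc[0])

    def test_distance_cap(self, make_matrix):
        rng = np.random.default_rng(17)
        expr = make_matrix(rng.normal(size=(3, 30)), phenotype_class="gene",
                           ids=["a", "b", "c"], start=[0, 500_000, 1_400_000],
                           end=[1000, 501_000, 1_401_000])
        pairs = assoc.coexpression_pairs(expr, max_distance_bp=1_000_000)
        got = set(zip(pairs["gene_a"], pairs["gene_b"]))
        assert got == {("a", "b"), ("b", "c")}  # a-c is 1.4 Mb apart


class TestSameCrdEnrichment:
    def test_toy_matches_enumeration(self):
        # 6 genes, 2 CRDs; genes g0,g1 -> c0; g2,g3 -> c1; g4,g5 none
        pairs = pd.DataFrame({
            "gene_a": ["g0", "g0", "g2", "g4"],
            "gene_b": ["g1", "g2", "g3", "g5"],
            "significant": [True, True, True, False],
            "distance": [10_000] * 4,
        })
        crd_gene = pd.DataFrame({
            "phenotype_id": ["c0", "c0", "c1", "c1"],
            "feature_id": ["g0", "g1", "g2", "g3"],
            "significant": [True] * 4,
            "rank": [0] * 4,
        })
        out = assoc.same_crd_enrichment(pairs, crd_gene, bins=[0, 100_000])
        # of 3 co-expressed pairs, 2 share a CRD (g0-g1 via c0, g2-g3 via c1)
        assert out["fraction_same_crd"].iloc[0] == pytest.approx(2 / 3)
        # 2x2 with zero cells -> Haldane: (2.5*1.5)/(1.5*0.5)
        assert out["odds_ratio"].iloc[0] == pytest.approx((2.5 * 1.5) / (1.5 * 0.5))

    def test_no_shared_crds_zero_fraction(self):
        pairs = pd.DataFrame({"gene_a": ["g0"], "gene_b": ["g1"],
                              "significant": [True], "distance": [5_000]})
        crd_gene = pd.DataFrame({"phenotype_id": ["c0"], "feature_id": ["g0"],
                                 "significant": [True], "rank": [0]})
        out = assoc.same_crd_enrichment(pairs, crd_gene, bins=[0, 10_000])
        assert out["fraction_same_crd"].iloc[0] == 0.0

    def test_empty_bin_is_missing(self):
        pairs = pd.DataFrame({"gene_a": [], "gene_b": [], "significant": [],
                              "distance": []})
        out = assoc.same_crd_enrichment(
            pairs, pd.DataFrame(columns=["phenotype_id", "feature_id",
                                         "significant", "rank"]),
            bins=[0, 1000])
        assert np.isnan(out["fraction_same_crd"].iloc[0])
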