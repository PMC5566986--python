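import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats as sps

import dyadscan as ds
from dyadscan.dyad import NotEvaluableError, _benjamini_hochberg
from dyadscan.io_model import DesignError

import oracles


# a fixed 6-vs-6 bivariate fixture with a visible but not overwhelming shift
FIX_A = np.array([
    [2.1, 3.0], [2.9, 3.8], [1.7, 2.6], [2.4, 3.9], [3.1, 4.4], [2.6, 3.1],
])
FIX_B = np.array([
    [1.2, 2.1], [0.8, 1.4], [1.9, 2.8], [1.1, 2.6], [0.4, 1.1], [1.5, 2.0],
])


class TestHotelling:
    def test_identical_groups_give_zero(self):
        res = ds.hotelling_two_sample(FIX_A, FIX_A)
        assert res.t2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_permuted_copy_with_same_moments(self):
        res = ds.hotelling_two_sample(FIX_A, FIX_A[::-1])
        assert res.t2 == pytest.approx(0.0, abs=1e-12)

    def test_univariate_case_is_squared_pooled_t(self):
        xa, xb = FIX_A[:, :1], FIX_B[:, :1]
        res = ds.hotelling_two_sample(xa, xb)
        t_ref = sps.ttest_ind(xa.ravel(), xb.ravel(), equal_var=True)
        assert res.t2 == pytest.approx(t_ref.statistic**2, rel=1e-12)
        assert res.p_value == pytest.approx(t_ref.pvalue, rel=1e-10)

    def test_fixture_matches_brute_force_and_trace_route(self):
        res = ds.hotelling_two_sample(FIX_A, FIX_B)
        t2, f, df1, df2 = oracles.hotelling_brute(FIX_A, FIX_B)
        assert res.t2 == pytest.approx(t2, rel=1e-12)
        assert res.f_stat == pytest.approx(f, rel=1e-12)
        assert (res.df1, res.df2) == (df1, df2)
        # Hotelling-Lawley trace route gives the same F
        assert res.f_stat == pytest.approx(
            res.hl_trace * res.df2 / res.df1, rel=1e-12
        )
        assert res.p_value == pytest.approx(sps.f.sf(f, df1, df2), rel=1e-12)

    def test_fixture_null_sampling_p_within_monte_carlo_error(self):
        """The sampling distribution of T^2 under the Gaussian null is an
        exact scaled F, so a fresh-data Monte-Carlo tail estimate must
        agree with the parametric p up to binomial noise."""
        res = ds.hotelling_two_sample(FIX_A, FIX_B)
        rng = np.random.default_rng(77)
        p_mc = oracles.null_sampling_p(res.t2, 6, 6, 100_000, rng)
        se = np.sqrt(max(p_mc * (1 - p_mc), 1e-12) / 100_000)
        assert abs(res.p_value - p_mc) <= 3 * se

    def test_fixture_permutation_p_is_consistent(self):
        """The label-permutation p-value is conditional on the data and
        agrees with the marginal F p-value only to O(1/n); at n = 12 they
        must still be close."""
        res = ds.hotelling_two_sample(FIX_A, FIX_B)
        rng = np.random.default_rng(78)
        p_perm = oracles.permutation_p(FIX_A, FIX_B, 20_000, rng)
        assert abs(res.p_value - p_perm) < 0.05

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_invariant_under_common_linear_transform(self, seed):
        r = np.random.default_rng(seed)
        xa = r.standard_normal((8, 2)) + [1.0, 0.5]
        xb = r.standard_normal((10, 2))
        A = r.standard_normal((2, 2))
        while abs(np.linalg.det(A)) < 0.1:
            A = r.standard_normal((2, 2))
        base = ds.hotelling_two_sample(xa, xb)
        trans = ds.hotelling_two_sample(xa @ A, xb @ A)
        assert trans.t2 == pytest.approx(base.t2, rel=1e-9)
        assert trans.p_value == pytest.approx(base.p_value, rel=1e-9)

    def test_symmetric_in_variable_order(self):
        res = ds.hotelling_two_sample(FIX_A, FIX_B)
        swapped = ds.hotelling_two_sample(FIX_A[:, ::-1], FIX_B[:, ::-1])
        assert swapped.t2 == pytest.approx(res.t2, rel=1e-12)

    def test_constant_gene_not_evaluable(self):
        xa = FIX_A.copy()
        xa[:, 0] = 1.0
        xb = FIX_B.copy()
        xb[:, 0] = 1.0
        with pytest.raises(NotEvaluableError):
            ds.hotelling_two_sample(xa, xb)

    def test_collinear_pair_not_evaluable(self):
        xa = np.column_stack([FIX_A[:, 0], 2 * FIX_A[:, 0]])
        xb = np.column_stack([FIX_B[:, 0], 2 * FIX_B[:, 0]])
        with pytest.raises(NotEvaluableError):
            ds.hotelling_two_sample(xa, xb)

    def test_too_small_groups_rejected(self):
        with pytest.raises(DesignError):
            ds.hotelling_two_sample(FIX_A[:2], FIX_B)


class TestFUpperTail:
    def test_zero_statistic_gives_one(self):
        assert ds.f_upper_tail(0.0, 2, 10) == 1.0

    def test_closed_form_value(self):
        # df1=2: sf(x) = (d2/(d2+2x))^(d2/2); at x=5, d2=10 this is 2^-5
        assert ds.f_upper_tail(5.0, 2, 10) == pytest.approx(1 / 32, rel=1e-12)

    def test_negative_statistic_rejected(self):
        with pytest.raises(DesignError):
            ds.f_upper_tail(-0.5, 2, 10)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_matches_quadrature_of_density(self, seed):
        r = np.random.default_rng(seed)
        d1 = int(r.integers(1, 8))
        d2 = int(r.integers(2, 60))
        x = float(r.uniform(0, 8))
        q, _ = integrate.quad(oracles.f_density, x, np.inf, args=(d1, d2), limit=200)
        assert ds.f_upper_tail(x, d1, d2) == pytest.approx(q, abs=1e-8)


class TestPearsonTumor:
    def test_perfect_linear_dependence(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        res = ds.pearson_tumor(x, 2 * x + 1)
        assert res.r == 1.0
        anti = ds.pearson_tumor(x, -x)
        assert anti.r == -1.0

    def test_eight_point_fixture_matches_reference(self):
        x = np.array([0.2, 1.5, 2.2, 3.9, 4.1, 5.8, 6.3, 7.9])
        y = np.array([1.1, 0.8, 2.9, 3.2, 5.1, 4.7, 6.6, 7.2])
        res = ds.pearson_tumor(x, y)
        ref_r, ref_p = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref_r, rel=1e-10)
        assert res.p_value == pytest.approx(ref_p, rel=1e-10)
        assert res.df == 6

    def test_constant_vector_not_evaluable(self):
        with pytest.raises(NotEvaluableError):
            ds.pearson_tumor([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _make_dyad(ga, gb, f=10.0, p=0.001, r=0.8, rp=0.01, n1=10, n2=10):
    t2 = f * 2 * (n1 + n2 - 2) / (n1 + n2 - 3)
    hot = ds.HotellingResult(
        t2=t2, f_stat=f, df1=2, df2=n1 + n2 - 3, p_value=p,
        n1=n1, n2=n2, hl_trace=t2 / (n1 + n2 - 2),
    )
    cor = ds.CorrelationResult(r=r, t_stat=1.0, df=n1 - 2, p_value=rp)
    return ds.DyadResult(gene_a=ga, gene_b=gb, hotelling=hot, correlation=cor)


def _make_gstats(gene, med=3.0, fc=3.0, fcb=3.0, vital=0.5):
    return ds.GeneStats(
        gene_id=gene, median_log2_tumor=med, median_tumor_fpkm=2**med - 1,
        logfc_vs_normal=fc, logfc_vs_brain=fcb, max_vital_fpkm=vital,
        t_stat=5.0, df=20.0, p_value=1e-6, passes_screen=True,
    )


class TestDyadScan:
    def test_two_genes_give_one_dyad(self, rng):
        vals = rng.uniform(1, 20, size=(2, 12))
        genes = ["gA", "gB"]
        cols = [f"t{i}" for i in range(6)] + [f"n{i}" for i in range(6)]
        m = ds.ExpressionMatrix(
            pd.DataFrame(vals, index=genes, columns=cols), scale="fpkm"
        )
        s = ds.SampleTable(pd.DataFrame(
            [{"sample_id": c,
              "group": "tumor" if c.startswith("t") else "normal",
              "cohort": "C" if c.startswith("t") else ""} for c in cols]
        ))
        out = ds.dyad_scan(ds.log2_transform(m), s, "C", ds.Thresholds())
        assert len(out) == 1
        assert (out[0].gene_a, out[0].gene_b) == ("gA", "gB")

    def test_27_genes_give_351_attempted_pairs(self, rng):
        vals = rng.uniform(1, 20, size=(27, 20))
        genes = [f"g{i:02d}" for i in range(27)]
        cols = [f"t{i}" for i in range(10)] + [f"n{i}" for i in range(10)]
        m = ds.ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=cols))
        s = ds.SampleTable(pd.DataFrame(
            [{"sample_id": c,
              "group": "tumor" if c.startswith("t") else "normal",
              "cohort": "C" if c.startswith("t") else ""} for c in cols]
        ))
        out = ds.dyad_scan(ds.log2_transform(m), s, "C", ds.Thresholds())
        assert len(out) == 27 * 26 // 2 == 351

    def test_planted_pairs_all_attempted(self, small_run):
        pairs = {(d.gene_a, d.gene_b) for d in small_run["dyads"]}
        assert set(small_run["truth"].planted_dyads) <= pairs

    def test_fpkm_scale_matrix_rejected(self, small_dataset):
        _, matrix, samples, _, _ = small_dataset
        with pytest.raises(DesignError):
            ds.dyad_scan(matrix, samples, "MYCN_NA", ds.Thresholds())


class TestApplyFilters:
    def test_weak_hotelling_fails_filter_a(self):
        dy = _make_dyad("g1", "g2", p=0.5)
        out = ds.apply_filters([dy], [_make_gstats("g1"), _make_gstats("g2")],
                               ds.Thresholds())
        assert "a" in out[0].filter_failures
        assert not out[0].passed_filters

    def test_vital_ceiling_loosening_admits_borderline_gene(self):
        """A pair with one member at vital-organ median FPKM 1.5 fails the
        ceiling at 1.0 but passes at 2.0."""
        dy = _make_dyad("g1", "g2")
        gstats = [_make_gstats("g1", vital=1.5), _make_gstats("g2", vital=0.3)]
        strict = ds.apply_filters([dy], gstats, ds.Thresholds(vital_fpkm_max=1.0))
        loose = ds.apply_filters([dy], gstats, ds.Thresholds(vital_fpkm_max=2.0))
        assert strict[0].filter_failures == ["f"]
        assert loose[0].passed_filters

    def test_missing_gene_stats_named(self):
        with pytest.raises(DesignError, match="g2"):
            ds.apply_filters([_make_dyad("g1", "g2")], [_make_gstats("g1")],
                             ds.Thresholds())

    def test_randomized_dyads_match_brute_force_filtering(self, rng):
        th = ds.Thresholds()
        genes = [f"g{i:03d}" for i in range(40)]
        gstats = [
            _make_gstats(
                g,
                med=rng.uniform(0, 5),
                fc=rng.uniform(0, 5),
                fcb=rng.uniform(0, 5),
                vital=rng.uniform(0, 3),
            )
            for g in genes
        ]
        by_gene = {g.gene_id: g for g in gstats}
        dyads = []
        for _ in range(100):
            ga, gb = sorted(rng.choice(genes, size=2, replace=False))
            dyads.append(_make_dyad(
                ga, gb, p=float(rng.uniform(0, 0.05)),
                rp=float(rng.uniform(0, 0.2)),
            ))
        out = ds.apply_filters(dyads, gstats, th)
        for dy in out:
            a, b = by_gene[dy.gene_a], by_gene[dy.gene_b]
            expected = (
                dy.hotelling.p_value <= 0.01
                and dy.correlation.p_value <= 0.05
                and min(a.median_log2_tumor, b.median_log2_tumor) >= 2
                and min(a.logfc_vs_normal, b.logfc_vs_normal) >= 2
                and min(a.logfc_vs_brain, b.logfc_vs_brain) >= 2
                and max(a.max_vital_fpkm, b.max_vital_fpkm) <= 1.0
            )
            assert dy.passed_filters == expected
            assert dy.passed_filters == (not dy.filter_failures)


class TestRankDyads:
    def test_empty_input(self):
        ranked, summary = ds.rank_dyads([])
        assert ranked == []
        assert summary == {"n_pairs": 0, "n_unique_genes": 0}

    def test_order_by_f_then_p(self):
        d1 = _make_dyad("a", "b", f=10.0, p=1e-5)
        d2 = _make_dyad("c", "d", f=5.0, p=1e-4)
        d3 = _make_dyad("e", "f", f=5.0, p=1e-6)
        for d in (d1, d2, d3):
            d.passed_filters = True
        ranked, summary = ds.rank_dyads([d2, d3, d1])
        assert [d.pair for d in ranked] == ["a_b", "e_f", "c_d"]
        assert [d.rank for d in ranked] == [1, 2, 3]
        assert summary == {"n_pairs": 3, "n_unique_genes": 6}

    def test_unique_gene_count_matches_set_union(self, small_run):
        ranked = small_run["ranked"]
        union = set()
        for d in ranked:
            union |= {d.gene_a, d.gene_b}
        assert small_run["summary"]["n_unique_genes"] == len(union)

    def test_only_passing_dyads_are_ranked(self, small_run):
        for d in small_run["dyads"]:
            if not d.passed_filters:
                assert d.rank is None


class TestCompareCohorts:
    def _ranked(self, pairs):
        out = []
        for i, (a, b) in enumerate(pairs):
            d = _make_dyad(a, b)
            d.passed_filters = True
            d.rank = i + 1
            out.append(d)
        return out

    def test_identical_lists_fully_shared(self):
        pairs = [("a", "b"), ("c", "d")]
        rep = ds.compare_cohorts(self._ranked(pairs), self._ranked(pairs))
        assert list(rep["pair"]) == ["a_b", "c_d"]

    def test_disjoint_lists_share_nothing(self):
        rep = ds.compare_cohorts(
            self._ranked([("a", "b")]), self._ranked([("c", "d")])
        )
        assert rep.empty

    def test_28_and_45_pair_lists_with_nine_common(self):
        shared = [(f"s{i:02d}", f"t{i:02d}") for i in range(9)]
        only_a = [(f"a{i:02d}", f"b{i:02d}") for i in range(19)]
        only_b = [(f"c{i:02d}", f"d{i:02d}") for i in range(36)]
        rep = ds.compare_cohorts(
            self._ranked(shared + only_a), self._ranked(only_b + shared)
        )
        assert len(rep) == 9
        assert set(rep["pair"]) == {f"s{i:02d}_t{i:02d}" for i in range(9)}


def test_benjamini_hochberg_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests
    p = rng.uniform(0, 1, size=37)
    ours = _benjamini_hochberg(p)
    _, ref, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(ours, ref, rtol=1e-12)
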