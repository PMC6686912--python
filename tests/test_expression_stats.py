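import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gbmc import (
    CountMatrix,
    bootstrap_mean_diff,
    chi_square_independence,
    clamp_differences,
    cohens_d,
    cpm_filter,
    discrete_diff_classes,
    equalize_coverage,
    fpkm_from_counts,
    log_transform,
    mean_difference,
    proportion_and_ratio,
    tmm_factors,
    wilcoxon_signed_rank,
)
from gbmc.expression_stats import effect_category


def make_cm(counts, lengths=None, lib_sizes=None):
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(len(df))]
    lengths = pd.Series(
        lengths if lengths is not None else 1000, index=df.index
    )
    if lib_sizes is not None:
        lib_sizes = pd.Series(lib_sizes, index=df.columns)
    return CountMatrix(df, lengths, lib_sizes)


class TestTransforms:
    def test_fpkm_arithmetic(self):
        cm = make_cm({"s1": [10]}, lengths=[1000], lib_sizes={"s1": 1e6})
        assert fpkm_from_counts(cm).values.iloc[0, 0] == pytest.approx(10.0)

    def test_fpkm_zero_count(self):
        cm = make_cm({"s1": [0, 5]}, lib_sizes={"s1": 1e6})
        assert fpkm_from_counts(cm).values.iloc[0, 0] == 0.0

    def test_fpkm_scale_invariance(self):
        cm1 = make_cm({"s1": [10, 30]}, lib_sizes={"s1": 40.0})
        cm2 = make_cm({"s1": [20, 60]}, lib_sizes={"s1": 80.0})
        pd.testing.assert_frame_equal(
            fpkm_from_counts(cm1).values, fpkm_from_counts(cm2).values
        )

    @pytest.mark.parametrize("x,expected", [(0, 0), (9, 1), (99, 2)])
    def test_log10p1_values(self, x, expected):
        cm = make_cm({"s1": [1]})
        em = fpkm_from_counts(cm)
        em.values.iloc[0, 0] = x
        assert log_transform(em).values.iloc[0, 0] == pytest.approx(expected)

    def test_double_transform_rejected(self):
        em = log_transform(fpkm_from_counts(make_cm({"s1": [1, 2]})))
        with pytest.raises(ValueError):
            log_transform(em)

    def test_cpm_filter_keeps_gene_expressed_in_two_libraries(self):
        cm = make_cm(
            {"s1": [15, 15, 500], "s2": [15, 1, 500], "s3": [1, 1, 500]},
            lib_sizes={"s1": 1e7, "s2": 1e7, "s3": 1e7},
        )
        kept = cpm_filter(cm, min_cpm=1.0, min_libraries=2)
        assert list(kept.genes) == ["g0", "g2"]

    def test_cpm_filter_zero_min_libraries_keeps_all(self):
        cm = make_cm({"s1": [0, 0], "s2": [0, 1]})
        assert len(cpm_filter(cm, 1.0, 0).genes) == 2


class TestTMM:
    def toy(self):
        # deterministic 200-gene toy: depth change in s2, 5% of genes
        # 8-fold up in s3 (composition effect)
        rng = np.random.default_rng(42)
        base = rng.lognormal(4, 1.2, 200).round().astype(int) + 1
        counts = pd.DataFrame(
            {
                "s1": rng.poisson(base),
                "s2": rng.poisson(base * 2),
                "s3": rng.poisson(np.where(np.arange(200) < 10, base * 8, base)),
                "s4": rng.poisson(base),
            },
            index=[f"g{i}" for i in range(200)],
        )
        return CountMatrix(counts, pd.Series(1000, index=counts.index))

    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [5, 10, 100], "s2": [5, 10, 100]})
        cm = CountMatrix(counts, pd.Series(1000, index=counts.index))
        assert tmm_factors(cm).to_numpy() == pytest.approx([1.0, 1.0])

    def test_pure_depth_change_gives_unit_factors(self):
        counts = pd.DataFrame(
            {"s1": [10, 50, 200, 40, 5, 80, 120, 60, 30, 90]}
        )
        counts["s2"] = counts["s1"] * 2
        cm = CountMatrix(counts, pd.Series(1000, index=counts.index))
        assert tmm_factors(cm).to_numpy() == pytest.approx([1.0, 1.0])

    def test_matches_edger_reference_on_frozen_toy(self):
        # expected factors computed with edgeR 4.0.16 calcNormFactors
        # (method="TMM") on this exact matrix
        expected = [1.0430164930, 1.0507808025, 0.8744816843, 1.0433883340]
        got = tmm_factors(self.toy())
        assert got.to_numpy() == pytest.approx(expected, rel=5e-7)

    def test_composition_effect_pulls_factor_below_one(self):
        f = tmm_factors(self.toy())
        assert f["s3"] < 1.0

    def test_single_sample_rejected(self):
        cm = make_cm({"s1": [1, 2]})
        with pytest.raises(ValueError):
            tmm_factors(cm)


class TestEqualizeCoverage:
    def test_target_equal_to_libsize_is_identity(self):
        cm = make_cm({"s1": [10, 20, 30]})
        out = equalize_coverage(cm, target_depth=60, seed=1)
        pd.testing.assert_frame_equal(out.counts, cm.counts)

    def test_same_seed_reproduces(self):
        cm = make_cm({"s1": [100, 200, 300], "s2": [50, 60, 700]})
        a = equalize_coverage(cm, 400, seed=9).counts
        b = equalize_coverage(cm, 400, seed=9).counts
        pd.testing.assert_frame_equal(a, b)

    def test_halving_depth_halves_expectations(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame({"s1": rng.poisson(200, 500)})
        cm = CountMatrix(counts, pd.Series(1000, index=counts.index))
        lib = float(cm.lib_sizes.iloc[0])
        target = int(lib // 2)
        out = equalize_coverage(cm, target, seed=3)
        total = out.counts["s1"].sum()
        sd = np.sqrt(lib * 0.5 * 0.5)
        assert abs(total - target) < 3 * sd

    def test_thinning_unbiased_on_fpkm_scale(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame({"s1": rng.poisson(500, 400)})
        cm = CountMatrix(counts, pd.Series(1000, index=counts.index))
        lib = float(cm.lib_sizes.iloc[0])
        fpkm0 = fpkm_from_counts(cm).values["s1"]
        thinned = equalize_coverage(cm, int(lib // 4), seed=2)
        # recompute FPKM against the thinned library's own size
        fpkm1 = fpkm_from_counts(thinned).values["s1"]
        assert fpkm1.mean() == pytest.approx(fpkm0.mean(), rel=0.02)

    def test_target_above_libsize_rejected(self):
        cm = make_cm({"s1": [1, 2]})
        with pytest.raises(ValueError):
            equalize_coverage(cm, 100, seed=0)


class TestMeanDifference:
    def test_identical_vectors_zero(self):
        assert mean_difference([1.0, 2.0], [1.0, 2.0], paired=True) == 0.0

    def test_paired_shift(self):
        assert mean_difference([1, 2], [0, 1], paired=True) == 1.0

    def test_unpaired_allows_unequal_lengths(self):
        assert mean_difference([2, 4], [1, 2, 3]) == pytest.approx(1.0)

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mean_difference([1, 2], [1], paired=True)


class TestBootstrap:
    def test_constant_identical_vectors(self):
        x = np.full(20, 3.0)
        res = bootstrap_mean_diff(x, x.copy(), n_reps=200, seed=1)
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=50), rng.normal(size=60)
        a = bootstrap_mean_diff(x, y, seed=123)
        b = bootstrap_mean_diff(x, y, seed=123)
        assert a.p_value == b.p_value and a.observed == b.observed

    def test_detects_large_shift(self):
        rng = np.random.default_rng(1)
        x = rng.normal(1.0, 0.2, 300)
        y = rng.normal(0.0, 0.2, 300)
        res = bootstrap_mean_diff(x, y, seed=2)
        assert res.p_value < 0.01 and res.direction == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_mean_diff([], [1.0], seed=0)


class TestWilcoxon:
    def test_three_positive_diffs_enumeration(self):
        # 8 sign assignments, two tails of W in {0, 6} -> p = 2/8
        assert wilcoxon_signed_rank([1, 2, 3]).p_value == pytest.approx(0.25)

    def test_symmetric_pair_p_one(self):
        assert wilcoxon_signed_rank([-1, 1]).p_value == pytest.approx(1.0)

    def test_all_zero_degenerate(self):
        res = wilcoxon_signed_rank([0.0, 0.0])
        assert res.p_value == 1.0 and res.extra["degenerate"]

    @pytest.mark.parametrize("n", [5, 8, 10])
    def test_exact_matches_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        d = rng.normal(0.2, 1.0, n).round(2)
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = []
        for mask in range(2 ** len(d)):
            signs = [(mask >> i) & 1 for i in range(len(d))]
            ws.append(sum(r for r, s in zip(ranks, signs) if s))
        ws = np.asarray(ws)
        p_oracle = min(
            1.0,
            2.0 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()),
        )
        assert wilcoxon_signed_rank(d).p_value == pytest.approx(p_oracle)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.3, 1.0, 14)
        ours = wilcoxon_signed_rank(d).p_value
        theirs = stats.wilcoxon(d, method="exact").pvalue
        assert ours == pytest.approx(theirs)

    def test_large_n_close_to_scipy_approx(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0.05, 1.0, 500)
        ours = wilcoxon_signed_rank(d)
        theirs = stats.wilcoxon(d, method="approx", correction=False).pvalue
        assert ours.extra["method"] == "normal_approx"
        assert ours.p_value == pytest.approx(theirs, rel=1e-6)


class TestCohensD:
    def test_identical_distributions_zero_negligible(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        res = cohens_d(x, x.copy())
        assert res.observed == 0.0
        assert res.effect_category == "negligible"

    def test_hand_arithmetic_unit_shift(self):
        res = cohens_d([1, 2, 3], [2, 3, 4])
        assert res.observed == pytest.approx(-1.0)
        assert res.effect_category == "large"
        assert res.direction == -1

    def test_sign_flips_when_swapped(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0.5, 1, 50), rng.normal(0, 1, 50)
        assert cohens_d(x, y).observed == pytest.approx(
            -cohens_d(y, x).observed
        )

    def test_invariant_under_common_shift(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0.5, 1, 50), rng.normal(0, 1, 60)
        assert cohens_d(x + 10, y + 10).observed == pytest.approx(
            cohens_d(x, y).observed
        )

    def test_recovers_half_sd_shift(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0.5, 1.0, 1000)
        y = rng.normal(0.0, 1.0, 1000)
        assert abs(cohens_d(x, y).observed - 0.5) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])

    @pytest.mark.parametrize(
        "d,cat",
        [(0.1, "negligible"), (0.3, "small"), (-0.6, "medium"), (1.2, "large")],
    )
    def test_category_bins(self, d, cat):
        assert effect_category(d) == cat


class TestDiscreteClasses:
    def test_boundary_inclusive_up(self):
        # FPKM 3 vs 1: log2(4/2) = 1 exactly -> counted as up
        c = discrete_diff_classes([3.0], [1.0], 1.0)
        assert (c.n_up, c.n_down, c.n_unchanged) == (1, 0, 0)

    def test_identical_pairs_unchanged(self):
        c = discrete_diff_classes([5.0, 2.0], [5.0, 2.0], 1.0)
        assert c.n_unchanged == 2

    def test_counts_match_per_pair_oracle(self):
        rng = np.random.default_rng(11)
        base = rng.lognormal(1, 1, 100)
        fold = 2.0 ** rng.normal(0, 1.5, 100)
        x = (base + 1) * fold - 1
        x = np.maximum(x, 0)
        c = discrete_diff_classes(x, base, 1.0)
        deltas = np.log2((x + 1) / (base + 1))
        assert c.n_up == int((deltas >= 1).sum())
        assert c.n_down == int((deltas <= -1).sum())
        assert c.n_up + c.n_down + c.n_unchanged == 100

    def test_huge_threshold_all_unchanged(self):
        rng = np.random.default_rng(1)
        x, y = rng.lognormal(size=50), rng.lognormal(size=50)
        c = discrete_diff_classes(x, y, 1e9)
        assert c.n_unchanged == 50

    def test_tiny_threshold_counts_only_exact_zeros_unchanged(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 5.0, 0.5])
        c = discrete_diff_classes(x, y, 1e-12)
        assert c.n_unchanged == 1


class TestClampAndChi2:
    @pytest.mark.parametrize(
        "val,expected", [(1.7, 1.0), (-0.3, -0.3), (-5.0, -1.0)]
    )
    def test_clamp(self, val, expected):
        assert clamp_differences([val], 1.0)[0] == expected

    def test_uniform_table_chi2_zero(self):
        res = chi_square_independence([[10, 10], [10, 10]])
        assert res.observed == 0.0 and res.p_value == 1.0

    def test_hand_expected_count_example(self):
        assert chi_square_independence([[20, 30], [30, 20]]).observed == (
            pytest.approx(4.0)
        )

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 200, 4)
            n = a + b + c + d
            closed = (a * d - b * c) ** 2 * n / (
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            res = chi_square_independence([[a, b], [c, d]])
            assert res.observed == pytest.approx(float(closed), rel=1e-10)

    def test_transposition_invariant(self):
        t = [[20, 35], [15, 60]]
        tt = [[20, 15], [35, 60]]
        assert chi_square_independence(t).observed == pytest.approx(
            chi_square_independence(tt).observed
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [5, 10]])


class TestProportions:
    def test_deg_share_example(self):
        rep = proportion_and_ratio([135, 926])
        assert rep.percents == [12.72, 87.28]

    def test_three_to_two_ratio(self):
        rep = proportion_and_ratio([81, 54])
        assert rep.pairwise_ratios[(0, 1)] == pytest.approx(1.5)

    def test_zero_count_gives_zero_percent(self):
        assert proportion_and_ratio([0, 10]).percents[0] == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            proportion_and_ratio([0, 0])
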