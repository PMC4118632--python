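"""Statistical layer, cross-checked against independent oracles
(scipy.f_oneway, sklearn's kappa, pingouin's ICC)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pulleyquant.exceptions import UndefinedStatisticError
from pulleyquant.stats import (ContingencyTable, GroupSummary,
                               anova_from_summary, anova_oneway_raw,
                               boxplot_summary, cohens_kappa,
                               contingency_percentages, icc_inter_rater,
                               lsd_pairwise, pearson_corr)

# published group summaries of the severity ratios by pathological grade
SR_SUMMARIES = [GroupSummary("L", 5, 0.14, 0.03),
                GroupSummary("M", 8, 0.20, 0.01),
                GroupSummary("H", 8, 0.26, 0.01)]

STUDY_TABLE = ContingencyTable(
    counts=((5, 0, 0), (3, 5, 0), (0, 1, 7)),
    row_labels=("L", "M", "H"), col_labels=("II", "III", "IV"))


class TestAnova:
    def test_identical_groups_give_zero_f_unit_p(self):
        res = anova_oneway_raw([[1, 2, 3], [1, 2, 3]])
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_within_variance_with_unequal_means_is_degenerate(self):
        res = anova_oneway_raw([[1, 1, 1], [2, 2, 2]])
        assert np.isinf(res.f_statistic)
        assert res.p_value == 0.0 and res.degenerate

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1.0, size=n)
                  for m, n in ((0.0, 7), (0.5, 9), (0.2, 5))]
        res = anova_oneway_raw(groups)
        f, p = sps.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(f, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_summary_form_is_algebraically_identical_to_raw(self):
        """Mean/SD/n summaries reconstruct the raw-sample ANOVA exactly."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = [rng.normal(rng.uniform(-1, 1), rng.uniform(0.2, 2),
                                 size=int(rng.integers(3, 12)))
                      for _ in range(k)]
            raw = anova_oneway_raw(groups)
            summaries = [GroupSummary(str(i), len(g), float(np.mean(g)),
                                      float(np.std(g, ddof=1)))
                         for i, g in enumerate(groups)]
            summ = anova_from_summary(summaries)
            assert summ.f_statistic == pytest.approx(raw.f_statistic,
                                                     rel=1e-10)
            assert summ.p_value == pytest.approx(raw.p_value, rel=1e-10)

    def test_two_groups_f_equals_squared_pooled_t(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 8), rng.normal(0.7, 1, 6)
        res = anova_oneway_raw([a, b])
        t, _ = sps.ttest_ind(a, b)
        assert res.f_statistic == pytest.approx(t**2, rel=1e-12)

    def test_published_severity_summaries_are_highly_significant(self):
        res = anova_from_summary(SR_SUMMARIES)
        assert res.p_value < 0.0001

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_from_summary([GroupSummary("a", 1, 0.0, 0.0),
                                GroupSummary("b", 3, 1.0, 0.5)])


class TestLSD:
    def test_identical_means_give_zero_t_unit_p(self):
        summ = [GroupSummary("a", 5, 1.0, 0.3), GroupSummary("b", 5, 1.0, 0.3)]
        res = lsd_pairwise(summ, mse=0.09, df=8)[0]
        assert res.t_statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_hand_computed_case(self):
        summ = [GroupSummary("a", 2, 0.0, 1.0), GroupSummary("b", 2, 1.0, 1.0)]
        res = lsd_pairwise(summ, mse=1.0, df=18)[0]
        assert abs(res.t_statistic) == pytest.approx(1.0)
        assert res.p_value == pytest.approx(2 * sps.t.sf(1.0, 18), rel=1e-12)

    def test_severity_h_vs_l_is_highly_significant(self):
        anova = anova_from_summary(SR_SUMMARIES)
        pairs = {(r.label_a, r.label_b): r
                 for r in lsd_pairwise(SR_SUMMARIES, anova.mse,
                                       anova.df_within)}
        assert pairs[("L", "H")].p_value < 0.0001

    def test_p_decreases_with_mean_difference(self):
        ps = []
        for diff in (0.1, 0.5, 1.0):
            summ = [GroupSummary("a", 6, 0.0, 0.5),
                    GroupSummary("b", 6, diff, 0.5)]
            ps.append(lsd_pairwise(summ, mse=0.25, df=10)[0].p_value)
        assert ps[0] > ps[1] > ps[2]

    def test_all_pairs_returned(self):
        res = lsd_pairwise(SR_SUMMARIES, mse=0.0003, df=18)
        assert len(res) == 3


class TestKappa:
    def test_study_contingency_reproduces_published_kappa(self):
        res = cohens_kappa(STUDY_TABLE)
        assert round(res.kappa, 3) == 0.717
        assert res.category == "fair to good"

    def test_perfect_diagonal_is_one(self):
        t = ContingencyTable(((7, 0, 0), (0, 7, 0), (0, 0, 7)),
                             ("a", "b", "c"), ("a", "b", "c"))
        res = cohens_kappa(t)
        assert res.kappa == pytest.approx(1.0)
        assert res.category == "excellent"

    def test_independence_is_zero(self):
        t = ContingencyTable(((1, 1), (1, 1)), ("a", "b"), ("a", "b"))
        assert cohens_kappa(t).kappa == pytest.approx(0.0)

    def test_matches_sklearn_on_random_tables(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        for _ in range(20):
            counts = rng.integers(0, 9, size=(3, 3))
            counts[np.diag_indices(3)] += 1   # keep Pe < 1
            y1, y2 = [], []
            for i in range(3):
                for j in range(3):
                    y1 += [i] * counts[i, j]
                    y2 += [j] * counts[i, j]
            t = ContingencyTable(tuple(map(tuple, counts.tolist())),
                                 ("0", "1", "2"), ("0", "1", "2"))
            expected = sklearn_metrics.cohen_kappa_score(
                y1, y2, labels=[0, 1, 2])
            assert cohens_kappa(t).kappa == pytest.approx(expected,
                                                          rel=1e-12)

    @given(perm=st.permutations([0, 1, 2]))
    @settings(deadline=None, max_examples=6, derandomize=True)
    def test_invariant_under_simultaneous_permutation(self, perm):
        arr = np.asarray(STUDY_TABLE.counts)[np.ix_(perm, perm)]
        t = ContingencyTable(tuple(map(tuple, arr.tolist())),
                             ("r0", "r1", "r2"), ("c0", "c1", "c2"))
        assert cohens_kappa(t).kappa == \
            pytest.approx(cohens_kappa(STUDY_TABLE).kappa)

    def test_degenerate_table_raises(self):
        t = ContingencyTable(((3, 0), (0, 0)), ("a", "b"), ("a", "b"))
        with pytest.raises(UndefinedStatisticError):
            cohens_kappa(t)

    def test_non_square_table_rejected(self):
        t = ContingencyTable(((1, 2, 3), (4, 5, 6)),
                             ("a", "b"), ("x", "y", "z"))
        with pytest.raises(ValueError):
            cohens_kappa(t)


class TestICC:
    def test_identical_raters_give_one(self):
        x = np.array([[2, 2], [3, 3], [4, 4], [2, 2]], dtype=float)
        assert icc_inter_rater(x).icc == pytest.approx(1.0)

    def test_pure_noise_rater_drives_icc_toward_zero(self):
        rng = np.random.default_rng(4)
        subjects = rng.normal(0, 0.5, size=60)
        x = np.column_stack([subjects, rng.normal(0, 20, size=60)])
        assert abs(icc_inter_rater(x).icc) < 0.15

    def test_matches_pingouin_two_way_random_absolute_single(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        x = np.array([[9, 2], [1, 10], [8, 8], [2, 6], [7, 8], [3, 4]],
                     dtype=float)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(6), 2),
            "rater": np.tile(["A", "B"], 6),
            "score": x.ravel()})
        icc_table = pingouin.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="score")
        row = icc_table["Type"].isin(["ICC2", "ICC(A,1)"])
        expected = float(icc_table.loc[row, "ICC"].iloc[0])
        assert icc_inter_rater(x).icc == pytest.approx(expected, rel=1e-9)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedStatisticError):
            icc_inter_rater(np.full((4, 2), 3.0))


class TestBoxplot:
    def test_seven_point_example(self):
        res = boxplot_summary([1, 2, 3, 4, 5, 6, 7])
        assert (res.q1, res.median, res.q3) == (2.5, 4.0, 5.5)
        assert res.outliers == ()

    def test_tukey_hinges_variant(self):
        # for even n the hinges sit on data points, unlike interpolation
        res = boxplot_summary([1, 2, 3, 4, 5, 6], quartile_method="tukey")
        assert (res.q1, res.median, res.q3) == (2.0, 3.5, 5.0)
        interp = boxplot_summary([1, 2, 3, 4, 5, 6])
        assert (interp.q1, interp.q3) == (2.25, 4.75)

    def test_constant_vector(self):
        res = boxplot_summary([5.0] * 6)
        assert res.q1 == res.median == res.q3 == 5.0
        assert res.outliers == ()

    def test_extreme_point_is_an_outlier(self):
        res = boxplot_summary([1, 2, 3, 4, 100])
        assert res.outliers == (100.0,)
        assert res.whisker_high <= 4.0

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_whisker_ordering_and_outlier_partition(self, values):
        res = boxplot_summary(values)
        assert res.whisker_low <= res.q1 <= res.median <= res.q3 \
            <= res.whisker_high
        inside = [v for v in values
                  if res.whisker_low <= v <= res.whisker_high]
        assert len(inside) + len(res.outliers) == len(values)


class TestPearsonAndPercentages:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_corr(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_corr(x, -x) == pytest.approx(-1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_corr([1, 1, 1], [1, 2, 3])

    def test_row_percentages_match_published_table(self):
        pct = contingency_percentages(STUDY_TABLE)
        assert pct["row_percentages"][0].tolist() == [100.0, 0.0, 0.0]
        assert pct["row_percentages"][1].tolist() == [37.5, 62.5, 0.0]
        assert pct["row_percentages"][2].tolist() == [0.0, 12.5, 87.5]
        assert pct["col_marginal_percentages"].tolist() == [38.1, 28.6, 33.3]

    def test_zero_row_is_flagged(self):
        t = ContingencyTable(((0, 0), (1, 2)), ("a", "b"), ("x", "y"))
        pct = contingency_percentages(t)
        assert pct["zero_rows"] == ["a"]
        assert np.isnan(pct["row_percentages"][0]).all()
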