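import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from stagescreen.coexpression_screen import (
    UndefinedCorrelationError,
    benjamini_hochberg,
    corr_t_statistic,
    correlate_sources_targets,
    cross_dataset_validate,
    pairwise_pearson,
    pearson_r,
    screen_pathway,
    select_candidates,
    significance_threshold_r,
    summarize_tf,
)
from stagescreen.data_model import (
    ExpressionMatrix,
    GeneCatalog,
    ScreenConfig,
    StageAxis,
    TFSummaryRow,
)


class TestPearson:
    def test_identity_and_mirror(self):
        x = [1.0, 4, 2, 8, 5, 7, 3]
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed_product_moment(self):
        # frozen from a hand evaluation of the product-moment formula
        r = pearson_r([1, 2, 3, 4, 5, 6, 7], [2, 1, 4, 3, 6, 5, 8])
        assert round(r, 3) == 0.896

    @given(st.lists(st.floats(-100, 100), min_size=5, max_size=9, unique=True))
    def test_matches_scipy(self, x):
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(x))
        assert pearson_r(x, y) == pytest.approx(
            stats.pearsonr(x, y).statistic, abs=1e-12)

    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
    def test_positive_affine_invariance(self, a, b):
        x = [1.0, 4, 2, 8, 5, 7, 3]
        y = [3.0, 1, 6, 2, 9, 4, 5]
        base = pearson_r(x, y)
        assert pearson_r([a * v + b for v in x], y) == pytest.approx(base, abs=1e-9)

    def test_zero_variance_flagged_not_zeroed(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1.0] * 7, [1, 2, 3, 4, 5, 6, 7])

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])


class TestTStatistic:
    def test_zero_r(self):
        assert corr_t_statistic(0.0, 7) == 0.0

    def test_half_r_n7(self):
        assert round(corr_t_statistic(0.5, 7), 3) == 1.291

    def test_odd_and_monotone(self):
        rs = [0.1, 0.3, 0.5, 0.7, 0.9]
        ts = [corr_t_statistic(r, 7) for r in rs]
        assert ts == sorted(ts)
        for r, t in zip(rs, ts):
            assert corr_t_statistic(-r, 7) == pytest.approx(-t)

    @pytest.mark.parametrize("r,n", [(1.0, 7), (-1.0, 7), (0.5, 2)])
    def test_domain(self, r, n):
        with pytest.raises(ValueError):
            corr_t_statistic(r, n)


class TestSignificanceThreshold:
    def test_seven_stage_cut(self):
        assert round(significance_threshold_r(7, 0.05), 3) == 0.754

    def test_minimum_df(self):
        assert round(significance_threshold_r(3, 0.05), 3) == 0.997

    def test_monotone_in_n_and_alpha(self):
        assert significance_threshold_r(12, 0.05) < significance_threshold_r(7, 0.05)
        assert significance_threshold_r(7, 0.10) < significance_threshold_r(7, 0.05)

    def test_mutual_inverse_with_t(self):
        for n, alpha in [(7, 0.05), (5, 0.01), (10, 0.1)]:
            r_star = significance_threshold_r(n, alpha)
            t_crit = stats.t.ppf(1 - alpha / 2, df=n - 2)
            assert corr_t_statistic(r_star, n) == pytest.approx(t_crit, abs=1e-9)

    @pytest.mark.parametrize("n,alpha", [(2, 0.05), (7, 0.0), (7, 1.0)])
    def test_domain(self, n, alpha):
        with pytest.raises(ValueError):
            significance_threshold_r(n, alpha)


class TestScreenPathway:
    def test_toy_screen(self, toy_screen_setup):
        m, catalog = toy_screen_setup
        cfg = ScreenConfig(min_rpkm=1.0)
        records = screen_pathway(m, catalog, "ascorbate", cfg)
        tf1 = [r for r in records if r.source_id == "TF1"]
        assert sum(r.significant for r in tf1) == 3
        assert sum(r.significant and r.sign == "positive" for r in tf1) == 2
        assert sum(r.significant and r.sign == "negative" for r in tf1) == 1
        tf2 = [r for r in records if r.source_id == "TF2"]
        assert all(r.excluded_reason is not None for r in tf2)
        assert all("zero-variance" in r.excluded_reason for r in tf2)

    def test_significance_requires_both_conditions(self, toy_screen_setup):
        m, catalog = toy_screen_setup
        # r_threshold 0.9 stricter than the t-test cut at n = 7
        records = screen_pathway(m, catalog, "ascorbate",
                                 ScreenConfig(min_rpkm=1.0, r_threshold=0.9))
        for r in records:
            if r.significant:
                assert abs(r.r) >= 0.9

    def test_empty_universe_errors(self, toy_screen_setup):
        m, catalog = toy_screen_setup
        with pytest.raises(ValueError):
            screen_pathway(m, catalog, "ascorbate", ScreenConfig(min_rpkm=1e6))

    def test_matches_brute_force_loop(self):
        """Vectorised screen == naive per-pair product-moment computation."""
        rng = np.random.default_rng(42)
        axis = StageAxis()
        tf_ids = [f"TF{i}" for i in range(20)]
        sg_ids = [f"SG{i}" for i in range(10)]
        data = pd.DataFrame(rng.uniform(5.0, 500.0, size=(30, 7)),
                            index=tf_ids + sg_ids, columns=list(axis.stages))
        m = ExpressionMatrix("AC", axis, data)
        catalog = GeneCatalog(pathways={"p": sg_ids}, tf_ids=tf_ids)
        cfg = ScreenConfig(min_rpkm=0.0)
        records = {(r.source_id, r.target_id): r
                   for r in screen_pathway(m, catalog, "p", cfg)}
        t_crit = stats.t.ppf(0.975, df=5)
        for tf in tf_ids:
            for sg in sg_ids:
                x, y = data.loc[tf].to_numpy(), data.loc[sg].to_numpy()
                r_naive = (((x - x.mean()) * (y - y.mean())).sum()
                           / math.sqrt(((x - x.mean()) ** 2).sum()
                                       * ((y - y.mean()) ** 2).sum()))
                rec = records[(tf, sg)]
                assert rec.r == pytest.approx(r_naive, abs=1e-12)
                t_naive = r_naive * math.sqrt(5) / math.sqrt(1 - r_naive ** 2)
                assert rec.t_stat == pytest.approx(t_naive, abs=1e-9)
                assert rec.significant == (
                    abs(r_naive) >= 0.8 and abs(t_naive) > t_crit)

    def test_log2_scale_switch_changes_r(self, toy_screen_setup):
        m, catalog = toy_screen_setup
        raw = screen_pathway(m, catalog, "ascorbate", ScreenConfig(min_rpkm=1.0))
        logd = screen_pathway(m, catalog, "ascorbate",
                              ScreenConfig(min_rpkm=1.0,
                                           correlation_scale="log2"))
        r_raw = {(r.source_id, r.target_id): r.r for r in raw
                 if r.excluded_reason is None}
        r_log = {(r.source_id, r.target_id): r.r for r in logd
                 if r.excluded_reason is None}
        # SG1 = c * TF1 is affine on both scales; SG3 = 70 - TF1 is a
        # perfect raw-scale mirror but not affine after log2(x + 1)
        assert r_raw[("TF1", "SG1")] == pytest.approx(1.0)
        assert r_log[("TF1", "SG1")] == pytest.approx(1.0, abs=1e-3)
        assert r_raw[("TF1", "SG3")] == pytest.approx(-1.0)
        assert r_log[("TF1", "SG3")] > -1.0 + 1e-6


class TestSummarizeAndSelect:
    def test_counts_and_notation(self, toy_screen_setup):
        m, catalog = toy_screen_setup
        records = screen_pathway(m, catalog, "ascorbate", ScreenConfig(min_rpkm=1.0))
        rows = {r.tf_id: r for r in summarize_tf(records, catalog)}
        assert rows["TF1"].rendered("AC") == "3(2)"
        assert rows["TF2"].rendered("AC") == "0(0)"
        assert rows["TF1"].family == "MYB"

    def test_positive_plus_negative_equals_correlated(self, toy_screen_setup):
        m, catalog = toy_screen_setup
        records = screen_pathway(m, catalog, "ascorbate", ScreenConfig(min_rpkm=1.0))
        for rec_tf in summarize_tf(records):
            for geno, (n, n_pos) in rec_tf.counts.items():
                n_neg = sum(r.significant and r.sign == "negative"
                            for r in records
                            if r.source_id == rec_tf.tf_id
                            and r.genotype_id == geno)
                assert n_pos + n_neg == n

    def test_mixed_pathways_rejected(self, toy_screen_setup):
        m, catalog = toy_screen_setup
        records = screen_pathway(m, catalog, "ascorbate", ScreenConfig(min_rpkm=1.0))
        other = [r.__class__(**{**r.__dict__, "pathway": "carotenoid"})
                 for r in records[:1]]
        with pytest.raises(ValueError, match="mix"):
            summarize_tf(records + other)

    def _row(self, tf, counts):
        return TFSummaryRow(tf, "", "carotenoid", counts)

    def test_selection_rules(self):
        rows = [
            self._row("TF_a", {"AC": (9, 9), "HG6-61": (6, 5)}),
            self._row("TF_b", {"AC": (16, 10), "HG6-61": (3, 3)}),
            self._row("TF_c", {"AC": (5, 5), "HG6-61": (5, 0)}),
        ]
        both = select_candidates(rows, min_count=5, require_both=True)
        assert [r.tf_id for r in both] == ["TF_a", "TF_c"]
        either = select_candidates(rows, min_count=5, require_both=False)
        assert [r.tf_id for r in either] == ["TF_b", "TF_a", "TF_c"]
        assert select_candidates(rows, 0, True) == sorted(
            rows, key=lambda r: (-r.max_count(), r.tf_id))
        with pytest.raises(ValueError):
            select_candidates(rows, -1)


class TestCrossDataset:
    def test_identical_dataset_reproduces_counts(self, toy_screen_setup):
        m, catalog = toy_screen_setup
        cfg = ScreenConfig(min_rpkm=1.0)
        rows = summarize_tf(screen_pathway(m, catalog, "ascorbate", cfg), catalog)
        clone = ExpressionMatrix("Heinz", m.axis, m.data.copy())
        table = cross_dataset_validate(rows, [clone], catalog, "ascorbate", cfg)
        assert (table["AC_n_correlated"] == table["Heinz_n_correlated"]).all()
        assert table.loc["TF1", "significant_in_all"]
        assert not table.loc["TF2", "significant_in_all"]

    def test_no_extras_returns_primary(self, toy_screen_setup):
        m, catalog = toy_screen_setup
        cfg = ScreenConfig(min_rpkm=1.0)
        rows = summarize_tf(screen_pathway(m, catalog, "ascorbate", cfg), catalog)
        table = cross_dataset_validate(rows, [], catalog, "ascorbate", cfg)
        assert table.loc["TF1", "AC_n_correlated"] == 3

    def test_disjoint_ids_error(self, toy_screen_setup):
        m, catalog = toy_screen_setup
        cfg = ScreenConfig(min_rpkm=1.0)
        rows = summarize_tf(screen_pathway(m, catalog, "ascorbate", cfg), catalog)
        axis = m.axis
        alien = ExpressionMatrix("X", axis, pd.DataFrame(
            np.ones((2, 7)) * 10, index=["zz1", "zz2"],
            columns=list(axis.stages)))
        with pytest.raises(ValueError, match="shares no gene ids"):
            cross_dataset_validate(rows, [alien], catalog, "ascorbate", cfg)

    def test_stage_permutation_destroys_significance(self):
        """Independently permuting each gene's stages leaves only
        chance-level correlation in the validation dataset."""
        rng = np.random.default_rng(3)
        axis = StageAxis()
        tf_ids = [f"TF{i}" for i in range(30)]
        sg_ids = [f"SG{i}" for i in range(10)]
        shared = rng.uniform(0, 1, 7)
        rows_data = [10 + 40 * shared + rng.normal(0, 0.5, 7)
                     for _ in range(40)]
        data = pd.DataFrame(rows_data, index=tf_ids + sg_ids,
                            columns=list(axis.stages))
        m = ExpressionMatrix("AC", axis, data)
        catalog = GeneCatalog(pathways={"p": sg_ids}, tf_ids=tf_ids)
        cfg = ScreenConfig(min_rpkm=0.0, r_threshold=0.754)
        primary = screen_pathway(m, catalog, "p", cfg)
        assert np.mean([r.significant for r in primary]) > 0.9
        permuted = data.copy()
        for g in permuted.index:
            permuted.loc[g] = rng.permutation(permuted.loc[g].to_numpy())
        mp = ExpressionMatrix("perm", axis, permuted)
        null = screen_pathway(mp, catalog, "p", cfg)
        frac = np.mean([r.significant for r in null])
        se = math.sqrt(0.05 * 0.95 / len(null))
        assert frac <= 0.05 + 5 * se


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        p = np.array([0.001, 0.02, 0.04, 0.2, 0.5, 0.9])
        np.testing.assert_allclose(
            benjamini_hochberg(p),
            multipletests(p, method="fdr_bh")[1], atol=1e-12)
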